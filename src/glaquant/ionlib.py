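"""DIA/SWATH ion libraries and isolation-window geometry.

An ion library catalogues, per peptidoform precursor, the reference
retention time and the scored fragment transitions used to interrogate DIA
data.  This module builds SWATH isolation-window schemes, assigns
precursors to windows, and detects *conflict groups*: peptidoforms whose
precursors fall in the same isolation window and elute at similar retention
time, so their transition signals cannot be separated and the variants must
be quantified together as a merged class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

LIBRARY_COLUMNS = [
    "protein",
    "peptide_id",
    "sequence",
    "mods",
    "precursor_mz",
    "charge",
    "rt",
    "confidence",
    "fragment",
    "fragment_mz",
    "rel_intensity",
]


@dataclass(frozen=True)
class SwathScheme:
    """An ordered list of [low, high) isolation windows covering an m/z
    range, generated from a fixed width and stride (stride < width gives
    overlapping edges)."""

    windows: tuple[tuple[float, float], ...]
    width: float
    stride: float
    start: float
    end: float

    def __len__(self) -> int:
        return len(self.windows)


def build_scheme(start: float, end: float, width: float, stride: float) -> SwathScheme:
    """Deterministic window list: window i is [start + i*stride,
    min(start + i*stride + width, end)); windows are emitted while their low
    edge lies below end, and the last window is clipped at end."""
    if end <= start:
        raise ValueError("end must exceed start")
    if width <= 0:
        raise ValueError("window width must be positive")
    if not (0 < stride <= width):
        raise ValueError("stride must satisfy 0 < stride <= width")
    windows = []
    low = start
    while low < end:
        windows.append((low, min(low + width, end)))
        low += stride
    return SwathScheme(tuple(windows), width, stride, start, end)


#: The study's default global DIA geometry: nominal 26 m/z windows with
#: 1 m/z overlap across 400-1250 m/z, first edge at 399.5.
DEFAULT_SCHEME = (399.5, 1250.0, 26.0, 25.0)
#: Narrow-window geometry used for derivatized GLA peptides.
GLA_SCHEME = (400.0, 917.0, 6.2, 6.2)


def assign_windows(mz: float, scheme: SwathScheme) -> list[int]:
    """Indices of every window whose [low, high) interval contains mz —
    one window, or two inside an overlap strip.  m/z outside the scheme
    range returns an empty list with a warning."""
    hits = [i for i, (lo, hi) in enumerate(scheme.windows) if lo <= mz < hi]
    if not hits:
        warnings.warn(f"m/z {mz} outside scheme range [{scheme.start}, {scheme.end})")
    return hits


@dataclass(frozen=True)
class IonLibraryEntry:
    """One peptidoform precursor with its scored transitions."""

    peptide_id: str
    sequence: str
    mods: str
    precursor_mz: float
    charge: int
    rt: float
    confidence: float
    protein: str
    transitions: tuple[tuple[str, float, float], ...]  # (label, m/z, rel. intensity)

    def __post_init__(self):
        if not self.transitions:
            raise ValueError(f"{self.peptide_id}: entry needs at least one transition")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"{self.peptide_id}: confidence {self.confidence} not in [0, 1]")


@dataclass(frozen=True)
class ConflictGroup:
    """Entries sharing an isolation window within an RT tolerance; their
    signals are pooled and reported as one merged peptidoform class."""

    members: tuple[str, ...]  # peptide_ids, sorted
    shared_windows: tuple[int, ...]
    rt_span: tuple[float, float]

    @property
    def merged_id(self) -> str:
        return "+".join(self.members)


def detect_conflicts(
    entries: list[IonLibraryEntry],
    scheme: SwathScheme,
    rt_tolerance: float = 1.0,
) -> list[ConflictGroup]:
    """Maximal groups of entries that are pairwise linked by sharing at
    least one isolation window and |ΔRT| <= rt_tolerance (connected
    components of the co-isolation graph); singletons are excluded.  The
    result is independent of input order."""
    items = sorted(entries, key=lambda e: e.peptide_id)
    wins = [set(assign_windows(e.precursor_mz, scheme)) for e in items]
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if wins[i] & wins[j] and abs(items[i].rt - items[j].rt) <= rt_tolerance:
                parent[find(i)] = find(j)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)

    groups = []
    for idxs in comps.values():
        if len(idxs) < 2:
            continue
        shared = set.intersection(*(wins[i] for i in idxs)) or set().union(
            *(wins[i] for i in idxs)
        )
        rts = [items[i].rt for i in idxs]
        groups.append(
            ConflictGroup(
                members=tuple(sorted(items[i].peptide_id for i in idxs)),
                shared_windows=tuple(sorted(shared)),
                rt_span=(min(rts), max(rts)),
            )
        )
    return sorted(groups, key=lambda g: g.members)


def conflict_class_map(groups: list[ConflictGroup]) -> dict[str, str]:
    """peptide_id -> merged class id (members of a group map to the group's
    merged id; everything else maps to itself at lookup time)."""
    out = {}
    for g in groups:
        for m in g.members:
            out[m] = g.merged_id
    return out


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------

def write_library(entries: list[IonLibraryEntry], path) -> None:
    rows = []
    for e in entries:
        for label, mz, inten in e.transitions:
            rows.append(
                {
                    "protein": e.protein,
                    "peptide_id": e.peptide_id,
                    "sequence": e.sequence,
                    "mods": e.mods or "-",
                    "precursor_mz": e.precursor_mz,
                    "charge": e.charge,
                    "rt": e.rt,
                    "confidence": e.confidence,
                    "fragment": label,
                    "fragment_mz": mz,
                    "rel_intensity": inten,
                }
            )
    pd.DataFrame(rows, columns=LIBRARY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_library(path, errors: list[str] | None = None) -> list[IonLibraryEntry]:
    """Read a transition-per-row TSV library.

    Malformed rows (bad numbers, confidence outside [0, 1]) are skipped and
    reported, with 1-based data line numbers, into the optional `errors`
    list; well-formed rows still load.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"library {path}: missing columns {missing}")
    sink = errors if errors is not None else []
    good_rows = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = {
                "protein": row.protein,
                "peptide_id": row.peptide_id,
                "sequence": row.sequence,
                "mods": "" if row.mods in ("-", "", None) else row.mods,
                "precursor_mz": float(row.precursor_mz),
                "charge": int(row.charge),
                "rt": float(row.rt),
                "confidence": float(row.confidence),
                "fragment": row.fragment,
                "fragment_mz": float(row.fragment_mz),
                "rel_intensity": float(row.rel_intensity),
            }
            if not (0.0 <= rec["confidence"] <= 1.0):
                raise ValueError(f"confidence {rec['confidence']} not in [0, 1]")
            if rec["rel_intensity"] < 0:
                raise ValueError("negative relative intensity")
        except (TypeError, ValueError) as exc:
            sink.append(f"line {line_no}: {exc}")
            continue
        good_rows.append(rec)

    by_key: dict[str, dict] = {}
    for rec in good_rows:
        e = by_key.setdefault(
            rec["peptide_id"],
            {
                "peptide_id": rec["peptide_id"],
                "sequence": rec["sequence"],
                "mods": rec["mods"],
                "precursor_mz": rec["precursor_mz"],
                "charge": rec["charge"],
                "rt": rec["rt"],
                "confidence": rec["confidence"],
                "protein": rec["protein"],
                "transitions": [],
            },
        )
        e["transitions"].append((rec["fragment"], rec["fragment_mz"], rec["rel_intensity"]))
    return [
        IonLibraryEntry(**{**v, "transitions": tuple(v["transitions"])})
        for v in by_key.values()
    ]


def filter_by_confidence(
    entries: list[IonLibraryEntry], threshold: float = 0.99
) -> list[IonLibraryEntry]:
    """Library-import confidence gate (peptides below the identification
    confidence threshold are not interrogated)."""
    return [e for e in entries if e.confidence >= threshold]
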