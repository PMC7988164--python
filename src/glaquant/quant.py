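"""Label-free quantification from transition-level DIA tables.

The pipeline mirrors a targeted DIA extraction: per sample and peptidoform
class, the observed transition intensities lying inside the retention-time
window around the library reference are summed (optionally only the top-N
transitions); peptide measurements failing the FDR threshold are
eliminated; protein intensities are recomputed as the sum of passing
peptide intensities; and protein abundances are normalized to a reference
peptidoform (by default the trypsin autolysis peptide VATVSLPR), which
cancels per-sample loading and instrument-response factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import ionlib

TRYPSIN_REFERENCE = "trypsin|VATVSLPR"

PEPTIDE_COLUMNS = ["sample", "peptide_class", "intensity", "fdr", "n_transitions", "flag"]


@dataclass(frozen=True)
class QuantProfile:
    """Extraction preset: how many transitions to sum and how wide the RT
    window is (full width, minutes), with per-class overrides."""

    name: str
    max_transitions: int | None  # None = all transitions
    rt_window: float
    rt_window_overrides: dict[str, float] = field(default_factory=dict)

    def window_for(self, peptide_class: str) -> float:
        for key, win in self.rt_window_overrides.items():
            if key in peptide_class:
                return win
        return self.rt_window


#: Global protein quantification: six transitions per peptide, 2 min XIC window.
GLOBAL_PROFILE = QuantProfile("global", 6, 2.0)
#: PTM-variant quantification: all transitions, 2 min window.
PTM_PROFILE = QuantProfile("ptm", None, 2.0)
#: Derivatized GLA-peptide quantification: all transitions, 6 min window
#: except the early-eluting CSFEEAR variant family (2 min).
GLA_METHYL_PROFILE = QuantProfile("gla-methyl", None, 6.0, {"CSFEEAR": 2.0})

PROFILES = {p.name: p for p in (GLOBAL_PROFILE, PTM_PROFILE, GLA_METHYL_PROFILE)}


def sum_transitions(
    table: pd.DataFrame,
    library: list[ionlib.IonLibraryEntry],
    conflict_map: dict[str, str] | None = None,
    profile: QuantProfile = GLOBAL_PROFILE,
) -> pd.DataFrame:
    """Per sample x peptidoform class: sum of the top-N in-window
    transition intensities; members of a conflict group are pooled into
    the group's merged class.

    Entries observed in a sample whose transitions all fall outside the RT
    window are reported with intensity 0 and flag "no_in_window_transitions".
    """
    conflict_map = conflict_map or {}
    ref_rt = {e.peptide_id: e.rt for e in library}
    known = table["peptide_id"].isin(ref_rt)
    df = table[known].copy()
    df["ref_rt"] = df["peptide_id"].map(ref_rt)
    df["peptide_class"] = df["peptide_id"].map(lambda pid: conflict_map.get(pid, pid))
    df["window"] = df["peptide_class"].map(profile.window_for)
    df["in_window"] = (df["rt"] - df["ref_rt"]).abs() <= df["window"] / 2.0

    rows = []
    for (sample, cls), grp in df.groupby(["sample", "peptide_class"], sort=True):
        inside = grp[grp["in_window"]]
        if inside.empty:
            rows.append((sample, cls, 0.0, float(grp["fdr"].min()), 0, "no_in_window_transitions"))
            continue
        vals = inside["intensity"].sort_values(ascending=False)
        if profile.max_transitions is not None:
            vals = vals.iloc[: profile.max_transitions]
        rows.append((sample, cls, float(vals.sum()), float(inside["fdr"].min()), len(vals), ""))
    return pd.DataFrame(rows, columns=PEPTIDE_COLUMNS)


def filter_fdr(peptides: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Eliminate peptide measurements with FDR above the threshold.

    Idempotent; the number of removed measurements is attached as
    DataFrame attribute 'n_removed'."""
    out = peptides[peptides["fdr"] <= threshold].reset_index(drop=True)
    out.attrs["n_removed"] = len(peptides) - len(out)
    return out


def protein_intensity(
    peptides: pd.DataFrame,
    mapping: dict[str, str | set[str]],
    shared: str = "exclude",
) -> pd.DataFrame:
    """Protein intensity = sum of passing peptide intensities.

    mapping: peptide class -> protein id, or a set of ids for shared
    peptides.  shared="exclude" (default) drops shared peptides from the
    rollup; "all" credits every mapped protein.  Unmapped classes are
    excluded with a warning.  Proteins whose peptides were all filtered are
    absent from the output (not reported as zero)."""
    if shared not in ("exclude", "all"):
        raise ValueError(f"unknown shared-peptide policy {shared!r}")
    rows = []
    unmapped = []
    for row in peptides.itertuples(index=False):
        target = mapping.get(row.peptide_class)
        if target is None:
            unmapped.append(row.peptide_class)
            continue
        if isinstance(target, (set, frozenset, list, tuple)):
            if len(target) > 1 and shared == "exclude":
                continue
            for prot in target:
                rows.append((row.sample, prot, row.intensity))
        else:
            rows.append((row.sample, target, row.intensity))
    if unmapped:
        import warnings

        warnings.warn(f"{len(set(unmapped))} peptide classes had no protein mapping")
    df = pd.DataFrame(rows, columns=["sample", "protein", "intensity"])
    return (
        df.groupby(["sample", "protein"], as_index=False)["intensity"].sum()
        if not df.empty
        else df
    )


def normalize_to_reference(
    proteins: pd.DataFrame,
    peptides: pd.DataFrame,
    reference: str = TRYPSIN_REFERENCE,
) -> pd.DataFrame:
    """Normalized abundance = protein intensity / reference-peptidoform
    intensity in the same sample.

    Samples where the reference was not quantified (absent or zero) are
    flagged and excluded from the normalized output; the excluded sample
    ids are attached as attribute 'excluded_samples'."""
    ref = (
        peptides[(peptides["peptide_class"] == reference) & (peptides["intensity"] > 0)]
        .set_index("sample")["intensity"]
    )
    out = proteins.copy()
    out["norm_abundance"] = out.apply(
        lambda r: r["intensity"] / ref[r["sample"]] if r["sample"] in ref.index else float("nan"),
        axis=1,
    )
    excluded = sorted(set(proteins["sample"]) - set(ref.index))
    result = out.dropna(subset=["norm_abundance"]).reset_index(drop=True)
    result.attrs["excluded_samples"] = excluded
    return result


def quantify(
    table: pd.DataFrame,
    library: list[ionlib.IonLibraryEntry],
    scheme: ionlib.SwathScheme | None = None,
    profile: QuantProfile = GLOBAL_PROFILE,
    fdr_threshold: float = 0.01,
    rt_tolerance: float = 1.0,
    shared: str = "exclude",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience pipeline: conflict detection (when a scheme is given),
    transition summation, FDR filtering, protein rollup, and trypsin
    normalization.  Returns (passing peptides, proteins, normalized)."""
    conflict_map = {}
    if scheme is not None:
        groups = ionlib.detect_conflicts(library, scheme, rt_tolerance)
        conflict_map = ionlib.conflict_class_map(groups)
    peptides = sum_transitions(table, library, conflict_map, profile)
    passing = filter_fdr(peptides, fdr_threshold)
    mapping: dict[str, set[str]] = {}
    for e in library:
        cls = conflict_map.get(e.peptide_id, e.peptide_id)
        mapping.setdefault(cls, set()).add(e.protein)
    mapping_flat = {k: (next(iter(v)) if len(v) == 1 else v) for k, v in mapping.items()}
    proteins = protein_intensity(passing, mapping_flat, shared=shared)
    normalized = (
        normalize_to_reference(proteins, passing)
        if (passing["peptide_class"] == TRYPSIN_REFERENCE).any()
        else proteins.assign(norm_abundance=float("nan"))
    )
    return passing, proteins, normalized
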