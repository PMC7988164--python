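"""Monoisotopic mass calculus for peptidoforms.

A *peptidoform* is a peptide sequence plus a set of localized (or, for
count-based variant families such as methyl esters, unlocalized)
modifications, including glycan compositions.  This module computes neutral
masses, precursor and fragment m/z values, glycopeptide Y ions and immonium
ions, performs in-silico protease digestion, and enumerates the
γ-carboxyform and methyl-ester variant families needed to quantify
GLA-domain carboxylation with and without methanolic derivatization.

All masses are monoisotopic, in Da; m/z values assume protonation in
positive mode.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .constants import (
    CO,
    IMMONIUM_OFFSET,
    LOSS_CO2,
    LOSS_SO3,
    MONOSACCHARIDE_MASS,
    PROTON,
    RESIDUE_MASS,
    WATER,
    Y_ION_ATTACH_ORDER,
)

N_TERM = "N-term"
C_TERM = "C-term"


@dataclass(frozen=True)
class ModificationDef:
    """A fixed-mass covalent modification.

    targets are residue one-letter codes and/or the tokens "N-term"/"C-term";
    an empty target set means the modification may sit anywhere (used for
    unlocalized count-based variants such as methyl esters on free
    carboxyls).
    """

    name: str
    delta_mass: float
    targets: frozenset[str] = frozenset()
    max_per_site: int = 1

    def __post_init__(self):
        if not (self.delta_mass == self.delta_mass and abs(self.delta_mass) < 1e6):
            raise ValueError(f"non-finite delta mass for {self.name!r}")


@dataclass(frozen=True)
class GlycanComposition:
    """A glycan as a multiset of monosaccharide residues (composition only,
    no topology)."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "GlycanComposition":
        for name, n in d.items():
            if name not in MONOSACCHARIDE_MASS:
                raise ValueError(f"unknown monosaccharide {name!r}")
            if n < 0:
                raise ValueError(f"negative count for {name}: {n}")
        items = tuple(sorted((k, v) for k, v in d.items() if v > 0))
        return cls(items)

    @classmethod
    def parse(cls, text: str) -> "GlycanComposition":
        """Parse compact composition strings such as 'HexNAc1Hex1NeuAc2'."""
        if text == "":
            return cls(())
        pos = 0
        counts: dict[str, int] = {}
        for m in re.finditer(r"([A-Za-z]+?)(\d+)", text):
            if m.start() != pos:
                raise ValueError(f"cannot parse glycan composition {text!r}")
            name, n = m.group(1), int(m.group(2))
            if name not in MONOSACCHARIDE_MASS:
                raise ValueError(f"unknown monosaccharide {name!r} in {text!r}")
            counts[name] = counts.get(name, 0) + n
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse glycan composition {text!r}")
        return cls.from_dict(counts)

    @property
    def mass(self) -> float:
        return sum(MONOSACCHARIDE_MASS[k] * v for k, v in self.counts)

    @property
    def nominal(self) -> int:
        """Integer-rounded mass, the '+656'/'+947' shorthand."""
        return round(self.mass)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __str__(self) -> str:
        return "".join(f"{k}{v}" for k, v in self.counts)

    def monosaccharides(self) -> list[str]:
        """Flat list of residues in Y-ion attachment order (core first)."""
        d = self.as_dict()
        out = []
        for name in Y_ION_ATTACH_ORDER:
            out.extend([name] * d.get(name, 0))
        return out


Mod = ModificationDef | GlycanComposition
Site = int | str | None  # 1-based position, "N-term"/"C-term", or None (unlocalized)


def glycan_mass(g: GlycanComposition) -> float:
    """Monoisotopic mass of a glycan composition (count-weighted sum)."""
    return g.mass


# ---------------------------------------------------------------------------
# Default modification registry
# ---------------------------------------------------------------------------

GAMMA_CARBOXY = ModificationDef("gamma-carboxy", 43.98983, frozenset("E"))
METHYL = ModificationDef("methyl", 14.01565, frozenset({"D", "E", C_TERM}))
PROPIONAMIDE = ModificationDef("propionamide", 71.03711, frozenset("C"))
OXIDATION = ModificationDef("oxidation", 15.99491, frozenset("D"))
DEAMIDATION = ModificationDef("deamidation", 0.98402, frozenset("NQ"))
SULFATION = ModificationDef("sulfation", 79.95682, frozenset("Y"))
PHOSPHO = ModificationDef("phospho", 79.96633, frozenset("YST"))

DEFAULT_MODIFICATIONS: dict[str, ModificationDef] = {
    m.name: m
    for m in (
        GAMMA_CARBOXY,
        METHYL,
        PROPIONAMIDE,
        OXIDATION,
        DEAMIDATION,
        SULFATION,
        PHOSPHO,
    )
}

#: Residues that may carry a glycan composition.
GLYCAN_TARGETS = frozenset("STN")


# ---------------------------------------------------------------------------
# Peptidoform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peptidoform:
    """A peptide sequence plus its modifications.

    mods is a tuple of (site, mod) pairs; site is a 1-based position within
    the sequence, "N-term"/"C-term", or None for unlocalized count-based
    modifications (methyl esters distributed over free carboxyl groups).
    provenance: protein id and 1-based start/end in the mature protein.
    """

    sequence: str
    mods: tuple[tuple[Site, Mod], ...] = ()
    protein_id: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        for ch in self.sequence:
            if ch not in RESIDUE_MASS:
                raise ValueError(f"unknown residue letter {ch!r} in {self.sequence!r}")
        n = len(self.sequence)
        for site, mod in self.mods:
            if site is None:
                continue
            if site in (N_TERM, C_TERM):
                continue
            if not isinstance(site, int) or not (1 <= site <= n):
                raise ValueError(f"mod site {site!r} outside [1, {n}]")
            residue = self.sequence[site - 1]
            if isinstance(mod, GlycanComposition):
                if residue not in GLYCAN_TARGETS:
                    raise ValueError(
                        f"glycan not allowed on residue {residue} at {site}"
                    )
            elif mod.targets and residue not in mod.targets:
                raise ValueError(
                    f"{mod.name} not allowed on residue {residue} at position {site}"
                )

    def with_mods(self, *extra: tuple[Site, Mod]) -> "Peptidoform":
        return replace(self, mods=self.mods + tuple(extra))

    def carboxyl_count(self) -> int:
        """Number of γ-carboxyglutamic acids carried."""
        return sum(
            1
            for _, m in self.mods
            if isinstance(m, ModificationDef) and m.name == GAMMA_CARBOXY.name
        )

    def methyl_count(self) -> int:
        return sum(
            1
            for _, m in self.mods
            if isinstance(m, ModificationDef) and m.name == METHYL.name
        )

    def glycans(self) -> list[tuple[Site, GlycanComposition]]:
        return [(s, m) for s, m in self.mods if isinstance(m, GlycanComposition)]


def neutral_mass(p: Peptidoform) -> float:
    """Monoisotopic neutral mass: Σ residue masses + water + Σ mod deltas."""
    m = sum(RESIDUE_MASS[ch] for ch in p.sequence) + WATER
    for _, mod in p.mods:
        m += mod.mass if isinstance(mod, GlycanComposition) else mod.delta_mass
    return m


def precursor_mz(p: Peptidoform, z: int) -> float:
    """m/z of the z-fold protonated peptidoform."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (neutral_mass(p) + z * PROTON) / z


def mass_to_mz(neutral: float, z: int) -> float:
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (neutral + z * PROTON) / z


def mz_to_mass(mz: float, z: int) -> float:
    """Neutral mass recovered from an observed m/z at charge z."""
    return z * (mz - PROTON)


def immonium_mz(residue: str, mods: list[ModificationDef] = ()) -> float:
    """Immonium ion m/z of a single (possibly modified) residue."""
    if len(residue) != 1 or residue not in RESIDUE_MASS:
        raise ValueError(f"unknown residue {residue!r}")
    return RESIDUE_MASS[residue] + sum(m.delta_mass for m in mods) + IMMONIUM_OFFSET


# ---------------------------------------------------------------------------
# Fragment ions
# ---------------------------------------------------------------------------

def _site_mass(mod: Mod) -> float:
    return mod.mass if isinstance(mod, GlycanComposition) else mod.delta_mass


def fragment_ions(
    p: Peptidoform,
    series: str = "by",
    z: int = 1,
    neutral_loss: str | None = None,
) -> list[tuple[str, float]]:
    """Full b/y (optionally a) fragment ladders with localized mods included.

    neutral_loss: "SO3" or "CO2" subtracts the loss from every fragment that
    spans a sulfation / γ-carboxylation site respectively (one loss per
    fragment, matching the dominant CID behaviour of sulfo- and
    Gla-peptides).  Unlocalized mods cannot be placed on partial fragments
    and are ignored in the ladders.
    """
    if z not in (1, 2):
        raise ValueError(f"fragment charge must be 1 or 2, got {z}")
    for s in series:
        if s not in "aby":
            raise ValueError(f"unsupported ion series {s!r}")

    n = len(p.sequence)
    site_extra = [0.0] * (n + 2)  # index 0 = N-term, n+1 = C-term
    loss_site = [False] * (n + 2)
    loss_name = {"SO3": (SULFATION.name, LOSS_SO3), "CO2": (GAMMA_CARBOXY.name, LOSS_CO2)}
    target_mod, loss_mass = loss_name.get(neutral_loss, (None, 0.0))
    if neutral_loss is not None and target_mod is None:
        raise ValueError(f"unsupported neutral loss {neutral_loss!r}")

    for site, mod in p.mods:
        if site is None:
            continue
        idx = 0 if site == N_TERM else (n + 1 if site == C_TERM else site)
        site_extra[idx] += _site_mass(mod)
        if (
            target_mod is not None
            and isinstance(mod, ModificationDef)
            and mod.name == target_mod
        ):
            loss_site[idx] = True

    prefix = [0.0] * (n + 1)  # prefix[i] = mass of residues 1..i incl. mods
    prefix_has_loss = [False] * (n + 1)
    acc, has = site_extra[0], loss_site[0]
    for i in range(1, n + 1):
        acc += RESIDUE_MASS[p.sequence[i - 1]] + site_extra[i]
        has = has or loss_site[i]
        prefix[i] = acc
        prefix_has_loss[i] = has
    total = prefix[n] + site_extra[n + 1]

    out: list[tuple[str, float]] = []
    for i in range(1, n + 1):
        if "b" in series and i < n:
            m = prefix[i] - (loss_mass if prefix_has_loss[i] else 0.0)
            out.append((f"b{i}" + ("++" if z == 2 else ""), (m + z * PROTON) / z))
        if "a" in series and i < n:
            m = prefix[i] - CO - (loss_mass if prefix_has_loss[i] else 0.0)
            out.append((f"a{i}" + ("++" if z == 2 else ""), (m + z * PROTON) / z))
        if "y" in series:
            suffix = total - prefix[n - i]
            # a y_i fragment spans residues n-i+1..n plus the C terminus
            has_l = _loss_in_suffix(loss_site, n - i, n)
            m = suffix + WATER - (loss_mass if has_l else 0.0)
            out.append((f"y{i}" + ("++" if z == 2 else ""), (m + z * PROTON) / z))
    return out


def _loss_in_suffix(loss_site: list[bool], start_excl: int, n: int) -> bool:
    return any(loss_site[j] for j in range(start_excl + 1, n + 2))


def glycopeptide_y_ions(p: Peptidoform) -> list[tuple[str, float]]:
    """Y-ion series of a glycopeptide: Y0 is the singly protonated peptide
    stripped of all glycans (other mods retained); Y_k re-attaches k
    monosaccharides, core HexNAc first, then Hex, then distal residues.

    Returns an empty list when the peptidoform carries no glycan.
    """
    glycans = p.glycans()
    if not glycans:
        return []
    bare = replace(
        p, mods=tuple((s, m) for s, m in p.mods if not isinstance(m, GlycanComposition))
    )
    y0 = precursor_mz(bare, 1)
    residues: list[str] = []
    order = {name: i for i, name in enumerate(Y_ION_ATTACH_ORDER)}
    pooled: dict[str, int] = {}
    for _, g in glycans:
        for k, v in g.counts:
            pooled[k] = pooled.get(k, 0) + v
    for name in sorted(pooled, key=order.__getitem__):
        residues.extend([name] * pooled[name])

    out = [("Y0", y0)]
    acc = y0
    for k, name in enumerate(residues, start=1):
        acc += MONOSACCHARIDE_MASS[name]
        out.append((f"Y{k}", acc))
    return out


# ---------------------------------------------------------------------------
# Protease digestion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteaseRule:
    """Cleavage specificity: residues, side (C- or N-terminal of the
    residue), and an optional suppression residue on the far side (the
    classical trypsin 'not before Pro')."""

    name: str
    residues: frozenset[str]
    side: str = "C"  # "C": cleave after residue; "N": cleave before residue
    not_next_to: frozenset[str] = frozenset()

    def cleavage_sites(self, protein: str) -> list[int]:
        """0-based positions i such that the bond between protein[i-1] and
        protein[i] is cleaved (i in 1..len-1)."""
        sites = []
        for i in range(1, len(protein)):
            if self.side == "C":
                if protein[i - 1] in self.residues and protein[i] not in self.not_next_to:
                    sites.append(i)
            else:
                if protein[i] in self.residues and protein[i - 1] not in self.not_next_to:
                    sites.append(i)
        return sites


PROTEASES: dict[str, ProteaseRule] = {
    "trypsin": ProteaseRule("trypsin", frozenset("KR"), "C", frozenset("P")),
    "trypsin/p": ProteaseRule("trypsin/p", frozenset("KR"), "C"),
    "gluc": ProteaseRule("gluc", frozenset("E"), "C"),
    "aspn": ProteaseRule("aspn", frozenset("D"), "N"),
    "chymotrypsin": ProteaseRule("chymotrypsin", frozenset("FWYL"), "C", frozenset("P")),
}


def digest(
    protein: str,
    rule: ProteaseRule | str = "trypsin",
    max_missed: int = 0,
    protein_id: str | None = None,
    min_length: int = 1,
) -> list[Peptidoform]:
    """Fully specific in-silico digestion.

    Returns every peptide bounded by cleavage sites (or the protein termini)
    containing at most max_missed internal cleavage sites, each carrying
    1-based coordinates in the given protein.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    if isinstance(rule, str):
        try:
            rule = PROTEASES[rule.lower()]
        except KeyError:
            raise ValueError(f"unknown protease rule {rule!r}") from None
    bounds = [0] + rule.cleavage_sites(protein) + [len(protein)]
    out = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            lo, hi = bounds[i], bounds[j]
            if hi - lo >= min_length:
                out.append(
                    Peptidoform(
                        protein[lo:hi],
                        protein_id=protein_id,
                        start=lo + 1,
                        end=hi,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Variant family enumeration
# ---------------------------------------------------------------------------

def enumerate_carboxyforms(
    p: Peptidoform, gla_sites: list[int]
) -> list[Peptidoform]:
    """One peptidoform per γ-carboxylation count k = 0..len(gla_sites).

    Quantification treats carboxyforms by count, not site combination, so a
    single representative (the first k sites in ascending order) is emitted
    per k; masses are identical across same-k site combinations.
    """
    sites = sorted(set(gla_sites))
    for s in sites:
        if not (1 <= s <= len(p.sequence)) or p.sequence[s - 1] != "E":
            raise ValueError(f"gla_site {s} is not a glutamate in {p.sequence!r}")
    forms = []
    for k in range(len(sites) + 1):
        extra = tuple((s, GAMMA_CARBOXY) for s in sites[:k])
        forms.append(p.with_mods(*extra))
    return forms


def free_carboxyl_inventory(p: Peptidoform, c_term_free: bool = True) -> int:
    """Number of free carboxyl groups available for methyl esterification:
    one per Asp side chain, one per non-carboxylated Glu side chain, two per
    γ-carboxyglutamate, plus the C-terminal carboxyl when free."""
    n_d = p.sequence.count("D")
    n_e = p.sequence.count("E")
    n_gla = p.carboxyl_count()
    return n_d + (n_e - n_gla) + 2 * n_gla + (1 if c_term_free else 0)


def enumerate_methylforms(
    p: Peptidoform, cap: int = 6, c_term_free: bool = True
) -> list[Peptidoform]:
    """Methyl-ester variants with 0..min(inventory, cap) methyl groups.

    Methanolic derivatization esterifies free carboxyls non-specifically, so
    methyl counts are modeled as unlocalized (site None) modifications."""
    top = min(free_carboxyl_inventory(p, c_term_free), cap)
    return [
        p.with_mods(*((None, METHYL),) * m) for m in range(top + 1)
    ]


# ---------------------------------------------------------------------------
# Modification-string round trip (used by the ion-library TSV format)
# ---------------------------------------------------------------------------

def format_mods(mods: tuple[tuple[Site, Mod], ...]) -> str:
    """Serialize mods as 'site:name' pairs joined by ';'.

    Glycans use 'site:glycan:COMPOSITION'; unlocalized sites use '?'."""
    parts = []
    for site, mod in mods:
        s = "?" if site is None else str(site)
        if isinstance(mod, GlycanComposition):
            parts.append(f"{s}:glycan:{mod}")
        else:
            parts.append(f"{s}:{mod.name}")
    return ";".join(parts)


def parse_mods(
    text: str, registry: dict[str, ModificationDef] | None = None
) -> tuple[tuple[Site, Mod], ...]:
    registry = registry or DEFAULT_MODIFICATIONS
    if not text or text == "-":
        return ()
    out: list[tuple[Site, Mod]] = []
    for part in text.split(";"):
        fields = part.split(":")
        if len(fields) not in (2, 3):
            raise ValueError(f"malformed modification token {part!r}")
        raw_site = fields[0]
        site: Site
        if raw_site == "?":
            site = None
        elif raw_site in (N_TERM, C_TERM):
            site = raw_site
        else:
            site = int(raw_site)
        if len(fields) == 3:
            if fields[1] != "glycan":
                raise ValueError(f"malformed modification token {part!r}")
            out.append((site, GlycanComposition.parse(fields[2])))
        else:
            name = fields[1]
            if name not in registry:
                raise ValueError(f"unknown modification {name!r}")
            out.append((site, registry[name]))
    return tuple(out)


def load_modifications(path) -> dict[str, ModificationDef]:
    """Load a modification registry from key-value text (YAML mapping:
    name -> {delta_mass, targets, max_per_site}); entries extend or
    override the shipped defaults."""
    import yaml

    data = yaml.safe_load(open(path)) or {}
    registry = dict(DEFAULT_MODIFICATIONS)
    for name, spec in data.items():
        registry[name] = ModificationDef(
            name=name,
            delta_mass=float(spec["delta_mass"]),
            targets=frozenset(spec.get("targets", ())),
            max_per_site=int(spec.get("max_per_site", 1)),
        )
    return registry


def read_fasta(path) -> dict[str, str]:
    """Protein sequences keyed by record id (1-based mature-protein
    coordinates are taken from the record as given)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
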