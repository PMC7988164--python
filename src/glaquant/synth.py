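"""Synthetic fed-batch bioprocess time courses rendered as DIA data.

The generator emulates the statistical structure the downstream analysis
assumes: two fed-batch bioreactor conditions run for a fixed number of
days, during which the recombinant product accumulates in the supernatant,
secreted host-cell proteins (HCPs) accumulate with it, and intracellular
HCPs are released in proportion to cumulative viability loss.  Product
peptide families carry per-day intensity shares over their variant classes
(γ-carboxylation counts with methyl-ester sub-variants, glycoforms,
oxidation states), and an anion-exchange purification step re-weights those
shares by a per-variant retention probability that typically increases with
carboxyl count.  States are rendered into transition-level observations
against an ion library under multiplicative log-normal noise with
below-threshold censoring, carrying FDR scores that separate rendered-true
entries from injected decoys.

Everything is deterministic given the scenario and a seed; all synthetic
sequences and trajectories are fixture choices, not measured values.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import chem, ionlib

PRODUCT = "rFIX"
TRYPSIN = "trypsin"
TRYPSIN_CLASS = "trypsin|VATVSLPR"
METHYL_CAP = 6
METHYL_PROB = 0.8  # per-carboxyl esterification probability in derivatized samples


# ---------------------------------------------------------------------------
# Scenario definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyDef:
    """A product peptide family whose variant classes share intensity.

    Either a γ-carboxyform family (gla_sites non-empty; classes are
    carboxyl-count × methyl-count combinations when derivatized) or a PTM
    variant family (explicit (label, modification-string) variants).
    retention: purification retention probability per class index
    (carboxyl count k, or variant position)."""

    name: str
    sequence: str
    gla_sites: tuple[int, ...] = ()
    variants: tuple[tuple[str, str], ...] = ()
    retention: tuple[float, ...] = ()
    charge: int = 2
    derivatized: bool = False
    protein: str = PRODUCT

    @property
    def n_classes(self) -> int:
        return len(self.gla_sites) + 1 if self.gla_sites else len(self.variants)


@dataclass(frozen=True)
class Condition:
    """Per-bioreactor trajectories.

    secretion: per-day product secretion increments (arbitrary units).
    viability: viable fraction per day.
    *_dists: family name -> (day-1 distribution, final-day distribution)
    over the family's class axis (k for carboxyforms, variant order
    otherwise); intermediate days interpolate linearly and renormalize."""

    name: str
    secretion: tuple[float, ...]
    viability: tuple[float, ...]
    lysis_coefficient: float
    family_dists: dict[str, tuple[tuple[float, ...], tuple[float, ...]]]
    hcp_secretion_scale: float = 1.0

    def __post_init__(self):
        if any(not (0.0 <= v <= 1.0) for v in self.viability):
            raise ValueError("viability values must lie in [0, 1]")
        if any(s < 0 for s in self.secretion):
            raise ValueError("secretion increments must be non-negative")
        for fam, (d0, d1) in self.family_dists.items():
            for d in (d0, d1):
                if any(x < 0 for x in d) or abs(sum(d) - 1.0) > 1e-9:
                    raise ValueError(f"{fam}: distribution must be a probability vector")


@dataclass(frozen=True)
class BioprocessScenario:
    n_days: int
    conditions: tuple[Condition, ...]
    families: tuple[FamilyDef, ...]
    hcp_panel: tuple[tuple[str, float, bool, bool], ...]  # (id, baseline, secreted, ca-binder)
    trypsin_level: float = 1000.0
    product_concentration_factor: float = 5.0
    carryover: dict[str, float] = field(
        default_factory=lambda: {"secreted": 0.02, "ca_binder": 0.2, "intracellular": 0.05}
    )
    seed: int = 0

    def condition(self, name: str) -> Condition:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass(frozen=True)
class NoiseModel:
    sigma: float = 0.2           # log-normal sd (natural log scale)
    baseline: float = 0.0        # additive offset per transition
    censor_limit: float = 1.0    # transitions below this intensity are dropped
    true_fdr_max: float = 0.005  # FDR scores of rendered-true entries
    decoy_fdr_min: float = 0.02  # FDR scores of injected decoys exceed this

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class SampleState:
    """Ground truth for one sample: protein abundances and within-family
    intensity shares per peptidoform class (shares sum to 1 per family)."""

    sample_id: str
    condition: str
    day: int | str  # 1..n_days, or "purified"
    protein_abundance: dict[str, float]
    class_share: dict[str, float]


# ---------------------------------------------------------------------------
# Class enumeration
# ---------------------------------------------------------------------------

def _methyl_split(inventory: int, cap: int = METHYL_CAP) -> dict[int, float]:
    """Share of a carboxyform's intensity carried by each methyl count:
    binomial esterification over the free-carboxyl inventory, mass above
    the cap collapsed onto the cap."""
    top = min(inventory, cap)
    probs = {m: float(binom.pmf(m, inventory, METHYL_PROB)) for m in range(top)}
    probs[top] = float(1.0 - sum(probs.values()))
    return probs


def family_classes(fam: FamilyDef) -> list[dict]:
    """Variant classes of a family: class_id, modification string, carboxyl
    count k, methyl count, and the family-axis index used for distribution
    and retention lookups."""
    rows = []
    if fam.gla_sites:
        base = chem.Peptidoform(fam.sequence)
        for k, form in enumerate(chem.enumerate_carboxyforms(base, list(fam.gla_sites))):
            if fam.derivatized:
                inv = chem.free_carboxyl_inventory(form)
                for m, frac in _methyl_split(inv).items():
                    mods = form.mods + ((None, chem.METHYL),) * m
                    rows.append(
                        dict(
                            class_id=f"{fam.name}|k{k}m{m}",
                            family=fam.name,
                            protein=fam.protein,
                            sequence=fam.sequence,
                            mods=chem.format_mods(mods),
                            charge=fam.charge,
                            k=k,
                            methyls=m,
                            axis=k,
                            within=frac,
                        )
                    )
            else:
                rows.append(
                    dict(
                        class_id=f"{fam.name}|k{k}",
                        family=fam.name,
                        protein=fam.protein,
                        sequence=fam.sequence,
                        mods=chem.format_mods(form.mods),
                        charge=fam.charge,
                        k=k,
                        methyls=0,
                        axis=k,
                        within=1.0,
                    )
                )
    else:
        for idx, (label, mods) in enumerate(fam.variants):
            rows.append(
                dict(
                    class_id=f"{fam.name}|{label}",
                    family=fam.name,
                    protein=fam.protein,
                    sequence=fam.sequence,
                    mods="" if mods in ("-", "") else mods,
                    charge=fam.charge,
                    k=None,
                    methyls=0,
                    axis=idx,
                    within=1.0,
                )
            )
    return rows


def class_table(sc: BioprocessScenario) -> pd.DataFrame:
    """All peptidoform classes of the scenario (product families, HCP
    peptides, and the trypsin reference), with annotation columns."""
    rows: list[dict] = []
    for fam in sc.families:
        rows.extend(family_classes(fam))
    for pid, _baseline, _secreted, _ca in sc.hcp_panel:
        for i, share in enumerate((0.6, 0.4)):
            rows.append(
                dict(
                    class_id=f"{pid}|pep{i}",
                    family=pid,
                    protein=pid,
                    sequence=None,
                    mods="",
                    charge=2,
                    k=None,
                    methyls=0,
                    axis=i,
                    within=share,
                )
            )
    rows.append(
        dict(
            class_id=TRYPSIN_CLASS,
            family=TRYPSIN,
            protein=TRYPSIN,
            sequence="VATVSLPR",
            mods="",
            charge=2,
            k=None,
            methyls=0,
            axis=0,
            within=1.0,
        )
    )
    return pd.DataFrame(rows)


def _interp_dist(start, end, day: int, n_days: int) -> np.ndarray:
    t = 0.0 if n_days == 1 else (day - 1) / (n_days - 1)
    d = (1 - t) * np.asarray(start, float) + t * np.asarray(end, float)
    return d / d.sum()


def family_truth(sc: BioprocessScenario, condition: str, day: int) -> dict[str, np.ndarray]:
    """Per-family class-axis distribution at a given day (the simulation
    ground truth the stoichiometry module should recover)."""
    cond = sc.condition(condition)
    out = {}
    for fam in sc.families:
        d0, d1 = cond.family_dists[fam.name]
        out[fam.name] = _interp_dist(d0, d1, day, sc.n_days)
    return out


# ---------------------------------------------------------------------------
# Time course and purification
# ---------------------------------------------------------------------------

def simulate_timecourse(sc: BioprocessScenario) -> list[SampleState]:
    """One SampleState per condition x day.

    Product and secreted-HCP abundances accumulate (cumulative sums of
    per-day secretion); intracellular HCPs appear in proportion to the
    cumulative viability loss scaled by the lysis coefficient.
    """
    states = []
    table = class_table(sc)
    for cond in sc.conditions:
        if len(cond.secretion) != sc.n_days or len(cond.viability) != sc.n_days:
            raise ValueError(f"{cond.name}: trajectories must have length n_days")
        product = np.cumsum(cond.secretion)
        v0 = cond.viability[0]
        for day in range(1, sc.n_days + 1):
            loss = max(0.0, v0 - cond.viability[day - 1])
            abundance = {PRODUCT: float(product[day - 1]), TRYPSIN: sc.trypsin_level}
            for pid, baseline, secreted, _ca in sc.hcp_panel:
                if secreted:
                    # secreted HCPs accumulate alongside the product
                    abundance[pid] = baseline * cond.hcp_secretion_scale * day / sc.n_days
                else:
                    abundance[pid] = baseline * cond.lysis_coefficient * loss
            shares = _state_shares(sc, table, cond, day)
            states.append(
                SampleState(
                    sample_id=f"{cond.name}_d{day:02d}",
                    condition=cond.name,
                    day=day,
                    protein_abundance=abundance,
                    class_share=shares,
                )
            )
    return states


def _state_shares(sc, table: pd.DataFrame, cond: Condition, day: int) -> dict[str, float]:
    dists = {
        fam.name: _interp_dist(*cond.family_dists[fam.name], day, sc.n_days)
        for fam in sc.families
    }
    shares = {}
    for row in table.itertuples(index=False):
        if row.family in dists:
            shares[row.class_id] = float(dists[row.family][row.axis] * row.within)
        else:
            shares[row.class_id] = float(row.within)
    return shares


def simulate_purification(final: SampleState, sc: BioprocessScenario) -> SampleState:
    """Anion-exchange purification of a final-day state.

    Within each product family the class shares are re-weighted by the
    family's retention probabilities (so a retention profile increasing in
    carboxyl count enriches high-k forms); the product is concentrated,
    while HCPs carry over with small category-dependent probabilities
    (elevated for calcium binders, which co-bind the resin).
    """
    if final.day == "purified":
        raise ValueError("state is already purified")
    table = class_table(sc)
    retmap = {fam.name: fam.retention for fam in sc.families}
    shares = dict(final.class_share)
    overall = {}
    for fam in sc.families:
        ret = np.asarray(retmap[fam.name], float)
        rows = table[table["family"] == fam.name]
        raw = np.array([final.class_share[r.class_id] * ret[r.axis] for r in rows.itertuples(index=False)])
        overall[fam.name] = raw.sum()
        if raw.sum() > 0:
            raw = raw / raw.sum()
        for r, s in zip(rows.itertuples(index=False), raw):
            shares[r.class_id] = float(s)

    abundance = {}
    product_ret = float(np.mean(list(overall.values()))) if overall else 1.0
    abundance[PRODUCT] = (
        final.protein_abundance[PRODUCT] * product_ret * sc.product_concentration_factor
    )
    abundance[TRYPSIN] = sc.trypsin_level
    for pid, _baseline, secreted, ca in sc.hcp_panel:
        key = "ca_binder" if ca else ("secreted" if secreted else "intracellular")
        abundance[pid] = final.protein_abundance[pid] * sc.carryover[key]
    return SampleState(
        sample_id=f"{final.condition}_purified",
        condition=final.condition,
        day="purified",
        protein_abundance=abundance,
        class_share=shares,
    )


# ---------------------------------------------------------------------------
# Ion library construction
# ---------------------------------------------------------------------------

def build_library(sc: BioprocessScenario, n_transitions: int = 6) -> list[ionlib.IonLibraryEntry]:
    """Deterministic ion library covering every scenario class.

    Product classes get theoretical precursor m/z and b/y transition m/z
    from their sequence and modifications; HCP stand-in peptides (synthetic,
    no concrete sequence) get hash-derived coordinates.  Reference RTs and
    relative intensities are drawn reproducibly from the scenario seed.
    """
    table = class_table(sc)
    entries = []
    for row in table.itertuples(index=False):
        rng = np.random.default_rng(
            (sc.seed * 1000003 + zlib.crc32(row.class_id.encode())) % (2**31)
        )
        rt = float(rng.uniform(5.0, 55.0))
        rel = np.sort(rng.uniform(0.2, 1.0, size=n_transitions))[::-1]
        if row.sequence:
            p = chem.Peptidoform(row.sequence, chem.parse_mods(row.mods))
            mz = chem.precursor_mz(p, row.charge)
            frags = chem.fragment_ions(p, "y", 1) + chem.fragment_ions(p, "b", 1)
            frags = [f for f in frags if f[1] >= 200.0] or frags
            chosen = frags[:n_transitions]
        else:
            mz = float(rng.uniform(420.0, 1200.0))
            chosen = [(f"y{i+3}", mz + 150.0 + 37.1 * i) for i in range(n_transitions)]
        transitions = tuple(
            (label, fmz, float(r)) for (label, fmz), r in zip(chosen, rel)
        )
        conf = 0.99 if row.class_id == TRYPSIN_CLASS else 0.999
        entries.append(
            ionlib.IonLibraryEntry(
                peptide_id=row.class_id,
                sequence=row.sequence or "",
                mods=row.mods,
                precursor_mz=float(mz),
                charge=int(row.charge),
                rt=rt,
                confidence=conf,
                protein=row.protein,
                transitions=transitions,
            )
        )
    return entries


def make_decoys(sc: BioprocessScenario, n: int = 10) -> list[ionlib.IonLibraryEntry]:
    """Spurious library entries used to exercise FDR filtering."""
    rng = np.random.default_rng(sc.seed + 77)
    out = []
    for i in range(n):
        mz = float(rng.uniform(420, 1200))
        out.append(
            ionlib.IonLibraryEntry(
                peptide_id=f"DECOY_{i:03d}",
                sequence="",
                mods="",
                precursor_mz=mz,
                charge=2,
                rt=float(rng.uniform(5, 55)),
                confidence=0.995,
                protein=f"DECOY_{i:03d}",
                transitions=tuple(
                    (f"y{j+3}", mz + 120 + 31.7 * j, float(rng.uniform(0.2, 1)))
                    for j in range(6)
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# DIA rendering
# ---------------------------------------------------------------------------

TRANSITION_COLUMNS = [
    "sample",
    "condition",
    "day",
    "replicate",
    "peptide_id",
    "protein",
    "fragment",
    "intensity",
    "rt",
    "fdr",
]


def render_dia(
    state: SampleState,
    library: list[ionlib.IonLibraryEntry],
    noise: NoiseModel,
    seed: int,
    replicate: int = 1,
    decoys: list[ionlib.IonLibraryEntry] = (),
) -> pd.DataFrame:
    """Render one sample into a transition table.

    Per transition: intensity = protein abundance x class share x library
    relative intensity x LogNormal(0, sigma) + baseline, censored below the
    limit.  Rendered-true entries get FDR scores below 0.01; decoys above.
    Library entries for classes absent from the state are skipped with a
    warning; scenario classes missing from the library are simply not
    rendered.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for e in library:
        share = state.class_share.get(e.peptide_id)
        if share is None:
            import warnings

            warnings.warn(f"library entry {e.peptide_id} not in sample state; skipped")
            continue
        abundance = state.protein_abundance.get(e.protein, 0.0)
        true_total = abundance * share
        fdr = float(rng.uniform(0.0, noise.true_fdr_max))
        relsum = sum(r for _, _, r in e.transitions)
        for label, fmz, rel in e.transitions:
            # relative intensities are normalized within the entry so that
            # the summed transition signal equals the true class intensity
            val = true_total * rel / relsum
            if noise.sigma > 0:
                val *= float(np.exp(rng.normal(0.0, noise.sigma)))
            val += noise.baseline
            if val < noise.censor_limit:
                continue
            rows.append(
                (
                    f"{state.sample_id}_r{replicate}",
                    state.condition,
                    state.day,
                    replicate,
                    e.peptide_id,
                    e.protein,
                    label,
                    val,
                    e.rt,
                    fdr,
                )
            )
    for e in decoys:
        fdr = float(rng.uniform(noise.decoy_fdr_min, 1.0))
        for label, fmz, rel in e.transitions:
            val = float(rng.uniform(noise.censor_limit, noise.censor_limit * 50 + 10))
            rows.append(
                (
                    f"{state.sample_id}_r{replicate}",
                    state.condition,
                    state.day,
                    replicate,
                    e.peptide_id,
                    e.protein,
                    label,
                    val,
                    e.rt,
                    fdr,
                )
            )
    return pd.DataFrame(rows, columns=TRANSITION_COLUMNS)


def render_dataset(
    sc: BioprocessScenario,
    noise: NoiseModel | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    days: list[int] | None = None,
    include_purified: bool = True,
    decoys: list[ionlib.IonLibraryEntry] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Render a full study: every condition x selected day x replicate,
    plus purified endpoints.  Returns (transition table, ground-truth
    table, manifest); the manifest records the scenario hash and seed so
    any rendered dataset can be reproduced exactly."""
    noise = noise or NoiseModel()
    library = build_library(sc)
    decoys = [] if decoys is None else decoys
    states = simulate_timecourse(sc)
    if days is not None:
        states = [s for s in states if s.day in days]
    if include_purified:
        finals = [
            s for s in simulate_timecourse(sc) if s.day == sc.n_days
        ]
        states = states + [simulate_purification(s, sc) for s in finals]

    tables = []
    truth_rows = []
    for i, state in enumerate(states):
        for rep in range(1, n_replicates + 1):
            sub_seed = (seed * 100003 + i * 101 + rep) % (2**31)
            tables.append(render_dia(state, library, noise, sub_seed, rep, decoys))
        for cid, share in state.class_share.items():
            truth_rows.append(
                dict(
                    sample=state.sample_id,
                    condition=state.condition,
                    day=state.day,
                    peptide_id=cid,
                    share=share,
                )
            )
        for pid, ab in state.protein_abundance.items():
            truth_rows.append(
                dict(
                    sample=state.sample_id,
                    condition=state.condition,
                    day=state.day,
                    peptide_id=f"protein:{pid}",
                    share=ab,
                )
            )
    data = pd.concat(tables, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    manifest = {"scenario_hash": scenario_hash(sc), "seed": seed, "n_replicates": n_replicates}
    return data, truth, manifest


def scenario_hash(sc: BioprocessScenario) -> str:
    payload = json.dumps(asdict(sc), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Default scenario
# ---------------------------------------------------------------------------

def _viability(final: float, n_days: int = 13, hold: int = 7, start: float = 0.98):
    tail = np.linspace(start, final, n_days - hold + 1)[1:]
    return tuple(np.round(np.concatenate([np.full(hold, start), tail]), 4))


def default_scenario(seed: int = 0) -> BioprocessScenario:
    """The 'h1h2-like' fixture: 13 days, condition A with better viability
    (0.93 final vs 0.77) and higher carboxyform occupancy, condition B with
    higher product yield, stronger lysis-driven HCP release, and a larger
    glycan/sialylation load.  Numeric trajectories are fixture choices that
    reproduce the qualitative study design, not measured values."""
    families = (
        FamilyDef(
            "LEEFVQGNLER",
            "LEEFVQGNLER",
            gla_sites=(2, 3, 10),
            retention=(0.10, 0.25, 0.55, 0.85),
            derivatized=True,
        ),
        FamilyDef(
            "CSFEEAR",
            "CSFEEAR",
            gla_sites=(4, 5),
            retention=(0.10, 0.35, 0.80),
            derivatized=True,
        ),
        FamilyDef(
            "EVFENTER",
            "EVFENTER",
            gla_sites=(1, 4, 7),
            retention=(0.10, 0.25, 0.55, 0.85),
            derivatized=True,
        ),
        FamilyDef(
            "TTEFWK",
            "TTEFWK",
            gla_sites=(3,),
            retention=(0.5, 0.5),  # E40-site carboxylation does not drive binding
            derivatized=True,
        ),
        FamilyDef(
            "T3839",
            "TTEFWK",
            variants=(
                ("bare", ""),
                ("+656", "1:glycan:HexNAc1Hex1NeuAc1"),
                ("+947", "1:glycan:HexNAc1Hex1NeuAc2"),
            ),
            retention=(0.5, 0.5, 0.5),
        ),
        FamilyDef(
            "S141",
            "VSQTSK",
            variants=(
                ("bare", ""),
                ("+656", "2:glycan:HexNAc1Hex1NeuAc1"),
                ("+947", "2:glycan:HexNAc1Hex1NeuAc2"),
            ),
            retention=(0.5, 0.5, 0.5),
        ),
        FamilyDef(
            "D64",
            "QYVDGDQCK",
            variants=(("bare", ""), ("+16", "4:oxidation")),
            retention=(0.5, 0.5),
        ),
    )

    cond_a = Condition(
        name="A",
        secretion=(400, 600, 800, 1000, 1200, 1400, 1600, 1800, 200, 100, 100, 50, 50),
        viability=_viability(0.93),
        lysis_coefficient=60.0,
        family_dists={
            "LEEFVQGNLER": ((0.05, 0.10, 0.25, 0.60), (0.04, 0.08, 0.20, 0.68)),
            "CSFEEAR": ((0.10, 0.20, 0.70), (0.08, 0.17, 0.75)),
            "EVFENTER": ((0.06, 0.12, 0.26, 0.56), (0.05, 0.10, 0.22, 0.63)),
            "TTEFWK": ((0.30, 0.70), (0.30, 0.70)),
            "T3839": ((0.80, 0.12, 0.08), (0.75, 0.15, 0.10)),
            "S141": ((0.50, 0.30, 0.20), (0.15, 0.45, 0.40)),
            "D64": ((0.90, 0.10), (0.88, 0.12)),
        },
        hcp_secretion_scale=1.0,
    )
    cond_b = Condition(
        name="B",
        secretion=(400, 600, 800, 1000, 1200, 1400, 1600, 1800, 1800, 1800, 1600, 1400, 1200),
        viability=_viability(0.77),
        lysis_coefficient=120.0,
        family_dists={
            "LEEFVQGNLER": ((0.08, 0.15, 0.30, 0.47), (0.15, 0.25, 0.30, 0.30)),
            "CSFEEAR": ((0.15, 0.30, 0.55), (0.25, 0.35, 0.40)),
            "EVFENTER": ((0.10, 0.18, 0.30, 0.42), (0.18, 0.26, 0.30, 0.26)),
            "TTEFWK": ((0.35, 0.65), (0.35, 0.65)),
            "T3839": ((0.75, 0.15, 0.10), (0.60, 0.25, 0.15)),
            "S141": ((0.45, 0.30, 0.25), (0.05, 0.50, 0.45)),
            "D64": ((0.88, 0.12), (0.80, 0.20)),
        },
        hcp_secretion_scale=1.2,
    )

    rng = np.random.default_rng(seed)
    panel = []
    for i in range(40):
        secreted = i < 20
        ca = i % 5 == 0
        baseline = float(np.round(rng.lognormal(np.log(50.0), 1.0), 3))
        panel.append((f"HCP{i:03d}", baseline, secreted, ca))

    return BioprocessScenario(
        n_days=13,
        conditions=(cond_a, cond_b),
        families=families,
        hcp_panel=tuple(panel),
        seed=seed,
    )
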