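"""Site-specific PTM stoichiometry.

Carboxyform profiles express, per GLA peptide family, the percentage of
total family intensity carried by each γ-carboxylation count k (methyl and
glycan sub-variants are marginalized out by summation, so the derivatized
and underivatized workflows report on the same axis).  PTM variant series
express the abundance of a modified peptide relative to total product
abundance in the same sample, which tracks site occupancy over the
bioprocess time course and through purification.

Percentages are conditional on the detectable variant classes: families
whose remaining forms escape detection (fully γ-carboxylated peptides in
underivatized samples) are profiled over what was measured, and families
with zero total intensity are reported as undefined rather than 0%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CarboxyformProfile:
    """Intensity and percentage per carboxyl count for one peptide family
    in one sample."""

    family: str
    sample: str
    intensity: dict[int, float]
    percentage: dict[int, float]
    defined: bool

    @property
    def mean_k(self) -> float:
        if not self.defined:
            return float("nan")
        return sum(k * p for k, p in self.percentage.items()) / 100.0


def carboxyform_profile(
    peptides: pd.DataFrame,
    k_of: dict[str, int],
    family: str = "",
    sample: str = "",
) -> CarboxyformProfile:
    """Profile one family from its peptide-class quantities.

    peptides: rows with columns peptide_class and intensity, already
    restricted to one family and one sample; k_of maps each class to its
    carboxyl count (classes differing only in methyl/glycan state share a
    k and are summed together).  An empty or zero-total family yields a
    flagged undefined profile."""
    sums: dict[int, float] = {}
    for row in peptides.itertuples(index=False):
        if row.peptide_class not in k_of:
            raise KeyError(f"no carboxyl-count annotation for {row.peptide_class!r}")
        k = k_of[row.peptide_class]
        sums[k] = sums.get(k, 0.0) + float(row.intensity)
    total = sum(sums.values())
    if not sums or total <= 0:
        return CarboxyformProfile(family, sample, dict(sums), {}, False)
    pct = {k: 100.0 * v / total for k, v in sorted(sums.items())}
    return CarboxyformProfile(family, sample, dict(sorted(sums.items())), pct, True)


def carboxyform_profiles(
    peptides: pd.DataFrame,
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Batch profiles across samples and families.

    annotations: columns class_id, family, k (k may be NaN for non-GLA
    classes, which are ignored).  Returns long-format rows (sample, family,
    k, intensity, percentage); zero-total families are omitted (they carry
    no defined stoichiometry)."""
    ann = annotations.dropna(subset=["k"])
    k_of = dict(zip(ann["class_id"], ann["k"].astype(int)))
    fam_of = dict(zip(ann["class_id"], ann["family"]))
    df = peptides[peptides["peptide_class"].isin(k_of)].copy()
    df["family"] = df["peptide_class"].map(fam_of)
    rows = []
    for (sample, family), grp in df.groupby(["sample", "family"], sort=True):
        prof = carboxyform_profile(grp, k_of, family, sample)
        if not prof.defined:
            continue
        for k in prof.intensity:
            rows.append(
                (sample, family, k, prof.intensity[k], prof.percentage.get(k, 0.0))
            )
    return pd.DataFrame(rows, columns=["sample", "family", "k", "intensity", "percentage"])


def ptm_relative_abundance(
    variants: pd.DataFrame,
    proteins: pd.DataFrame,
    product: str = "rFIX",
) -> pd.DataFrame:
    """Variant intensity divided by product protein abundance per sample.

    variants: peptide-quant rows (sample, peptide_class, intensity);
    proteins: protein-quant rows (sample, protein, intensity).  Samples
    where the product is absent or non-positive are omitted; their ids are
    attached as attribute 'omitted_samples'."""
    prod = (
        proteins[(proteins["protein"] == product) & (proteins["intensity"] > 0)]
        .set_index("sample")["intensity"]
    )
    out = variants.copy()
    out["rel_abundance"] = [
        row.intensity / prod[row.sample] if row.sample in prod.index else np.nan
        for row in variants.itertuples(index=False)
    ]
    omitted = sorted(set(variants["sample"]) - set(prod.index))
    result = out.dropna(subset=["rel_abundance"]).reset_index(drop=True)
    result.attrs["omitted_samples"] = omitted
    return result


def timecourse_matrix(
    series: pd.DataFrame,
    value: str = "rel_abundance",
    log10: bool = False,
) -> pd.DataFrame:
    """Pivot a long (peptide_class x sample) series into a variant-by-sample
    matrix with explicit missing values (NaN, never imputed zero).

    Duplicate (variant, sample) pairs are rejected.  log10=True transforms
    positive values for display parity with abundance heatmaps."""
    dup = series.duplicated(subset=["peptide_class", "sample"])
    if dup.any():
        pairs = series.loc[dup, ["peptide_class", "sample"]].values.tolist()
        raise ValueError(f"duplicate (variant, sample) entries: {pairs[:5]}")
    mat = series.pivot(index="peptide_class", columns="sample", values=value)
    if log10:
        mat = np.log10(mat.where(mat > 0))
    return mat


def max_scaled(mat: pd.DataFrame) -> pd.DataFrame:
    """Per-row max scaling to [0, 1] (display-only convention for
    abundance heatmaps)."""
    return mat.div(mat.max(axis=1), axis=0)
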