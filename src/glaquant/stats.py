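"""Statistical comparisons for time-course and group contrasts.

Three procedures cover the analysis surface: a pooled-variance one-tailed
two-sample t-test for per-variant comparisons; multiple-t-test screening
across time points with the two-stage linear step-up false-discovery
procedure of Benjamini, Krieger & Yekutieli (BKY); and a protein-level
differential-abundance routine (log2 transform, median-polish run
summarization, equal-variance t-test, Benjamini-Hochberg adjustment) that
serves as a deliberately simplified stand-in for full mixed-model
summarization frameworks.  All tests operate on the log scale where
intensities enter, so results are invariant to unit rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    df: float
    flagged: bool = False  # degenerate-input convention applied


def one_tailed_t(a, b, direction: str = "greater") -> TTestResult:
    """Pooled-variance two-sample t-test, one-tailed.

    direction "greater" tests mean(a) > mean(b); "less" the reverse.
    Both groups need n >= 2.  When both groups have zero variance and equal
    means the test is undefined; the symmetric-null convention p = 0.5 is
    returned with the flag set."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two replicates")
    df = len(a) + len(b) - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 0.5, df, flagged=True)
        stat = np.inf if a.mean() > b.mean() else -np.inf
        p = 0.0 if (stat > 0) == (direction == "greater") else 1.0
        return TTestResult(float(stat), p, df, flagged=True)
    res = sps.ttest_ind(a, b, equal_var=True, alternative=direction)
    return TTestResult(float(res.statistic), float(res.pvalue), df)


def bky_two_stage(pvalues, q: float = 0.01) -> np.ndarray:
    """Two-stage linear step-up FDR control (Benjamini, Krieger &
    Yekutieli 2006).

    Stage 1 runs Benjamini-Hochberg at q' = q / (1 + q) to estimate the
    number of true nulls m0 = m - r1; stage 2 reruns BH at level
    q' * m / m0.  Returns a boolean discovery vector.  The procedure never
    discovers less than plain BH at the same q."""
    p = np.asarray(pvalues, float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-d array")
    if not ((p >= 0) & (p <= 1)).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    q1 = q / (1.0 + q)
    stage1 = _bh_reject(p, q1)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(m, bool)
    if r1 == m:
        return np.ones(m, bool)
    m0 = m - r1
    return _bh_reject(p, q1 * m / m0)


def _bh_reject(p: np.ndarray, q: float) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    thresh = q * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    out = np.zeros(m, bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        out[order[: k + 1]] = True
    return out


def multi_t_bky(
    series: pd.DataFrame,
    q: float = 0.01,
    direction: str | None = None,
) -> pd.DataFrame:
    """Per-unit two-sample t-tests across replicate columns with BKY
    discovery flags.

    series: long rows (unit, group, value) with exactly two group labels;
    direction=None runs two-sided tests (the usual multiple-t-test screen),
    otherwise the stated one-tailed direction (first group vs second in
    sorted order).  Units with fewer than two values in either group are
    excluded and listed in attribute 'excluded_units'."""
    groups = sorted(series["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    rows, excluded = [], []
    for unit, grp in series.groupby("unit", sort=True):
        a = grp.loc[grp["group"] == groups[0], "value"].to_numpy(float)
        b = grp.loc[grp["group"] == groups[1], "value"].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            excluded.append(unit)
            continue
        if direction is None:
            if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
                stat, p = 0.0, 1.0
            else:
                res = sps.ttest_ind(a, b, equal_var=True)
                stat, p = float(res.statistic), float(res.pvalue)
        else:
            r = one_tailed_t(a, b, direction)
            stat, p = r.statistic, r.pvalue
        rows.append((unit, stat, p))
    out = pd.DataFrame(rows, columns=["unit", "statistic", "pvalue"])
    if len(out):
        out["discovery"] = bky_two_stage(out["pvalue"].to_numpy(), q)
    else:
        out["discovery"] = pd.Series(dtype=bool)
    out.attrs["excluded_units"] = excluded
    return out


# ---------------------------------------------------------------------------
# Protein-level differential abundance
# ---------------------------------------------------------------------------

def median_polish(x: np.ndarray, max_iter: int = 10, tol: float = 1e-6) -> np.ndarray:
    """Tukey median polish of a features x runs matrix (NaN-tolerant);
    returns the per-run summary (overall effect + column effects)."""
    x = np.asarray(x, float)
    overall = 0.0
    row = np.zeros(x.shape[0])
    col = np.zeros(x.shape[1])
    resid = x.copy()
    for _ in range(max_iter):
        rmed = np.nanmedian(resid, axis=1)
        rmed = np.where(np.isnan(rmed), 0.0, rmed)
        resid -= rmed[:, None]
        row += rmed
        cmed_r = np.nanmedian(row)
        row -= cmed_r
        overall += cmed_r
        cmed = np.nanmedian(resid, axis=0)
        cmed = np.where(np.isnan(cmed), 0.0, cmed)
        resid -= cmed[None, :]
        col += cmed
        rmed_c = np.nanmedian(col)
        col -= rmed_c
        overall += rmed_c
        if abs(rmed_c) < tol and np.all(np.abs(cmed) < tol):
            break
    return overall + col


def protein_diff(
    features: pd.DataFrame,
    groups: dict[str, str],
    alpha: float = 1e-5,
) -> pd.DataFrame:
    """Protein-level group comparison.

    features: long rows (protein, peptide_class, sample, intensity) of
    FDR-passing feature intensities; groups maps sample -> group label
    (exactly two labels).  Per protein, feature intensities are log2
    transformed, summarized to run level by median polish, and the two
    groups compared with an equal-variance t-test; p-values are BH-adjusted
    across proteins and flagged significant at alpha.

    Proteins observed in only one group get the infinite-fold-change
    convention (±inf log2FC, flagged, excluded from testing).
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two group labels, got {labels}")
    rows = []
    for protein, grp in features.groupby("protein", sort=True):
        pos = grp[grp["intensity"] > 0]
        mat = pos.pivot_table(
            index="peptide_class", columns="sample", values="intensity", aggfunc="sum"
        )
        run_log = pd.Series(
            median_polish(np.log2(mat.to_numpy())), index=mat.columns
        )
        ga = run_log[[s for s in run_log.index if groups.get(s) == labels[0]]]
        gb = run_log[[s for s in run_log.index if groups.get(s) == labels[1]]]
        if len(ga) == 0 or len(gb) == 0:
            lfc = np.inf if len(ga) else -np.inf
            rows.append((protein, lfc, np.nan, np.nan, len(ga), len(gb), True))
            continue
        lfc = float(ga.mean() - gb.mean())
        if len(ga) < 2 or len(gb) < 2:
            rows.append((protein, lfc, np.nan, np.nan, len(ga), len(gb), True))
            continue
        if ga.var(ddof=1) == 0 and gb.var(ddof=1) == 0:
            stat, p = (0.0, 1.0) if ga.mean() == gb.mean() else (np.inf, 0.0)
        else:
            res = sps.ttest_ind(ga, gb, equal_var=True)
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append((protein, lfc, stat, p, len(ga), len(gb), False))
    out = pd.DataFrame(
        rows,
        columns=["protein", "log2fc", "statistic", "pvalue", "n_a", "n_b", "excluded"],
    )
    tested = out["pvalue"].notna()
    out["adj_pvalue"] = np.nan
    if tested.any():
        out.loc[tested, "adj_pvalue"] = multipletests(
            out.loc[tested, "pvalue"], method="fdr_bh"
        )[1]
    out["significant"] = (out["adj_pvalue"] <= alpha).fillna(False)
    return out


def volcano_table(comparisons: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot export: per protein, log2 fold change and -log10 of the
    adjusted p-value."""
    out = comparisons[["protein", "log2fc"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_adj_p"] = -np.log10(comparisons["adj_pvalue"])
    return out
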