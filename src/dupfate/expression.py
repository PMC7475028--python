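"""Tissue-expression profiles and divergence statistics for duplicate pairs.

Expression values (TPM) from replicate libraries are quartile-binned per
library, collapsed to one bin per condition by strict replicate majority,
and binarized (lowest quartile → not expressed).  Divergence between the
binary profiles of two copies is summarized by three statistics in [0, 1],
all restricted to conditions observed (non-NA) in both genes:

* normalized Hamming distance — differing conditions / considered;
* tissue expression complementarity (TEC) — the larger, over the two genes,
  of the fraction of its expressed conditions that are exclusive to it;
* tissue divergence dT — (conditions where either is expressed − conditions
  where both are) / conditions where either is expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def fpkm_to_tpm(fpkm: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """TPM(i) = FPKM(i) / Σ FPKM × 10⁶ (column-wise normalization)."""
    values = np.asarray(fpkm, dtype=float)
    if np.any(values < 0):
        raise ValueError("FPKM values must be non-negative")
    total = values.sum()
    if total <= 0:
        raise ValueError("cannot convert an all-zero FPKM vector")
    tpm = values / total * 1e6
    if isinstance(fpkm, pd.Series):
        return pd.Series(tpm, index=fpkm.index)
    return tpm


@dataclass
class QuartileBins:
    bins: pd.Series  # gene → 1..4
    degenerate: bool  # constant column


def quartile_bin(column: pd.Series) -> QuartileBins:
    """Quartile-bin one library's expression values across genes.

    Cut points are the 25/50/75th percentiles (linear interpolation); a
    value v gets bin 1 if v ≤ Q1, 2 if v ≤ Q2, 3 if v ≤ Q3, else 4.  A
    constant column collapses every gene into bin 1 and is flagged.
    """
    values = column.astype(float)
    if len(values) < 4:
        raise ValueError("quartile binning requires >= 4 genes")
    q1, q2, q3 = np.quantile(values.to_numpy(), [0.25, 0.5, 0.75])
    bins = pd.Series(4, index=values.index, dtype=int)
    bins[values <= q3] = 3
    bins[values <= q2] = 2
    bins[values <= q1] = 1
    return QuartileBins(bins=bins, degenerate=bool(q1 == q3))


def collapse_replicates(
    bins: pd.DataFrame, design: dict[str, str]
) -> pd.DataFrame:
    """Collapse per-library bins to per-condition bins by strict majority.

    A condition's bin is assigned when more than 50% of its replicate
    libraries agree; otherwise the value is NA.  ``design`` maps library
    column → condition.
    """
    missing = set(bins.columns) - set(design)
    if missing:
        raise ValueError(f"libraries without a condition: {sorted(missing)}")
    conditions = list(dict.fromkeys(design[lib] for lib in bins.columns))
    out = pd.DataFrame(np.nan, index=bins.index, columns=conditions)
    for cond in conditions:
        libs = [lib for lib in bins.columns if design[lib] == cond]
        sub = bins[libs]
        n = len(libs)
        for gene, row in sub.iterrows():
            counts = row.value_counts()
            if counts.iloc[0] * 2 > n:
                out.at[gene, cond] = counts.index[0]
    return out


def binarize(collapsed: pd.DataFrame | pd.Series):
    """Bin 1 → 0 (not expressed); bins 2–4 → 1; NA propagates."""

    def conv(v):
        if pd.isna(v):
            return np.nan
        return 0.0 if v == 1 else 1.0

    if isinstance(collapsed, pd.Series):
        return collapsed.map(conv)
    return collapsed.map(conv) if hasattr(collapsed, "map") else collapsed.applymap(conv)


@dataclass
class DivergenceStats:
    pair_id: str
    hamming: float
    tec: float
    dt: float
    considered: int


def divergence_stats(
    profile_a: pd.Series,
    profile_b: pd.Series,
    pair_id: str = "",
    tec_mode: str = "max",
) -> DivergenceStats:
    """Hamming / TEC / dT divergence between two binary profiles.

    All statistics are computed over conditions non-NA in both profiles;
    with no such condition every statistic is NA.  ``tec_mode`` selects how
    the two per-gene complementarity fractions are combined ("max" or
    "mean").
    """
    a, b = profile_a.align(profile_b, join="inner")
    mask = a.notna() & b.notna()
    a, b = a[mask].astype(float), b[mask].astype(float)
    considered = int(mask.sum())
    if considered == 0:
        return DivergenceStats(pair_id, math.nan, math.nan, math.nan, 0)

    differing = int((a != b).sum())
    hamming = differing / considered

    expr_a = set(a.index[a == 1])
    expr_b = set(b.index[b == 1])
    either = expr_a | expr_b
    both = expr_a & expr_b
    dt = (len(either) - len(both)) / len(either) if either else math.nan

    if not expr_a or not expr_b:
        tec = math.nan
    else:
        frac_a = len(expr_a - expr_b) / len(expr_a)
        frac_b = len(expr_b - expr_a) / len(expr_b)
        if tec_mode == "max":
            tec = max(frac_a, frac_b)
        elif tec_mode == "mean":
            tec = 0.5 * (frac_a + frac_b)
        else:
            raise ValueError("tec_mode must be 'max' or 'mean'")

    return DivergenceStats(pair_id, hamming, tec, dt, considered)


@dataclass
class GainLossReport:
    pair_id: str
    gains: int
    losses: int
    background_gene: str = ""
    considered: int = 0


def gain_loss(
    selected_profile: pd.Series,
    background_profile: pd.Series,
    pair_id: str = "",
    background_gene: str = "",
) -> GainLossReport:
    """Expression gains/losses of the selected copy against the background.

    The background is the non-selected copy's profile.  A *gain* is a
    jointly observed condition where the selected copy is expressed and the
    background is not; a *loss* is the reverse.
    """
    sel, bg = selected_profile.align(background_profile, join="inner")
    mask = sel.notna() & bg.notna()
    sel, bg = sel[mask].astype(float), bg[mask].astype(float)
    gains = int(((sel == 1) & (bg == 0)).sum())
    losses = int(((sel == 0) & (bg == 1)).sum())
    return GainLossReport(
        pair_id=pair_id,
        gains=gains,
        losses=losses,
        background_gene=background_gene,
        considered=int(mask.sum()),
    )


@dataclass
class PairCorrelation:
    pair_id: str
    r: float
    p: float
    r2: float
    slope: float
    n_conditions: int
    degenerate: bool = False


def condition_medians(
    expression: pd.DataFrame, design: dict[str, str]
) -> pd.DataFrame:
    """Per-condition median TPM over replicate libraries (genes × conditions)."""
    groups: dict[str, list[str]] = {}
    for lib in expression.columns:
        groups.setdefault(design[lib], []).append(lib)
    return pd.DataFrame(
        {cond: expression[libs].median(axis=1) for cond, libs in sorted(groups.items())}
    )


def _rescale(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def pair_correlation(
    expr_a: pd.Series,
    expr_b: pd.Series,
    pair_id: str = "",
) -> PairCorrelation:
    """Pearson r / p and linear-model r² and slope across conditions.

    Inputs are per-condition expression summaries (e.g. median TPM over
    replicates); each gene is min–max rescaled to [0, 1] across conditions
    before correlating, and copy B is regressed on copy A.  Zero variance
    in either gene yields NA statistics with the degenerate flag set.
    """
    a, b = expr_a.align(expr_b, join="inner")
    mask = a.notna() & b.notna()
    a, b = a[mask].astype(float), b[mask].astype(float)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("pair correlation requires >= 3 jointly observed conditions")
    xa, xb = _rescale(a.to_numpy()), _rescale(b.to_numpy())
    if np.all(xa == xa[0]) or np.all(xb == xb[0]):
        return PairCorrelation(pair_id, math.nan, math.nan, math.nan, math.nan,
                               n, degenerate=True)
    r, p = stats.pearsonr(xa, xb)
    fit = stats.linregress(xa, xb)
    return PairCorrelation(
        pair_id=pair_id,
        r=float(r),
        p=float(p),
        r2=float(r) ** 2,
        slope=float(fit.slope),
        n_conditions=n,
    )


def profiles_from_matrix(
    expression: pd.DataFrame, design: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Expression matrix → (binary profiles, collapsed bins, degenerate libs).

    Convenience composition of quartile binning (per library), replicate
    collapsing and binarization.
    """
    bins = {}
    degenerate: list[str] = []
    for lib in expression.columns:
        qb = quartile_bin(expression[lib])
        bins[lib] = qb.bins
        if qb.degenerate:
            degenerate.append(lib)
    bin_df = pd.DataFrame(bins)
    collapsed = collapse_replicates(bin_df, design)
    return binarize(collapsed), collapsed, degenerate
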