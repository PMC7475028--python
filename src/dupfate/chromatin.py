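"""TSS chromatin accessibility from FAIRE/Input coverage tracks.

Coverage tracks are depth-normalized to equal totals, binned at 10 bp, and
converted to a log2(FAIRE/Input) signal track.  For each gene the signal is
averaged over a 900 bp window centered on the transcription start site
(450 bp each side, strand-aware by default) and thresholded at 1 to call
the TSS open or closed.  Joint chromatin-by-expression categories are
assigned per condition and summarized at the gene level when at least 75%
of informative conditions agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from dupfate.classify import GeneModel

CATEGORIES = (
    "open+expressed",
    "open+not-expressed",
    "closed+expressed",
    "closed+not-expressed",
)


@dataclass
class SignalTrack:
    """Per-contig fixed-width bins of log2(FAIRE/Input); NaN = absent."""

    bin_size: int
    values: dict[str, np.ndarray]


def log2_ratio_track(
    faire: Mapping[str, np.ndarray],
    control: Mapping[str, np.ndarray],
    bin_size: int = 10,
    pseudocount: float = 1.0,
) -> SignalTrack:
    """Depth-normalized, binned log2(FAIRE/Input) track.

    Inputs are per-base coverage arrays per contig.  Both tracks are scaled
    to equal total signal before the per-bin ratio; bins with no coverage
    in either track are absent (NaN), not zero.
    """
    if set(faire) != set(control):
        raise ValueError("FAIRE and control tracks cover different contigs")
    total_f = sum(float(np.sum(v)) for v in faire.values())
    total_c = sum(float(np.sum(v)) for v in control.values())
    if total_f <= 0 or total_c <= 0:
        raise ValueError("empty coverage track")
    target = 0.5 * (total_f + total_c)
    sf, sc = target / total_f, target / total_c

    values: dict[str, np.ndarray] = {}
    for contig in sorted(faire):
        f = np.asarray(faire[contig], dtype=float)
        c = np.asarray(control[contig], dtype=float)
        if f.shape != c.shape:
            raise ValueError(f"{contig}: track lengths differ")
        n_bins = math.ceil(len(f) / bin_size)
        pad = n_bins * bin_size - len(f)
        if pad:
            f = np.concatenate([f, np.zeros(pad)])
            c = np.concatenate([c, np.zeros(pad)])
        fb = f.reshape(n_bins, bin_size).mean(axis=1) * sf
        cb = c.reshape(n_bins, bin_size).mean(axis=1) * sc
        ratio = np.log2((fb + pseudocount) / (cb + pseudocount))
        ratio[(fb == 0) & (cb == 0)] = np.nan
        values[contig] = ratio
    return SignalTrack(bin_size=bin_size, values=values)


@dataclass
class TssWindowSignal:
    gene: str
    mean: float  # NaN when the window has no covered bins
    coverage_fraction: float


def tss_window_mean(
    track: SignalTrack,
    model: GeneModel,
    half_window: int = 450,
    strand_aware: bool = True,
) -> TssWindowSignal:
    """Mean signal over the TSS window, overlap-weighted across bins.

    The window is ``[tss − half, tss + half)`` in 0-based coordinates, where
    the TSS is the gene's strand-aware start (its 1-based ``start`` on the +
    strand, its ``end`` on the −strand) — or simply ``start`` when
    ``strand_aware`` is off.  The window is clipped to the contig; a window
    entirely outside gives NaN.
    """
    if model.contig not in track.values:
        raise KeyError(f"contig {model.contig} absent from signal track")
    values = track.values[model.contig]
    contig_len = len(values) * track.bin_size
    if strand_aware and model.strand == "-":
        tss0 = model.end - 1
    else:
        tss0 = model.start - 1
    lo, hi = tss0 - half_window, tss0 + half_window
    window = 2 * half_window
    clipped_lo, clipped_hi = max(lo, 0), min(hi, contig_len)
    if clipped_hi <= clipped_lo:
        return TssWindowSignal(model.gene, math.nan, 0.0)

    weight_sum = 0.0
    acc = 0.0
    first_bin = clipped_lo // track.bin_size
    last_bin = (clipped_hi - 1) // track.bin_size
    for b in range(first_bin, last_bin + 1):
        b_lo, b_hi = b * track.bin_size, (b + 1) * track.bin_size
        overlap = min(b_hi, clipped_hi) - max(b_lo, clipped_lo)
        v = values[b]
        if overlap > 0 and not math.isnan(v):
            acc += v * overlap
            weight_sum += overlap
    if weight_sum == 0:
        return TssWindowSignal(model.gene, math.nan, 0.0)
    return TssWindowSignal(model.gene, acc / weight_sum, weight_sum / window)


def call_open_closed(signal: float, threshold: float = 1.0) -> str | None:
    """Open iff mean log2(FAIRE/Input) ≥ threshold; NaN signal → no call."""
    if signal is None or math.isnan(signal):
        return None
    return "open" if signal >= threshold else "closed"


@dataclass
class ChromatinCall:
    gene: str
    per_condition: dict[str, str] = field(default_factory=dict)
    gene_category: str | None = None
    informative_conditions: int = 0


def assign_joint_category(
    open_calls: Mapping[str, str | None],
    binary_profile: pd.Series,
    gene: str = "",
    min_agreement: float = 0.75,
) -> ChromatinCall:
    """Joint chromatin × expression category per condition and per gene.

    Conditions contribute when both an open/closed call and a non-NA
    expression value exist.  The gene-level category is the modal category
    when it covers at least ``min_agreement`` of informative conditions.
    """
    per_condition: dict[str, str] = {}
    for cond, state in open_calls.items():
        if state is None or cond not in binary_profile.index:
            continue
        expr = binary_profile[cond]
        if pd.isna(expr):
            continue
        suffix = "expressed" if expr == 1 else "not-expressed"
        per_condition[cond] = f"{state}+{suffix}"
    n = len(per_condition)
    category = None
    if n:
        counts = pd.Series(list(per_condition.values())).value_counts()
        if counts.iloc[0] / n >= min_agreement:
            category = str(counts.index[0])
    return ChromatinCall(
        gene=gene,
        per_condition=per_condition,
        gene_category=category,
        informative_conditions=n,
    )


def pair_different_chromatin(
    calls_a: Mapping[str, str | None], calls_b: Mapping[str, str | None]
) -> bool:
    """True iff one copy is open and the other closed in any shared condition."""
    for cond, state_a in calls_a.items():
        state_b = calls_b.get(cond)
        if state_a is None or state_b is None:
            continue
        if {state_a, state_b} == {"open", "closed"}:
            return True
    return False
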