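"""Population-genetic summaries: Tajima's D and codon-usage optimality.

Pooled per-site allele counts are subsampled without replacement to a fixed
target coverage (sites outside the coverage window are discarded), and the
classic Tajima (1989) statistic is computed on the subsampled counts with n
equal to the target coverage.  Codon adaptation index (CAI) is calibrated
against an expected CAI (eCAI): the 95th percentile of CAI over random
sequences of matched length and nucleotide composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from dupfate.codon import GENETIC_CODE, STOP_CODONS, NUCLEOTIDES, split_codons

ALLELES = ("A", "C", "G", "T")


def subsample_site(
    counts: Mapping[str, int] | Sequence[int],
    rng: np.random.Generator,
    target: int = 15,
    max_coverage: int = 150,
) -> dict[str, int] | None:
    """Hypergeometric subsample of one site's allele counts to ``target``.

    Returns ``None`` (site discarded) when coverage is below the target or
    above ``max_coverage``; otherwise draws exactly ``target`` reads without
    replacement.
    """
    if isinstance(counts, Mapping):
        alleles = [a for a in ALLELES if counts.get(a, 0) > 0]
        vec = [int(counts[a]) for a in alleles]
    else:
        alleles = list(ALLELES[: len(counts)])
        vec = [int(c) for c in counts]
    coverage = sum(vec)
    if coverage < target or coverage > max_coverage:
        return None
    drawn = rng.multivariate_hypergeometric(vec, target)
    return {a: int(k) for a, k in zip(alleles, drawn) if k > 0}


def tajima_constants(n: int) -> dict[str, float]:
    """The a1, a2, b1, b2, c1, c2, e1, e2 constants of Tajima (1989)."""
    if n < 2:
        raise ValueError("Tajima constants require n >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


@dataclass
class TajimaDResult:
    feature: str
    n: int
    sites: int
    segregating: int
    pi: float
    d: float  # NaN when S = 0


def tajima_d(
    site_counts: Iterable[Mapping[str, int] | Sequence[int]],
    n: int,
    feature: str = "",
) -> TajimaDResult:
    """Tajima's D from per-site allele counts of ``n`` sampled haplotypes.

    π is the mean number of pairwise differences accumulated over sites and
    S the number of segregating sites; D = (π − S/a1) / sqrt(e1·S +
    e2·S·(S−1)).  Monomorphic input (S = 0) yields D = NaN.
    """
    if n < 2:
        raise ValueError("Tajima's D requires n >= 2")
    pairs = n * (n - 1) / 2.0
    s = 0
    pi = 0.0
    n_sites = 0
    for counts in site_counts:
        vec = (
            [c for c in counts.values()]
            if isinstance(counts, Mapping)
            else list(counts)
        )
        vec = [int(c) for c in vec if c > 0]
        if sum(vec) != n:
            raise ValueError(f"site counts sum to {sum(vec)}, expected n={n}")
        n_sites += 1
        if len(vec) > 1:
            s += 1
            same = sum(c * (c - 1) / 2.0 for c in vec)
            pi += 1.0 - same / pairs
    if s == 0:
        return TajimaDResult(feature, n, n_sites, 0, 0.0, math.nan)
    k = tajima_constants(n)
    theta_w = s / k["a1"]
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    d = (pi - theta_w) / math.sqrt(var)
    return TajimaDResult(feature, n, n_sites, s, pi, d)


def haplotypes_to_site_counts(haplotypes: np.ndarray) -> list[list[int]]:
    """Genotype matrix (sites × samples, integer alleles) → per-site counts."""
    out = []
    for row in np.asarray(haplotypes):
        _, counts = np.unique(row, return_counts=True)
        out.append([int(c) for c in counts])
    return out


def feature_tajima(
    sites: Sequence[tuple[int, Mapping[str, int]]],
    intervals: Mapping[str, Sequence[tuple[int, int]]],
    n: int,
) -> dict[str, TajimaDResult]:
    """Tajima's D per feature from retained (position, counts) sites.

    ``intervals`` maps feature id → list of 1-based inclusive (start, end)
    spans (a gene, its exons, or its introns).  Features with no retained
    site yield D = NaN over zero sites.
    """
    results: dict[str, TajimaDResult] = {}
    for feature, spans in intervals.items():
        selected = [
            counts
            for pos, counts in sites
            if any(lo <= pos <= hi for lo, hi in spans)
        ]
        if not selected:
            results[feature] = TajimaDResult(feature, n, 0, 0, 0.0, math.nan)
        else:
            results[feature] = tajima_d(selected, n, feature=feature)
    return results


# ---------------------------------------------------------------------------
# Codon adaptation index
# ---------------------------------------------------------------------------


def relative_adaptiveness(
    usage: Mapping[str, float], epsilon: float = 0.01
) -> dict[str, float]:
    """w(codon) = usage / max usage among its synonymous family.

    Zero-usage codons are floored at ``epsilon`` (flagged by the caller via
    the returned value).  Scale-invariant to a constant factor on the table.
    """
    families: dict[str, list[str]] = {}
    for codon, aa in GENETIC_CODE.items():
        if codon in STOP_CODONS:
            continue
        families.setdefault(aa, []).append(codon)
    w: dict[str, float] = {}
    for aa, codons in families.items():
        peak = max(float(usage.get(c, 0.0)) for c in codons)
        if peak <= 0:
            raise ValueError(f"usage table has no counts for amino acid {aa}")
        for c in codons:
            w[c] = max(float(usage.get(c, 0.0)) / peak, epsilon)
    return w


_SINGLE_CODON_AAS = {
    aa
    for aa in set(GENETIC_CODE.values())
    if aa != "*"
    and sum(1 for c, a in GENETIC_CODE.items() if a == aa and c not in STOP_CODONS) == 1
}


def cai_value(seq: str, w: Mapping[str, float]) -> float:
    """Geometric-mean CAI, excluding single-codon families (Met, Trp)."""
    codons = [
        c
        for c in split_codons(seq)
        if c not in STOP_CODONS and GENETIC_CODE[c] not in _SINGLE_CODON_AAS
    ]
    if not codons:
        raise ValueError("no informative codons for CAI")
    return float(math.exp(sum(math.log(w[c]) for c in codons) / len(codons)))


@dataclass
class CAIResult:
    gene: str
    cai: float
    ecai: float
    optimized: bool
    n_random: int
    percentile: float


def _random_matched_sequence(
    n_codons: int, nt_probs: np.ndarray, rng: np.random.Generator
) -> str:
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list(NUCLEOTIDES), size=3, p=nt_probs))
        if codon not in STOP_CODONS:
            codons.append(codon)
    return "".join(codons)


def cai(
    seq: str,
    usage: Mapping[str, float],
    rng: np.random.Generator,
    gene: str = "",
    n_random: int = 1000,
    percentile: float = 95.0,
) -> CAIResult:
    """CAI with an expected-CAI (eCAI) optimality call.

    eCAI is the given percentile of CAI over ``n_random`` random sequences
    of matched codon count and mononucleotide composition (stop codons
    resampled); a gene is *optimized* iff CAI > eCAI.
    """
    w = relative_adaptiveness(usage)
    observed = cai_value(seq, w)
    counts = np.array([seq.upper().count(nt) for nt in NUCLEOTIDES], dtype=float)
    if counts.sum() == 0:
        raise ValueError("empty sequence")
    nt_probs = counts / counts.sum()
    n_codons = len(split_codons(seq))
    randoms = [
        cai_value(_random_matched_sequence(n_codons, nt_probs, rng), w)
        for _ in range(n_random)
    ]
    ecai = float(np.percentile(randoms, percentile))
    return CAIResult(
        gene=gene,
        cai=observed,
        ecai=ecai,
        optimized=observed > ecai,
        n_random=n_random,
        percentile=percentile,
    )
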