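"""Per-branch substitution rates and selection calls for duplicate pairs.

Branch rates are obtained by reconstructing ancestral codon sequences with
Fitch parsimony on a small pair-plus-outgroups topology and applying the
Nei–Gojobori (1986) counting estimator with Jukes–Cantor correction to each
parent→child branch.  This is a deliberate desk-scale counting estimator:
it preserves the downstream decision rules (fast/slow by dS, dS age filters,
positive-selection calls on externally computed branch-site p-values)
without maximum-likelihood codon-model optimization.

Conventions for NG86 as implemented here:

* synonymous sites per codon are the fraction of the nine single-nucleotide
  changes that preserve the amino acid; changes creating a stop codon count
  as nonsynonymous sites, so S + N = 3 per codon;
* observed differences are averaged over all mutational pathways between the
  two codons, excluding pathways that pass through a stop codon (all
  pathways are used if every one is blocked);
* the Jukes–Cantor transform saturates at a proportion of 0.75; saturated
  rates are reported as ``inf`` and flagged so the gene is routed to the
  dS > 2 exclusion path.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from statsmodels.stats.multitest import multipletests

_TABLE = unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
for _stop in STOP_CODONS:
    GENETIC_CODE[_stop] = "*"
NUCLEOTIDES = "ACGT"

#: (synonymous sites, nonsynonymous sites) per codon, NG86 convention.
_CODON_SITES: dict[str, tuple[float, float]] = {}
for _codon in GENETIC_CODE:
    if _codon in STOP_CODONS:
        continue
    _syn = 0.0
    for _pos in range(3):
        for _nt in NUCLEOTIDES:
            if _nt == _codon[_pos]:
                continue
            _alt = _codon[:_pos] + _nt + _codon[_pos + 1 :]
            if _alt not in STOP_CODONS and GENETIC_CODE[_alt] == GENETIC_CODE[_codon]:
                _syn += 1.0 / 3.0
    _CODON_SITES[_codon] = (_syn, 3.0 - _syn)


def split_codons(seq: str) -> list[str]:
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS and i < len(codons) - 1:
            raise ValueError(f"internal stop codon {codon} at codon {i}")
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return codons


def _pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (syn, nonsyn) difference counts over mutational pathways."""
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0
    valid: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(positions):
        current = codon_a
        syn = nonsyn = 0.0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            if GENETIC_CODE.get(current, "*") == GENETIC_CODE.get(nxt, "*"):
                syn += 1.0
            else:
                nonsyn += 1.0
            current = nxt
        (blocked if through_stop else valid).append((syn, nonsyn))
    pool = valid if valid else blocked
    return (
        sum(s for s, _ in pool) / len(pool),
        sum(n for _, n in pool) / len(pool),
    )


@dataclass
class PairwiseRates:
    """NG86 distances between two codon sequences."""

    dn: float
    ds: float
    pn: float
    ps: float
    n_sites: float
    s_sites: float
    saturated: bool = False

    @property
    def omega(self) -> float | None:
        """dN/dS; ``None`` (flagged undefined) when dS is 0 or saturated."""
        if self.saturated or self.ds == 0.0 or not math.isfinite(self.ds):
            return None
        return self.dn / self.ds


def _jukes_cantor(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return math.inf, True
    if p == 0.0:
        return 0.0, False
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def ng86_pairwise(seq_a: str, seq_b: str) -> PairwiseRates:
    """Nei–Gojobori (1986) dN and dS with Jukes–Cantor correction.

    Symmetric in its arguments; raises on length mismatch, gaps or internal
    stop codons.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("codon sequences differ in length")
    if "-" in seq_a or "-" in seq_b:
        raise ValueError("gap characters are not allowed in NG86 input")
    codons_a = split_codons(seq_a)
    codons_b = split_codons(seq_b)
    if len(codons_a) != len(codons_b):
        raise ValueError("codon sequences differ in length after stop trimming")
    s_a = s_b = sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        s_a += _CODON_SITES[ca][0]
        s_b += _CODON_SITES[cb][0]
        d_s, d_n = _pathway_diffs(ca, cb)
        sd += d_s
        nd += d_n
    s_sites = 0.5 * (s_a + s_b)
    n_sites = 3.0 * len(codons_a) - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds, sat_s = _jukes_cantor(ps)
    dn, sat_n = _jukes_cantor(pn)
    return PairwiseRates(
        dn=dn,
        ds=ds,
        pn=pn,
        ps=ps,
        n_sites=n_sites,
        s_sites=s_sites,
        saturated=sat_s or sat_n,
    )


# ---------------------------------------------------------------------------
# Fitch ancestors on the pair + outgroups ladder topology
# ---------------------------------------------------------------------------


@dataclass
class PairTreeRates:
    """Per-branch rates around a duplication node.

    ``pre`` is the branch leading into the duplication node; ``post`` maps
    each copy to the branch from the duplication node to that tip.
    ``ancestral`` is the Fitch sequence reconstructed at the duplication
    node, and ``unresolved_fraction`` the share of codons whose Fitch state
    set at that node had more than one member before resolution.
    """

    pre: PairwiseRates
    post: dict[str, PairwiseRates]
    ancestral: str
    pre_ancestral: str
    unresolved_fraction: float


def _fitch_codons(
    leaf_states: Sequence[list[str]], topology: Sequence[tuple[int, int]]
) -> tuple[list[list[str]], list[int]]:
    """Generic Fitch over whole-codon states.

    ``leaf_states[i]`` is the codon list of leaf ``i``; ``topology`` lists
    internal nodes bottom-up as pairs of child indices (children may be
    leaves ``0..n_leaves-1`` or previously created internal nodes).
    Returns assigned codon lists for internal nodes and, per internal node,
    the count of ambiguous codons (set size > 1 in the up-pass).
    """
    n_leaves = len(leaf_states)
    n_codons = len(leaf_states[0])
    up: list[list[frozenset[str]]] = [
        [frozenset({c}) for c in states] for states in leaf_states
    ]
    for left, right in topology:
        sets = []
        for k in range(n_codons):
            inter = up[left][k] & up[right][k]
            sets.append(inter if inter else up[left][k] | up[right][k])
        up.append(sets)

    n_internal = len(topology)
    root_idx = n_leaves + n_internal - 1
    assigned: dict[int, list[str]] = {}
    ambiguous = [0] * n_internal

    order = list(range(n_leaves + n_internal - 1, n_leaves - 1, -1))
    parent_of: dict[int, int] = {}
    for i, (left, right) in enumerate(topology):
        parent_of[left] = n_leaves + i
        parent_of[right] = n_leaves + i

    for idx in order:
        internal_i = idx - n_leaves
        states = []
        for k in range(n_codons):
            options = up[idx][k]
            if idx == root_idx:
                if len(options) > 1:
                    ambiguous[internal_i] += 1
                states.append(min(options))
            else:
                parent_state = assigned[parent_of[idx]][k]
                if parent_state in options:
                    states.append(parent_state)
                else:
                    # parent cannot resolve: lexicographic fallback
                    if len(options) > 1:
                        ambiguous[internal_i] += 1
                    states.append(min(options))
        assigned[idx] = states
    return [assigned[n_leaves + i] for i in range(n_internal)], ambiguous


def branch_rates_on_pair_tree(
    alignment: Mapping[str, str],
    gene_a: str,
    gene_b: str,
    outgroups: Sequence[str],
    max_unresolved: float = 0.5,
) -> PairTreeRates:
    """Estimate pre- and post-duplication branch rates.

    The topology is the outgroup-rooted ladder
    ``(...((gene_a, gene_b), out1), out2, ...)``: ancestral codon sequences
    are reconstructed by Fitch parsimony (whole-codon states, ambiguities
    resolved toward the outgroup-side parent, then lexicographically) and
    each branch's rates are ``ng86_pairwise(parent, child)``.
    """
    if len(outgroups) < 2:
        raise ValueError("at least two outgroups are required")
    names = [gene_a, gene_b, *outgroups]
    leaf_codons = [split_codons(alignment[name]) for name in names]
    lengths = {len(c) for c in leaf_codons}
    if len(lengths) != 1:
        raise ValueError("alignment sequences differ in codon length")
    n_codons = lengths.pop()

    # ladder topology: node n+k joins previous internal node with outgroup k
    n = len(names)
    topology: list[tuple[int, int]] = [(0, 1)]
    for k in range(2, n):
        topology.append((n + len(topology) - 1, k))

    internal_states, ambiguous = _fitch_codons(leaf_codons, topology)
    dup_seq = "".join(internal_states[0])
    pre_seq = "".join(internal_states[1])  # parent of the duplication node

    unresolved = ambiguous[0] / n_codons if n_codons else 0.0
    if unresolved > max_unresolved:
        raise ValueError(
            f"unresolved parsimony state at {unresolved:.0%} of codons"
        )

    return PairTreeRates(
        pre=ng86_pairwise(pre_seq, dup_seq),
        post={
            gene_a: ng86_pairwise(dup_seq, "".join(leaf_codons[0])),
            gene_b: ng86_pairwise(dup_seq, "".join(leaf_codons[1])),
        },
        ancestral=dup_seq,
        pre_ancestral=pre_seq,
        unresolved_fraction=unresolved,
    )


# ---------------------------------------------------------------------------
# Fast/slow classification and rate filters
# ---------------------------------------------------------------------------


@dataclass
class FastSlowCall:
    pair_id: str
    slow: str
    fast: str
    ds_slow: float
    ds_fast: float
    tie: bool = False


def classify_fast_slow(
    pair_id: str, gene_a: str, gene_b: str, ds_a: float, ds_b: float
) -> FastSlowCall:
    """Slow copy = lowest post-duplication dS; ties break lexicographically."""
    if ds_a is None or ds_b is None:
        raise ValueError("both post-duplication dS values are required")
    if ds_a == ds_b:
        slow, fast = sorted([gene_a, gene_b])
        return FastSlowCall(pair_id, slow, fast, ds_a, ds_b, tie=True)
    if ds_a < ds_b:
        return FastSlowCall(pair_id, gene_a, gene_b, ds_a, ds_b)
    return FastSlowCall(pair_id, gene_b, gene_a, ds_b, ds_a)


def apply_rate_filters(
    ds_by_gene: Mapping[str, float],
    ds_min: float = 0.01,
    ds_max: float = 2.0,
) -> set[str]:
    """Genes retained by the dS age filters (boundaries inclusive).

    Saturated (infinite) dS follows the high-dS exclusion path.
    """
    return {
        gene
        for gene, ds in ds_by_gene.items()
        if ds is not None and math.isfinite(ds) and ds_min <= ds <= ds_max
    }


def apply_pair_rate_filters(
    ds_by_pair: Mapping[str, tuple[float, float]],
    ds_min: float = 0.01,
    ds_max: float = 2.0,
) -> set[str]:
    """Pairs retained when *both* copies pass the dS filters."""
    retained = set()
    for pair_id, (ds_a, ds_b) in ds_by_pair.items():
        ok = apply_rate_filters({"a": ds_a, "b": ds_b}, ds_min, ds_max)
        if ok == {"a", "b"}:
            retained.add(pair_id)
    return retained


# ---------------------------------------------------------------------------
# Multinucleotide mutations
# ---------------------------------------------------------------------------


@dataclass
class MNMReport:
    gene: str
    codons_compared: int
    mnm_count: int

    @property
    def percent(self) -> float:
        if self.codons_compared == 0:
            return 0.0
        return 100.0 * self.mnm_count / self.codons_compared


def count_mnm(ancestral: str, derived: str, gene: str = "") -> MNMReport:
    """Codons differing from the ancestor at two or more positions."""
    if len(ancestral) != len(derived):
        raise ValueError("ancestral and derived sequences differ in length")
    codons_anc = split_codons(ancestral)
    codons_der = split_codons(derived)
    mnm = sum(
        1
        for ca, cd in zip(codons_anc, codons_der)
        if sum(x != y for x, y in zip(ca, cd)) >= 2
    )
    return MNMReport(gene=gene, codons_compared=len(codons_anc), mnm_count=mnm)


# ---------------------------------------------------------------------------
# Multiple-testing adjustment and the positive-selection decision rule
# ---------------------------------------------------------------------------

ADJUSTMENT_METHODS = ("holm", "hochberg", "sidak_ss", "sidak_sd", "bh", "by")

_STATSMODELS_METHOD = {
    "holm": "holm",
    "hochberg": "simes-hochberg",
    "sidak_ss": "sidak",
    "sidak_sd": "holm-sidak",
    "bh": "fdr_bh",
    "by": "fdr_by",
}


def adjust_pvalues(pvalues: Sequence[float], method: str) -> np.ndarray:
    """Adjusted p-values under one of the six supported procedures.

    Methods: Holm, Hochberg, Šidák single-step (``sidak_ss``), Šidák
    step-down (``sidak_sd``), Benjamini–Hochberg (``bh``) and
    Benjamini–Yekutieli (``by``).  Results are clipped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in _STATSMODELS_METHOD:
        raise ValueError(
            f"unknown method {method!r}; choose from {ADJUSTMENT_METHODS}"
        )
    _, adjusted, _, _ = multipletests(
        p, alpha=0.05, method=_STATSMODELS_METHOD[method], is_sorted=False
    )
    return np.clip(adjusted, 0.0, 1.0)


@dataclass
class SelectionCall:
    gene: str
    raw_p: float
    adjusted: dict[str, float]
    positively_selected: bool
    bs_mnm: bool | None = None


def call_positive_selection(
    raw_p_by_gene: Mapping[str, float],
    alpha: float = 0.01,
    bs_mnm_flags: Mapping[str, bool] | None = None,
) -> dict[str, SelectionCall]:
    """Flag a gene as selected if *any* adjusted p-value falls below alpha.

    All six adjustment procedures are computed over the full gene set; the
    decision rule is ``min over methods of adjusted p < alpha``.
    """
    genes = sorted(raw_p_by_gene)
    raw = np.array([raw_p_by_gene[g] for g in genes], dtype=float)
    adjusted = {m: adjust_pvalues(raw, m) for m in ADJUSTMENT_METHODS}
    calls: dict[str, SelectionCall] = {}
    for i, gene in enumerate(genes):
        per_method = {m: float(adjusted[m][i]) for m in ADJUSTMENT_METHODS}
        calls[gene] = SelectionCall(
            gene=gene,
            raw_p=float(raw[i]),
            adjusted=per_method,
            positively_selected=min(per_method.values()) < alpha,
            bs_mnm=None if bs_mnm_flags is None else bool(bs_mnm_flags.get(gene)),
        )
    return calls


# ---------------------------------------------------------------------------
# Alignment identity
# ---------------------------------------------------------------------------


def translate_codon_alignment(alignment: Mapping[str, str]) -> dict[str, str]:
    """Codon alignment → amino-acid alignment ('-' for gap codons)."""
    out = {}
    for name, seq in alignment.items():
        seq = seq.upper()
        if len(seq) % 3:
            raise ValueError(f"{name}: length not divisible by 3")
        aas = []
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            aas.append("-" if "-" in codon else GENETIC_CODE.get(codon, "X"))
        out[name] = "".join(aas)
    return out


def compute_median_identity(
    alignment: Mapping[str, str], as_protein: bool = True
) -> dict[str, float]:
    """Median pairwise percent identity of each sequence against the rest.

    Identity of a pair = identical columns / columns where neither sequence
    has a gap.
    """
    if len(alignment) < 2:
        raise ValueError("median identity requires >= 2 sequences")
    seqs = translate_codon_alignment(alignment) if as_protein else dict(alignment)
    names = sorted(seqs)
    identities: dict[str, list[float]] = {n: [] for n in names}
    for a, b in itertools.combinations(names, 2):
        sa, sb = seqs[a], seqs[b]
        if len(sa) != len(sb):
            raise ValueError("alignment sequences differ in length")
        compared = identical = 0
        for x, y in zip(sa, sb):
            if x == "-" or y == "-":
                continue
            compared += 1
            identical += x == y
        ident = 100.0 * identical / compared if compared else float("nan")
        identities[a].append(ident)
        identities[b].append(ident)
    return {n: float(np.median(vals)) for n, vals in identities.items()}


# ---------------------------------------------------------------------------
# External selection-test ingest
# ---------------------------------------------------------------------------


def read_selection_pvalues(path) -> dict[str, float]:
    """Read a branch-site result TSV (gene, test, lnL0, lnL1, p) → gene→p."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"gene", "p"}
    if not required <= set(df.columns):
        raise ValueError(f"selection TSV must contain columns {sorted(required)}")
    return dict(zip(df["gene"].astype(str), df["p"].astype(float)))
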