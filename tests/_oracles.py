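"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle recomputes a statistic from first principles, sharing no code
with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Seq import Seq


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def is_stop(codon: str) -> bool:
    return translate(codon) == "*"


# -- species-overlap labelling ---------------------------------------------


def species_overlap_labels(tree, species_of):
    """Per-node labels by direct leaf scans (no shared traversal code)."""

    def leaf_species(node):
        return {species_of(lf.taxon.label) for lf in node.leaf_iter()}

    labels = {}
    for node in tree.preorder_internal_node_iter():
        children = node.child_nodes()
        dup = False
        for i in range(len(children)):
            for j in range(i + 1, len(children)):
                if leaf_species(children[i]) & leaf_species(children[j]):
                    dup = True
        labels[node] = "duplication" if dup else "speciation"
    return labels


# -- NG86 ------------------------------------------------------------------


def ng86(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Pathway-averaging NG86 (dN, dS) recomputed from scratch."""

    def codons(seq):
        cs = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if cs and is_stop(cs[-1]):
            cs = cs[:-1]
        return cs

    def syn_sites(codon):
        syn = 0.0
        for pos in range(3):
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1 :]
                if not is_stop(alt) and translate(alt) == translate(codon):
                    syn += 1 / 3
        return syn

    def diffs(ca, cb):
        pos = [i for i in range(3) if ca[i] != cb[i]]
        if not pos:
            return 0.0, 0.0
        paths, blocked = [], []
        for order in itertools.permutations(pos):
            cur, syn, nonsyn, stop = ca, 0.0, 0.0, False
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1 :]
                if is_stop(nxt):
                    stop = True
                if translate(cur) == translate(nxt):
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            (blocked if stop else paths).append((syn, nonsyn))
        pool = paths or blocked
        return (
            sum(s for s, _ in pool) / len(pool),
            sum(n for _, n in pool) / len(pool),
        )

    ca, cb = codons(seq_a), codons(seq_b)
    s_sites = sum(syn_sites(c) for c in ca) / 2 + sum(syn_sites(c) for c in cb) / 2
    n_sites = 3 * len(ca) - s_sites
    sd = nd = 0.0
    for x, y in zip(ca, cb):
        ds_, dn_ = diffs(x, y)
        sd += ds_
        nd += dn_
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0

    def jc(p):
        if p >= 0.75:
            return math.inf
        if p == 0:
            return 0.0
        return -0.75 * math.log(1 - 4 * p / 3)

    return jc(pn), jc(ps)


# -- Tajima's D -------------------------------------------------------------


def tajima_d(site_counts, n):
    """Textbook Tajima (1989) from per-site allele-count lists."""
    s = 0
    pi = 0.0
    for counts in site_counts:
        counts = [c for c in counts if c > 0]
        if len(counts) > 1:
            s += 1
            hom = sum(c * (c - 1) for c in counts) / (n * (n - 1))
            pi += 1.0 - hom
    if s == 0:
        return math.nan
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


# -- quartile binning -------------------------------------------------------


def quartile_bins(values):
    """Sort-based linear-interpolation quartile bins (1..4)."""
    v = np.asarray(values, dtype=float)
    srt = np.sort(v)
    n = len(srt)

    def pctl(p):
        h = (n - 1) * p
        lo = int(math.floor(h))
        hi = min(lo + 1, n - 1)
        return srt[lo] + (h - lo) * (srt[hi] - srt[lo])

    q1, q2, q3 = pctl(0.25), pctl(0.5), pctl(0.75)
    out = []
    for x in v:
        if x <= q1:
            out.append(1)
        elif x <= q2:
            out.append(2)
        elif x <= q3:
            out.append(3)
        else:
            out.append(4)
    return out


# -- multiple-testing adjustments -------------------------------------------


def adjust(p, method):
    """Hand-rolled step-up/step-down adjustments (the six procedures)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = np.empty(m)
    if method == "holm":
        vals = [(m - i) * ranked[i] for i in range(m)]
        adj_sorted = np.maximum.accumulate(vals)
    elif method == "sidak_sd":
        vals = [1 - (1 - ranked[i]) ** (m - i) for i in range(m)]
        adj_sorted = np.maximum.accumulate(vals)
    elif method == "hochberg":
        vals = [(m - i) * ranked[i] for i in range(m)]
        adj_sorted = np.minimum.accumulate(vals[::-1])[::-1]
    elif method == "bh":
        vals = [m / (i + 1) * ranked[i] for i in range(m)]
        adj_sorted = np.minimum.accumulate(vals[::-1])[::-1]
    elif method == "by":
        c = sum(1 / i for i in range(1, m + 1))
        vals = [c * m / (i + 1) * ranked[i] for i in range(m)]
        adj_sorted = np.minimum.accumulate(vals[::-1])[::-1]
    elif method == "sidak_ss":
        adj_sorted = 1 - (1 - ranked) ** m
    else:
        raise ValueError(method)
    adj[order] = np.clip(adj_sorted, 0, 1)
    return adj


# -- binary-profile divergence ----------------------------------------------


def divergence(profile_a, profile_b):
    """(hamming, tec, dt) by explicit counting over shared conditions.

    Profiles are dicts condition → 0/1/None.
    """
    shared = [
        c
        for c in profile_a
        if c in profile_b and profile_a[c] is not None and profile_b[c] is not None
    ]
    if not shared:
        return math.nan, math.nan, math.nan
    differ = sum(1 for c in shared if profile_a[c] != profile_b[c])
    hamming = differ / len(shared)
    ea = {c for c in shared if profile_a[c] == 1}
    eb = {c for c in shared if profile_b[c] == 1}
    either, both = ea | eb, ea & eb
    dt = (len(either) - len(both)) / len(either) if either else math.nan
    if not ea or not eb:
        tec = math.nan
    else:
        tec = max(len(ea - eb) / len(ea), len(eb - ea) / len(eb))
    return hamming, tec, dt
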