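"""Synthetic inputs with ground truth for every pipeline stage.

The generators emulate the structure of the real study inputs — gene trees
with lineage-specific duplications under a 9-taxon Sternorrhyncha-like
species tree, codon alignments evolved with per-branch dN/dS, replicate
expression matrices with planted profile divergence, FAIRE/Input coverage
tracks with planted open and closed TSSs, and neutral coalescent samples —
while staying deliberately simple (no rate heterogeneity, no indels, no
read-level noise).  Every generator is driven by an explicit seed or
``numpy.random.Generator`` and returns a machine-readable truth table next
to its outputs; the same seed reproduces identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import msprime
import numpy as np
import pandas as pd

from dupfate.classify import GeneModel, assign_ranks
from dupfate.codon import GENETIC_CODE, NUCLEOTIDES, STOP_CODONS, split_codons
from dupfate.datasets import CONDITIONS, FOCAL_SPECIES, SPECIES
from dupfate.io import read_newick

_TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Gene trees with planted species-specific duplications
# ---------------------------------------------------------------------------


def _apisum_clade(genes: Sequence[str], support: float, bl: float) -> str:
    """Nested caterpillar clade of focal-species copies."""
    clade = f"{genes[0]}:{bl:.4f}"
    for g in genes[1:]:
        clade = f"({clade},{g}:{bl:.4f}){support:.2f}:{bl:.4f}"
    return clade


def simulate_gene_trees(
    n_trees: int,
    seed: int | np.random.Generator,
    duplication_plan: Mapping[int, int] | None = None,
    duplication_fraction: float = 0.3,
    max_copies: int = 2,
    planted_support: float = 0.99,
    speciation_support: float = 1.0,
) -> tuple[list[dendropy.Tree], pd.DataFrame]:
    """Gene trees over the 9-taxon species tree with planted focal duplications.

    ``duplication_plan`` maps tree index → copy count (≥2) for trees that
    carry a terminal duplication of the focal species; when absent, a
    random ``duplication_fraction`` of trees receives 2..``max_copies``
    copies.  Leaf names encode the species (``Species_t0007`` /
    ``Apisum_t0007a`` …); planted duplication nodes get ``planted_support``.
    Returns the trees and a truth table (tree_id, planted, copies, members).
    """
    rng = _as_rng(seed)
    if duplication_plan is None:
        duplication_plan = {}
        for i in range(n_trees):
            if rng.random() < duplication_fraction:
                duplication_plan[i] = int(rng.integers(2, max_copies + 1))

    trees: list[dendropy.Tree] = []
    records = []
    for i in range(n_trees):
        tag = f"t{i:04d}"
        copies = duplication_plan.get(i, 1)
        bl = float(rng.uniform(0.05, 0.3))
        if copies >= 2:
            members = [f"{FOCAL_SPECIES}_{tag}{chr(97 + k)}" for k in range(copies)]
            apisum = _apisum_clade(members, planted_support, bl)
        else:
            members = [f"{FOCAL_SPECIES}_{tag}"]
            apisum = f"{FOCAL_SPECIES}_{tag}:{bl:.4f}"
        leaf = {sp: f"{sp}_{tag}:{bl:.4f}" for sp in SPECIES if sp != FOCAL_SPECIES}
        s = speciation_support
        newick = (
            f"({leaf['Dcitri']},({leaf['Btabaci']},({leaf['Dvitifoliae']},"
            f"({leaf['Ccedri']},(({leaf['Rpadi']},{leaf['Aglycines']}){s:.2f}:{bl:.4f},"
            f"({leaf['Dnoxia']},({leaf['Mpersicae']},{apisum}){s:.2f}:{bl:.4f})"
            f"{s:.2f}:{bl:.4f}){s:.2f}:{bl:.4f}){s:.2f}:{bl:.4f})"
            f"{s:.2f}:{bl:.4f}){s:.2f}:{bl:.4f});"
        )
        trees.append(read_newick(newick))
        records.append(
            {
                "tree_id": tag,
                "planted": copies >= 2,
                "copies": copies if copies >= 2 else 0,
                "members": ";".join(members) if copies >= 2 else "",
            }
        )
    return trees, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Codon-alignment evolution with per-branch omega
# ---------------------------------------------------------------------------


def random_codon_sequence(n_codons: int, rng: np.random.Generator) -> str:
    sense = sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)
    return "".join(rng.choice(sense, size=n_codons))


def evolve_sequence(
    seq: str,
    branch_length: float,
    omega: float,
    rng: np.random.Generator,
    kappa: float = 2.0,
) -> str:
    """Evolve a codon sequence along one branch.

    Single-nucleotide changes are proposed at a rate proportional to the
    branch length (in expected proposals per nucleotide site), with
    transition:transversion weight ``kappa``.  Synonymous proposals are
    always accepted and nonsynonymous ones with probability ``omega``; for
    omega > 1 the proposal rate is inflated by omega and acceptance
    probabilities divided by it, so the synonymous rate is unchanged.
    Changes creating stop codons are rejected.
    """
    codons = split_codons(seq)
    n_sites = 3 * len(codons)
    inflate = max(1.0, omega)
    n_prop = rng.poisson(branch_length * n_sites * inflate)
    p_syn = 1.0 / inflate
    p_nonsyn = omega / inflate
    weights = np.array([kappa, 1.0, 1.0])
    weights = weights / weights.sum()
    for _ in range(n_prop):
        site = int(rng.integers(n_sites))
        ci, pos = divmod(site, 3)
        codon = codons[ci]
        current = codon[pos]
        ts = _TRANSITIONS[current]
        tv = [nt for nt in NUCLEOTIDES if nt != current and nt != ts]
        alt = str(rng.choice([ts, tv[0], tv[1]], p=weights))
        new_codon = codon[:pos] + alt + codon[pos + 1 :]
        if new_codon in STOP_CODONS:
            continue
        syn = GENETIC_CODE[new_codon] == GENETIC_CODE[codon]
        accept_p = p_syn if syn else p_nonsyn
        if rng.random() < accept_p:
            codons[ci] = new_codon
    return "".join(codons)


@dataclass
class PairAlignmentTruth:
    gene_a: str
    gene_b: str
    outgroups: list[str]
    omega_a: float
    omega_b: float
    omega_pre: float
    t_post: float


def simulate_pair_alignment(
    seed: int | np.random.Generator,
    n_codons: int = 300,
    omega_a: float = 0.2,
    omega_b: float = 1.5,
    omega_pre: float = 0.2,
    omega_background: float = 0.2,
    t_post: float = 0.2,
    t_pre: float = 0.15,
    t_out: float = 0.25,
    n_outgroups: int = 2,
    kappa: float = 2.0,
    gene_a: str = "Apisum_ga",
    gene_b: str = "Apisum_gb",
) -> tuple[dict[str, str], PairAlignmentTruth]:
    """Codon alignment for a duplicate pair plus outgroups, with truth.

    Topology is the ladder ``(...((a, b)dup, out1), out2, …)``; the two
    post-duplication branches evolve with ``omega_a`` and ``omega_b``, the
    pre-duplication branch with ``omega_pre``, outgroup branches with
    ``omega_background``.
    """
    rng = _as_rng(seed)
    outgroup_names = [f"out{k}_g1" for k in range(1, n_outgroups + 1)]
    root = random_codon_sequence(n_codons, rng)
    alignment: dict[str, str] = {}
    inner = root
    # walk root → ... → duplication-node parent, peeling one outgroup per level
    for name in reversed(outgroup_names):
        alignment[name] = evolve_sequence(inner, t_out, omega_background, rng, kappa)
        inner = evolve_sequence(inner, t_out / 2.0, omega_background, rng, kappa)
    dup = evolve_sequence(inner, t_pre, omega_pre, rng, kappa)
    alignment[gene_a] = evolve_sequence(dup, t_post, omega_a, rng, kappa)
    alignment[gene_b] = evolve_sequence(dup, t_post, omega_b, rng, kappa)
    truth = PairAlignmentTruth(
        gene_a=gene_a,
        gene_b=gene_b,
        outgroups=outgroup_names,
        omega_a=omega_a,
        omega_b=omega_b,
        omega_pre=omega_pre,
        t_post=t_post,
    )
    return alignment, truth


# ---------------------------------------------------------------------------
# Expression matrices with planted divergence types
# ---------------------------------------------------------------------------

DIVERGENCE_TYPES = ("identical", "specialized", "gained")


def simulate_expression(
    n_pairs: int,
    seed: int | np.random.Generator,
    type_fractions: Mapping[str, float] | None = None,
    conditions: Sequence[str] = CONDITIONS,
    replicates: int = 3,
    n_background: int = 200,
    noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Replicate TPM matrix for duplicate pairs with planted binary profiles.

    Each pair has a non-selected "background" copy and a "selected" copy.
    Divergence types: *identical* (same profile), *specialized* (selected
    copy loses expression in some conditions) and *gained* (selected copy
    expressed where the background copy is not).  Planted "not expressed"
    cells have zero TPM, so the lowest quartile recovers them exactly in
    the noise-free case; background filler genes (a silent block plus
    expressed genes) make the per-library quartiles well defined.
    Returns (matrix, library→condition design, truth table).
    """
    rng = _as_rng(seed)
    fractions = dict(type_fractions or {"identical": 0.4, "specialized": 0.3, "gained": 0.3})
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("type fractions must sum to 1")
    conditions = list(conditions)
    n_cond = len(conditions)
    libraries = [f"{cond}_r{k + 1}" for cond in conditions for k in range(replicates)]
    design = {lib: lib.rsplit("_r", 1)[0] for lib in libraries}

    # deterministic type assignment honouring the requested fractions
    types: list[str] = []
    for t in DIVERGENCE_TYPES:
        types += [t] * round(fractions.get(t, 0.0) * n_pairs)
    while len(types) < n_pairs:
        types.append("identical")
    types = types[:n_pairs]

    rows: dict[str, np.ndarray] = {}
    records = []

    def expressed_values(base: float, scale: float) -> np.ndarray:
        vals = np.full(replicates, base * scale)
        if noise_sd > 0:
            vals = vals * rng.lognormal(0.0, noise_sd, size=replicates)
        return vals

    for p in range(n_pairs):
        pair = f"pair{p:03d}"
        g_bg, g_sel = f"Apisum_{pair}a", f"Apisum_{pair}b"
        dtype = types[p]
        if dtype == "identical":
            profile_bg = np.ones(n_cond, dtype=int)
            profile_sel = profile_bg.copy()
        elif dtype == "specialized":
            profile_bg = np.ones(n_cond, dtype=int)
            profile_sel = np.ones(n_cond, dtype=int)
            n_loss = int(rng.integers(1, max(2, n_cond // 3)))
            losses = rng.choice(n_cond, size=n_loss, replace=False)
            profile_sel[losses] = 0
        else:  # gained
            profile_bg = np.ones(n_cond, dtype=int)
            n_off = int(rng.integers(2, max(3, n_cond // 2)))
            off = rng.choice(n_cond, size=n_off, replace=False)
            profile_bg[off] = 0
            profile_sel = profile_bg.copy()
            n_gain = int(rng.integers(1, n_off + 1))
            gains = rng.choice(off, size=n_gain, replace=False)
            profile_sel[gains] = 1
        base_bg = float(rng.uniform(20, 200))
        base_sel = float(rng.uniform(20, 200))
        # per-condition activity shared by the two copies: same-profile
        # pairs then correlate across conditions, as real paralogs do
        cond_scales = rng.uniform(0.5, 2.0, size=n_cond)
        for gene, profile, base in (
            (g_bg, profile_bg, base_bg),
            (g_sel, profile_sel, base_sel),
        ):
            vals = np.concatenate(
                [
                    expressed_values(base, cond_scales[c])
                    if profile[c]
                    else np.zeros(replicates)
                    for c in range(n_cond)
                ]
            )
            rows[gene] = vals
        records.append(
            {
                "pair": pair,
                "gene_background": g_bg,
                "gene_selected": g_sel,
                "type": dtype,
                "profile_background": "".join(map(str, profile_bg)),
                "profile_selected": "".join(map(str, profile_sel)),
                "gains": int(((profile_sel == 1) & (profile_bg == 0)).sum()),
                "losses": int(((profile_sel == 0) & (profile_bg == 1)).sum()),
            }
        )

    n_silent = max(1, int(0.35 * n_background))
    for b in range(n_background):
        gene = f"bg{b:04d}"
        if b < n_silent:
            rows[gene] = np.zeros(n_cond * replicates)
        else:
            base = float(rng.uniform(5, 500))
            rows[gene] = np.concatenate(
                [
                    expressed_values(base, float(rng.uniform(0.5, 2.0)))
                    for _ in range(n_cond)
                ]
            )

    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=libraries)
    matrix.index.name = "gene"
    return matrix, design, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# FAIRE / Input coverage tracks with planted TSS states
# ---------------------------------------------------------------------------


def simulate_faire(
    n_genes: int,
    seed: int | np.random.Generator,
    conditions: Sequence[str] = ("AM", "AP", "E0"),
    open_probability: float = 0.5,
    plan: pd.DataFrame | None = None,
    models: Sequence[GeneModel] | None = None,
    depth: float = 100.0,
    open_ratio: float = 4.0,
    gene_length: int = 1000,
    spacing: int = 5000,
    half_window: int = 450,
    contig: str = "contig_1",
) -> tuple[dict[str, tuple[dict, dict]], dict[str, GeneModel], pd.DataFrame]:
    """FAIRE and Input coverage tracks with planted open/closed TSSs.

    By default genes are laid out along one contig with alternating
    strands; an explicit ``models`` sequence overrides the layout.  The
    Input track is uniform; the FAIRE track equals the Input except over
    the 900 bp TSS window of planted-open genes, where it is multiplied by
    ``open_ratio``.  ``plan`` (gene × condition, values "open"/"closed")
    overrides the random state assignment.  Returns per-condition
    ``(faire, input)`` track pairs, rank-annotated gene models, and the
    truth table.
    """
    rng = _as_rng(seed)
    conditions = list(conditions)
    if models is None:
        models = [
            GeneModel(
                gene=f"Apisum_f{g:03d}",
                contig=contig,
                start=spacing * (g + 1),
                end=spacing * (g + 1) + gene_length - 1,
                strand="+" if g % 2 == 0 else "-",
                exon_count=2,
            )
            for g in range(n_genes)
        ]
    else:
        models = list(models)
    models_by_gene = assign_ranks(models)
    contig_lengths: dict[str, int] = {}
    for m in models:
        contig_lengths[m.contig] = max(
            contig_lengths.get(m.contig, 0), m.end + spacing
        )

    if plan is None:
        states = {
            m.gene: {
                cond: "open" if rng.random() < open_probability else "closed"
                for cond in conditions
            }
            for m in models
        }
    else:
        states = {
            row["gene"]: {cond: row[cond] for cond in conditions}
            for _, row in plan.iterrows()
        }

    tracks: dict[str, tuple[dict, dict]] = {}
    for cond in conditions:
        control = {c: np.full(n, depth) for c, n in contig_lengths.items()}
        faire = {c: arr.copy() for c, arr in control.items()}
        for m in models:
            if states[m.gene][cond] != "open":
                continue
            tss0 = (m.start - 1) if m.strand == "+" else (m.end - 1)
            lo = max(tss0 - half_window, 0)
            hi = min(tss0 + half_window, contig_lengths[m.contig])
            faire[m.contig][lo:hi] *= open_ratio
        tracks[cond] = (faire, control)

    truth = pd.DataFrame(
        [
            {"gene": m.gene, **{cond: states[m.gene][cond] for cond in conditions}}
            for m in models
        ]
    )
    return tracks, models_by_gene, truth


# ---------------------------------------------------------------------------
# Neutral coalescent samples
# ---------------------------------------------------------------------------


def simulate_coalescent(
    n: int,
    theta: float,
    replicates: int,
    seed: int,
) -> list[np.ndarray]:
    """Neutral Kingman-coalescent haplotype samples under infinite sites.

    Each replicate is a (sites × samples) genotype matrix for ``n`` haploid
    samples with scaled mutation rate θ per locus (E[pairwise differences]
    = θ).  Simulation is delegated to msprime (ploidy 1, Ne = 1,
    continuous genome).
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 2)) + 1 for s in ss.spawn(2 * replicates)]
    out = []
    for r in range(replicates):
        ts = msprime.sim_ancestry(
            samples=n,
            ploidy=1,
            population_size=1.0,
            sequence_length=1.0,
            discrete_genome=False,
            random_seed=child_seeds[2 * r],
        )
        if theta > 0:
            ts = msprime.sim_mutations(
                ts,
                rate=theta / 2.0,
                discrete_genome=False,
                random_seed=child_seeds[2 * r + 1],
            )
        out.append(ts.genotype_matrix())
    return out
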