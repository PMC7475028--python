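"""End-to-end orchestration of the duplicate-fate analysis.

``run_pipeline`` exercises every stage on synthetic inputs with known
ground truth: gene-tree duplication detection and pair selection, branch
rates with fast/slow classification and dS filters, positive-selection
calls, family and location classes, tissue-expression divergence with
gain/loss counting, and TSS chromatin comparison.  The result bundle joins
everything into a pair-level master table; given the same configuration
and seed, reruns produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from dupfate import chromatin, classify, codon, expression, simulate, trees
from dupfate.classify import GeneModel
from dupfate.datasets import CONDITIONS, DISTANT_SPECIES, FOCAL_SPECIES
from dupfate.io import write_tsv

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage thresholds (defaults = the published analysis values)."""

    seed: int = 0
    # synthetic-data scale
    n_trees: int = 40
    duplication_fraction: float = 0.5
    max_copies: int = 3
    n_codons: int = 200
    replicates: int = 3
    expression_noise_sd: float = 0.0
    selected_fraction: float = 0.6  # pairs with one copy under selection
    # detection
    min_support: float = 0.95
    min_orthologs: int = 2
    # rates & age filters
    ds_min: float = 0.01
    ds_max: float = 2.0
    omega_fast: float = 1.5
    omega_slow: float = 0.1
    # selection decision rule
    alpha: float = 0.01
    # expression
    conditions: tuple = tuple(CONDITIONS)
    # chromatin
    faire_conditions: tuple = ("AM", "AP", "E0")
    faire_threshold: float = 1.0
    category_agreement: float = 0.75
    # popgen defaults (exposed for the CLI stages)
    subsample_target: int = 15
    subsample_max: int = 150
    ecai_percentile: float = 95.0


@dataclass
class PipelineResult:
    master: pd.DataFrame
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _location_plan(rng: np.random.Generator) -> str:
    # tandem : dispersed-same-contig : dispersed-different-contig,
    # roughly in the proportions seen among the analyzed duplications
    r = rng.random()
    if r < 0.12:
        return "tandem"
    if r < 0.25:
        return "dispersed-same-contig"
    return "dispersed-different-contig"


def _build_gene_models(
    pairs: Sequence[trees.DuplicatePairCandidate],
    rng: np.random.Generator,
) -> tuple[dict[str, GeneModel], pd.DataFrame]:
    """Synthetic genome layout realizing a per-pair location plan."""
    models: list[GeneModel] = []
    plan_records = []
    contig_no = 0
    gene_len, gap = 1000, 5000
    for pair in pairs:
        loc = _location_plan(rng)
        retro = loc != "tandem" and rng.random() < 0.06
        exons = (1, 3) if retro else (3, 3)
        contig_no += 1
        c1 = f"contig_{contig_no:03d}"
        if loc == "tandem":
            starts = [(c1, gap), (c1, gap + gene_len + gap)]
        elif loc == "dispersed-same-contig":
            starts = [(c1, gap), (c1, gap + 3 * (gene_len + gap))]
            # filler gene in between breaks adjacency
            models.append(
                GeneModel(
                    gene=f"filler_{contig_no:03d}",
                    contig=c1,
                    start=gap + gene_len + gap,
                    end=gap + 2 * gene_len + gap,
                    strand="+",
                    exon_count=2,
                )
            )
        else:
            contig_no += 1
            c2 = f"contig_{contig_no:03d}"
            starts = [(c1, gap), (c2, gap)]
        for gene, (contig, start), n_exons in zip(
            (pair.gene_a, pair.gene_b), starts, exons
        ):
            models.append(
                GeneModel(
                    gene=gene,
                    contig=contig,
                    start=start,
                    end=start + gene_len - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                    exon_count=n_exons,
                )
            )
        plan_records.append(
            {"pair_id": pair.pair_id, "planted_location": loc, "planted_retro": retro}
        )
    return classify.assign_ranks(models), pd.DataFrame(plan_records)


def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> PipelineResult:
    """Run every stage on synthetic data and assemble the master table."""
    rng = np.random.default_rng(config.seed)

    # --- stage 1: gene trees, duplication detection, pair selection -------
    gene_trees, tree_truth = simulate.simulate_gene_trees(
        config.n_trees,
        rng,
        duplication_fraction=config.duplication_fraction,
        max_copies=config.max_copies,
    )
    selected: list[tuple[str, trees.DuplicatePairCandidate, trees.DuplicationEvent]] = []
    event_records = []
    for tree, tree_id in zip(gene_trees, tree_truth["tree_id"]):
        events = trees.fuse_overlapping_duplications(
            trees.find_species_specific_duplications(tree, FOCAL_SPECIES)
        )
        for event in events:
            event_records.append(
                {
                    "tree_id": tree_id,
                    "members": ";".join(sorted(event.members)),
                    "n_members": len(event.members),
                }
            )
        pairs = trees.select_duplicate_pairs(
            tree,
            events,
            FOCAL_SPECIES,
            min_support=config.min_support,
            min_orthologs=config.min_orthologs,
        )
        for pair in pairs:
            if trees.distant_species_filter(pair, DISTANT_SPECIES):
                event = next(
                    e for e in events if {pair.gene_a, pair.gene_b} <= e.members
                )
                selected.append((tree_id, pair, event))
    selected.sort(key=lambda t: t[1].pair_id)

    # --- stage 2: branch rates, fast/slow, dS filters ---------------------
    rate_rows = []
    selection_truth: dict[str, bool] = {}
    raw_p: dict[str, float] = {}
    pair_meta = []
    for tree_id, pair, event in selected:
        has_selected = rng.random() < config.selected_fraction
        omega_b = config.omega_fast if has_selected else config.omega_slow
        alignment, aln_truth = simulate.simulate_pair_alignment(
            rng,
            n_codons=config.n_codons,
            omega_a=config.omega_slow,
            omega_b=omega_b,
            gene_a=pair.gene_a,
            gene_b=pair.gene_b,
        )
        rates = codon.branch_rates_on_pair_tree(
            alignment, pair.gene_a, pair.gene_b, aln_truth.outgroups
        )
        ds_a = rates.post[pair.gene_a].ds
        ds_b = rates.post[pair.gene_b].ds
        call = codon.classify_fast_slow(
            pair.pair_id, pair.gene_a, pair.gene_b, ds_a, ds_b
        )
        passes = bool(
            codon.apply_pair_rate_filters(
                {pair.pair_id: (ds_a, ds_b)}, config.ds_min, config.ds_max
            )
        )
        mnm = {
            g: codon.count_mnm(rates.ancestral, alignment[g], gene=g)
            for g in (pair.gene_a, pair.gene_b)
        }
        for gene in (pair.gene_a, pair.gene_b):
            is_selected = has_selected and gene == pair.gene_b
            selection_truth[gene] = is_selected
            raw_p[gene] = float(
                rng.uniform(1e-8, 1e-5) if is_selected else rng.uniform(0.05, 1.0)
            )
            r = rates.post[gene]
            rate_rows.append(
                {
                    "pair_id": pair.pair_id,
                    "gene": gene,
                    "branch": "post",
                    "dn": r.dn,
                    "ds": r.ds,
                    "omega": r.omega if r.omega is not None else np.nan,
                    "mnm_percent": mnm[gene].percent,
                }
            )
        rate_rows.append(
            {
                "pair_id": pair.pair_id,
                "gene": "",
                "branch": "pre",
                "dn": rates.pre.dn,
                "ds": rates.pre.ds,
                "omega": rates.pre.omega if rates.pre.omega is not None else np.nan,
                "mnm_percent": np.nan,
            }
        )
        pair_meta.append(
            {
                "tree_id": tree_id,
                "pair": pair,
                "event": event,
                "fast_slow": call,
                "passes_ds_filter": passes,
                "planted_selected": has_selected,
            }
        )

    # --- stage 3: positive-selection calls --------------------------------
    calls = (
        codon.call_positive_selection(raw_p, alpha=config.alpha) if raw_p else {}
    )

    # --- stage 4: family and location classes -----------------------------
    pairs_only = [m["pair"] for m in pair_meta]
    models, location_plan = _build_gene_models(pairs_only, rng)
    locations = {
        m["pair"].pair_id: classify.classify_location(
            m["pair"].gene_a, m["pair"].gene_b, models, m["pair"].pair_id
        )
        for m in pair_meta
    }

    # --- stage 5: expression profiles and divergence ----------------------
    matrix, design, expr_truth = simulate.simulate_expression(
        len(pair_meta),
        rng,
        conditions=config.conditions,
        replicates=config.replicates,
        noise_sd=config.expression_noise_sd,
    )
    rename: dict[str, str] = {}
    for m, (_, truth_row) in zip(pair_meta, expr_truth.iterrows()):
        pair = m["pair"]
        # gene_b carries the planted-selected role when the pair has one
        rename[truth_row["gene_background"]] = pair.gene_a
        rename[truth_row["gene_selected"]] = pair.gene_b
        m["expr_type"] = truth_row["type"]
    matrix = matrix.rename(index=rename)
    profiles, _, _ = expression.profiles_from_matrix(matrix, design)
    medians = expression.condition_medians(matrix, design)

    divergence_rows = []
    for m in pair_meta:
        pair = m["pair"]
        prof_a, prof_b = profiles.loc[pair.gene_a], profiles.loc[pair.gene_b]
        stats = expression.divergence_stats(prof_a, prof_b, pair.pair_id)
        corr = expression.pair_correlation(
            medians.loc[pair.gene_a], medians.loc[pair.gene_b], pair.pair_id
        )
        one_selected = (
            calls
            and calls[pair.gene_a].positively_selected
            != calls[pair.gene_b].positively_selected
        )
        if one_selected:
            sel, bg = (
                (pair.gene_a, pair.gene_b)
                if calls[pair.gene_a].positively_selected
                else (pair.gene_b, pair.gene_a)
            )
            gl = expression.gain_loss(
                profiles.loc[sel], profiles.loc[bg], pair.pair_id, bg
            )
            gains, losses = gl.gains, gl.losses
        else:
            gains = losses = np.nan
        m.update(
            hamming=stats.hamming,
            tec=stats.tec,
            dt=stats.dt,
            considered=stats.considered,
            gains=gains,
            losses=losses,
            pearson_r=corr.r,
            slope=corr.slope,
        )
        divergence_rows.append(
            {
                "pair_id": pair.pair_id,
                "hamming": stats.hamming,
                "tec": stats.tec,
                "dt": stats.dt,
                "considered": stats.considered,
                "gains": gains,
                "losses": losses,
                "pearson_r": corr.r,
                "pearson_p": corr.p,
                "r2": corr.r2,
                "slope": corr.slope,
            }
        )

    # --- stage 6: chromatin state around the TSS --------------------------
    pair_genes = [g for m in pair_meta for g in (m["pair"].gene_a, m["pair"].gene_b)]
    faire_tracks, faire_models, faire_truth = simulate.simulate_faire(
        len(pair_genes),
        rng,
        conditions=config.faire_conditions,
        models=[models[g] for g in pair_genes],
    )
    open_calls: dict[str, dict[str, str | None]] = {g: {} for g in pair_genes}
    for cond, (faire_cov, input_cov) in faire_tracks.items():
        track = chromatin.log2_ratio_track(faire_cov, input_cov)
        for gene in pair_genes:
            sig = chromatin.tss_window_mean(track, faire_models[gene])
            open_calls[gene][cond] = chromatin.call_open_closed(
                sig.mean, config.faire_threshold
            )
    categories = {
        gene: chromatin.assign_joint_category(
            open_calls[gene],
            profiles.loc[gene],
            gene,
            min_agreement=config.category_agreement,
        )
        for gene in pair_genes
    }
    for m in pair_meta:
        pair = m["pair"]
        m["chromatin_different"] = chromatin.pair_different_chromatin(
            open_calls[pair.gene_a], open_calls[pair.gene_b]
        )

    # --- master table ------------------------------------------------------
    master_rows = []
    for m in pair_meta:
        pair = m["pair"]
        call = m["fast_slow"]
        loc = locations[pair.pair_id]
        master_rows.append(
            {
                "pair_id": pair.pair_id,
                "tree_id": m["tree_id"],
                "gene_a": pair.gene_a,
                "gene_b": pair.gene_b,
                "support": pair.duplication_support,
                "n_orthologs": len(pair.orthologs),
                "family_class": classify.classify_family(m["event"]),
                "location": loc.location,
                "retrocopy": loc.retrocopy,
                "slow_copy": call.slow,
                "fast_copy": call.fast,
                "ds_slow": call.ds_slow,
                "ds_fast": call.ds_fast,
                "passes_ds_filter": m["passes_ds_filter"],
                "selected_a": calls[pair.gene_a].positively_selected,
                "selected_b": calls[pair.gene_b].positively_selected,
                "hamming": m["hamming"],
                "tec": m["tec"],
                "dt": m["dt"],
                "gains": m["gains"],
                "losses": m["losses"],
                "pearson_r": m["pearson_r"],
                "slope": m["slope"],
                "chromatin_different": m["chromatin_different"],
                "category_a": categories[pair.gene_a].gene_category or "unassigned",
                "category_b": categories[pair.gene_b].gene_category or "unassigned",
            }
        )
    master = pd.DataFrame(master_rows)
    if not master.empty:
        master = master.sort_values("pair_id").reset_index(drop=True)

    tables = {
        "tree_truth": tree_truth,
        "events": pd.DataFrame(event_records),
        "rates": pd.DataFrame(rate_rows),
        "divergence": pd.DataFrame(divergence_rows),
        "expression_truth": expr_truth,
        "faire_truth": faire_truth,
        "location_plan": location_plan,
        "selection_truth": pd.DataFrame(
            sorted(
                ({"gene": g, "planted_selected": v} for g, v in selection_truth.items()),
                key=lambda r: r["gene"],
            )
        ),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tsv(master, outdir / "master.tsv")
        for name, df in tables.items():
            write_tsv(df, outdir / f"{name}.tsv")
        provenance = {
            "config": asdict(config),
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
        (outdir / "provenance.json").write_text(
            json.dumps(provenance, indent=2, default=str) + "\n"
        )

    return PipelineResult(master=master, tables=tables)
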