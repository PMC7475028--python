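"""Readers and writers for the standard text formats the pipeline consumes.

Coordinate conventions: GFF3 gene models are 1-based inclusive; coverage
tracks and signal bins are 0-based half-open.  All conversions happen here.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from dupfate.classify import GeneModel, assign_ranks


# -- trees ------------------------------------------------------------------


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a rooted Newick tree; internal-node labels carry aLRT support."""
    looks_like_newick = isinstance(source, str) and source.lstrip().startswith("(")
    if isinstance(source, Path) or (not looks_like_newick and Path(source).exists()):
        data = Path(source).read_text()
    else:
        data = str(source)
    tree = dendropy.Tree.get(
        data=data,
        schema="newick",
        rooting="default-rooted",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True)
    )


def read_species_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (gene id, species) → mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "species"])
    return dict(zip(df["gene"].astype(str), df["species"].astype(str)))


# -- sequences --------------------------------------------------------------


def read_codon_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_codon_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# -- gene models ------------------------------------------------------------


def read_gff_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Gene models (with exon counts and contig ranks) from a GFF3 file.

    Uses ``gene`` features for coordinates and counts ``exon`` features per
    gene via the ``Parent``/``ID`` attributes (a gene with no annotated
    exons counts as single-exon).
    """
    cols = [
        "seqid", "source", "type", "start", "end",
        "score", "strand", "phase", "attributes",
    ]
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=cols,
        dtype={"seqid": str, "type": str, "attributes": str},
    )

    def attr(s: str, key: str) -> str | None:
        for part in s.split(";"):
            part = part.strip()
            if part.startswith(key + "="):
                return part[len(key) + 1 :]
        return None

    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    for _, row in df[df["type"] == "gene"].iterrows():
        gid = attr(row["attributes"], "ID")
        if gid is None:
            raise ValueError("gene feature without ID attribute")
        genes[gid] = {
            "contig": row["seqid"],
            "start": int(row["start"]),
            "end": int(row["end"]),
            "strand": row["strand"],
            "exons": 0,
        }
    for _, row in df[df["type"] == "mRNA"].iterrows():
        mid = attr(row["attributes"], "ID")
        parent = attr(row["attributes"], "Parent")
        if mid and parent in genes:
            mrna_parent[mid] = parent
    for _, row in df[df["type"] == "exon"].iterrows():
        parent = attr(row["attributes"], "Parent")
        if parent is None:
            continue
        for p in parent.split(","):
            gene = mrna_parent.get(p, p)
            if gene in genes:
                genes[gene]["exons"] += 1

    models = [
        GeneModel(
            gene=gid,
            contig=info["contig"],
            start=info["start"],
            end=info["end"],
            strand=info["strand"],
            exon_count=max(info["exons"], 1),
        )
        for gid, info in genes.items()
    ]
    return assign_ranks(models)


def write_gff_gene_models(
    models: Iterable[GeneModel], path: str | Path, exon_spans: Mapping[str, list] | None = None
) -> None:
    """Emit gene (+ optional exon) features as GFF3."""
    lines = ["##gff-version 3"]
    for m in sorted(models, key=lambda m: (m.contig, m.start, m.gene)):
        lines.append(
            "\t".join(
                [m.contig, "dupfate", "gene", str(m.start), str(m.end),
                 ".", m.strand, ".", f"ID={m.gene}"]
            )
        )
        spans = (exon_spans or {}).get(m.gene)
        if spans is None:
            spans = [(m.start, m.end)] if m.exon_count == 1 else []
        for i, (lo, hi) in enumerate(spans, 1):
            lines.append(
                "\t".join(
                    [m.contig, "dupfate", "exon", str(lo), str(hi),
                     ".", m.strand, ".", f"ID={m.gene}.e{i};Parent={m.gene}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# -- expression -------------------------------------------------------------


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes × libraries TPM/FPKM table (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_design(path: str | Path) -> dict[str, str]:
    """Two-column TSV (library, condition) → mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["library", "condition"])
    return dict(zip(df["library"].astype(str), df["condition"].astype(str)))


# -- coverage tracks --------------------------------------------------------


def read_bedgraph(
    path: str | Path, contig_lengths: Mapping[str, int] | None = None
) -> dict[str, np.ndarray]:
    """bedGraph (contig, start, end, value; 0-based half-open) → per-base arrays."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["contig", "start", "end", "value"],
        dtype={"contig": str},
    )
    lengths = dict(contig_lengths or {})
    for contig, sub in df.groupby("contig"):
        lengths.setdefault(contig, int(sub["end"].max()))
        lengths[contig] = max(lengths[contig], int(sub["end"].max()))
    tracks = {c: np.zeros(n, dtype=float) for c, n in lengths.items()}
    for row in df.itertuples(index=False):
        tracks[row.contig][int(row.start) : int(row.end)] = float(row.value)
    return tracks


def write_bedgraph(tracks: Mapping[str, np.ndarray], path: str | Path) -> None:
    buf = _io.StringIO()
    for contig in sorted(tracks):
        arr = np.asarray(tracks[contig], dtype=float)
        if len(arr) == 0:
            continue
        # run-length encode constant stretches
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(arr)]])
        for lo, hi in zip(starts, ends):
            buf.write(f"{contig}\t{lo}\t{hi}\t{arr[lo]:g}\n")
    Path(path).write_text(buf.getvalue())


# -- site counts ------------------------------------------------------------


def read_site_counts(path: str | Path) -> pd.DataFrame:
    """Pileup-like TSV: contig, pos (1-based), A, C, G, T, coverage."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    required = {"contig", "pos", "A", "C", "G", "T"}
    if not required <= set(df.columns):
        raise ValueError(f"site-count TSV must contain columns {sorted(required)}")
    if "coverage" not in df.columns:
        df["coverage"] = df[["A", "C", "G", "T"]].sum(axis=1)
    return df


def read_codon_usage(path: str | Path) -> dict[str, float]:
    """Codon usage TSV (codon, frequency per 1000) → mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["codon", "freq"],
                     comment="#")
    return dict(zip(df["codon"].str.upper(), df["freq"].astype(float)))


# -- generic TSV output -----------------------------------------------------


def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    """Deterministic TSV output (fixed float formatting, no index)."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
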