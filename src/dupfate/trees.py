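"""Species-overlap duplication detection in rooted gene trees.

A gene-tree internal node is a *duplication* when the species sets of its
daughter partitions intersect, and a *speciation* otherwise (the
reconciliation-free species-overlap rule).  Lineage-specific duplications of
a focal species are the maximal clades whose leaves all belong to that
species; overlapping events are fused, and analyzable paralog pairs are
selected on branch support and on the availability of single-copy orthologs.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import dendropy

logger = logging.getLogger(__name__)

SPECIES_PATTERN = re.compile(r"^([^_]+)_")


def species_of_label(label: str, pattern: re.Pattern | str = SPECIES_PATTERN) -> str:
    """Extract the species identifier from a ``SPECIES_geneid`` leaf label."""
    if isinstance(pattern, str):
        pattern = re.compile(pattern)
    m = pattern.match(label)
    if m is None:
        raise ValueError(f"cannot parse species from leaf label {label!r}")
    return m.group(1)


def _leaf_label(leaf: dendropy.Node) -> str:
    if leaf.taxon is not None:
        return leaf.taxon.label
    if leaf.label is not None:
        return leaf.label
    raise ValueError("leaf without a label")


def _species_lookup(
    species_map: Mapping[str, str] | Callable[[str], str] | None,
) -> Callable[[str], str]:
    if species_map is None:
        return species_of_label
    if callable(species_map):
        return species_map
    return lambda label: species_map[label]


def leaf_species_sets(
    tree: dendropy.Tree,
    species_map: Mapping[str, str] | Callable[[str], str] | None = None,
) -> dict[dendropy.Node, frozenset[str]]:
    """Species set of the clade under every node (postorder accumulation)."""
    lookup = _species_lookup(species_map)
    sets: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset({lookup(_leaf_label(node))})
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= sets[child]
            sets[node] = frozenset(acc)
    return sets


def label_nodes_species_overlap(
    tree: dendropy.Tree,
    species_map: Mapping[str, str] | Callable[[str], str] | None = None,
) -> dict[dendropy.Node, str]:
    """Label every internal node ``"speciation"`` or ``"duplication"``.

    A node is a duplication iff any two of its daughter partitions share at
    least one species (polytomies are treated pairwise).

    Raises
    ------
    ValueError
        If the tree has fewer than two leaves or an unresolved (unrooted)
        basal trichotomy flagged as unrooted by the source.
    """
    if len(tree.leaf_nodes()) < 2:
        raise ValueError("species-overlap labelling requires >= 2 leaves")
    if tree.is_rooted is False:
        raise ValueError("species-overlap labelling requires a rooted tree")
    sets = leaf_species_sets(tree, species_map)
    labels: dict[dendropy.Node, str] = {}
    for node in tree.preorder_internal_node_iter():
        children = node.child_nodes()
        dup = any(
            sets[a] & sets[b] for a, b in itertools.combinations(children, 2)
        )
        labels[node] = "duplication" if dup else "speciation"
    return labels


@dataclass
class DuplicationEvent:
    """A maximal focal-species-only clade with >= 2 genes."""

    members: frozenset[str]
    node: dendropy.Node | None = None
    fused_from: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a duplication event needs >= 2 member genes")


def find_species_specific_duplications(
    tree: dendropy.Tree,
    focal: str,
    species_map: Mapping[str, str] | Callable[[str], str] | None = None,
) -> list[DuplicationEvent]:
    """Maximal nodes whose leaves are all (>1) genes of the focal species."""
    sets = leaf_species_sets(tree, species_map)
    events: list[DuplicationEvent] = []

    def walk(node: dendropy.Node) -> None:
        if sets[node] == frozenset({focal}):
            leaves = [_leaf_label(lf) for lf in node.leaf_iter()]
            if len(leaves) > 1:
                events.append(
                    DuplicationEvent(members=frozenset(leaves), node=node)
                )
            return  # maximal: do not descend into nested focal-only clades
        for child in node.child_nodes():
            walk(child)

    walk(tree.seed_node)
    return events


def fuse_overlapping_duplications(
    events: Sequence[DuplicationEvent],
) -> list[DuplicationEvent]:
    """Fuse events sharing more than half of the smaller event's members.

    Two events fuse when ``|A ∩ B| / min(|A|, |B|) > 0.5``.  Fusion is
    applied to closure: merged events are re-examined against the rest
    until no further pair satisfies the criterion, so fusing an
    already-fused list is a no-op.
    """

    def one_pass(
        current: list[DuplicationEvent],
    ) -> tuple[list[DuplicationEvent], bool]:
        n = len(current)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        changed = False
        for i, j in itertools.combinations(range(n), 2):
            a, b = current[i].members, current[j].members
            if len(a & b) / min(len(a), len(b)) > 0.5 and find(i) != find(j):
                parent[find(i)] = find(j)
                changed = True
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        merged: list[DuplicationEvent] = []
        for idxs in groups.values():
            if len(idxs) == 1:
                merged.append(current[idxs[0]])
            else:
                members = frozenset().union(*(current[i].members for i in idxs))
                fused_from: list[frozenset[str]] = []
                for i in idxs:
                    fused_from.extend(
                        current[i].fused_from or [current[i].members]
                    )
                merged.append(
                    DuplicationEvent(
                        members=members, node=None, fused_from=fused_from
                    )
                )
        return merged, changed

    fused = list(events)
    changed = True
    while changed:
        fused, changed = one_pass(fused)
    fused.sort(key=lambda e: sorted(e.members))
    return fused


@dataclass
class DuplicatePairCandidate:
    """A selected focal paralog pair with its support and ortholog context."""

    gene_a: str
    gene_b: str
    duplication_support: float
    orthologs: list[tuple[str, str]]
    from_expansion: bool = False
    event_members: frozenset[str] = frozenset()
    retained: bool | None = None

    @property
    def pair_id(self) -> str:
        return f"{min(self.gene_a, self.gene_b)}|{max(self.gene_a, self.gene_b)}"

    @property
    def ortholog_species(self) -> set[str]:
        return {sp for sp, _ in self.orthologs}


def node_support(node: dendropy.Node) -> float | None:
    """aLRT support parsed from the internal-node label position."""
    label = node.label
    if label is None and node.taxon is not None:
        label = node.taxon.label
    if label is None:
        return None
    try:
        return float(label)
    except (TypeError, ValueError):
        return None


def mrca_of_leaves(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Node:
    wanted = set(labels)
    found: dict[str, dendropy.Node] = {}
    for leaf in tree.leaf_node_iter():
        lab = _leaf_label(leaf)
        if lab in wanted:
            found[lab] = leaf
    missing = wanted - set(found)
    if missing:
        raise KeyError(f"leaves not present in tree: {sorted(missing)}")
    nodes = list(found.values())
    paths = []
    for node in nodes:
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        paths.append(path[::-1])
    mrca = None
    for ancestors in zip(*paths):
        if all(a is ancestors[0] for a in ancestors):
            mrca = ancestors[0]
        else:
            break
    assert mrca is not None
    return mrca


def single_copy_orthologs(
    tree: dendropy.Tree,
    focal: str,
    species_map: Mapping[str, str] | Callable[[str], str] | None = None,
) -> list[tuple[str, str]]:
    """Non-focal species represented by exactly one gene in the tree."""
    lookup = _species_lookup(species_map)
    per_species: dict[str, list[str]] = {}
    for leaf in tree.leaf_node_iter():
        lab = _leaf_label(leaf)
        per_species.setdefault(lookup(lab), []).append(lab)
    return sorted(
        (sp, genes[0])
        for sp, genes in per_species.items()
        if sp != focal and len(genes) == 1
    )


def select_duplicate_pairs(
    tree: dendropy.Tree,
    events: Sequence[DuplicationEvent],
    focal: str,
    min_support: float = 0.95,
    min_orthologs: int = 2,
    tips_only_for_expansions: bool = True,
    species_map: Mapping[str, str] | Callable[[str], str] | None = None,
) -> list[DuplicatePairCandidate]:
    """Select analyzable paralog pairs from duplication events.

    A pair qualifies when its duplication node's aLRT support strictly
    exceeds ``min_support`` and the tree provides single-copy orthologs in
    at least ``min_orthologs`` other species.  For events with more than two
    members only sister tips (cherries) are paired.  Pairs whose duplication
    node carries no parseable support are skipped with a warning.
    """
    orthologs = single_copy_orthologs(tree, focal, species_map)
    pairs: list[DuplicatePairCandidate] = []
    if len(orthologs) < min_orthologs:
        return pairs

    for event in events:
        members = sorted(event.members)
        expansion = len(members) > 2
        candidates: list[tuple[str, str, dendropy.Node]] = []
        if not expansion:
            node = event.node or mrca_of_leaves(tree, members)
            candidates.append((members[0], members[1], node))
        elif tips_only_for_expansions:
            clade = event.node or mrca_of_leaves(tree, members)
            for node in clade.preorder_iter():
                children = node.child_nodes()
                if len(children) == 2 and all(c.is_leaf() for c in children):
                    a, b = sorted(_leaf_label(c) for c in children)
                    if a in event.members and b in event.members:
                        candidates.append((a, b, node))
        for gene_a, gene_b, node in candidates:
            support = node_support(node)
            if support is None:
                logger.warning(
                    "pair (%s, %s) skipped: duplication node has no support",
                    gene_a,
                    gene_b,
                )
                continue
            if support > min_support:
                pairs.append(
                    DuplicatePairCandidate(
                        gene_a=gene_a,
                        gene_b=gene_b,
                        duplication_support=support,
                        orthologs=list(orthologs),
                        from_expansion=expansion,
                        event_members=event.members,
                    )
                )
    return pairs


def verify_duplication_retained(
    second_tree: dendropy.Tree,
    pair: DuplicatePairCandidate,
    focal: str,
    species_map: Mapping[str, str] | Callable[[str], str] | None = None,
) -> bool:
    """True iff the pair's MRCA in a re-estimated tree is focal-species-only."""
    lookup = _species_lookup(species_map)
    mrca = mrca_of_leaves(second_tree, [pair.gene_a, pair.gene_b])
    return all(
        lookup(_leaf_label(leaf)) == focal for leaf in mrca.leaf_iter()
    )


def distant_species_filter(
    pair: DuplicatePairCandidate, distant_species: set[str]
) -> bool:
    """Keep a pair unless all of its orthologs are in the distant species."""
    species = pair.ortholog_species
    return not (species and species <= set(distant_species))


def duplication_ratio_per_node(
    species_tree: dendropy.Tree,
    gene_trees: Sequence[dendropy.Tree],
    species_map: Mapping[str, str] | Callable[[str], str] | None = None,
) -> dict[frozenset[str], float]:
    """Duplications per species-tree node over gene trees containing it.

    A duplication node maps to the species-tree MRCA of its descendant
    species.  A gene tree "contains" a species-tree node when it samples at
    least one species from each daughter partition of that node (for tips:
    when the species is present), so that the node would appear in the
    induced species tree.  Results are keyed by the node's clade species set.
    """
    if not gene_trees:
        raise ValueError("empty gene-tree set")
    sp_sets = leaf_species_sets(species_tree, species_map=lambda lab: lab)
    node_partitions: dict[frozenset[str], list[frozenset[str]]] = {}
    for node in species_tree.preorder_node_iter():
        clade = sp_sets[node]
        node_partitions[clade] = [sp_sets[c] for c in node.child_nodes()]

    dup_counts: dict[frozenset[str], int] = {k: 0 for k in node_partitions}
    containing: dict[frozenset[str], int] = {k: 0 for k in node_partitions}

    for tree in gene_trees:
        gsets = leaf_species_sets(tree, species_map)
        tree_species = gsets[tree.seed_node]
        for clade, parts in node_partitions.items():
            if not parts:  # species-tree tip
                present = clade <= tree_species
            else:
                present = all(tree_species & p for p in parts)
            if present:
                containing[clade] += 1
        labels = label_nodes_species_overlap(tree, species_map)
        for node, lab in labels.items():
            if lab != "duplication":
                continue
            dup_species = gsets[node]
            target = min(
                (c for c in node_partitions if dup_species <= c),
                key=len,
                default=None,
            )
            if target is not None:
                dup_counts[target] += 1

    return {
        clade: (dup_counts[clade] / containing[clade]) if containing[clade] else 0.0
        for clade in node_partitions
    }
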