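"""Gene-tree / species-tree conflict and minimize-deep-coalescences (MDC).

Conflict detection works on group-level, support-collapsed trees: two
trees conflict when some pair of their resolved splits is incompatible.
The *conflicted groups* of a marker are the smallest set of group codes
whose removal from both trees leaves every remaining pair of splits
compatible; found by exhaustive search over subsets in increasing size
(at most 7 groups, so at most 128 subsets).  When several subsets of
the minimal size work, their union is reported — the duplication-scheme
builder treats that union conservatively.

MDC scoring counts "extra lineages": for each cluster C of the species
tree, the minimum number of gene-tree lineages exiting C is the number
of maximal gene-tree clades whose tips all map into C, and each lineage
beyond the first is an extra one (Maddison's deep-coalescence count).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import dendropy

from . import treekit as tk

__all__ = [
    "ConflictReport",
    "conflicting_bipartitions",
    "identify_conflicting_groups",
    "mdc_score",
    "min_resolved_mdc_score",
    "MDCResult",
    "infer_species_tree_mdc",
]


@dataclass
class ConflictReport:
    """Per-marker summary of conflict against a reference topology."""

    marker: str
    reference: str
    conflicted_groups: frozenset[str]
    conflicting_pairs: list[tuple[frozenset[str], frozenset[str]]] = field(
        default_factory=list
    )
    rf: int = 0
    minimal_subsets: list[frozenset[str]] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not self.conflicted_groups

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "reference": self.reference,
            "conflicted_groups": sorted(self.conflicted_groups),
            "rf": self.rf,
            "n_conflicting_pairs": len(self.conflicting_pairs),
            "minimal_subsets": [sorted(s) for s in self.minimal_subsets],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @staticmethod
    def tsv_header() -> str:
        return "marker\treference\tconflicted_groups\trf"

    def to_tsv_row(self) -> str:
        return (
            f"{self.marker}\t{self.reference}\t"
            f"{','.join(sorted(self.conflicted_groups)) or '-'}\t{self.rf}"
        )


def conflicting_bipartitions(t1: dendropy.Tree, t2: dendropy.Tree):
    """All pairwise-incompatible split pairs (one from each tree)."""
    x1, x2 = tk.tip_labels(t1), tk.tip_labels(t2)
    if x1 != x2:
        raise tk.TipSetMismatchError(
            f"tip sets differ: {sorted(x1 ^ x2)} not shared"
        )
    ref = min(x1)
    out = []
    for b1 in sorted(tk.bipartitions(t1, ref), key=sorted):
        for b2 in sorted(tk.bipartitions(t2, ref), key=sorted):
            if not tk.splits_compatible(b1, b2, x1):
                out.append((b1, b2))
    return out


def _all_compatible(s1, s2, taxa) -> bool:
    return all(tk.splits_compatible(a, b, taxa) for a in s1 for b in s2)


def identify_conflicting_groups(
    gene_tree: dendropy.Tree,
    reference: dendropy.Tree,
    groups: tk.GroupMap,
    marker: str = "gene",
    reference_name: str = "reference",
) -> ConflictReport:
    """Minimal group removal reconciling a gene tree with the reference.

    Both trees must already be reduced to group level (one tip per
    group code) and support-collapsed.  All minimal subsets are found;
    ``conflicted_groups`` is their union.
    """
    taxa = tk.tip_labels(gene_tree)
    if taxa != tk.tip_labels(reference):
        raise tk.TipSetMismatchError("gene tree and reference differ in tips")
    ref_taxon = min(taxa)
    s_gene = tk.bipartitions(gene_tree, ref_taxon)
    s_ref = tk.bipartitions(reference, ref_taxon)
    pairs = conflicting_bipartitions(gene_tree, reference)
    rf = len(s_gene ^ s_ref)

    minimal: list[frozenset[str]] = []
    codes = sorted({groups.group_of(t) for t in taxa})
    for size in range(len(codes) + 1):
        for combo in itertools.combinations(codes, size):
            drop = set().union(*(groups.taxa_of(c) for c in combo)) if combo else set()
            keep = frozenset(taxa - drop)
            r_gene = tk.restrict_splits(s_gene, keep)
            r_ref = tk.restrict_splits(s_ref, keep)
            if _all_compatible(r_gene, r_ref, keep):
                minimal.append(frozenset(combo))
        if minimal:
            break
    conflicted = frozenset().union(*minimal) if minimal else frozenset()
    return ConflictReport(
        marker=marker,
        reference=reference_name,
        conflicted_groups=frozenset(conflicted),
        conflicting_pairs=pairs,
        rf=rf,
        minimal_subsets=minimal,
    )


# ---------------------------------------------------------------------------
# MDC


def _is_binary(tree: dendropy.Tree) -> bool:
    return all(len(nd.child_nodes()) == 2 for nd in tree.preorder_internal_node_iter())


def _species_clusters(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf sets of all non-root clusters (internal and tip edges)."""
    out = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        ls = (
            frozenset({nd.taxon.label})
            if nd.is_leaf()
            else frozenset(l.taxon.label for l in nd.leaf_iter())
        )
        out.append(ls)
    return out


def _maximal_clades_within(gene_tree: dendropy.Tree, allowed: set[str],
                           allele_map) -> int:
    """Number of maximal gene-tree clades whose tips all map into ``allowed``."""

    count = 0
    inside: dict = {}
    for nd in gene_tree.postorder_node_iter():
        if nd.is_leaf():
            inside[nd] = allele_map[nd.taxon.label] in allowed
        else:
            inside[nd] = all(inside[ch] for ch in nd.child_nodes())
    for nd in gene_tree.preorder_node_iter():
        if inside[nd] and (nd.parent_node is None or not inside[nd.parent_node]):
            count += 1
    return count


def mdc_score(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    allele_map: dict[str, str] | None = None,
) -> int:
    """Deep-coalescence count for embedding a binary gene tree in a binary
    species tree.  ``allele_map`` maps gene tips to species tips (identity
    by default).  The score is 0 iff (with one allele per species) the two
    trees share their topology."""
    if not _is_binary(gene_tree):
        raise ValueError("gene tree must be binary (resolve polytomies first)")
    if not _is_binary(species_tree):
        raise ValueError("species tree must be binary")
    gtips = tk.tip_labels(gene_tree)
    if allele_map is None:
        allele_map = {t: t for t in gtips}
    unmapped = gtips - set(allele_map)
    if unmapped:
        raise tk.UnknownTaxonError(sorted(unmapped))
    stips = tk.tip_labels(species_tree)
    bad = {allele_map[t] for t in gtips} - stips
    if bad:
        raise tk.UnknownTaxonError(sorted(bad))

    total = 0
    for cluster in _species_clusters(species_tree):
        k = _maximal_clades_within(gene_tree, set(cluster), allele_map)
        if k:
            total += k - 1
    return total


def min_resolved_mdc_score(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    allele_map: dict[str, str] | None = None,
    limit: int = 100_000,
) -> int:
    """MDC score of a possibly polytomous gene tree: the best (minimum)
    score over its binary resolutions (exhaustive; small trees only)."""
    if _is_binary(gene_tree):
        return mdc_score(gene_tree, species_tree, allele_map)
    best = None
    for top in tk.enumerate_resolutions(gene_tree, limit=limit):
        s = mdc_score(tk.tree_from_nested(top), species_tree, allele_map)
        if best is None or s < best:
            best = s
        if best == 0:
            break
    return best


@dataclass
class MDCResult:
    tree: dendropy.Tree
    score: int
    co_optimal: list[str]  # newick strings of all optimal topologies


# -- bitmask fast path for the exhaustive search ----------------------------
# Leaf sets become integer bitmasks over the species list; the per-cluster
# maximal-clade count is then a pair of masked comparisons, vectorized over
# every binary resolution of every gene tree at once.


def _collect_mask_nodes(nested, bit: dict[str, int], amap):
    """(mask, parent_mask) for every node of a nested topology; the root's
    pseudo-parent carries a sentinel bit outside every cluster."""
    entries: list[tuple[int, int]] = []
    sentinel = 1 << len(bit)

    def mask_of(node) -> int:
        if not isinstance(node, tuple):
            return bit[amap[node]]
        m = 0
        for c in node:
            m |= mask_of(c)
        return m

    def collect(node, node_mask):
        for c in node:
            cm = mask_of(c)
            entries.append((cm, node_mask))
            if isinstance(c, tuple):
                collect(c, cm)

    full = mask_of(nested)
    entries.append((full, sentinel))
    collect(nested, full)
    return entries


def _cluster_masks(nested, bit: dict[str, int]) -> list[int]:
    """Masks of all non-root clusters (tip and internal) of a topology."""
    out: list[int] = []

    def walk(node, is_root) -> int:
        if not isinstance(node, tuple):
            m = bit[node]
            out.append(m)
            return m
        mask = 0
        for c in node:
            mask |= walk(c, False)
        if not is_root:
            out.append(mask)
        return mask

    walk(nested, True)
    return out


def infer_species_tree_mdc(
    gene_trees: list[dendropy.Tree],
    allele_map: dict[str, str] | None = None,
    species: list[str] | None = None,
) -> MDCResult:
    """Exhaustive MDC species-tree search over rooted binary topologies.

    Limited to <= 8 species (7 species already mean 10,395 candidate
    topologies).  Ties are all returned; ``tree`` is the first winner in
    canonical (sorted-Newick) order.
    """
    if not gene_trees:
        raise ValueError("no gene trees given")
    if allele_map is None:
        allele_map = {}
        for gt in gene_trees:
            allele_map.update({t: t for t in tk.tip_labels(gt)})
    if species is None:
        species = sorted(set(allele_map.values()))
    if len(species) > 8:
        raise ValueError(
            f"{len(species)} species: exhaustive search capped at 8 "
            "(a heuristic search is out of scope)"
        )

    import numpy as np

    bit = {s: 1 << i for i, s in enumerate(species)}

    # Pre-resolve polytomous gene trees once, flattening every binary
    # resolution of every gene tree into shared mask arrays.
    node_masks: list[int] = []
    parent_masks: list[int] = []
    res_ids: list[int] = []
    res_gene: list[int] = []  # resolution index -> gene index
    n_res = 0
    for gi, gt in enumerate(gene_trees):
        nesteds = (
            [_tree_to_nested(gt)]
            if _is_binary(gt)
            else list(tk.enumerate_resolutions(gt))
        )
        for nested in nesteds:
            for m, p in _collect_mask_nodes(nested, bit, allele_map):
                node_masks.append(m)
                parent_masks.append(p)
                res_ids.append(n_res)
            res_gene.append(gi)
            n_res += 1
    node_arr = np.array(node_masks, dtype=np.int64)
    parent_arr = np.array(parent_masks, dtype=np.int64)
    res_arr = np.array(res_ids, dtype=np.int64)
    res_gene_arr = np.array(res_gene, dtype=np.int64)
    full = (1 << len(species)) - 1

    best_score = None
    best_newicks: list[str] = []
    for top in tk.enumerate_rooted_topologies(species):
        totals = np.zeros(n_res, dtype=np.int64)
        for cluster in _cluster_masks(top, bit):
            not_c = (full ^ cluster) | (1 << len(species))
            inside = (node_arr & not_c) == 0
            crossing = inside & ((parent_arr & not_c) != 0)
            counts = np.bincount(res_arr[crossing], minlength=n_res)
            totals += counts - (counts > 0)
        # each gene contributes the best (minimum) of its resolutions
        total = 0
        for gi in range(len(gene_trees)):
            total += int(totals[res_gene_arr == gi].min())
        if best_score is None or total < best_score:
            best_score = total
            best_newicks = [tk.nested_to_newick(top)]
        elif total == best_score:
            best_newicks.append(tk.nested_to_newick(top))
    best_newicks.sort()
    return MDCResult(
        tree=tk.parse_newick(best_newicks[0]),
        score=int(best_score),
        co_optimal=best_newicks,
    )


def _tree_to_nested(tree: dendropy.Tree):
    def walk(nd):
        if nd.is_leaf():
            return nd.taxon.label
        kids = [walk(c) for c in nd.child_nodes()]
        out = kids[0]
        for k in kids[1:]:
            out = (out, k)
        return out

    return walk(tree.seed_node)
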