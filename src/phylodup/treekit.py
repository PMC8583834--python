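"""Rooted-tree data model and basic operations.

Trees are held as :class:`dendropy.Tree` objects (rooted, polytomies
allowed).  Node supports are posterior-probability-like values in [0, 1]
parsed from numeric internal-node labels; they live on ``node.support``
and are written back as internal labels.  Branch lengths may be in
substitutions/site or in Ma — callers track which.

The split (bipartition) machinery is set-based: each non-trivial split
is represented by the frozenset of tip labels on the side *not*
containing a designated reference taxon (by default the
lexicographically smallest tip), so complementary sides compare equal.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "NewickParseError",
    "TipSetMismatchError",
    "UnknownTaxonError",
    "NonUltrametricError",
    "NonMonophyleticGroupError",
    "GroupMap",
    "parse_newick",
    "write_newick",
    "clone_tree",
    "tip_labels",
    "collapse_low_support",
    "bipartitions",
    "rf_distance",
    "is_monophyletic",
    "node_ages",
    "tmrca",
    "to_group_tree",
    "restrict_splits",
    "splits_compatible",
    "random_binary_tree",
    "enumerate_rooted_topologies",
    "enumerate_resolutions",
    "nested_to_newick",
    "tree_from_nested",
]


class NewickParseError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate tips...)."""


class TipSetMismatchError(ValueError):
    """Two trees that should share a tip set do not."""


class UnknownTaxonError(KeyError):
    """A taxon named in a query is not a tip of the tree."""


class NonUltrametricError(ValueError):
    """An operation requiring equal root-to-tip depths got an uneven tree."""


class NonMonophyleticGroupError(ValueError):
    """A group that must form a clade does not."""

    def __init__(self, group: str):
        super().__init__(f"group {group!r} is not monophyletic")
        self.group = group


# ---------------------------------------------------------------------------
# Group map


@dataclass(frozen=True)
class GroupMap:
    """Taxon -> group code mapping plus group metadata.

    ``roles`` marks each group code as ``"ingroup"`` or ``"outgroup"``.
    """

    taxon_to_group: dict[str, str]
    display_names: dict[str, str] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)

    @property
    def codes(self) -> list[str]:
        seen: list[str] = []
        for g in self.taxon_to_group.values():
            if g not in seen:
                seen.append(g)
        return sorted(seen)

    @property
    def ingroup_codes(self) -> list[str]:
        return [c for c in self.codes if self.roles.get(c, "ingroup") == "ingroup"]

    @property
    def outgroup_codes(self) -> list[str]:
        return [c for c in self.codes if self.roles.get(c) == "outgroup"]

    def group_of(self, taxon: str) -> str:
        try:
            return self.taxon_to_group[taxon]
        except KeyError:
            raise UnknownTaxonError(taxon) from None

    def taxa_of(self, code: str) -> set[str]:
        return {t for t, g in self.taxon_to_group.items() if g == code}


#: Seven-group layout used throughout: five ingroup sections (A-E) of a
#: hybrid-origin subgenus and two outgroup subgenera (F, G).  Codes map
#: one-to-one onto taxa, which is the group-level case; species-level
#: maps are built with :func:`group_map_for_species`.
DEFAULT_GROUP_NAMES = {
    "A": "sect. Coryopedilum",
    "B": "sect. Pardalopetalum",
    "C": "sect. Cochlopetalum",
    "D": "sect. Barbata",
    "E": "sect. Paphiopedilum",
    "F": "subgen. Brachypetalum",
    "G": "subgen. Parvisepalum",
}
DEFAULT_GROUP_ROLES = {
    "A": "ingroup",
    "B": "ingroup",
    "C": "ingroup",
    "D": "ingroup",
    "E": "ingroup",
    "F": "outgroup",
    "G": "outgroup",
}


def default_group_map() -> GroupMap:
    """Group-level map where each code is its own single taxon."""
    return GroupMap(
        taxon_to_group={c: c for c in "ABCDEFG"},
        display_names=dict(DEFAULT_GROUP_NAMES),
        roles=dict(DEFAULT_GROUP_ROLES),
    )


def group_map_for_species(species_per_group: dict[str, list[str]]) -> GroupMap:
    """Build a species-level map from ``{code: [species, ...]}``."""
    t2g = {sp: code for code, sps in species_per_group.items() for sp in sps}
    return GroupMap(
        taxon_to_group=t2g,
        display_names=dict(DEFAULT_GROUP_NAMES),
        roles={c: DEFAULT_GROUP_ROLES.get(c, "ingroup") for c in species_per_group},
    )


# ---------------------------------------------------------------------------
# Newick I/O


def _interpret_support(label: str) -> float | None:
    try:
        val = float(label)
    except (TypeError, ValueError):
        return None
    if 0.0 <= val <= 1.0:
        return val
    if 1.0 < val <= 100.0:
        logger.warning("support %g looks like a percentage; dividing by 100", val)
        return val / 100.0
    return None


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree.

    Numeric internal-node labels are interpreted as node supports;
    values in (1, 100] are taken as percentages and rescaled to [0, 1].
    Raises :class:`NewickParseError` on malformed input or duplicate
    tip labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise NewickParseError(
            f"duplicate tip label(s): {sorted(dupes)} in {text.strip()[:80]!r}"
        )
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            nd.support = None
        else:
            nd.support = _interpret_support(nd.label)
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick, emitting supports as internal labels."""
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf():
            sup = getattr(nd, "support", None)
            nd.label = None if sup is None else format(sup, "g")
    has_lengths = any(
        nd.edge.length is not None
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None
    )
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_edge_lengths=not has_lengths,
    ).strip()


def clone_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Deep copy via Newick round-trip (preserves lengths and supports)."""
    return parse_newick(write_newick(tree))


def tip_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


# ---------------------------------------------------------------------------
# Support collapsing


def collapse_low_support(tree: dendropy.Tree, threshold: float) -> dendropy.Tree:
    """Collapse internal nodes whose support is strictly below ``threshold``.

    The root is never collapsed and nodes carrying no support value are
    kept.  Collapsed branch lengths are discarded: downstream use of
    collapsed trees is topology-only.  The input is not modified.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    out = clone_tree(tree)
    doomed = [
        nd
        for nd in out.preorder_internal_node_iter()
        if nd.parent_node is not None
        and getattr(nd, "support", None) is not None
        and nd.support < threshold
    ]
    for nd in doomed:
        nd.edge.collapse()
    for nd in out.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = None
    return out


# ---------------------------------------------------------------------------
# Splits


def _leafset(node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def clades(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf sets of all internal nodes (root included)."""
    return [_leafset(nd) for nd in tree.preorder_internal_node_iter()]


def canonical_split(side: frozenset[str], taxa: frozenset[str],
                    reference: str | None = None) -> frozenset[str]:
    """Canonical form of an unrooted split: the side without ``reference``."""
    ref = reference if reference is not None else min(taxa)
    return taxa - side if ref in side else side


def bipartitions(tree: dendropy.Tree, reference: str | None = None) -> frozenset[frozenset[str]]:
    """Non-trivial unrooted splits of the tree, canonicalized.

    One split per internal edge; single-tip sides are excluded; the two
    root-adjacent edges that induce the same split are counted once.
    Trees with fewer than 3 tips (or a star tree) yield the empty set.
    """
    taxa = tip_labels(tree)
    if len(taxa) < 3:
        return frozenset()
    out = set()
    for nd in tree.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        side = _leafset(nd)
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        out.add(canonical_split(side, taxa, reference))
    return frozenset(out)


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: |symmetric difference of split sets|."""
    x1, x2 = tip_labels(t1), tip_labels(t2)
    if x1 != x2:
        raise TipSetMismatchError(
            f"tip sets differ: only-in-first={sorted(x1 - x2)}, "
            f"only-in-second={sorted(x2 - x1)}"
        )
    ref = min(x1)
    return len(bipartitions(t1, ref) ^ bipartitions(t2, ref))


def splits_compatible(a: frozenset[str], b: frozenset[str], taxa: frozenset[str]) -> bool:
    """Two splits on the same taxon set are compatible iff one of the four
    intersections of their sides is empty."""
    ac, bc = taxa - a, taxa - b
    return not (a & b) or not (a & bc) or not (ac & b) or not (ac & bc)


def restrict_splits(splits, keep: frozenset[str], reference: str | None = None):
    """Restrict splits to a taxon subset, dropping the ones that become trivial."""
    out = set()
    for s in splits:
        r = s & keep
        if len(r) >= 2 and len(keep - r) >= 2:
            out.add(canonical_split(r, keep, reference))
    return frozenset(out)


# ---------------------------------------------------------------------------
# Monophyly / ages


def is_monophyletic(tree: dendropy.Tree, taxa) -> bool:
    """True iff some node's tip-descendant set equals ``taxa`` exactly."""
    taxa = frozenset(taxa)
    tips = tip_labels(tree)
    unknown = taxa - tips
    if unknown:
        raise UnknownTaxonError(sorted(unknown))
    if len(taxa) == 1:
        return True
    for nd in tree.preorder_internal_node_iter():
        if _leafset(nd) == taxa:
            return True
    return taxa == tips


def node_ages(tree: dendropy.Tree, rtol: float = 1e-9) -> dict:
    """Map node -> age for an ultrametric tree (tips at age 0).

    Raises :class:`NonUltrametricError` when root-to-tip path lengths
    disagree beyond ``rtol`` (relative to tree depth).
    """
    ages: dict = {}
    depth = 0.0
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            ages[nd] = 0.0
            continue
        cand = []
        for ch in nd.child_nodes():
            el = ch.edge.length if ch.edge.length is not None else 0.0
            cand.append(ages[ch] + el)
        lo, hi = min(cand), max(cand)
        depth = max(depth, hi)
        if hi - lo > rtol * max(hi, 1.0):
            raise NonUltrametricError(
                f"root-to-tip depths disagree below a node: {lo} vs {hi}"
            )
        ages[nd] = hi
    return ages


def tmrca(tree: dendropy.Tree, taxa, rtol: float = 1e-9) -> float:
    """Age of the most recent node ancestral to all named taxa."""
    taxa = frozenset(taxa)
    tips = tip_labels(tree)
    unknown = taxa - tips
    if unknown:
        raise UnknownTaxonError(sorted(unknown))
    ages = node_ages(tree, rtol=rtol)
    best = None
    for nd in tree.postorder_node_iter():
        if taxa <= _leafset(nd) if not nd.is_leaf() else taxa == {nd.taxon.label}:
            if best is None or ages[nd] < ages[best]:
                best = nd
    return ages[best]


# ---------------------------------------------------------------------------
# Group-level reduction


def to_group_tree(tree: dendropy.Tree, groups: GroupMap) -> dendropy.Tree:
    """Relabel tips to group codes, reducing each group's clade to one tip.

    Every group present in the tree must be monophyletic (or a single
    tip); otherwise :class:`NonMonophyleticGroupError` names the first
    offending group.  Branch lengths and supports are dropped — group
    trees are topological objects.
    """
    tips = tip_labels(tree)
    present = {}
    for t in tips:
        present.setdefault(groups.group_of(t), set()).add(t)
    for code in sorted(present):
        if len(present[code]) > 1 and not is_monophyletic(tree, present[code]):
            raise NonMonophyleticGroupError(code)

    def reduce(nd) -> str:
        ls = _leafset(nd) if not nd.is_leaf() else frozenset({nd.taxon.label})
        codes = {groups.group_of(t) for t in ls}
        if len(codes) == 1:
            return next(iter(codes))
        return "(" + ",".join(reduce(ch) for ch in nd.child_nodes()) + ")"

    return parse_newick(reduce(tree.seed_node) + ";")


# ---------------------------------------------------------------------------
# Random trees and topology enumeration (nested-tuple representation:
# a leaf is a label string, an internal node a tuple of children)


def random_binary_tree(labels, rng, ultrametric: bool = False,
                       depth: float = 1.0) -> dendropy.Tree:
    """Uniform-ish random rooted binary tree built by random joins.

    With ``ultrametric=True``, node ages are spread uniformly so that
    the root sits at ``depth`` and tips at 0.
    """
    items = [str(l) for l in labels]
    if len(items) < 2:
        raise ValueError("need at least two labels")
    rng.shuffle(items)
    while len(items) > 1:
        i, j = sorted(rng.sample(range(len(items)), 2), reverse=True)
        a, b = items.pop(i), items.pop(j)
        items.append(f"({a},{b})")
    tree = parse_newick(items[0] + ";")
    if ultrametric:
        ages = {}
        internals = [nd for nd in tree.postorder_internal_node_iter()]
        # root last in postorder; assign increasing ages along postorder
        for k, nd in enumerate(internals):
            ages[nd] = depth * (k + 1) / len(internals)
        ages[tree.seed_node] = depth
        # enforce child < parent by averaging upward where violated
        for nd in tree.postorder_internal_node_iter():
            for ch in nd.child_nodes():
                cage = 0.0 if ch.is_leaf() else ages[ch]
                if cage >= ages[nd]:
                    ages[nd] = cage + depth * 0.01
        for nd in tree.postorder_node_iter():
            if nd.parent_node is not None:
                cage = 0.0 if nd.is_leaf() else ages[nd]
                nd.edge.length = ages[nd.parent_node] - cage
    return tree


def enumerate_rooted_topologies(labels):
    """Yield every rooted binary topology on ``labels`` as nested tuples.

    There are (2n-3)!! of them; callers must keep n small (<= 8 or so).
    """
    labels = sorted(str(l) for l in labels)

    def insert_everywhere(top, leaf):
        # yield copies of `top` with `leaf` inserted on every edge,
        # including the edge above the root
        yield (top, leaf)
        if isinstance(top, tuple):
            a, b = top
            for sub in insert_everywhere(a, leaf):
                yield (sub, b)
            for sub in insert_everywhere(b, leaf):
                yield (a, sub)

    def build(tops, remaining):
        if not remaining:
            yield from tops
            return
        leaf, rest = remaining[0], remaining[1:]
        nxt = []
        for t in tops:
            nxt.extend(insert_everywhere(t, leaf))
        yield from build(nxt, rest)

    if len(labels) == 1:
        yield labels[0]
        return
    yield from build([(labels[0], labels[1])], labels[2:])


def nested_to_newick(top) -> str:
    def fmt(t):
        if isinstance(t, tuple):
            return "(" + ",".join(fmt(c) for c in t) + ")"
        return t
    return fmt(top) + ";"


def tree_from_nested(top) -> dendropy.Tree:
    return parse_newick(nested_to_newick(top))


def _node_resolutions(children):
    """All binary joins of an ordered list of child tokens, as nested tuples."""
    # Treat each child as a leaf token and enumerate rooted topologies
    # over the tokens; tokens are indices to keep them hashable/ordered.
    idx = list(range(len(children)))
    if len(idx) <= 2:
        yield tuple(children) if len(idx) == 2 else children[0]
        return

    def subst(t):
        if isinstance(t, tuple):
            return tuple(subst(c) for c in t)
        return children[int(t)]

    for top in enumerate_rooted_topologies([str(i) for i in idx]):
        yield subst(top)


def enumerate_resolutions(tree: dendropy.Tree, limit: int = 100_000):
    """Yield every binary resolution of a (possibly polytomous) rooted tree
    as nested tuples.  Raises ``ValueError`` past ``limit`` resolutions."""

    def expand(nd):
        if nd.is_leaf():
            yield nd.taxon.label
            return
        child_sets = [list(expand(ch)) for ch in nd.child_nodes()]
        for combo in itertools.product(*child_sets):
            yield from _node_resolutions(list(combo))

    count = 0
    for top in expand(tree.seed_node):
        count += 1
        if count > limit:
            raise ValueError(f"more than {limit} resolutions")
        yield top
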