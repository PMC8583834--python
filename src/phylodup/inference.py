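"""Desk-scale distance inference and strict-clock dating.

This is the deterministic stand-in for the Bayesian MCMC layer: JC69
distances, neighbor-joining (with optional bootstrap supports), a
strict-clock chronogram obtained by UPGMA-style averaging of root-to-tip
distances on the fixed rooted topology, and tMRCA-based classification
of markers into one-parent vs. two-parent inheritance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from . import treekit as tk

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "MarkerClassification",
    "jc_distance",
    "nj_tree",
    "nj_bootstrap",
    "strict_clock_chronogram",
    "classify_marker",
]

JC_CEILING = 5.0  # substitutions/site reported when p >= 3/4 (saturation)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(v, v.T, atol=1e-12) or np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if np.any(v < 0):
            raise ValueError("negative distances")
        self.values = v

    def to_phylip(self) -> str:
        lines = [f" {len(self.taxa)}"]
        for i, t in enumerate(self.taxa):
            lines.append(
                f"{t:<12}" + "  ".join(f"{x:.8f}" for x in self.values[i])
            )
        return "\n".join(lines) + "\n"


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def _encode_nuc(matrix) -> tuple[list[str], np.ndarray]:
    lut = np.full(256, 255, dtype=np.uint8)
    for ch, v in _CODE.items():
        lut[ord(ch)] = v
        lut[ord(ch.lower())] = v
    taxa = list(matrix.taxa)
    arr = np.empty((len(taxa), matrix.length), dtype=np.uint8)
    for i, t in enumerate(taxa):
        arr[i] = lut[np.frombuffer(matrix.rows[t].encode("ascii"), dtype=np.uint8)]
    return taxa, arr


def _pairwise_p(arr: np.ndarray) -> np.ndarray:
    n = arr.shape[0]
    p = np.zeros((n, n))
    valid = arr != 255
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                p[i, j] = p[j, i] = np.nan
                continue
            d = int((arr[i][both] != arr[j][both]).sum())
            p[i, j] = p[j, i] = d / m
    return p


def jc_distance(matrix, ceiling: float = JC_CEILING) -> DistanceMatrix:
    """Jukes-Cantor distances d = -(3/4) ln(1 - (4/3) p) over mutually
    non-missing sites; saturated pairs (p >= 3/4) get ``ceiling``."""
    taxa, arr = _encode_nuc(matrix)
    p = _pairwise_p(arr)
    with np.errstate(invalid="ignore"):
        d = -0.75 * np.log1p(-(4.0 / 3.0) * p)
    sat = ~np.isfinite(d) | (p >= 0.75)
    if sat.any():
        logger.warning(
            "%d saturated/undefined pairs set to ceiling %.3g",
            int(sat.sum()) // 2, ceiling,
        )
        d[sat] = ceiling
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(taxa=taxa, values=d)


def nj_tree(d: DistanceMatrix, outgroup: str | None = None) -> dendropy.Tree:
    """Neighbor-joining tree; negative branch lengths are clamped to 0.

    With ``outgroup`` given, the tree is rooted at the midpoint of the
    edge subtending that tip; otherwise the (arbitrary) skbio rooting
    is kept.
    """
    if len(d.taxa) < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    if not np.all(np.isfinite(d.values)):
        raise ValueError("non-finite distances")
    sk = _skbio_nj(_SkbioDM(d.values, ids=d.taxa), neg_as_zero=True)
    tree = tk.parse_newick(str(sk))
    if outgroup is not None:
        _root_at_tip(tree, outgroup)
    return tree


def _mean_tip_depth(node) -> float:
    depth, n = 0.0, 0
    stack = [(node, 0.0)]
    while stack:
        nd, acc = stack.pop()
        if nd.is_leaf():
            depth += acc
            n += 1
        for ch in nd.child_nodes():
            stack.append((ch, acc + (ch.edge.length or 0.0)))
    return depth / max(n, 1)


def _root_at_tip(tree: dendropy.Tree, outgroup: str) -> None:
    """Root on the outgroup tip's edge, placing the root so that the
    outgroup depth matches the mean tip depth of the other side (the
    clock-consistent position; a midpoint split would not be, since the
    outgroup branch spans the full root-to-tip depth)."""
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == outgroup:
            leaf = lf
            break
    if leaf is None:
        raise tk.UnknownTaxonError(outgroup)
    length = leaf.edge.length or 0.0
    tree.reroot_at_edge(leaf.edge, length1=length / 2.0, length2=length / 2.0)
    # rerooting can leave a unifurcation at the old root
    tree.suppress_unifurcations()
    root = tree.seed_node
    kids = root.child_nodes()
    new_leaf = next(k for k in kids if k.is_leaf() and k.taxon.label == outgroup)
    other = next(k for k in kids if k is not new_leaf)
    total = (new_leaf.edge.length or 0.0) + (other.edge.length or 0.0)
    m = _mean_tip_depth(other)
    x = min(max((total - m) / 2.0, 0.0), total)
    other.edge.length = x
    new_leaf.edge.length = total - x
    for nd in tree.preorder_node_iter():
        if not hasattr(nd, "support"):
            nd.support = None


def nj_bootstrap(
    matrix,
    outgroup: str | None = None,
    reps: int = 100,
    rng: np.random.Generator | None = None,
) -> dendropy.Tree:
    """NJ tree with bootstrap proportions (in [0, 1]) as node supports."""
    rng = rng if rng is not None else np.random.default_rng(0)
    taxa, arr = _encode_nuc(matrix)
    base = nj_tree(jc_distance(matrix), outgroup=outgroup)
    ref = min(taxa)
    counts: dict = {s: 0 for s in tk.bipartitions(base, ref)}
    L = arr.shape[1]
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        rep_arr = arr[:, cols]
        p = _pairwise_p(rep_arr)
        with np.errstate(invalid="ignore"):
            dv = -0.75 * np.log1p(-(4.0 / 3.0) * p)
        dv[~np.isfinite(dv) | (p >= 0.75)] = JC_CEILING
        np.fill_diagonal(dv, 0.0)
        rep_tree = nj_tree(DistanceMatrix(taxa=taxa, values=dv))
        for s in tk.bipartitions(rep_tree, ref):
            if s in counts:
                counts[s] += 1
    taxa_set = frozenset(taxa)
    for nd in base.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        if len(side) < 2 or len(taxa_set - side) < 2:
            continue
        nd.support = counts.get(tk.canonical_split(side, taxa_set, ref), 0) / reps
    return base


def strict_clock_chronogram(tree: dendropy.Tree, root_age: float) -> dendropy.Tree:
    """Clock-scale a rooted tree with substitution branch lengths.

    Each node's height is the mean root-to-tip substitution distance of
    the tips below it (averaging on the fixed topology); heights are
    rescaled so the root sits at ``root_age`` and monotonicity is
    enforced top-down.  The result is ultrametric with ages in the
    calibration's units.
    """
    out = tk.clone_tree(tree)
    mean_depth: dict = {}
    n_tips: dict = {}
    for nd in out.postorder_node_iter():
        if nd.is_leaf():
            mean_depth[nd], n_tips[nd] = 0.0, 1
            continue
        tot, n = 0.0, 0
        for ch in nd.child_nodes():
            el = ch.edge.length or 0.0
            tot += (mean_depth[ch] + el) * n_tips[ch]
            n += n_tips[ch]
        mean_depth[nd], n_tips[nd] = tot / n, n
    root_depth = mean_depth[out.seed_node]
    if root_depth <= 0:
        raise ValueError("zero total depth: cannot scale to a chronogram")
    ages = {
        nd: (0.0 if nd.is_leaf() else mean_depth[nd] * root_age / root_depth)
        for nd in out.postorder_node_iter()
    }
    for nd in out.preorder_node_iter():
        if nd.parent_node is not None:
            ages[nd] = min(ages[nd], ages[nd.parent_node])
            nd.edge.length = ages[nd.parent_node] - ages[nd]
    return out


@dataclass
class MarkerClassification:
    """Verdict on whether a marker's ingroup coalesces before or after
    the hybridization event."""

    marker: str
    ingroup_tmrca: float
    threshold_age: float
    inheritance: str  # "one_parent" | "two_parent"

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "ingroup_tmrca": self.ingroup_tmrca,
            "threshold_age": self.threshold_age,
            "inheritance": self.inheritance,
        }


def classify_marker(
    chronogram: dendropy.Tree,
    ingroup_taxa,
    threshold_age: float,
    marker: str = "marker",
) -> MarkerClassification:
    """Two-parent iff the ingroup tMRCA predates ``threshold_age``
    (typically midway between the hybridization and proto-split ages)."""
    ingroup_taxa = frozenset(ingroup_taxa)
    if not ingroup_taxa & tk.tip_labels(chronogram):
        raise tk.UnknownTaxonError("no ingroup taxa present in chronogram")
    t = tk.tmrca(chronogram, ingroup_taxa, rtol=1e-6)
    return MarkerClassification(
        marker=marker,
        ingroup_tmrca=float(t),
        threshold_age=float(threshold_age),
        inheritance="two_parent" if t > threshold_age else "one_parent",
    )
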