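"""Fitch parsimony, site classification, and homoplasy indices.

Characters are nucleotides; '?' and '-' are treated as fully ambiguous
(they can take any state at no cost), and site classification counts
only unambiguous A/C/G/T observations.  For a matrix with S observed
steps on a tree, per-site minima m_i = (observed states - 1) and maxima
g_i = (non-missing taxa) - (count of the most frequent state) give

    CI = sum(m_i) / S          (consistency index)
    RI = (sum(g_i) - S) / (sum(g_i) - sum(m_i))   (retention index)

with sites where g_i = m_i dropped from the RI sums.  An invariant
matrix has S = 0 and both indices are defined as 1.0.

The exact most-parsimonious-tree search enumerates all unrooted binary
topologies (via rooted topologies on n-1 taxa with the first taxon
re-attached at the root) and is capped at 9 taxa.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np

from . import treekit as tk

logger = logging.getLogger(__name__)

__all__ = [
    "ParsimonyStats",
    "classify_sites",
    "fitch_length",
    "ci_ri",
    "parsimony_stats",
    "MPResult",
    "brute_force_mp_tree",
]

_STATE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "U": 8}
# IUPAC ambiguity codes resolve to their state unions; everything else
# (including '?' and '-') is fully ambiguous.
_IUPAC = {
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15, "?": 15, "-": 15,
}
_FULL = 15


def _bit(ch: str) -> int:
    c = ch.upper()
    return _STATE_BITS.get(c) or _IUPAC.get(c, _FULL)


def encode(matrix, taxa_order=None) -> tuple[list[str], np.ndarray]:
    """Encode an AlignmentMatrix as (taxa, uint8 bitmask array taxa x sites)."""
    taxa = list(taxa_order) if taxa_order is not None else list(matrix.taxa)
    arr = np.empty((len(taxa), matrix.length), dtype=np.uint8)
    lut = np.full(256, _FULL, dtype=np.uint8)
    for ch, b in {**_STATE_BITS, **_IUPAC}.items():
        lut[ord(ch)] = b
        lut[ord(ch.lower())] = b
    for i, t in enumerate(taxa):
        arr[i] = lut[np.frombuffer(matrix.rows[t].encode("ascii"), dtype=np.uint8)]
    return taxa, arr


def classify_sites(matrix) -> list[str]:
    """Per-site labels: 'constant', 'variable-uninformative', 'informative'.

    A site is informative iff at least two states are each observed in
    at least two taxa; ambiguity codes and missing data are ignored.
    """
    out = []
    for j in range(matrix.length):
        counts = Counter(
            c for c in (matrix.rows[t][j].upper() for t in matrix.taxa)
            if c in "ACGT"
        )
        if len(counts) <= 1:
            out.append("constant")
        elif sum(1 for v in counts.values() if v >= 2) >= 2:
            out.append("informative")
        else:
            out.append("variable-uninformative")
    return out


def _fitch_steps(tree: dendropy.Tree, taxa: list[str], arr: np.ndarray) -> int:
    """Vectorized Fitch pass over all sites at once."""
    index = {t: i for i, t in enumerate(taxa)}
    steps = np.zeros(arr.shape[1], dtype=np.int64)
    state: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            state[nd] = arr[index[nd.taxon.label]]
            continue
        children = nd.child_nodes()
        cur = state[children[0]]
        for ch in children[1:]:
            inter = cur & state[ch]
            union = cur | state[ch]
            miss = inter == 0
            steps += miss
            cur = np.where(miss, union, inter)
        state[nd] = cur
    return int(steps.sum())


def fitch_length(tree: dendropy.Tree, matrix) -> int:
    """Total Fitch small-parsimony steps of ``matrix`` on ``tree``.

    Polytomies are allowed (the Fitch pass generalizes by folding
    children in sequence, which matches binary scoring on binary trees).
    """
    tips = tk.tip_labels(tree)
    if tips != frozenset(matrix.taxa):
        raise tk.TipSetMismatchError(
            f"tree/matrix taxa differ: {sorted(tips ^ frozenset(matrix.taxa))}"
        )
    taxa, arr = encode(matrix)
    return _fitch_steps(tree, taxa, arr)


def _site_min_max(matrix) -> tuple[np.ndarray, np.ndarray]:
    m = np.zeros(matrix.length, dtype=np.int64)
    g = np.zeros(matrix.length, dtype=np.int64)
    for j in range(matrix.length):
        counts = Counter(
            c for c in (matrix.rows[t][j].upper() for t in matrix.taxa)
            if c in "ACGT"
        )
        if counts:
            m[j] = len(counts) - 1
            g[j] = sum(counts.values()) - max(counts.values())
    return m, g


def ci_ri(matrix, tree: dendropy.Tree) -> tuple[float, float]:
    """Consistency and retention indices of ``matrix`` on ``tree``."""
    s = fitch_length(tree, matrix)
    m, g = _site_min_max(matrix)
    if s == 0:
        logger.info("invariant data on this tree: CI = RI = 1 by convention")
        return 1.0, 1.0
    ci = float(m.sum()) / s
    keep = g != m
    g_sum, m_sum = int(g[keep].sum()), int(m[keep].sum())
    # steps attributable to RI-eligible sites: subtract the fixed m of
    # the excluded (g==m) sites, on which any tree spends exactly m
    s_eligible = s - int(m[~keep].sum())
    if g_sum == m_sum:
        return ci, 1.0
    ri = (g_sum - s_eligible) / (g_sum - m_sum)
    return ci, float(ri)


@dataclass
class ParsimonyStats:
    """The classic character-matrix summary block."""

    n_taxa: int
    included_positions: int
    variable_sites: int
    parsimony_uninformative: int
    parsimony_informative: int
    tree_length: int
    min_length: int
    max_length: int
    ci: float
    ri: float

    def to_tsv(self) -> str:
        rows = [
            ("No. of taxa", self.n_taxa),
            ("Included positions in matrix", self.included_positions),
            ("Variable site", self.variable_sites),
            ("Parsimony-uninformative sites", self.parsimony_uninformative),
            ("Parsimony-informative sites", self.parsimony_informative),
            ("Tree length", self.tree_length),
            ("Consistency index (CI)", round(self.ci, 2)),
            ("Retention index (RI)", round(self.ri, 2)),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows)


def parsimony_stats(matrix, tree: dendropy.Tree) -> ParsimonyStats:
    labels = classify_sites(matrix)
    m, g = _site_min_max(matrix)
    s = fitch_length(tree, matrix)
    ci, ri = ci_ri(matrix, tree)
    n_var = sum(1 for l in labels if l != "constant")
    n_inf = labels.count("informative")
    return ParsimonyStats(
        n_taxa=len(matrix.taxa),
        included_positions=matrix.length,
        variable_sites=n_var,
        parsimony_uninformative=n_var - n_inf,
        parsimony_informative=n_inf,
        tree_length=s,
        min_length=int(m.sum()),
        max_length=int(g.sum()),
        ci=ci,
        ri=ri,
    )


@dataclass
class MPResult:
    tree: dendropy.Tree
    length: int
    co_optimal: list[str]  # newicks of all equally short topologies


def brute_force_mp_tree(matrix, taxa: list[str] | None = None) -> MPResult:
    """Exact maximum-parsimony search over all unrooted binary topologies.

    Capped at 9 taxa ((2n-5)!! topologies).  The returned tree is the
    canonically first winner (rooted representation with the first
    taxon attached at the root); all co-optimal topologies are listed.
    """
    taxa = sorted(taxa if taxa is not None else matrix.taxa)
    if len(taxa) > 9:
        raise ValueError(
            f"{len(taxa)} taxa: exact search capped at 9 "
            "(heuristic search is out of scope)"
        )
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    order, arr = encode(matrix, taxa_order=taxa)
    index = {t: i for i, t in enumerate(order)}

    first, rest = taxa[0], taxa[1:]
    best_len = None
    best: list[str] = []
    for top in tk.enumerate_rooted_topologies(rest):
        newick = f"({first},{tk.nested_to_newick(top)[:-1]});"
        tree = tk.parse_newick(newick)
        s = _fitch_steps(tree, order, arr[[index[t] for t in order]])
        if best_len is None or s < best_len:
            best_len, best = s, [newick]
        elif s == best_len:
            best.append(newick)
    best.sort()
    return MPResult(tree=tk.parse_newick(best[0]), length=int(best_len),
                    co_optimal=best)
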