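"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles, without
touching the package's tree machinery: a minimal Newick reader into
nested tuples, split enumeration by recursion, exhaustive small
parsimony over all internal state assignments, and deep-coalescence
counting by enumerating every valid embedding of a gene tree into a
species tree.
"""

from __future__ import annotations

import itertools


# ---------------------------------------------------------------------------
# Tiny independent Newick reader -> nested tuples (leaves are strings)


def parse(newick: str):
    s = newick.strip().rstrip(";")

    def read(i):
        if s[i] == "(":
            children = []
            i += 1
            while True:
                child, i = read(i)
                children.append(child)
                if s[i] == ",":
                    i += 1
                    continue
                if s[i] == ")":
                    i += 1
                    break
            # skip label/length after ')'
            j = i
            while j < len(s) and s[j] not in ",()":
                j += 1
            return tuple(children), j
        j = i
        while j < len(s) and s[j] not in ",()":
            j += 1
        name = s[i:j].split(":")[0]
        return name, j

    top, _ = read(0)
    return top


def leaves(t) -> frozenset:
    if isinstance(t, tuple):
        return frozenset().union(*(leaves(c) for c in t))
    return frozenset({t})


def clades(t) -> list:
    """Leaf sets of all internal nodes (root included)."""
    out = []
    if isinstance(t, tuple):
        out.append(leaves(t))
        for c in t:
            out.extend(clades(c))
    return out


def splits(t) -> frozenset:
    """Non-trivial unrooted splits: canonical side excludes min taxon."""
    taxa = leaves(t)
    ref = min(taxa)
    out = set()
    for cl in clades(t):
        if cl == taxa:
            continue
        side = taxa - cl if ref in cl else cl
        if 2 <= len(side) <= len(taxa) - 2:
            out.add(side)
    return frozenset(out)


def rf(t1, t2) -> int:
    return len(splits(t1) ^ splits(t2))


# ---------------------------------------------------------------------------
# Exhaustive small parsimony (min over all internal state assignments)

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "?": 15, "-": 15}


def _edges(t, nodes=None, parent=None):
    """Postorder internal node list + edge list (parent_idx or None root)."""
    internal = []
    edge_list = []  # (child, parent_internal_index) where child is
    # either ('tip', name) or ('int', index)

    def walk(node):
        if not isinstance(node, tuple):
            return ("tip", node)
        kids = [walk(c) for c in node]
        idx = len(internal)
        internal.append(node)
        for k in kids:
            edge_list.append((k, idx))
        return ("int", idx)

    root = walk(t)
    return internal, edge_list, root


def exhaustive_parsimony_site(tree, column: dict[str, str]) -> int:
    """Minimum changes for one site over every assignment of A/C/G/T to
    the internal nodes; missing/ambiguous tips cost 0 when the adjacent
    internal state is allowed by their bitmask."""
    internal, edge_list, _root = _edges(tree)
    k = len(internal)
    best = None
    for assign in itertools.product(range(4), repeat=k):
        cost = 0
        for (kind, ref), pidx in edge_list:
            pstate = assign[pidx]
            if kind == "int":
                cost += assign[ref] != pstate
            else:
                allowed = _BITS.get(column[ref].upper(), 15)
                cost += not (allowed >> pstate) & 1
        if best is None or cost < best:
            best = cost
            if best == 0:
                break
    return best


def exhaustive_parsimony(tree, rows: dict[str, str]) -> int:
    length = len(next(iter(rows.values())))
    return sum(
        exhaustive_parsimony_site(tree, {t: r[j] for t, r in rows.items()})
        for j in range(length)
    )


def site_min_max(column: dict[str, str]) -> tuple[int, int]:
    from collections import Counter

    counts = Counter(c.upper() for c in column.values() if c.upper() in "ACGT")
    if not counts:
        return 0, 0
    return len(counts) - 1, sum(counts.values()) - max(counts.values())


def exhaustive_ci_ri(tree, rows: dict[str, str]):
    """CI/RI from exhaustive per-site steps (independent arithmetic)."""
    length = len(next(iter(rows.values())))
    s_tot = m_tot = 0
    g_el = m_el = s_el = 0
    for j in range(length):
        col = {t: r[j] for t, r in rows.items()}
        s = exhaustive_parsimony_site(tree, col)
        m, g = site_min_max(col)
        s_tot += s
        m_tot += m
        if g != m:
            g_el += g
            m_el += m
            s_el += s
    if s_tot == 0:
        return 1.0, 1.0
    ci = m_tot / s_tot
    ri = 1.0 if g_el == m_el else (g_el - s_el) / (g_el - m_el)
    return ci, ri


# ---------------------------------------------------------------------------
# Exhaustive deep-coalescence (MDC) oracle


def _species_index(sp):
    """Species nodes as leaf-set frozensets with parent links."""
    nodes = []  # (cluster, parent_index or None)

    def walk(node, parent_idx):
        cluster = leaves(node)
        idx = len(nodes)
        nodes.append([cluster, parent_idx])
        if isinstance(node, tuple):
            for c in node:
                walk(c, idx)
        return idx

    walk(sp, None)
    return nodes


def exhaustive_mdc(gene, sp) -> int:
    """Minimum extra lineages over every valid embedding of the gene
    tree's coalescences onto species-tree branches."""
    s_nodes = _species_index(sp)

    def ancestors_or_self(idx):
        out = []
        while idx is not None:
            out.append(idx)
            idx = s_nodes[idx][1]
        return out

    def is_anc_or_self(a, b):  # a ancestor-or-equal of b
        return a in ancestors_or_self(b)

    def mrca_of(tips):
        for idx, (cluster, _p) in sorted(
            enumerate(s_nodes), key=lambda kv: len(kv[1][0])
        ):
            if tips <= cluster:
                return idx
        raise AssertionError

    # gene internal nodes (preorder) with parent links; leaves are
    # pinned to their species tips and handled separately
    g_nodes = []

    def gwalk2(node, parent_idx):
        idx = len(g_nodes)
        g_nodes.append([parent_idx, leaves(node), node])
        for c in node:
            if isinstance(c, tuple):
                gwalk2(c, idx)

    gwalk2(gene, None)

    choices = [
        [i for i in range(len(s_nodes)) if is_anc_or_self(i, mrca_of(tips))]
        for _p, tips, _n in g_nodes
    ]
    # leaf positions: tip name -> species leaf node index
    leaf_pos = {}
    for idx, (cluster, _p) in enumerate(s_nodes):
        if len(cluster) == 1:
            leaf_pos[next(iter(cluster))] = idx

    # gene edges: (child_position_resolver, parent_gene_index)
    gene_edges = []  # (child_is_leaf, child_key, gene_parent_idx)
    for gi, (_p, _tips, node) in enumerate(g_nodes):
        for c in node:
            if isinstance(c, tuple):
                continue
            gene_edges.append((True, c, gi))
    for gi, (gp, _tips, _node) in enumerate(g_nodes):
        if gp is not None:
            gene_edges.append((False, gi, gp))

    best = None
    for assign in itertools.product(*choices):
        # embedding must respect gene-tree ancestry
        ok = all(
            gp is None or is_anc_or_self(assign[gp], assign[gi])
            for gi, (gp, _t, _n) in enumerate(g_nodes)
        )
        if not ok:
            continue
        total = 0
        for e_idx, (cluster, parent) in enumerate(s_nodes):
            if parent is None:
                continue  # root has no subtending edge
            # lineages crossing the top of this edge
            k = 0
            for is_leaf, key, gp in gene_edges:
                pos = leaf_pos[key] if is_leaf else assign[key]
                ppos = assign[gp]
                if is_anc_or_self(e_idx, pos) and not is_anc_or_self(e_idx, ppos):
                    k += 1
            if k:
                total += k - 1
        if best is None or total < best:
            best = total
    return best
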