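"""Network-coalescent simulator with one ancestral homoploid hybridization.

The species history is a dated tree over seven groups — five ingroup
sections A-E descending from a single hybrid lineage, plus two outgroup
subgenera F and G — with one reticulation.  The ancestor of A-E formed
at the *hybridization age* from two parental "proto" populations P1 and
P2 that diverged from each other (and from the F lineage) at the
*proto-split age*.  Default ages (Ma): root (G split) 24, proto split
16.5, hybridization 12, and the ingroup radiation at 11 (A-E crown),
9 (A,B,C crown), 8.5 (D,E crown), 8 (A,B crown).

A locus evolves under the multispecies coalescent on this structure,
with one twist that encodes the post-hybridization allele sorting: each
ingroup section fixes one parental copy of the locus, and below the
hybridization age lineages carrying *different* parental copies cannot
coalesce (they are divergent haplotype classes held in the mosaic
hybrid genome).  At the hybridization age each lineage is routed into
its parental population.  Three sorting modes are distinguished:

- ``single_parent``: the whole locus comes from one parent (drawn with
  probability gamma per locus) — plastid-like behavior; ingroup tMRCA
  is the radiation age.
- ``random_sorting``: each section independently fixes parent 1's copy
  with probability gamma; loci whose sections span both parents have
  ingroup tMRCA at the proto split.
- ``congruent_sorting``: the multi-flowered ({A,B,C}) and the
  single-flowered ({D,E}) daughter lineages fix opposite parental
  copies — the gene tree mirrors the species tree but its ingroup root
  is the (older) proto split.

Times are Ma; coalescence within a population is Kingman with haploid
size N_e and a generation time converting Ma to generations.  N_e = 0
is the zero-ILS limit: deterministic, instantaneous coalescence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import treekit as tk
from .supermatrix import AlignmentMatrix

__all__ = [
    "SpeciesNetwork",
    "SimulationParams",
    "SORTING_MODES",
    "MARKER_PANEL",
    "assign_parental_origin",
    "simulate_gene_tree",
    "simulate_sequences",
    "simulate_marker",
    "StudyBundle",
    "make_study_bundle",
    "bundle_from_manifest",
    "write_bundle",
]

SORTING_MODES = ("single_parent", "random_sorting", "congruent_sorting")

#: Default marker panel emulating a six-nuclear-genes-plus-plastid study:
#: three one-parent markers, three randomly sorted ones, one congruently
#: sorted one.
MARKER_PANEL = (
    ("plastid_like", "single_parent"),
    ("ACO_like", "single_parent"),
    ("DEF4_like", "single_parent"),
    ("XDH_like", "random_sorting"),
    ("LFY_like", "random_sorting"),
    ("RAD51_like", "random_sorting"),
    ("PHYC_like", "congruent_sorting"),
)

INGROUP = ("A", "B", "C", "D", "E")
MULTIFLOWERED = ("A", "B", "C")
SINGLEFLOWERED = ("D", "E")


@dataclass(frozen=True)
class SpeciesNetwork:
    """Dated 7-group species network with one reticulation."""

    root_age: float = 24.0
    proto_split_age: float = 16.5
    hybridization_age: float = 12.0
    radiation_ages: dict = field(
        default_factory=lambda: {"ABCDE": 11.0, "ABC": 9.0, "AB": 8.0, "DE": 8.5}
    )
    gamma: float = 0.5

    def __post_init__(self):
        r = self.radiation_ages
        ok = (
            0.0 <= self.gamma <= 1.0
            and r["AB"] < r["ABC"] < r["ABCDE"]
            and r["DE"] < r["ABCDE"]
            and r["ABCDE"] < self.hybridization_age
            < self.proto_split_age
            < self.root_age
        )
        if not ok:
            raise ValueError(f"inconsistent network ages/gamma: {self}")

    @property
    def proto_gap(self) -> float:
        """Age offset separating two-parent from one-parent ingroup tMRCAs."""
        return self.proto_split_age - self.radiation_ages["ABCDE"]

    def species_tree(self) -> "tk.dendropy.Tree":
        """The dated species tree (reticulation collapsed onto its
        hybrid-lineage path): (((((A,B),C),(D,E)),F),G)."""
        r = self.radiation_ages
        ab = r["AB"]
        abc = r["ABC"]
        de = r["DE"]
        abcde = r["ABCDE"]
        ps = self.proto_split_age
        rt = self.root_age
        nwk = (
            f"(((((A:{ab},B:{ab}):{abc - ab},C:{abc}):{abcde - abc},"
            f"(D:{de},E:{de}):{abcde - de}):{ps - abcde},F:{ps}):{rt - ps},G:{rt});"
        )
        return tk.parse_newick(nwk)

    def to_dict(self) -> dict:
        return {
            "root_age": self.root_age,
            "proto_split_age": self.proto_split_age,
            "hybridization_age": self.hybridization_age,
            "radiation_ages": dict(self.radiation_ages),
            "gamma": self.gamma,
        }


@dataclass(frozen=True)
class SimulationParams:
    """Free parameters of the simulator (the real values are unknown for
    the study system; these defaults are plausible for long-lived
    perennials)."""

    n_loci: int = 1
    sorting_mode: str = "random_sorting"
    N_e: float = 1e5  # haploid lineages
    generation_time: float = 10.0  # years
    seq_length: int = 1000
    subst_model: str = "JC69"  # or "HKY85"
    kappa: float = 2.0
    clock_rate: float = 1.5e-3  # substitutions / site / Myr
    alleles_per_species: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.sorting_mode not in SORTING_MODES:
            raise ValueError(f"unknown sorting mode {self.sorting_mode!r}")
        for name in ("n_loci", "generation_time", "seq_length", "clock_rate",
                     "alleles_per_species"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.N_e < 0:
            raise ValueError("N_e must be >= 0 (0 = zero-ILS limit)")

    @property
    def coal_unit_myr(self) -> float:
        """Myr per N_e generations (the coalescent time unit)."""
        return self.N_e * self.generation_time / 1e6


def assign_parental_origin(network: SpeciesNetwork, mode: str,
                           rng: np.random.Generator) -> dict[str, int]:
    """Draw per-section parental labels (1 or 2) for one locus."""
    g = network.gamma
    if mode == "single_parent":
        p = 1 if rng.random() < g else 2
        return {s: p for s in INGROUP}
    if mode == "random_sorting":
        return {s: (1 if rng.random() < g else 2) for s in INGROUP}
    if mode == "congruent_sorting":
        p_multi = 1 if rng.random() < g else 2
        out = {s: p_multi for s in MULTIFLOWERED}
        out.update({s: 3 - p_multi for s in SINGLEFLOWERED})
        return out
    raise ValueError(f"unknown sorting mode {mode!r}")


# ---------------------------------------------------------------------------
# Coalescent machinery


class _Lineage:
    __slots__ = ("node", "age", "label", "key", "src")

    def __init__(self, node, age, label, key, src=0):
        self.node = node  # tip name or (left_node, right_node, age)
        self.age = age
        self.label = label  # parental label below the hybridization age
        self.key = key  # deterministic ordering
        self.src = src  # source-population priority (zero-ILS fold order)


def _merge(a: _Lineage, b: _Lineage, age: float) -> _Lineage:
    first, second = sorted((a, b), key=lambda l: l.key)
    return _Lineage((first.node, second.node, age), age, first.label,
                    min(a.key, b.key))


def _coalesce_in_pop(lineages, t0, t1, coal_unit, restricted, rng):
    """Kingman coalescence among ``lineages`` between ages t0 and t1
    (t1 may be inf).  In a restricted population only lineages with the
    same parental label may coalesce.  coal_unit == 0 is the
    deterministic zero-ILS limit: allowed groups merge instantly at t0
    in arrival order."""
    lineages = sorted(lineages, key=lambda l: (l.src, l.key))
    if coal_unit == 0.0:
        groups: dict = {}
        for lin in lineages:
            groups.setdefault(lin.label if restricted else None, []).append(lin)
        out = []
        for _, grp in sorted(groups.items(), key=lambda kv: str(kv[0])):
            acc = grp[0]
            for nxt in grp[1:]:
                acc = _merge(acc, nxt, t0)
            out.append(acc)
        return out

    t = t0
    while True:
        pairs = [
            (i, j)
            for i in range(len(lineages))
            for j in range(i + 1, len(lineages))
            if not restricted or lineages[i].label == lineages[j].label
        ]
        if not pairs:
            return lineages
        rate = len(pairs) / coal_unit
        t = t + rng.exponential(1.0 / rate)
        if t >= t1:
            return lineages
        i, j = pairs[rng.integers(len(pairs))]
        merged = _merge(lineages[i], lineages[j], t)
        lineages = [l for k, l in enumerate(lineages) if k not in (i, j)] + [merged]


def _populations(network: SpeciesNetwork):
    """Ordered population table: (name, bottom, top, restricted, members).

    ``members`` lists the leaf groups (for tip placement); internal
    populations receive the outputs of their child populations.  The
    processing order below is a valid topological order of the
    population DAG.
    """
    r = network.radiation_ages
    h = network.hybridization_age
    ps = network.proto_split_age
    rt = network.root_age
    return [
        # leaf populations (bottom age 0)
        ("A", 0.0, r["AB"], True, ("A",)),
        ("B", 0.0, r["AB"], True, ("B",)),
        ("C", 0.0, r["ABC"], True, ("C",)),
        ("D", 0.0, r["DE"], True, ("D",)),
        ("E", 0.0, r["DE"], True, ("E",)),
        ("F", 0.0, ps, False, ("F",)),
        ("G", 0.0, rt, False, ("G",)),
        # ancestral populations of the hybrid lineage (label-restricted)
        ("AB", r["AB"], r["ABC"], True, ()),
        ("DE", r["DE"], r["ABCDE"], True, ()),
        ("ABC", r["ABC"], r["ABCDE"], True, ()),
        ("HYB", r["ABCDE"], h, True, ()),
        # the two parental proto populations
        ("P1", h, ps, False, ()),
        ("P2", h, ps, False, ()),
        # post-proto-split ancestor (P1 + P2 + F) and the root
        ("ANC", ps, rt, False, ()),
        ("ROOT", rt, math.inf, False, ()),
    ]


#: Fold order for deterministic (zero-ILS) merging in the receiving
#: population: outgroup lineages attach after the lineages of the
#: population's "own" descent path (F after the two parental proto
#: lineages at the proto split, G last at the root).
_SRC_PRIORITY = {
    "A": 0, "B": 1, "C": 2, "D": 3, "E": 4, "AB": 5, "DE": 6, "ABC": 7,
    "HYB": 8, "P1": 9, "P2": 10, "F": 11, "ANC": 12, "G": 13,
}

#: Where each population's surviving lineages go next.  The hybrid
#: population routes by parental label.
_DEST = {
    "A": "AB", "B": "AB", "AB": "ABC", "C": "ABC", "ABC": "HYB",
    "D": "DE", "E": "DE", "DE": "HYB",
    "HYB": {1: "P1", 2: "P2"},
    "P1": "ANC", "P2": "ANC", "F": "ANC",
    "ANC": "ROOT", "G": "ROOT",
}


def _lineage_to_tree(lin: _Lineage) -> "tk.dendropy.Tree":
    def fmt(node, parent_age):
        if isinstance(node, tuple):
            left, right, age = node
            return f"({fmt(left, age)},{fmt(right, age)}):{parent_age - age:.10g}"
        return f"{node}:{parent_age:.10g}"

    left, right, age = lin.node
    return tk.parse_newick(f"({fmt(left, age)},{fmt(right, age)});")


def simulate_gene_tree(
    network: SpeciesNetwork,
    origins: dict[str, int],
    params: SimulationParams,
    rng: np.random.Generator,
) -> "tk.dendropy.Tree":
    """One coalescent gene tree (ultrametric, ages in Ma) for a locus
    whose sections carry the parental labels in ``origins``."""
    missing = set(INGROUP) - set(origins)
    if missing:
        raise ValueError(f"no parental label for sections {sorted(missing)}")
    cu = params.coal_unit_myr
    k = params.alleles_per_species

    incoming: dict[str, list[_Lineage]] = {}
    key = 0
    for name, bottom, top, restricted, members in _populations(network):
        for grp in members:
            label = origins.get(grp)
            for i in range(k):
                tip = grp if k == 1 else f"{grp}_{i + 1}"
                incoming.setdefault(name, []).append(
                    _Lineage(tip, 0.0, label, key)
                )
                key += 1

    for name, bottom, top, restricted, _members in _populations(network):
        lineages = incoming.get(name, [])
        if not lineages:
            continue
        survivors = _coalesce_in_pop(lineages, bottom, top, cu, restricted, rng)
        dest = _DEST.get(name)
        if dest is None:  # ROOT: everything must have coalesced (top = inf)
            assert len(survivors) == 1
            return _lineage_to_tree(survivors[0])
        for lin in survivors:
            if isinstance(dest, dict):
                lin_dest = dest[lin.label]
                lin.label = None  # labels are dropped at the routing point
            else:
                lin_dest = dest
            lin.src = _SRC_PRIORITY[name]
            incoming.setdefault(lin_dest, []).append(lin)
    raise AssertionError("unreachable: root population did not close")


# ---------------------------------------------------------------------------
# Sequence evolution


_BASES = np.array(list("ACGT"))


def _rate_matrix(model: str, kappa: float) -> np.ndarray:
    """Normalized (1 expected substitution per unit time) rate matrix with
    uniform base frequencies."""
    if model == "JC69":
        q = np.full((4, 4), 1.0 / 3.0)
    elif model == "HKY85":
        # order A C G T; transitions A<->G, C<->T
        q = np.ones((4, 4))
        q[0, 2] = q[2, 0] = q[1, 3] = q[3, 1] = kappa
    else:
        raise ValueError(f"unknown substitution model {model!r}")
    np.fill_diagonal(q, 0.0)
    q = q / 4.0  # uniform equilibrium frequencies
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.sum(np.diag(q)) / 4.0
    return q / scale


def _transition_matrix(q: np.ndarray, branch_subs: float) -> np.ndarray:
    from scipy.linalg import expm

    return expm(q * branch_subs)


def simulate_sequences(
    gene_tree, params: SimulationParams, rng: np.random.Generator
) -> AlignmentMatrix:
    """Evolve sequences along an ultrametric gene tree under a strict
    clock: expected substitutions on a branch = length (Ma) x clock rate."""
    L = params.seq_length
    q = _rate_matrix(params.subst_model, params.kappa)
    states: dict = {}
    root = gene_tree.seed_node
    states[root] = rng.integers(0, 4, size=L)
    rows = {}
    for nd in gene_tree.preorder_node_iter():
        if nd.parent_node is not None:
            bl = (nd.edge.length or 0.0) * params.clock_rate
            if bl == 0.0:
                child = states[nd.parent_node].copy()
            else:
                p = _transition_matrix(q, bl)
                cum = np.cumsum(p, axis=1)
                u = rng.random(L)
                child = (u[:, None] > cum[states[nd.parent_node]]).sum(axis=1)
            states[nd] = child
        if nd.is_leaf():
            rows[nd.taxon.label] = "".join(_BASES[states[nd]])
    taxa = sorted(rows)
    return AlignmentMatrix(taxa=taxa, rows=rows)


# ---------------------------------------------------------------------------
# Study bundle


@dataclass
class MarkerRealization:
    name: str
    mode: str
    origins: dict[str, int]
    gene_tree: "tk.dendropy.Tree"
    alignment: AlignmentMatrix


@dataclass
class StudyBundle:
    network: SpeciesNetwork
    params: SimulationParams
    markers: dict[str, MarkerRealization]

    def manifest(self) -> dict:
        return {
            "seed": self.params.seed,
            "network": self.network.to_dict(),
            "params": asdict(self.params),
            "markers": {
                m.name: {
                    "mode": m.mode,
                    "origins": dict(m.origins),
                    "gene_tree": tk.write_newick(m.gene_tree),
                }
                for m in self.markers.values()
            },
        }


def _marker_rng(seed: int, marker_index: int, locus: int = 0) -> np.random.Generator:
    """Deterministic per-marker/locus stream derived from the root seed."""
    ss = np.random.SeedSequence(entropy=seed,
                                spawn_key=(marker_index, locus))
    return np.random.default_rng(ss)


def simulate_marker(
    network: SpeciesNetwork,
    params: SimulationParams,
    name: str,
    mode: str,
    marker_index: int,
) -> MarkerRealization:
    rng = _marker_rng(params.seed, marker_index)
    origins = assign_parental_origin(network, mode, rng)
    tree = simulate_gene_tree(network, origins, params, rng)
    aln = simulate_sequences(tree, params, rng)
    return MarkerRealization(name, mode, origins, tree, aln)


def make_study_bundle(
    network: SpeciesNetwork | None = None,
    params: SimulationParams | None = None,
    panel=MARKER_PANEL,
) -> StudyBundle:
    """Simulate the full marker panel; bit-reproducible from the seed."""
    network = network or SpeciesNetwork()
    params = params or SimulationParams()
    markers = {}
    for idx, (name, mode) in enumerate(panel):
        markers[name] = simulate_marker(network, params, name, mode, idx)
    return StudyBundle(network=network, params=params, markers=markers)


def bundle_from_manifest(manifest: dict) -> StudyBundle:
    """Replay a simulation from its manifest (seed + parameters only)."""
    network = SpeciesNetwork(
        root_age=manifest["network"]["root_age"],
        proto_split_age=manifest["network"]["proto_split_age"],
        hybridization_age=manifest["network"]["hybridization_age"],
        radiation_ages=dict(manifest["network"]["radiation_ages"]),
        gamma=manifest["network"]["gamma"],
    )
    params = SimulationParams(**manifest["params"])
    panel = tuple((m, spec["mode"]) for m, spec in manifest["markers"].items())
    return make_study_bundle(network, params, panel)


def write_bundle(bundle: StudyBundle, outdir) -> None:
    """FASTA per marker, Newick gene trees, origin TSV, YAML manifest."""
    from pathlib import Path
    from .supermatrix import write_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for m in bundle.markers.values():
        write_matrix(m.alignment, outdir / f"{m.name}.fasta", "fasta")
        (outdir / f"{m.name}.nwk").write_text(tk.write_newick(m.gene_tree) + "\n")
    with open(outdir / "origins.tsv", "w") as fh:
        fh.write("marker\t" + "\t".join(INGROUP) + "\n")
        for m in bundle.markers.values():
            fh.write(m.name + "\t" + "\t".join(str(m.origins[s]) for s in INGROUP) + "\n")
    (outdir / "manifest.yaml").write_text(
        yaml.safe_dump(bundle.manifest(), sort_keys=True)
    )
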