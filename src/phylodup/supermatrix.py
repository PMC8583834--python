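"""Duplicated-supermatrix construction and alignment I/O.

The concatenation scheme here resolves gene-tree conflict at the matrix
level: a marker whose topology conflicts with the reference for entire
groups is *duplicated* into two partitions.  One copy keeps only the
conflicted groups (plus the always-present outgroups), the other keeps
the remaining ingroup sections (plus outgroups), with excluded taxa
coded as missing ('?').  Every observed character therefore enters the
combined analysis exactly once per copy and no taxon ever carries two
mutually conflicting placements inside a single partition.

Matrices are taxa x sites character matrices over {A,C,G,T,-,?} with
named, 0-based half-open column partitions that tile the row length.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import yaml
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .treekit import GroupMap

logger = logging.getLogger(__name__)

MISSING = "?"
GAP = "-"

__all__ = [
    "Partition",
    "AlignmentMatrix",
    "DuplicationScheme",
    "scheme_from_conflicts",
    "build_duplicated_matrix",
    "write_matrix",
    "read_matrix",
]


@dataclass(frozen=True)
class Partition:
    name: str
    start: int  # 0-based inclusive
    end: int  # exclusive


@dataclass
class AlignmentMatrix:
    """Ordered taxa, equal-length character rows, tiling partitions."""

    taxa: list[str]
    rows: dict[str, str]
    partitions: list[Partition] = field(default_factory=list)

    def __post_init__(self):
        if set(self.taxa) != set(self.rows):
            raise ValueError("taxa list and row keys disagree")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"rows of unequal length: {sorted(lengths)}")
        if not self.partitions and self.rows:
            self.partitions = [Partition("all", 0, self.length)]
        self._check_tiling()

    def _check_tiling(self):
        pos = 0
        for p in self.partitions:
            if p.start != pos or p.end <= p.start:
                raise ValueError(f"partitions do not tile columns at {p}")
            pos = p.end
        if self.rows and pos != self.length:
            raise ValueError("partitions do not cover the full row length")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def column(self, j: int) -> list[str]:
        return [self.rows[t][j] for t in self.taxa]

    def slice(self, start: int, end: int, name: str = "all") -> "AlignmentMatrix":
        return AlignmentMatrix(
            taxa=list(self.taxa),
            rows={t: self.rows[t][start:end] for t in self.taxa},
            partitions=[Partition(name, 0, end - start)],
        )

    def partition_matrix(self, name: str) -> "AlignmentMatrix":
        for p in self.partitions:
            if p.name == name:
                return self.slice(p.start, p.end, name)
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Duplication scheme


@dataclass
class DuplicationScheme:
    """Per-marker assignment of groups to submatrix copies.

    ``modes[m]`` is "single" or "duplicated"; duplicated markers list
    the group codes excluded from each copy.  Groups in
    ``always_present`` (the outgroup subgenera by default) are excluded
    from neither copy.
    """

    modes: dict[str, str]
    copy1_excluded: dict[str, frozenset[str]] = field(default_factory=dict)
    copy2_excluded: dict[str, frozenset[str]] = field(default_factory=dict)
    always_present: frozenset[str] = frozenset({"F", "G"})

    def validate(self):
        for m, mode in self.modes.items():
            if mode == "single":
                continue
            c1 = self.copy1_excluded.get(m, frozenset())
            c2 = self.copy2_excluded.get(m, frozenset())
            if c1 & c2:
                raise ValueError(f"{m}: groups excluded from both copies: {c1 & c2}")
            if (c1 | c2) & self.always_present:
                raise ValueError(f"{m}: always-present group excluded")
            if not c1 or not c2:
                raise ValueError(f"{m}: a duplicated marker needs two proper copies")

    def to_dict(self) -> dict:
        return {
            m: (
                {"mode": "single"}
                if mode == "single"
                else {
                    "mode": "duplicated",
                    "copy1_excluded": sorted(self.copy1_excluded[m]),
                    "copy2_excluded": sorted(self.copy2_excluded[m]),
                }
            )
            for m, mode in self.modes.items()
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict, always_present=frozenset({"F", "G"})):
        modes, c1, c2 = {}, {}, {}
        for m, spec in d.items():
            modes[m] = spec["mode"]
            if spec["mode"] == "duplicated":
                c1[m] = frozenset(spec["copy1_excluded"])
                c2[m] = frozenset(spec["copy2_excluded"])
        out = cls(modes, c1, c2, frozenset(always_present))
        out.validate()
        return out


def scheme_from_conflicts(reports, groups: GroupMap) -> DuplicationScheme:
    """Turn per-marker conflict reports into a duplication scheme.

    Clean markers stay single.  A conflicted marker is duplicated: the
    conflicted groups are excluded from copy 1 and kept in copy 2, the
    remaining ingroup sections the other way around; outgroup subgenera
    stay in both.  A marker conflicted in *every* ingroup section has
    no meaningful split and raises ``ValueError``.
    """
    ingroup = frozenset(groups.ingroup_codes)
    outgroup = frozenset(groups.outgroup_codes)
    modes, c1, c2 = {}, {}, {}
    for rep in reports:
        conflicted = frozenset(rep.conflicted_groups) & ingroup
        if not conflicted:
            modes[rep.marker] = "single"
            continue
        if conflicted == ingroup:
            raise ValueError(
                f"{rep.marker}: every ingroup section is conflicted; "
                "the duplication scheme is undefined"
            )
        modes[rep.marker] = "duplicated"
        c1[rep.marker] = conflicted
        c2[rep.marker] = ingroup - conflicted
    scheme = DuplicationScheme(modes, c1, c2, always_present=outgroup)
    scheme.validate()
    return scheme


def build_duplicated_matrix(
    alignments: dict[str, AlignmentMatrix],
    scheme: DuplicationScheme,
    taxa: list[str],
    groups: GroupMap | None = None,
) -> AlignmentMatrix:
    """Concatenate per-marker alignments under the duplication scheme.

    ``taxa`` is the master row order.  For duplicated markers the two
    partitions are named ``<marker>_1`` / ``<marker>_2``; a taxon whose
    group is excluded from a copy (or that is absent from the source
    alignment) is coded '?' across that partition.  When group-code
    exclusions must be resolved for species-level taxa, pass ``groups``.
    """
    if not alignments:
        raise ValueError("no alignments given")
    covered = set().union(*(set(a.taxa) for a in alignments.values()))
    if not set(taxa) & covered:
        raise ValueError("master taxon list shares no taxa with the alignments")

    def group_of(taxon: str) -> str:
        return groups.group_of(taxon) if groups is not None else taxon

    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    parts: list[Partition] = []
    pos = 0
    for marker in scheme.modes:
        aln = alignments[marker]
        width = aln.length
        copies = (
            [(f"{marker}", frozenset())]
            if scheme.modes[marker] == "single"
            else [
                (f"{marker}_1", scheme.copy1_excluded[marker]),
                (f"{marker}_2", scheme.copy2_excluded[marker]),
            ]
        )
        for pname, excluded in copies:
            for t in taxa:
                if t in aln.rows and group_of(t) not in excluded:
                    chunks[t].append(aln.rows[t])
                else:
                    chunks[t].append(MISSING * width)
            parts.append(Partition(pname, pos, pos + width))
            pos += width
    return AlignmentMatrix(
        taxa=list(taxa),
        rows={t: "".join(chunks[t]) for t in taxa},
        partitions=parts,
    )


# ---------------------------------------------------------------------------
# I/O


def _sanitize(name: str, fmt: str) -> str:
    if re.search(r"\s", name):
        if fmt == "nexus":
            return f"'{name}'"
        clean = re.sub(r"\s+", "_", name)
        logger.warning("taxon %r renamed %r for %s output", name, clean, fmt)
        return clean
    return name


def _to_biopython(matrix: AlignmentMatrix, fmt: str) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        SeqRecord(Seq(matrix.rows[t]), id=_sanitize(t, fmt), description="")
        for t in matrix.taxa
    )


def _nexus_text(matrix: AlignmentMatrix) -> str:
    name_w = max(len(t) for t in matrix.taxa) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={matrix.length};",
        f'    FORMAT DATATYPE=DNA MISSING={MISSING} GAP={GAP};',
        "    MATRIX",
    ]
    for t in matrix.taxa:
        lines.append(f"    {_sanitize(t, 'nexus'):<{name_w}}{matrix.rows[t]}")
    lines += ["    ;", "END;", "BEGIN SETS;"]
    for p in matrix.partitions:
        # NEXUS charsets are 1-based inclusive
        lines.append(f"    CHARSET {p.name} = {p.start + 1}-{p.end};")
    lines += ["END;", ""]
    return "\n".join(lines)


def write_matrix(matrix: AlignmentMatrix, path, fmt: str = "nexus") -> None:
    """Write NEXUS (with charsets), relaxed PHYLIP, or FASTA."""
    path = Path(path)
    if fmt == "nexus":
        path.write_text(_nexus_text(matrix))
    elif fmt == "phylip-relaxed":
        AlignIO.write(_to_biopython(matrix, fmt), str(path), "phylip-relaxed")
    elif fmt == "fasta":
        AlignIO.write(_to_biopython(matrix, fmt), str(path), "fasta")
    else:
        raise ValueError(f"unknown format {fmt!r}")


_CHARSET_RE = re.compile(
    r"charset\s+(\S+)\s*=\s*(\d+)\s*-\s*(\d+)\s*;", re.IGNORECASE
)


def read_matrix(path, fmt: str = "nexus") -> AlignmentMatrix:
    """Read an alignment back; NEXUS charsets become partitions."""
    path = Path(path)
    schema = {"nexus": "nexus", "phylip-relaxed": "phylip-relaxed", "fasta": "fasta"}[fmt]
    aln = AlignIO.read(StringIO(path.read_text()), schema)
    taxa = [rec.id.strip("'") for rec in aln]
    rows = {rec.id.strip("'"): str(rec.seq).upper() for rec in aln}
    partitions = []
    if fmt == "nexus":
        pos = 0
        for m in _CHARSET_RE.finditer(path.read_text()):
            name, start, end = m.group(1), int(m.group(2)) - 1, int(m.group(3))
            if start == pos:
                partitions.append(Partition(name, start, end))
                pos = end
    return AlignmentMatrix(taxa=taxa, rows=rows, partitions=partitions)
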