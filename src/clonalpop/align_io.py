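"""Alignment / annotation data model and the file formats around it.

The unit every statistic consumes is an :class:`Alignment`: *n* haploid
sequences of identical length *L* over ``{A,C,G,T,N,-}``.  Annotations are
a deliberately small TSV dialect (CDS / intergenic intervals with strand)
rather than full GFF3 — only interval, strand and kind are ever needed
downstream; a GFF3 importer is a documented extension point.

Coordinates are 1-based inclusive throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import (
    AlignmentLengthError,
    AlphabetError,
    AnnotationError,
    CoordinateError,
    DuplicateIdError,
    FastaFormatError,
    SerializationError,
)

ALPHABET = frozenset("ACGTN-")

_PathLike = Union[str, Path]


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment of haploid sequences.

    Parameters
    ----------
    ids:
        Unique sequence identifiers, in input order.
    seqs:
        Uppercase sequences over ``{A,C,G,T,N,-}``, all of length ``L``.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise AlignmentLengthError("ids and seqs differ in count")
        if not self.seqs:
            raise FastaFormatError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            raise DuplicateIdError("duplicate sequence identifiers")
        L = len(self.seqs[0])
        if L < 1:
            raise AlignmentLengthError("alignment length must be >= 1")
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != L:
                raise AlignmentLengthError(
                    f"sequence {sid!r} has length {len(s)}, expected {L}"
                )
            bad = set(s) - ALPHABET
            if bad:
                raise AlphabetError(f"sequence {sid!r} contains {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def L(self) -> int:
        return len(self.seqs[0])

    def subset_columns(self, columns: Iterable[int]) -> "Alignment":
        """New alignment keeping only the given 0-based columns (in order)."""
        cols = list(columns)
        return Alignment(
            ids=self.ids,
            seqs=tuple("".join(s[c] for c in cols) for s in self.seqs),
        )


def read_fasta_alignment(path: _PathLike) -> Alignment:
    """Read an aligned FASTA file.

    Sequences are uppercased; record order is preserved.  Ragged record
    lengths, duplicate identifiers and empty files are rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    return Alignment(ids=ids, seqs=seqs)


def write_fasta(aln: Alignment, path: _PathLike, width: int = 70) -> None:
    """Write an alignment as FASTA, wrapping sequence lines at ``width``."""
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class Feature:
    """One annotated interval (1-based inclusive)."""

    feature_id: str
    replicon: str
    start: int
    end: int
    strand: str  # '+' or '-'
    kind: str  # 'CDS' or 'IGR'

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AnnotationTable:
    """CDS / intergenic features over one or more reference replicons.

    ``references`` maps replicon name to its (uppercase) sequence; every
    feature must fit inside its replicon, CDS lengths must be divisible by
    3, and features of the same kind on one replicon must not overlap.
    """

    features: tuple[Feature, ...]
    references: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for f in self.features:
            if f.strand not in ("+", "-"):
                raise AnnotationError(f"{f.feature_id}: bad strand {f.strand!r}")
            if f.kind not in ("CDS", "IGR"):
                raise AnnotationError(f"{f.feature_id}: bad kind {f.kind!r}")
            if f.start < 1 or f.start > f.end:
                raise CoordinateError(
                    f"{f.feature_id}: bad interval {f.start}..{f.end}"
                )
            if f.replicon in self.references:
                rl = len(self.references[f.replicon])
                if f.end > rl:
                    raise CoordinateError(
                        f"{f.feature_id}: end {f.end} beyond replicon length {rl}"
                    )
            if f.kind == "CDS" and f.length % 3 != 0:
                raise AnnotationError(
                    f"{f.feature_id}: CDS length {f.length} not divisible by 3"
                )
        # same-kind features on one replicon must not overlap
        by_group: dict[tuple[str, str], list[Feature]] = {}
        for f in self.features:
            by_group.setdefault((f.replicon, f.kind), []).append(f)
        for (rep, kind), feats in by_group.items():
            feats = sorted(feats, key=lambda f: f.start)
            for a, b in zip(feats, feats[1:]):
                if b.start <= a.end:
                    raise AnnotationError(
                        f"overlapping {kind} features {a.feature_id}/"
                        f"{b.feature_id} on {rep}"
                    )

    def cds_features(self, replicon: str | None = None) -> list[Feature]:
        return [
            f
            for f in self.features
            if f.kind == "CDS" and (replicon is None or f.replicon == replicon)
        ]

    def feature_at(self, replicon: str, position: int, kind: str = "CDS") -> Feature | None:
        """The feature of ``kind`` covering 1-based ``position``, or None."""
        for f in self.features:
            if f.replicon == replicon and f.kind == kind and f.start <= position <= f.end:
                return f
        return None

    def cds_sequence(self, feature: Feature) -> str:
        """Strand-oriented (coding) sequence of a CDS feature."""
        ref = self.references[feature.replicon]
        seg = ref[feature.start - 1 : feature.end]
        if feature.strand == "-":
            seg = str(Seq(seg).reverse_complement())
        return seg


_ANNOT_COLUMNS = ("id", "replicon", "start", "end", "strand", "kind")


def read_annotation(
    path: _PathLike,
    references: Mapping[str, str] | _PathLike | None = None,
) -> AnnotationTable:
    """Read the package's TSV annotation dialect.

    Columns (tab-separated, ``#`` comments and an optional header allowed):
    ``id  replicon  start  end  strand  kind`` with 1-based inclusive
    coordinates.  ``references`` may be a mapping of replicon name to
    sequence or a path to a FASTA file of reference replicons.
    """
    refs: Mapping[str, str]
    if references is None:
        refs = {}
    elif isinstance(references, (str, Path)):
        refs = {
            r.id: str(r.seq).upper() for r in SeqIO.parse(str(references), "fasta")
        }
    else:
        refs = {k: v.upper() for k, v in references.items()}

    feats: list[Feature] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "id" and tuple(parts[:6]) == _ANNOT_COLUMNS:
                continue  # header
            if len(parts) < 6:
                raise AnnotationError(f"{path}:{ln}: expected 6 columns")
            fid, rep, start, end, strand, kind = parts[:6]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise CoordinateError(f"{path}:{ln}: non-integer coordinate") from exc
            feats.append(Feature(fid, rep, s, e, strand, kind))
    return AnnotationTable(features=tuple(feats), references=refs)


def write_annotation(table: AnnotationTable, path: _PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOT_COLUMNS) + "\n")
        for f in table.features:
            fh.write(
                f"{f.feature_id}\t{f.replicon}\t{f.start}\t{f.end}\t"
                f"{f.strand}\t{f.kind}\n"
            )


@dataclass
class TreeNode:
    """Minimal rooted tree with branch lengths (to the parent).

    Used for UPGMA output and simulated genealogies; serialized as newick.
    """

    name: str | None = None
    length: float | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to a newick string with branch lengths.

    Every leaf must carry a name; internal nodes may be anonymous.
    """

    def render(node: TreeNode, is_root: bool) -> str:
        if node.is_leaf:
            if not node.name:
                raise SerializationError("unlabeled leaf in tree")
            body = node.name
        else:
            body = "(" + ",".join(render(c, False) for c in node.children) + ")"
            if node.name:
                body += node.name
        if not is_root and node.length is not None:
            body += f":{node.length:g}"
        return body

    return render(tree, True) + ";"
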