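"""Protein sequences and class-A GPCR topology annotations.

A class-A GPCR is described here by its residue string plus an ordered
partition into the canonical topology segments: the extracellular N-terminus,
seven transmembrane helices (TM1-TM7) alternating with intracellular (ICL1-3)
and extracellular (ECL1-3) loops, an optional membrane-proximal helix 8, and
the C-terminal tail.  Chimera design operates on these named segments, so all
file formats in this module carry 1-based inclusive residue coordinates (the
GFF3 convention).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical one-letter amino-acid codes plus 'X' for unknown residues.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Canonical N-to-C order of class-A GPCR topology segments.  H8 is optional.
CANONICAL_SEGMENT_ORDER = (
    "NTERM",
    "TM1", "ICL1", "TM2", "ECL1", "TM3", "ICL2", "TM4",
    "ECL2", "TM5", "ICL3", "TM6", "ECL3", "TM7",
    "H8", "CTERM",
)

_SEGMENT_RANK = {name: i for i, name in enumerate(CANONICAL_SEGMENT_ORDER)}

ICL_SEGMENTS = ("ICL1", "ICL2", "ICL3")
TM_SEGMENTS = ("TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7")

FASTA_LINE_WIDTH = 60


class TopologyError(ValueError):
    """Raised when a sequence or topology annotation violates its contract."""


@dataclass(frozen=True)
class ProteinSequence:
    """A named protein sequence over the canonical amino-acid alphabet."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise TopologyError("sequence id must be non-empty")
        if not self.residues:
            raise TopologyError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "residues", self.residues.upper())
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in AMINO_ALPHABET:
                raise TopologyError(
                    f"illegal residue {ch!r} at position {pos} in record {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def checksum(self) -> str:
        """Short content hash used to track design inputs."""
        return hashlib.sha1(self.residues.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class Segment:
    """A named topology segment with 1-based inclusive residue bounds."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.name not in _SEGMENT_RANK:
            raise TopologyError(f"unknown segment name {self.name!r}")
        if not (1 <= self.start <= self.end):
            raise TopologyError(
                f"segment {self.name}: invalid range {self.start}..{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TopologyAnnotation:
    """An ordered, contiguous segmentation of one receptor sequence.

    Segments must tile residues ``1..length`` without gaps or overlaps and
    appear in canonical N-to-C order; any subset of the canonical segment
    names is allowed (toy receptors typically use only a few).
    """

    sequence_id: str
    segments: tuple[Segment, ...]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        segments = tuple(self.segments)
        object.__setattr__(self, "segments", segments)
        if not segments:
            raise TopologyError("topology has no segments")
        names = [s.name for s in segments]
        if len(set(names)) != len(names):
            raise TopologyError(f"duplicate segment names in {names}")
        ranks = [_SEGMENT_RANK[n] for n in names]
        if ranks != sorted(ranks):
            bad = names[next(i for i in range(1, len(ranks)) if ranks[i] < ranks[i - 1])]
            raise TopologyError(f"segment {bad} out of canonical N-to-C order")
        if segments[0].start != 1:
            raise TopologyError(
                f"first segment {segments[0].name} starts at {segments[0].start}, not 1"
            )
        for prev, cur in zip(segments, segments[1:]):
            if cur.start != prev.end + 1:
                kind = "overlap" if cur.start <= prev.end else "gap"
                raise TopologyError(
                    f"{kind} between segments {prev.name} (ends {prev.end}) and "
                    f"{cur.name} (starts {cur.start})"
                )
        object.__setattr__(self, "length", segments[-1].end)

    def validate_against(self, sequence: ProteinSequence) -> None:
        if sequence.id != self.sequence_id:
            raise TopologyError(
                f"topology annotates {self.sequence_id!r}, not {sequence.id!r}"
            )
        if self.length != len(sequence):
            raise TopologyError(
                f"topology covers 1..{self.length} but sequence {sequence.id!r} "
                f"has {len(sequence)} residues"
            )

    def segment(self, name: str) -> Segment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(seg.name == name for seg in self.segments)

    def segment_of(self, position: int) -> Segment:
        """Return the segment containing a 1-based residue position."""
        for seg in self.segments:
            if seg.start <= position <= seg.end:
                return seg
        raise TopologyError(f"position {position} outside 1..{self.length}")


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein records from a FASTA file.

    Residues are uppercased; a single trailing ``*`` (stop) is stripped.
    Duplicate ids and residues outside the canonical alphabet are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise TopologyError(f"no FASTA records found in {path}")
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise TopologyError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if residues.endswith("*"):
            residues = residues[:-1]
        out.append(ProteinSequence(id=rec.id, residues=residues,
                                   description=rec.description))
    return out


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path) -> None:
    """Write sequences as FASTA wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id,
                  description=s.description if s.description != s.id else "")
        for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_LINE_WIDTH)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Topology TSV I/O


def load_topology(path: str | Path, sequence: ProteinSequence) -> TopologyAnnotation:
    """Load a segment table (``segment<TAB>start<TAB>end``, 1-based inclusive).

    Lines starting with ``#`` are comments.  The resulting annotation must
    tile the full sequence; gaps, overlaps, unknown names, out-of-order
    segments, or a coverage mismatch raise :class:`TopologyError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    segments: list[Segment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() == "segment":
                continue  # header
            if len(fields) != 3:
                raise TopologyError(f"{path}:{lineno}: expected 3 tab-separated fields")
            name, start, end = fields
            try:
                segments.append(Segment(name.upper(), int(start), int(end)))
            except ValueError as exc:
                raise TopologyError(f"{path}:{lineno}: {exc}") from exc
    topo = TopologyAnnotation(sequence_id=sequence.id, segments=tuple(segments))
    topo.validate_against(sequence)
    return topo


def write_topology(topology: TopologyAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("segment\tstart\tend\n")
        for seg in topology.segments:
            fh.write(f"{seg.name}\t{seg.start}\t{seg.end}\n")


def default_backbone_topology(sequence: ProteinSequence) -> TopologyAnnotation:
    """Load the shipped bovine-rhodopsin segment table for a 348-residue backbone.

    The shipped boundaries are an implementer-provided approximation of the
    rhodopsin helix/loop architecture; users with their own boundary
    definitions should supply a topology TSV instead.
    """
    from importlib.resources import files

    path = files("optoxr") / "data" / "rhodopsin_topology.tsv"
    return load_topology(str(path), sequence)


# ---------------------------------------------------------------------------
# Design outputs (FASTA + GFF3 provenance map)


def write_design_outputs(design, fasta_path: str | Path, gff3_path: str | Path) -> None:
    """Write a chimera design as FASTA plus a GFF3 provenance map.

    GFF3 features are emitted in protein coordinates (1-based inclusive), one
    feature per contiguous same-source provenance block, with attributes
    recording the source sequence, source coordinates, segment name, and the
    rule set that produced the design.
    """
    write_fasta([design.chimera], fasta_path)
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {design.chimera.id} 1 {len(design.chimera)}\n")
        for block in design.provenance_blocks():
            attrs = (
                f"ID=block{block.start};source_id={block.source_sequence_id};"
                f"source_start={block.source_start};source_end={block.source_end};"
                f"segment={block.segment_name};ruleset={design.ruleset_name}"
            )
            fh.write(
                "\t".join(
                    [
                        design.chimera.id,
                        "optoxr",
                        f"{block.source.lower()}_segment",
                        str(block.start),
                        str(block.end),
                        ".",
                        ".",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_design_gff3(path: str | Path) -> list[dict]:
    """Parse a provenance GFF3 back into a list of feature dicts (for checks)."""
    features = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise TopologyError(f"malformed GFF3 line: {line!r}")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            features.append(
                {
                    "seqid": cols[0],
                    "type": cols[2],
                    "start": int(cols[3]),
                    "end": int(cols[4]),
                    **attrs,
                }
            )
    return features
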