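"""Global pairwise alignment and cut-site projection between receptors.

Chimera design needs a residue-level correspondence between the light-sensitive
backbone (rhodopsin) and the target GPCR so that segment boundaries defined on
the backbone can be carried over to homologous positions on the target.  This
module provides:

* an affine-gap Needleman-Wunsch/Gotoh global aligner with fixed, documented
  tie-breaking so designs are bit-stable across runs and platforms;
* an importer for externally computed pairwise alignments (aligned FASTA),
  for users who want to reproduce a specific alignment program's output;
* projection of a backbone topology annotation onto target coordinates
  through the alignment column map.

Scoring convention: ``score = sum of substitution scores - sum over gaps of
(gap_open + (len - 1) * gap_extend)``, i.e. the first residue of a gap costs
``gap_open`` and each additional residue ``gap_extend``.  Terminal gaps are
penalized like internal ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Align import substitution_matrices

from .topology import ProteinSequence, Segment, TopologyAnnotation

#: Gap marker used in alignment column maps.
GAP = None

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0

_NEG_INF = float("-inf")


class AlignmentError(ValueError):
    """Raised for invalid alignment inputs or inconsistent column maps."""


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue substitution matrix (BLOSUM62 by default)."""

    name: str
    _array: object  # Bio.Align.substitution_matrices.Array

    def score(self, a: str, b: str) -> float:
        try:
            return float(self._array[a, b])
        except (KeyError, IndexError) as exc:
            missing = a if a not in self._array.alphabet else b
            raise AlignmentError(
                f"residue {missing!r} absent from matrix {self.name}"
            ) from exc

    @classmethod
    def load(cls, name: str = "BLOSUM62") -> "SubstitutionMatrix":
        """Load a named matrix from Biopython's packaged collection."""
        return cls(name=name, _array=substitution_matrices.load(name))

    @classmethod
    def read(cls, path: str | Path) -> "SubstitutionMatrix":
        """Read a matrix in NCBI text format from a file."""
        with open(path) as fh:
            arr = substitution_matrices.read(fh)
        return cls(name=Path(path).stem, _array=arr)


def blosum62() -> SubstitutionMatrix:
    return SubstitutionMatrix.load("BLOSUM62")


@dataclass(frozen=True)
class AlignmentColumnMap:
    """An ordered list of aligned residue-index pairs plus the alignment score.

    Each column pairs a backbone residue index with a target residue index
    (1-based) or :data:`GAP`.  Indices on each side are strictly increasing,
    jointly exhaustive, and no column is gap/gap.
    """

    columns: tuple[tuple[Optional[int], Optional[int]], ...]
    score: float
    backbone_length: int
    target_length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "columns", tuple(self.columns))
        b_seen, t_seen = [], []
        for b, t in self.columns:
            if b is GAP and t is GAP:
                raise AlignmentError("all-gap column")
            if b is not GAP:
                b_seen.append(b)
            if t is not GAP:
                t_seen.append(t)
        for seen, length, side in ((b_seen, self.backbone_length, "backbone"),
                                   (t_seen, self.target_length, "target")):
            if seen != list(range(1, length + 1)):
                raise AlignmentError(
                    f"{side} indices do not enumerate 1..{length} in order"
                )

    def __len__(self) -> int:
        return len(self.columns)

    def checksum(self) -> str:
        import hashlib

        text = ";".join(f"{b}:{t}" for b, t in self.columns)
        return hashlib.sha1(text.encode()).hexdigest()[:12]

    def backbone_column(self, backbone_index: int) -> int:
        """Column position (0-based) holding a given backbone residue."""
        for i, (b, _) in enumerate(self.columns):
            if b == backbone_index:
                return i
        raise AlignmentError(f"backbone index {backbone_index} not in alignment")


def score_columns(
    columns,
    a: ProteinSequence,
    b: ProteinSequence,
    matrix: SubstitutionMatrix,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Recompute the affine-gap score of an explicit column list."""
    score = 0.0
    prev_gap_side = None  # 'a', 'b', or None
    for bi, ti in columns:
        if bi is not GAP and ti is not GAP:
            score += matrix.score(a.residues[bi - 1], b.residues[ti - 1])
            prev_gap_side = None
        else:
            side = "b" if ti is GAP else "a"
            score -= gap_extend if prev_gap_side == side else gap_open
            prev_gap_side = side
    return score


def global_align(
    a: ProteinSequence,
    b: ProteinSequence,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentColumnMap:
    """Optimal global alignment of backbone ``a`` against target ``b``.

    Uses the Gotoh three-state dynamic program.  Ties in the traceback are
    broken by preferring, at every cell, substitution over a gap in the
    target over a gap in the backbone, which makes the returned column map
    deterministic.
    """
    if matrix is None:
        matrix = blosum62()
    if gap_open < 0 or gap_extend < 0:
        raise AlignmentError("gap penalties must be non-negative")
    if gap_extend > gap_open:
        raise AlignmentError("gap_extend must not exceed gap_open")

    ra, rb = a.residues, b.residues
    n, m = len(ra), len(rb)

    # State 0 = match/mismatch, 1 = gap in target (consumes a), 2 = gap in
    # backbone (consumes b).  Preference order for ties: 0 > 1 > 2.
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Ga = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Gb = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ga[i][0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Gb[0][j] = -(gap_open + (j - 1) * gap_extend)

    for i in range(1, n + 1):
        row_m, row_ga, row_gb = M[i], Ga[i], Gb[i]
        prev_m, prev_ga, prev_gb = M[i - 1], Ga[i - 1], Gb[i - 1]
        ai = ra[i - 1]
        for j in range(1, m + 1):
            s = matrix.score(ai, rb[j - 1])
            row_m[j] = s + max(prev_m[j - 1], prev_ga[j - 1], prev_gb[j - 1])
            row_ga[j] = max(
                prev_m[j] - gap_open,
                prev_ga[j] - gap_extend,
                prev_gb[j] - gap_open,
            )
            row_gb[j] = max(
                row_m[j - 1] - gap_open,
                row_ga[j - 1] - gap_open,
                row_gb[j - 1] - gap_extend,
            )

    def best_state(i: int, j: int) -> int:
        vals = (M[i][j], Ga[i][j], Gb[i][j])
        best = max(vals)
        return vals.index(best)  # index() returns the first == preference order

    state = best_state(n, m)
    score = (M[n][m], Ga[n][m], Gb[n][m])[state]

    # Traceback, preferring predecessor states in order 0 > 1 > 2 on ties.
    columns: list[tuple[Optional[int], Optional[int]]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            prevs = (M[i - 1][j - 1], Ga[i - 1][j - 1], Gb[i - 1][j - 1])
            columns.append((i, j))
            i, j = i - 1, j - 1
        elif state == 1:
            prevs = (
                M[i - 1][j] - gap_open,
                Ga[i - 1][j] - gap_extend,
                Gb[i - 1][j] - gap_open,
            )
            columns.append((i, GAP))
            i = i - 1
        else:
            prevs = (
                M[i][j - 1] - gap_open,
                Ga[i][j - 1] - gap_open,
                Gb[i][j - 1] - gap_extend,
            )
            columns.append((GAP, j))
            j = j - 1
        if i == 0 and j == 0:
            break
        # The cell value was defined as max(prevs) (plus the substitution
        # score for state 0), so the first-maximal predecessor reproduces the
        # DP exactly and encodes the documented tie preference 0 > 1 > 2.
        state = prevs.index(max(prevs))

    columns.reverse()
    return AlignmentColumnMap(
        columns=tuple(columns),
        score=score,
        backbone_length=n,
        target_length=m,
    )


def import_alignment(
    path: str | Path,
    backbone_id: str,
    target_id: str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentColumnMap:
    """Build a column map from an externally computed aligned FASTA.

    Both records must be present and of equal gapped length (gap character
    ``-``).  The score is recomputed under the supplied matrix and gap
    parameters so imported and internally computed alignments are comparable.
    """
    if matrix is None:
        matrix = blosum62()
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    for rid in (backbone_id, target_id):
        if rid not in records:
            raise AlignmentError(f"record {rid!r} not found in {path}")
    ga, gb = records[backbone_id], records[target_id]
    if len(ga) != len(gb):
        raise AlignmentError(
            f"aligned records have unequal lengths ({len(ga)} vs {len(gb)})"
        )
    columns: list[tuple[Optional[int], Optional[int]]] = []
    bi = ti = 0
    for ca, cb in zip(ga, gb):
        if ca == "-" and cb == "-":
            raise AlignmentError("all-gap column in imported alignment")
        b = t = GAP
        if ca != "-":
            bi += 1
            b = bi
        if cb != "-":
            ti += 1
            t = ti
        columns.append((b, t))
    a_seq = ProteinSequence(id=backbone_id, residues=ga.replace("-", ""))
    b_seq = ProteinSequence(id=target_id, residues=gb.replace("-", ""))
    score = score_columns(columns, a_seq, b_seq, matrix, gap_open, gap_extend)
    return AlignmentColumnMap(
        columns=tuple(columns), score=score,
        backbone_length=bi, target_length=ti,
    )


def project_topology(
    backbone_topology: TopologyAnnotation,
    colmap: AlignmentColumnMap,
    target_id: str,
) -> TopologyAnnotation:
    """Carry backbone segment boundaries over to target coordinates.

    Each internal cut site (the first residue of a segment) is mapped to the
    target residue aligned in the same column; when the target carries a gap
    there, the boundary shifts to the nearest non-gap column toward that
    segment's interior (i.e. forward along the alignment).  The first segment
    is pinned to target residue 1 and the last to the target's final residue,
    so projected segments tile the target exactly.
    """
    if backbone_topology.length != colmap.backbone_length:
        raise AlignmentError(
            f"alignment covers a backbone of {colmap.backbone_length} residues "
            f"but the topology annotates {backbone_topology.length}"
        )
    # Target index at or after each column (forward shift into the interior).
    n_cols = len(colmap.columns)
    next_target = [None] * n_cols
    nxt = None
    for k in range(n_cols - 1, -1, -1):
        t = colmap.columns[k][1]
        if t is not GAP:
            nxt = t
        next_target[k] = nxt

    starts: list[int] = []
    for idx, seg in enumerate(backbone_topology.segments):
        if idx == 0:
            starts.append(1)
            continue
        col = colmap.backbone_column(seg.start)
        t = next_target[col]
        if t is None:
            raise AlignmentError(
                f"segment {seg.name}: no target residue at or beyond its cut site"
            )
        starts.append(t)

    segments: list[Segment] = []
    for idx, seg in enumerate(backbone_topology.segments):
        start = starts[idx]
        end = (
            starts[idx + 1] - 1
            if idx + 1 < len(starts)
            else colmap.target_length
        )
        if end < start:
            raise AlignmentError(
                f"projected segment {seg.name} collapses to zero length"
            )
        segments.append(Segment(seg.name, start, end))
    topo = TopologyAnnotation(sequence_id=target_id, segments=tuple(segments))
    return topo
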