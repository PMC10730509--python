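"""Global aligner, alignment import, and cut-site projection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optoxr import (
    GAP,
    AlignmentError,
    ProteinSequence,
    Segment,
    TopologyAnnotation,
    global_align,
    import_alignment,
    project_topology,
    score_columns,
)
from optoxr.align import AlignmentColumnMap


def brute_force_best_score(a, b, matrix, gap_open, gap_extend):
    """Independent oracle: enumerate every global alignment path explicitly.

    Recursion over alignment columns, scoring gap runs as
    ``gap_open + (len - 1) * gap_extend``; exponential, so only usable on
    short sequences.
    """
    best = [float("-inf")]

    def rec(i, j, last_gap, score):
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, None, score + matrix.score(a[i], b[j]))
        if i < len(a):  # column (a_i, GAP): gap in the second sequence
            cost = gap_extend if last_gap == "b" else gap_open
            rec(i + 1, j, "b", score - cost)
        if j < len(b):  # column (GAP, b_j)
            cost = gap_extend if last_gap == "a" else gap_open
            rec(i, j + 1, "a", score - cost)

    rec(0, 0, None, 0.0)
    return best[0]


class TestGlobalAlign:
    def test_identical_sequences_score_sum_of_diagonal(self, matrix):
        cm = global_align(
            ProteinSequence("a", "ACDE"), ProteinSequence("b", "ACDE"), matrix, 11, 1
        )
        assert cm.columns == ((1, 1), (2, 2), (3, 3), (4, 4))
        # BLOSUM62 diagonal: A=4, C=9, D=6, E=5
        assert cm.score == 24

    def test_single_residue_identity(self, matrix):
        cm = global_align(
            ProteinSequence("a", "M"), ProteinSequence("b", "M"), matrix, 11, 1
        )
        assert cm.columns == ((1, 1),)
        assert cm.score == matrix.score("M", "M")

    def test_score_matches_column_recomputation(self, matrix):
        rng = np.random.default_rng(7)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(25):
            a = ProteinSequence("a", "".join(rng.choice(list(alphabet), size=rng.integers(3, 30))))
            b = ProteinSequence("b", "".join(rng.choice(list(alphabet), size=rng.integers(3, 30))))
            cm = global_align(a, b, matrix, 11, 1)
            assert score_columns(cm.columns, a, b, matrix, 11, 1) == cm.score

    def test_symmetry_of_optimal_score(self, matrix):
        rng = np.random.default_rng(11)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(15):
            a = ProteinSequence("a", "".join(rng.choice(list(alphabet), size=rng.integers(2, 20))))
            b = ProteinSequence("b", "".join(rng.choice(list(alphabet), size=rng.integers(2, 20))))
            assert global_align(a, b, matrix).score == global_align(b, a, matrix).score

    def test_matches_bruteforce_on_short_pairs(self, matrix):
        """DP optimum equals exhaustive path enumeration (lengths <= 3)."""
        alphabet = "ACDE"
        seqs = [
            "".join(t)
            for n in (1, 2, 3)
            for t in itertools.product(alphabet, repeat=n)
        ]
        rng = np.random.default_rng(3)
        pairs = [(seqs[i], seqs[j])
                 for i, j in rng.integers(0, len(seqs), size=(300, 2))]
        for sa, sb in pairs:
            a, b = ProteinSequence("a", sa), ProteinSequence("b", sb)
            got = global_align(a, b, matrix, 11, 1).score
            want = brute_force_best_score(sa, sb, matrix, 11, 1)
            assert got == want, (sa, sb)

    def test_gap_parameter_validation(self, matrix):
        a = ProteinSequence("a", "MK")
        with pytest.raises(AlignmentError):
            global_align(a, a, matrix, gap_open=1, gap_extend=2)

    def test_residue_missing_from_matrix(self, tmp_path):
        from optoxr import SubstitutionMatrix

        matrix_path = tmp_path / "tiny.mat"
        matrix_path.write_text(
            "   A  C\nA  4  0\nC  0  9\n"
        )
        tiny = SubstitutionMatrix.read(matrix_path)
        a = ProteinSequence("a", "ADC")
        b = ProteinSequence("b", "AC")
        with pytest.raises(AlignmentError, match="D"):
            global_align(a, b, tiny, gap_open=2, gap_extend=1)

    def test_deterministic_output(self, matrix):
        a = ProteinSequence("a", "MKTAYIAKQR")
        b = ProteinSequence("b", "MKTAIAKQRG")
        assert global_align(a, b, matrix).columns == global_align(a, b, matrix).columns


class TestImportAlignment:
    def _write(self, tmp_path, records):
        p = tmp_path / "aln.fasta"
        p.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in records))
        return p

    def test_direct_parse(self, tmp_path, matrix):
        p = self._write(tmp_path, [("bb", "AC-E"), ("tg", "ACDE")])
        cm = import_alignment(p, "bb", "tg", matrix)
        assert cm.columns == ((1, 1), (2, 2), (GAP, 3), (3, 4))
        assert cm.score == score_columns(
            cm.columns,
            ProteinSequence("bb", "ACE"),
            ProteinSequence("tg", "ACDE"),
            matrix, 11, 1,
        )

    def test_unequal_lengths_error(self, tmp_path, matrix):
        p = self._write(tmp_path, [("bb", "ACE"), ("tg", "ACDE")])
        with pytest.raises(AlignmentError, match="unequal"):
            import_alignment(p, "bb", "tg", matrix)

    def test_missing_id_error(self, tmp_path, matrix):
        p = self._write(tmp_path, [("bb", "ACE")])
        with pytest.raises(AlignmentError, match="tg"):
            import_alignment(p, "bb", "tg", matrix)

    def test_all_gap_column_error(self, tmp_path, matrix):
        p = self._write(tmp_path, [("bb", "A-E"), ("tg", "A-DE"[:3])])
        with pytest.raises(AlignmentError, match="all-gap"):
            import_alignment(p, "bb", "tg", matrix)


def _colmap(columns, score=0.0):
    b = max((c[0] for c in columns if c[0] is not GAP), default=0)
    t = max((c[1] for c in columns if c[1] is not GAP), default=0)
    return AlignmentColumnMap(tuple(columns), score, b, t)


class TestProjectTopology:
    def test_identity_alignment_projects_identically(self):
        topo = TopologyAnnotation(
            "x", (Segment("TM1", 1, 4), Segment("ICL1", 5, 8), Segment("TM2", 9, 12))
        )
        cm = _colmap([(i, i) for i in range(1, 13)])
        proj = project_topology(topo, cm, "y")
        assert [(s.name, s.start, s.end) for s in proj.segments] == [
            ("TM1", 1, 4), ("ICL1", 5, 8), ("TM2", 9, 12)
        ]

    def test_insertion_inside_loop_extends_it(self):
        """An extra target residue inside ICL1 stretches the projected loop."""
        topo = TopologyAnnotation(
            "x", (Segment("TM1", 1, 4), Segment("ICL1", 5, 8), Segment("TM2", 9, 12))
        )
        columns = [(i, i) for i in range(1, 7)] + [(GAP, 7)] + [
            (i, i + 1) for i in range(7, 13)
        ]
        proj = project_topology(topo, _colmap(columns), "y")
        assert [(s.name, s.start, s.end) for s in proj.segments] == [
            ("TM1", 1, 4), ("ICL1", 5, 9), ("TM2", 10, 13)
        ]

    def test_boundary_in_gap_shifts_into_segment_interior(self):
        """Target gap at a cut-site column: boundary moves to the nearest
        interior (following) non-gap target residue."""
        topo = TopologyAnnotation("x", (Segment("TM1", 1, 2), Segment("ICL1", 3, 5)))
        # target is gapped exactly at the ICL1 start column
        columns = [(1, 1), (2, 2), (3, GAP), (4, 3), (5, 4)]
        proj = project_topology(topo, _colmap(columns), "y")
        assert [(s.name, s.start, s.end) for s in proj.segments] == [
            ("TM1", 1, 2), ("ICL1", 3, 4)
        ]

    def test_collapsed_segment_reports_name(self):
        topo = TopologyAnnotation("x", (Segment("TM1", 1, 2), Segment("ICL1", 3, 4),
                                        Segment("TM2", 5, 6)))
        # the whole of ICL1 is deleted in the target
        columns = [(1, 1), (2, 2), (3, GAP), (4, GAP), (5, 3), (6, 4)]
        with pytest.raises(AlignmentError, match="ICL1"):
            project_topology(topo, _colmap(columns), "y")

    def test_projection_tiles_target_on_random_homologous_pairs(self):
        from optoxr import make_toy_pair

        for seed in range(10):
            backbone, topo, target, _, cm = make_toy_pair(seed)
            proj = project_topology(topo, cm, target.id)
            assert proj.length == len(target)  # tiling is enforced on build


@settings(max_examples=40, deadline=None)
@given(
    st.text(alphabet="ACDE", min_size=1, max_size=5),
    st.text(alphabet="ACDE", min_size=1, max_size=5),
)
def test_aligner_never_beats_or_trails_bruteforce(matrix_cache, sa, sb):
    matrix = matrix_cache
    got = global_align(ProteinSequence("a", sa), ProteinSequence("b", sb),
                       matrix, 11, 1).score
    assert got == brute_force_best_score(sa, sb, matrix, 11, 1)


@pytest.fixture(scope="module")
def matrix_cache(matrix):
    return matrix
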