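"""Chimera rule sets, stitching, provenance, diffing, back-translation."""

import numpy as np
import pytest

from optoxr import (
    BACKBONE,
    EPITOPE,
    TARGET,
    CodonUsageTable,
    DesignError,
    ProteinSequence,
    back_translate,
    design_chimera,
    design_from_files,
    diff_designs,
    global_align,
    make_ruleset,
    make_toy_pair,
    read_design_gff3,
    read_fasta,
    translate,
    write_design_outputs,
)
from optoxr.fixtures import LOOP_POOL, TM_POOL


class TestMakeRuleset:
    def test_v1_swaps_all_icls_and_cterm(self):
        rs = make_ruleset("V1")
        assert all(rs.source_of(s) == TARGET for s in ("ICL1", "ICL2", "ICL3", "CTERM"))
        assert all(rs.source_of(s) == BACKBONE for s in ("NTERM", "TM1", "TM7", "ECL2"))
        assert rs.cterm_cut_shift == 0

    def test_v2_retains_backbone_icl1_and_shifts_cterm_cut(self):
        rs = make_ruleset("V2")
        assert rs.source_of("ICL1") == BACKBONE
        assert rs.source_of("ICL2") == TARGET
        assert rs.source_of("CTERM") == TARGET
        assert rs.cterm_cut_shift > 0

    def test_unknown_version(self):
        with pytest.raises(DesignError, match="unknown ruleset version"):
            make_ruleset("V3")

    def test_v1_keep_icl1_variant(self):
        assert make_ruleset("V1", keep_icl1=True).source_of("ICL1") == BACKBONE

    def test_preset_invariants_protected(self):
        with pytest.raises(DesignError):
            make_ruleset("V1", cterm_cut_shift=5)
        with pytest.raises(DesignError):
            make_ruleset("V2", cterm_cut_shift=0)
        with pytest.raises(DesignError):
            make_ruleset("V2", source_by_segment={"ICL1": TARGET})

    def test_custom_requires_source_map(self):
        with pytest.raises(DesignError):
            make_ruleset("custom")


class TestDesignChimera:
    def test_hand_stitched_toy(self, toy_backbone, toy_target):
        """ICL1 plus one flanking TM residue per side and the C-terminus come
        from the target; stitched by hand this is MAAGYKKKYGAAD."""
        backbone, topo = toy_backbone
        cm = global_align(backbone, toy_target)
        rs = make_ruleset(
            "custom",
            source_by_segment={
                "NTERM": BACKBONE, "TM1": BACKBONE, "ICL1": TARGET,
                "TM2": BACKBONE, "CTERM": TARGET,
            },
            proximal_tm_offset=1,
            epitope="",
        )
        design = design_chimera(backbone, topo, toy_target, cm, rs)
        assert design.chimera.residues == "MAAGYKKKYGAAD"

    def test_all_backbone_ruleset_is_identity(self, toy_backbone, toy_target):
        backbone, topo = toy_backbone
        cm = global_align(backbone, toy_target)
        rs = make_ruleset(
            "custom",
            source_by_segment={s.name: BACKBONE for s in topo.segments},
            proximal_tm_offset=0,
            epitope="",
        )
        design = design_chimera(backbone, topo, toy_target, cm, rs)
        assert design.chimera.residues == backbone.residues
        assert all(rec.source == BACKBONE for rec in design.provenance)

    def test_epitope_appended_with_epitope_provenance(self):
        backbone, topo, target, _, cm = make_toy_pair(0)
        design = design_chimera(backbone, topo, target, cm, make_ruleset("V2"))
        assert design.chimera.residues.endswith("TETSQVAPA")
        tail = design.provenance[-9:]
        assert all(rec.source == EPITOPE for rec in tail)
        assert [rec.source_index for rec in tail] == list(range(1, 10))

    def test_v2_structural_invariants_on_random_pairs(self):
        for seed in range(15):
            backbone, topo, target, _, cm = make_toy_pair(seed)
            design = design_chimera(backbone, topo, target, cm, make_ruleset("V2"))
            # backbone ICL1 retained verbatim
            icl1 = topo.segment("ICL1")
            icl1_blocks = [
                blk for blk in design.provenance_blocks()
                if blk.segment_name == "ICL1" and blk.source == BACKBONE
            ]
            assert len(icl1_blocks) == 1
            blk = icl1_blocks[0]
            assert (blk.source_start, blk.source_end) == (icl1.start, icl1.end)
            assert (
                design.chimera.residues[blk.start - 1 : blk.end]
                == backbone.residues[icl1.start - 1 : icl1.end]
            )
            # every target-sourced block is a verbatim target substring
            for b in design.provenance_blocks():
                if b.source == TARGET:
                    assert (
                        design.chimera.residues[b.start - 1 : b.end]
                        == target.residues[b.source_start - 1 : b.source_end]
                    )

    def test_provenance_reconstructs_chimera_under_fuzzing(self):
        rng = np.random.default_rng(5)
        for seed in range(12):
            backbone, topo, target, _, cm = make_toy_pair(seed + 100)
            version = ["V1", "V2"][seed % 2]
            kwargs = dict(proximal_tm_offset=int(rng.integers(0, 4)))
            if version == "V2":
                kwargs["cterm_cut_shift"] = int(rng.integers(1, 9))
            design = design_chimera(
                backbone, topo, target, cm, make_ruleset(version, **kwargs)
            )
            lookup = {BACKBONE: backbone.residues, TARGET: target.residues,
                      EPITOPE: "TETSQVAPA"}
            rebuilt = "".join(
                lookup[r.source][r.source_index - 1] for r in design.provenance
            )
            assert rebuilt == design.chimera.residues
            # within-block source indices are consecutive by construction
            for b in design.provenance_blocks():
                assert b.source_end - b.source_start == b.end - b.start

    def test_unknown_residue_inside_exchanged_segment_rejected(self, toy_backbone):
        backbone, topo = toy_backbone
        target = ProteinSequence("t", "MGGGYKXKYGGGD")  # X inside the loop
        cm = global_align(backbone, ProteinSequence("t", "MGGGYKKKYGGGD"))
        rs = make_ruleset(
            "custom",
            source_by_segment={
                "NTERM": BACKBONE, "TM1": BACKBONE, "ICL1": TARGET,
                "TM2": BACKBONE, "CTERM": BACKBONE,
            },
            proximal_tm_offset=0,
            epitope="",
        )
        with pytest.raises(DesignError, match="'X'"):
            design_chimera(backbone, topo, target, cm, rs)


class TestDiffDesigns:
    def test_v1_vs_v2_differ_at_icl1_and_cterm_junction(self):
        backbone, topo, target, _, cm = make_toy_pair(1)
        v1 = design_chimera(backbone, topo, target, cm, make_ruleset("V1"))
        v2 = design_chimera(backbone, topo, target, cm, make_ruleset("V2"))
        diffs = diff_designs(v1, v2, topo)
        touched = {seg for d in diffs for seg in d.segments}
        assert "ICL1" in touched  # V1 swaps it, V2 retains it
        assert "TM7" in touched  # V2 moves the C-terminal cut into TM7
        icl1_diffs = [d for d in diffs if "ICL1" in d.segments]
        assert all(d.source_a == TARGET and d.source_b == BACKBONE
                   for d in icl1_diffs)

    def test_identical_designs_empty_report(self):
        backbone, topo, target, _, cm = make_toy_pair(2)
        a = design_chimera(backbone, topo, target, cm, make_ruleset("V2"))
        b = design_chimera(backbone, topo, target, cm, make_ruleset("V2"))
        assert diff_designs(a, b, topo) == []

    def test_designs_from_different_targets_rejected(self):
        backbone, topo, target, _, cm = make_toy_pair(3)
        backbone2, topo2, target2, _, cm2 = make_toy_pair(4)
        a = design_chimera(backbone, topo, target, cm, make_ruleset("V2"))
        b = design_chimera(backbone2, topo2, target2, cm2, make_ruleset("V2"))
        with pytest.raises(DesignError, match="different inputs"):
            diff_designs(a, b, topo)


class TestDesignOutputs:
    def test_fasta_and_gff3_round_trip(self, tmp_path):
        backbone, topo, target, _, cm = make_toy_pair(6)
        design = design_chimera(backbone, topo, target, cm, make_ruleset("V2"))
        fasta, gff3 = tmp_path / "chimera.fasta", tmp_path / "chimera.gff3"
        write_design_outputs(design, fasta, gff3)
        assert read_fasta(fasta)[0].residues == design.chimera.residues
        features = read_design_gff3(gff3)
        assert len(features) == len(design.provenance_blocks())
        # features tile 1..L without gaps
        spans = sorted((f["start"], f["end"]) for f in features)
        assert spans[0][0] == 1
        assert spans[-1][1] == len(design.chimera)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 == e1 + 1


class TestBackTranslate:
    def test_methionine_single_codon(self):
        assert back_translate(ProteinSequence("p", "M")) == "ATG"

    def test_round_trip_on_random_proteins(self):
        rng = np.random.default_rng(9)
        table = CodonUsageTable.default()
        pool = list(TM_POOL + LOOP_POOL)
        for i in range(100):
            protein = ProteinSequence(
                f"p{i}", "".join(rng.choice(pool, size=rng.integers(1, 60)))
            )
            for mode, seed in (("most_frequent", None), ("weighted", i)):
                dna = back_translate(protein, table, mode=mode, seed=seed)
                assert len(dna) == 3 * len(protein)
                assert translate(dna) == protein.residues

    def test_weighted_mode_deterministic_given_seed(self):
        p = ProteinSequence("p", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
        a = back_translate(p, mode="weighted", seed=123)
        b = back_translate(p, mode="weighted", seed=123)
        assert a == b
        assert back_translate(p, mode="weighted", seed=124) != a

    def test_weighted_requires_seed(self):
        with pytest.raises(DesignError, match="seed"):
            back_translate(ProteinSequence("p", "MK"), mode="weighted")

    def test_unknown_amino_acid_rejected(self):
        with pytest.raises(DesignError, match="'X'"):
            back_translate(ProteinSequence("p", "MXK"))

    def test_stop_codon_appended_on_request(self):
        dna = back_translate(ProteinSequence("p", "MK"), append_stop=True)
        assert len(dna) == 9
        assert translate(dna) == "MK*"


def test_design_from_files_aligns_when_needed():
    backbone, topo, target, _, cm = make_toy_pair(8)
    via_wrapper = design_from_files(backbone, target, topo, make_ruleset("V2"))
    direct = design_chimera(backbone, topo, target, cm, make_ruleset("V2"))
    assert via_wrapper.chimera.residues == direct.chimera.residues
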