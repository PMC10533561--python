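"""IMGT numbering, segmentation, validity filtering and trimming."""

import pytest

from hybseq import annotate, simulate
from hybseq.config import HEAVY, HEAVY_SCAFFOLD, KAPPA, LIGHT_SCAFFOLD
from hybseq.seqs import reverse_translate, translate


def _light_v(cdr3="QQSYSTPLT", cdr1="QSISSY", cdr2="AAS"):
    return LIGHT_SCAFFOLD.assemble(cdr1, cdr2, cdr3)


def _interior(cfg, v_aa, locus):
    return (cfg.utr + cfg.leader_nt() + reverse_translate(v_aa)
            + cfg.stub_cores[locus])


class TestReadingFrame:
    def test_simulator_clone_frame_matches_construction(self, cfg, clones):
        interior = simulate.interior_of(clones[0].vl_nt, KAPPA, cfg)
        frame, aa = annotate.find_reading_frame(interior, "light")
        assert frame == len(cfg.utr) % 3
        assert cfg.leader_aa in aa

    def test_stop_codon_in_fr3_fails(self, cfg):
        v = _light_v()
        # engineer a stop into FR3 (between leader start and FR4)
        broken = v[:80] + "*" + v[81:]
        nt = _interior(cfg, broken, "light")
        with pytest.raises(annotate.AnnotationError):
            annotate.find_reading_frame(nt, "light")

    def test_single_nt_deletion_fails(self, cfg, clones):
        interior = simulate.interior_of(clones[0].vl_nt, KAPPA, cfg)
        # delete 1 nt inside FR2: frameshift destroys downstream anchors
        cut = len(cfg.utr) + len(cfg.leader_nt()) + 3 * 35
        with pytest.raises(annotate.AnnotationError):
            annotate.find_reading_frame(interior[:cut] + interior[cut + 1:],
                                        "light")


class TestNumbering:
    def test_cdr3_of_13_has_no_insertions(self):
        v = HEAVY_SCAFFOLD.assemble("GDTVSSNY", "ISGSGGST", "ARDLRSYGAFDVW"[:13])
        imgt = annotate.assign_imgt_numbering(v, "heavy")
        labels = [lab for lab, _ in imgt]
        cdr3 = [l for l in labels if annotate.region_of(l) == "CDR3"]
        assert cdr3 == [str(p) for p in range(105, 118)]

    @pytest.mark.parametrize("n,expected_insertions", [
        (14, ["112A"]), (15, ["111A", "112A"]), (16, ["111A", "112B", "112A"]),
    ])
    def test_long_cdr3_insertion_labels(self, n, expected_insertions):
        cdr3 = ("ARDLRSYGAGYDVNAPT" + "QS")[:n]
        v = HEAVY_SCAFFOLD.assemble("GDTVSSNY", "ISGSGGST", cdr3)
        imgt = annotate.assign_imgt_numbering(v, "heavy")
        labels = [lab for lab, _ in imgt]
        assert [l for l in labels if len(l) > 3] == expected_insertions
        # order follows the IMGT traversal
        keys = [annotate.imgt_key(l) for l in labels]
        assert keys == sorted(keys)

    def test_short_cdr3_gaps_in_middle(self):
        v = _light_v(cdr3="QQSYS")  # 5 residues: 105-107 + 116-117
        imgt = annotate.assign_imgt_numbering(v, "light")
        cdr3 = [l for l, _ in imgt if annotate.region_of(l) == "CDR3"]
        assert cdr3 == ["105", "106", "107", "116", "117"]

    def test_anchor_residues_at_their_positions(self, cfg, clones):
        interior = simulate.interior_of(clones[0].vh_nt, HEAVY, cfg)
        ann = annotate.annotate_sequence(interior, HEAVY)
        m = dict(ann.imgt_map)
        assert m["23"] == "C" and m["41"] == "W" and m["104"] == "C"
        assert m["118"] in "FW"


class TestSegmentation:
    def test_regions_partition_all_residues(self, cfg, clones):
        interior = simulate.interior_of(clones[0].vl_nt, KAPPA, cfg)
        ann = annotate.annotate_sequence(interior, KAPPA)
        assert sum(len(v) for v in ann.regions.values()) == len(ann.imgt_map)
        assert all(ann.regions[r] for r in annotate.REGION_ORDER)
        # scaffold framework regions recovered exactly
        assert ann.regions["FR1"] == LIGHT_SCAFFOLD.fr1
        assert ann.regions["FR2"] == LIGHT_SCAFFOLD.fr2
        assert ann.regions["FR3"] == LIGHT_SCAFFOLD.fr3
        assert ann.regions["FR4"] == LIGHT_SCAFFOLD.fr4

    @pytest.mark.parametrize("label,region", [
        ("26", "FR1"), ("27", "CDR1"), ("38", "CDR1"), ("39", "FR2"),
        ("104", "FR3"), ("105", "CDR3"), ("111A", "CDR3"), ("118", "FR4"),
    ])
    def test_boundary_table(self, label, region):
        assert annotate.region_of(label) == region


class TestValidity:
    def test_intact_clone_passes(self, cfg, clones):
        interior = simulate.interior_of(clones[0].vh_nt, HEAVY, cfg)
        ann = annotate.annotate_sequence(interior, HEAVY)
        assert ann.valid and not ann.reasons

    def test_zero_length_region_fails(self, cfg, clones):
        interior = simulate.interior_of(clones[0].vl_nt, KAPPA, cfg)
        ann = annotate.annotate_sequence(interior, KAPPA)
        ann.regions["CDR2"] = ""
        ok, reasons = annotate.validate_domain(ann)
        assert not ok and any("zero-length" in r for r in reasons)

    def test_truncated_fr1_fails(self, cfg, clones):
        interior = simulate.interior_of(clones[0].vl_nt, KAPPA, cfg)
        ann = annotate.annotate_sequence(interior, KAPPA)
        ann.imgt_map = [(l, r) for l, r in ann.imgt_map
                        if not (l.isdigit() and int(l) <= 7)]
        ok, reasons = annotate.validate_domain(ann)
        assert not ok and any("FR1" in r for r in reasons)

    def test_missing_start_codon_fails(self, cfg, clones):
        interior = simulate.interior_of(clones[0].vl_nt, KAPPA, cfg)
        ann = annotate.annotate_sequence(interior, KAPPA)
        ann.has_start_codon = False
        ok, reasons = annotate.validate_domain(ann)
        assert not ok and any("start codon" in r for r in reasons)

    @pytest.mark.parametrize("region_pos", [5, 30, 60, 90, 105])
    def test_any_infrme_stop_in_v_domain_flips_valid(self, cfg, clones,
                                                     region_pos):
        interior = simulate.interior_of(clones[0].vl_nt, KAPPA, cfg)
        ann = annotate.annotate_sequence(interior, KAPPA)
        codon_start = ann.frame + 3 * (ann.v_start + region_pos)
        mutated = interior[:codon_start] + "TAA" + interior[codon_start + 3:]
        ann2 = annotate.annotate_sequence(mutated, KAPPA)
        assert not ann2.valid


class TestTrim:
    def test_light_chain_trim_length(self, cfg, clones):
        # scaffold light chain: 110 IMGT residues -> 330 nt
        interior = simulate.interior_of(clones[0].vl_nt, KAPPA, cfg)
        ann = annotate.annotate_sequence(interior, KAPPA)
        assert len(ann.trimmed_nt) == 3 * len(ann.imgt_map) == 330

    def test_trim_translation_roundtrip(self, cfg, clones):
        for clone in clones:
            for chain, nt in ((KAPPA, clone.vl_nt), (HEAVY, clone.vh_nt)):
                interior = simulate.interior_of(nt, chain, cfg)
                ann = annotate.annotate_sequence(interior, chain)
                assert translate(ann.trimmed_nt) == ann.v_aa

    def test_annotation_idempotent_on_trimmed(self, cfg, clones):
        interior = simulate.interior_of(clones[0].vh_nt, HEAVY, cfg)
        ann = annotate.annotate_sequence(interior, HEAVY)
        imgt2 = annotate.assign_imgt_numbering(translate(ann.trimmed_nt), HEAVY)
        assert imgt2 == ann.imgt_map
        assert annotate.segment_regions(imgt2) == ann.regions


class TestGroupIdentical:
    def test_utr_variants_merge_additively(self):
        entries = [
            {"trimmed_nt": "ATGGCC", "count": 70, "reads_per_primer_well": 100},
            {"trimmed_nt": "ATGGCC", "count": 30, "reads_per_primer_well": 100},
        ]
        merged = annotate.group_identical(entries)
        assert len(merged) == 1
        assert merged[0]["count"] == 100 and merged[0]["fraction"] == 1.0

    def test_distinct_sequences_not_merged(self):
        entries = [
            {"trimmed_nt": "ATGGCC", "count": 60, "reads_per_primer_well": 100},
            {"trimmed_nt": "ATGTCC", "count": 40, "reads_per_primer_well": 100},
        ]
        assert len(annotate.group_identical(entries)) == 2

    def test_single_entry_unchanged(self):
        entries = [{"trimmed_nt": "ATG", "count": 5, "reads_per_primer_well": 5}]
        merged = annotate.group_identical(entries)
        assert merged[0]["count"] == 5 and merged[0]["fraction"] == 1.0
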