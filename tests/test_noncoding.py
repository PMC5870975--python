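"""Control region location, motif scanning, conserved blocks, spacer tests."""

import random

import numpy as np
import pytest

from mitocomp import mito_io, noncoding
from mitocomp.synthetic_data import GeneratorConfig, generate_cohort, generate_mitogenome

from .oracles import motif_slide


# ---------------------------------------------------------------------------
# motif scanning


def test_cbs1_and_polyt_found_in_toy_region():
    hits = noncoding.scan_motifs("GATAGATTTTTTG")
    by_id = {h.motif_id: (h.start, h.end) for h in hits}
    assert by_id["CBS1"] == (2, 6)
    assert by_id["POLY_T"] == (7, 12)


def test_cbs3_iupac_r_semantics():
    assert noncoding.iupac_match("ACCRT", "ACCGT")
    assert noncoding.iupac_match("ACCRT", "ACCAT")
    assert not noncoding.iupac_match("ACCRT", "ACCCT")
    assert [h.motif_id for h in noncoding.scan_motifs("ACCGT")] == ["CBS3"]


def test_unknown_iupac_letter_rejected():
    with pytest.raises(ValueError, match="IUPAC"):
        noncoding.scan_motifs("ACGT", motifs=(noncoding.MotifDef("X", "AXG"),))
    with pytest.raises(ValueError):
        noncoding.scan_motifs("")


def test_repeat_hits_are_maximal():
    hits = noncoding.scan_motifs("GGATATATATGG")
    (hit,) = [h for h in hits if h.motif_id == "AT_MICROSAT"]
    assert (hit.start, hit.end) == (3, 10)
    assert hit.matched == "ATATATAT"


def test_both_strand_scan_maps_coordinates_back_to_forward_strand():
    # reverse complement of CBS1 (ATAGA) is TCTAT
    region = "GGTCTATGG"
    hits = noncoding.scan_motifs(region, strands=("J", "N"))
    (hit,) = [h for h in hits if h.motif_id == "CBS1"]
    assert hit.strand == "N"
    assert (hit.start, hit.end) == (3, 7)
    assert hit.matched == "TCTAT"


def test_iupac_scan_equals_bruteforce_slide_on_random_strings():
    rng = random.Random(17)
    patterns = ["ATAGA", "ACCRT", "ATACTAW", "ATTTA", "WWSNR"]
    for _ in range(30):
        region = "".join(rng.choice("ACGT") for _ in range(200))
        for pat in patterns:
            got = [(h.start, h.end) for h in noncoding.scan_motifs(
                region, motifs=(noncoding.MotifDef("M", pat),))]
            assert got == motif_slide(region, pat)


# ---------------------------------------------------------------------------
# control region and spacers


def test_annotated_cr_returned_verbatim(genome, truth):
    cr = noncoding.locate_control_region(genome)
    assert (cr.start, cr.end) == truth.cr_span
    assert not cr.inferred


def test_unannotated_cr_inferred_from_rrnS_trnM_gap():
    g, t = generate_mitogenome(GeneratorConfig(seed=9, annotate_cr=False))
    cr = noncoding.locate_control_region(g)
    assert cr.inferred
    assert (cr.start, cr.end) == t.cr_span


def test_no_cr_candidate_errors():
    g, _ = generate_mitogenome(
        GeneratorConfig(seed=9, annotate_cr=False, cr_length=40,
                        cr_motifs=(("CBS1", 10, "ATAGA"),)))
    with pytest.raises(ValueError, match="no CR candidate"):
        noncoding.locate_control_region(g)


def test_planted_cr_motifs_all_detected_at_planted_offsets(genome, truth):
    cr = noncoding.locate_control_region(genome)
    region = mito_io.extract_gene(genome, cr)
    hits = noncoding.scan_motifs(region)
    for motif_id, start, end, _ in truth.planted_cr_motifs:
        covering = [h for h in hits if h.motif_id == motif_id
                    and h.start <= start and h.end >= end]
        assert covering, f"planted {motif_id} at {start}-{end} not detected"


def test_dmttf_motif_in_trns_nd1_spacer(genome, truth):
    spacers = {s.name: s for s in noncoding.intergenic_spacers(genome,
                                                               min_length=5)}
    spacer = spacers["trnS^UCN-ND1"]
    assert (spacer.start, spacer.end) == truth.snd1_spacer_span
    region = mito_io.extract_gene(genome, spacer)
    hits = [h for h in noncoding.scan_motifs(region)
            if h.motif_id == "DmTTF_ATACTAW"]
    start, end, literal = truth.dmttf_in_spacer
    assert [(h.start, h.end, h.matched) for h in hits] == [(start, end, literal)]


# ---------------------------------------------------------------------------
# conserved blocks


def test_planted_identical_block_recovered_exactly():
    rng = random.Random(23)
    ntaxa, ncol = 20, 60
    cols = [[rng.choice("ACGT") for _ in range(ntaxa)] for _ in range(ncol)]
    for k in range(25, 31):  # 6 identical columns (1-based 26-31)
        cols[k] = ["A"] * ntaxa
    rows = ["".join(cols[k][t] for k in range(ncol)) for t in range(ntaxa)]
    blocks = noncoding.find_conserved_blocks(rows, window=5, min_identity=0.9)
    assert len(blocks) == 1
    assert blocks[0].columns == (26, 31)
    assert blocks[0].consensus == "AAAAAA"
    assert blocks[0].mean_identity == 1.0


def test_all_identical_alignment_yields_single_full_span_block():
    rows = ["ACGTACGTAC"] * 4
    (block,) = noncoding.find_conserved_blocks(rows, window=4,
                                               min_identity=0.95)
    assert block.columns == (1, 10)
    assert block.consensus == "ACGTACGTAC"
    assert block.support == 1.0


def test_random_alignment_produces_no_blocks_at_high_threshold():
    rng = random.Random(31)
    rows = ["".join(rng.choice("ACGT") for _ in range(120))
            for _ in range(20)]
    assert noncoding.find_conserved_blocks(rows, window=5,
                                           min_identity=0.95) == []


def test_block_caller_invariant_under_taxon_reordering():
    rng = random.Random(5)
    rows = ["".join(rng.choice("AT") for _ in range(40)) for _ in range(8)]
    a = noncoding.find_conserved_blocks(rows, window=5, min_identity=0.7)
    b = noncoding.find_conserved_blocks(rows[::-1], window=5, min_identity=0.7)
    assert [(x.columns, x.mean_identity) for x in a] == \
           [(x.columns, x.mean_identity) for x in b]


def test_block_caller_input_validation():
    with pytest.raises(ValueError, match=">= 3"):
        noncoding.find_conserved_blocks(["AC", "AC"])
    with pytest.raises(ValueError, match="window"):
        noncoding.find_conserved_blocks(["AC", "AC", "AC"], window=5)


def test_cohort_crs_share_blocks_at_planted_motifs(config):
    # same planted layout, independent random backgrounds: the conserved
    # blocks across genomes are exactly the planted elements
    cohort = generate_cohort(config)
    rows = []
    for g, t in cohort:
        cr = noncoding.locate_control_region(g)
        rows.append(mito_io.extract_gene(g, cr))
    blocks = noncoding.find_conserved_blocks(rows, window=5, min_identity=0.9)
    truth = cohort[0][1]
    for motif_id, start, end, _ in truth.planted_cr_motifs:
        if end - start + 1 >= 5:
            assert any(b.columns[0] <= start and b.columns[1] >= end
                       for b in blocks), motif_id


# ---------------------------------------------------------------------------
# spacer similarity


def test_spacer_identical_to_gene_slice_scores_full_identity():
    rng = random.Random(2)
    gene = "".join(rng.choice("ACGT") for _ in range(300))
    spacer = gene[100:130]
    res = noncoding.spacer_similarity(spacer, gene)
    assert res.identity == 1.0
    assert res.subject_span == (101, 130)


def test_decayed_nd2_fragment_located_within_2bp(genome, truth):
    spacers = {s.name: s for s in noncoding.intergenic_spacers(genome,
                                                               min_length=5)}
    spacer_seq = mito_io.extract_gene(genome, spacers["trnQ-ND2"])
    nd2 = mito_io.extract_gene(genome, genome.feature("ND2"))
    res = noncoding.spacer_similarity(spacer_seq, nd2)
    lo, hi = truth.nd2_source_slice
    assert abs(res.subject_span[0] - lo) <= 2
    assert abs(res.subject_span[1] - hi) <= 2
    # 10% divergence leaves high residual similarity
    assert res.identity > 0.8
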