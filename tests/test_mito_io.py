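"""Genome I/O, circular gene extraction and supermatrix construction."""

import random

import dendropy
import pytest

from mitocomp import mito_io
from mitocomp.model import GeneFeature, MitoGenome, reverse_complement


def _feature_tuple(g):
    return [(f.name, f.kind, f.start, f.end, f.strand, f.codon_start,
             f.structure, f.wraps_origin) for f in g.features]


# ---------------------------------------------------------------------------
# extraction


def test_extract_gene_reverse_complement():
    g = MitoGenome("toy", "AACCGGTTAACC")
    f = GeneFeature("x", "spacer", 1, 4, strand="N")
    assert mito_io.extract_gene(g, f) == reverse_complement("AACC") == "GGTT"


def test_extract_wrapping_feature_concatenates_across_origin():
    seq = "ACGTACGTACGTACGTACGT"  # length 20
    g = MitoGenome("toy", seq)
    f = GeneFeature("w", "spacer", 18, 3, wraps_origin=True)
    assert mito_io.extract_gene(g, f) == seq[17:] + seq[:3]
    assert f.length(20) == 6


def test_extract_random_minority_strand_features_match_revcomp_slice():
    rng = random.Random(5)
    seq = "".join(rng.choice("ACGT") for _ in range(200))
    g = MitoGenome("toy", seq)
    for _ in range(50):
        s = rng.randint(1, 190)
        e = rng.randint(s, 200)
        f = GeneFeature("x", "spacer", s, e, strand="N")
        assert mito_io.extract_gene(g, f) == reverse_complement(seq[s - 1:e])


def test_extract_out_of_range_feature_errors():
    g = MitoGenome("toy", "ACGT")
    with pytest.raises(ValueError):
        mito_io.extract_gene(g, GeneFeature("x", "spacer", 1, 9))


# ---------------------------------------------------------------------------
# GenBank and feature-table round trips


def test_genbank_roundtrip_preserves_sequence_and_features(genome, tmp_path):
    path = tmp_path / "syn.gb"
    mito_io.write_genbank(genome, path)
    back = mito_io.read_genbank(path)
    assert back.sequence == genome.sequence
    assert _feature_tuple(back) == _feature_tuple(genome)
    assert back.is_circular


def test_genbank_wrapping_cds_flagged_and_extractable(tmp_path):
    rng = random.Random(1)
    seq = "".join(rng.choice("ACGT") for _ in range(100))
    g = MitoGenome("toy", seq, features=[
        GeneFeature("ND2", "PCG", 80, 9, codon_start=0, wraps_origin=True)])
    path = tmp_path / "wrap.gb"
    mito_io.write_genbank(g, path)
    back = mito_io.read_genbank(path)
    f = back.feature("ND2")
    assert f.wraps_origin and (f.start, f.end) == (80, 9)
    extracted = mito_io.extract_gene(back, f)
    assert extracted == seq[79:] + seq[:9]
    assert len(extracted) == (100 - 80 + 1) + 9


def test_genbank_parser_counts_pyraloid_gene_complement(genome, tmp_path):
    # a complete record carries 13 PCGs, 22 tRNAs and 2 rRNAs
    path = tmp_path / "syn.gb"
    mito_io.write_genbank(genome, path)
    back = mito_io.read_genbank(path)
    kinds = [f.kind for f in back.features]
    assert kinds.count("PCG") == 13
    assert kinds.count("tRNA") == 22
    assert kinds.count("rRNA") == 2
    assert kinds.count("CR") == 1


def test_malformed_genbank_errors(tmp_path):
    bad = tmp_path / "bad.gb"
    bad.write_text("LOCUS broken\nthis is not genbank\n")
    with pytest.raises(ValueError, match="malformed|ORIGIN"):
        mito_io.read_genbank(bad)


def test_feature_table_roundtrip(genome, tmp_path):
    fasta, table = tmp_path / "g.fa", tmp_path / "g.tsv"
    mito_io.write_feature_table(genome, fasta, table)
    back = mito_io.read_feature_table(fasta, table)
    assert back.sequence == genome.sequence
    assert _feature_tuple(back) == _feature_tuple(genome)


def test_tsv_roundtrip(tmp_path):
    import pandas as pd
    df = pd.DataFrame({"gene": ["ND2", "COI"], "len": [1002, 1536]})
    path = tmp_path / "t.tsv"
    mito_io.write_tsv(df, path)
    assert mito_io.read_tsv(path).equals(df)


# ---------------------------------------------------------------------------
# supermatrix


@pytest.fixture(scope="module")
def matrices(cohort):
    return {code: mito_io.build_supermatrix(cohort, code)
            for code in ("PCG123", "PCG12", "PCG123R")}


def test_partitions_tile_matrix_and_pcg_blocks_are_codon_multiples(matrices):
    sm = matrices["PCG123"]
    assert len(sm.partitions) == 13 * 3
    covered = set()
    for _, ranges in sm.partitions:
        for r in ranges:
            covered |= set(r.columns())
    assert covered == set(range(1, sm.n_columns + 1))
    for gene, (s, e) in sm.gene_blocks.items():
        assert (e - s + 1) % 3 == 0, gene


def test_pcg12_width_is_two_thirds_of_pcg123(matrices):
    assert matrices["PCG12"].n_columns * 3 == matrices["PCG123"].n_columns * 2


def test_pcg123r_extends_pcg123_with_rna_blocks(matrices):
    sm, smr = matrices["PCG123"], matrices["PCG123R"]
    for a, b in zip(sm.rows, smr.rows):
        assert b[: sm.n_columns] == a
    names = [name for name, _ in smr.partitions]
    assert names[-3:] == ["rrnL", "rrnS", "tRNAs"]


def test_missing_gene_raises_named_error(cohort):
    import copy
    broken = copy.deepcopy(cohort[0])
    broken.features = [f for f in broken.features if f.name != "ND3"]
    with pytest.raises(mito_io.MissingGeneError, match="ND3"):
        mito_io.build_supermatrix([broken, cohort[1]], "PCG123")


def test_written_formats_match_matrix_dimensions(matrices, tmp_path):
    sm = matrices["PCG123R"]
    nex, phy = tmp_path / "m.nex", tmp_path / "m.phy"
    mito_io.write_nexus(sm, nex)
    mito_io.write_phylip(sm, phy)
    header = phy.read_text().splitlines()[0].split()
    assert header == [str(len(sm.taxa)), str(sm.n_columns)]
    ncharsets = sum(1 for line in nex.read_text().splitlines()
                    if line.strip().startswith("charset"))
    assert ncharsets == len(sm.partitions)
    # an independent NEXUS reader agrees on the dimensions
    mat = dendropy.DnaCharacterMatrix.get(path=str(nex), schema="nexus")
    assert len(mat) == len(sm.taxa)
    assert mat.max_sequence_size == sm.n_columns
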