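"""Codon census, RSCU, missing codons, start/stop survey."""

import pytest

from mitocomp import codon_usage, genetic_code, mito_io
from mitocomp.codon_usage import CodonCensus
from mitocomp.model import GeneFeature, MitoGenome

from .oracles import codon_tally


def _toy_genome(cds: str, name: str = "ND2") -> MitoGenome:
    return MitoGenome("toy", cds, features=[
        GeneFeature(name, "PCG", 1, len(cds), codon_start=0)])


def test_toy_gene_census_excludes_terminator():
    census = codon_usage.codon_census(_toy_genome("ATGAAATAA"))
    nonzero = {c: n for c, n in census.counts.items() if n}
    assert nonzero == {"AUG": 1, "AAA": 1}
    assert census.sense_codon_count == 2


def test_census_matches_3mer_stepping_oracle(genome):
    census = codon_usage.codon_census(genome)
    expected: dict[str, int] = {}
    for f in genome.features_of_kind("PCG"):
        sense = mito_io.extract_gene(genome, f)
        for codon, n in codon_tally(sense, f.codon_start or 0).items():
            expected[codon] = expected.get(codon, 0) + n
    observed = {c: n for c, n in census.counts.items() if n}
    assert observed == expected


def test_internal_stop_warns_and_short_gene_errors():
    with pytest.warns(UserWarning, match="internal stop"):
        codon_usage.codon_census(_toy_genome("ATGTAAAAATAA"))
    with pytest.raises(ValueError, match="shorter"):
        codon_usage.codon_census(_toy_genome("ATGAA"))


def test_excluded_codons_recovered_as_missing_exactly(genome, truth):
    census = codon_usage.codon_census(genome)
    assert set(codon_usage.missing_codons(census)) == set(truth.excluded_codons)


def test_missing_codons_ordered_by_degeneracy_then_alphabet():
    counts = {c: 1 for c in genetic_code.SENSE_CODONS}
    for c in ("ACG", "AGG", "UCG", "AUG"):  # Thr(4), Ser(8), Ser(8), Met(2)
        counts[c] = 0
    for c in genetic_code.STOP_CODONS:
        counts[c] = 0
    census = CodonCensus("x", counts)
    assert codon_usage.missing_codons(census) == ["AGG", "UCG", "ACG", "AUG"]


def test_missing_codons_empty_when_all_sense_codons_used():
    counts = {c: 1 for c in codon_usage.ALL_CODONS}
    assert codon_usage.missing_codons(CodonCensus("x", counts)) == []


def test_format_missing_matches_published_table_style():
    counts = {c: 1 for c in codon_usage.ALL_CODONS}
    counts["AGG"] = 0
    got = codon_usage.format_missing(
        codon_usage.missing_codons(CodonCensus("x", counts)))
    assert got == ["AGG(S)"]  # AGA/AGG are serine under the invertebrate code


def test_rscu_two_member_family_example():
    counts = {c: 0 for c in codon_usage.ALL_CODONS}
    counts["UUU"], counts["UUC"] = 3, 1
    vals = codon_usage.rscu(CodonCensus("x", counts))
    assert vals["UUU"] == pytest.approx(1.5)
    assert vals["UUC"] == pytest.approx(0.5)


def test_rscu_uniform_usage_gives_all_ones_and_zero_families_flagged():
    counts = {c: 2 for c in genetic_code.SENSE_CODONS}
    for c in genetic_code.STOP_CODONS:
        counts[c] = 0
    for c in genetic_code.FAMILIES["K"]:
        counts[c] = 0
    census = CodonCensus("x", counts)
    vals = codon_usage.rscu(census)
    assert all(vals[c] == pytest.approx(1.0)
               for c in genetic_code.SENSE_CODONS
               if genetic_code.amino_acid(c) != "K")
    assert all(vals[c] == 0.0 for c in genetic_code.FAMILIES["K"])
    assert codon_usage.undefined_families(census) == {"K"}


def test_rscu_family_sums_equal_family_sizes(genome):
    census = codon_usage.codon_census(genome)
    vals = codon_usage.rscu(census)
    for aa, family in genetic_code.FAMILIES.items():
        total = sum(census.counts[c] for c in family)
        if total:
            assert sum(vals[c] for c in family) == pytest.approx(len(family))


def test_top_codons_tiebreak_and_at_richness(genome):
    counts = {c: 0 for c in codon_usage.ALL_CODONS}
    counts["AAA"] = counts["UUU"] = 5
    counts["CCC"] = 1
    assert codon_usage.top_codons(CodonCensus("x", counts), 2) == ["AAA", "UUU"]
    assert len(codon_usage.top_codons(CodonCensus("x", counts), 99)) == 3
    # in an AT-rich genome every top codon is G+C poor
    census = codon_usage.codon_census(genome)
    for codon in codon_usage.top_codons(census, 6):
        assert sum(codon.count(b) for b in "GC") <= 1


def test_census_times_three_bounded_by_framed_length(genome):
    census = codon_usage.codon_census(genome)
    framed = sum(len(mito_io.framed_cds(genome, f))
                 for f in genome.features_of_kind("PCG"))
    assert census.sense_codon_count * 3 <= framed


def test_start_stop_survey_recovers_generator_ground_truth(genome, truth):
    survey = codon_usage.start_stop_survey(genome)
    assert survey.starts == truth.start_codons
    assert survey.stops == truth.terminators
    assert survey.stops["COI"] == "T"        # incomplete, polyadenylated
    assert survey.starts["COI"] == "CGA"     # the unusual COI start
    assert not survey.non_canonical


def test_incomplete_stop_classified_from_trailing_bases():
    survey = codon_usage.start_stop_survey(_toy_genome("ATGAAAT"))
    assert survey.stops["ND2"] == "T"
    survey = codon_usage.start_stop_survey(_toy_genome("ATGAAATA"))
    assert survey.stops["ND2"] == "TA"
    survey = codon_usage.start_stop_survey(_toy_genome("ATGAAATAG"))
    assert survey.stops["ND2"] == "UAG"
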