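"""Cloverleaf parsing, mismatch detection and conservation profiling."""

import random

import pytest

from mitocomp import trna_profile as tp
from mitocomp.synthetic_data import GeneratorConfig, build_trna
import numpy as np

# a minimal hand-built cloverleaf: 2-bp acceptor, 2-bp arms, 3-nt loops,
# all stems Watson-Crick paired, anticodon UCA
TOY_SEQ = "GGAAGCAAAGCAAGCUCAGCAAGCAAAGCAACC"
TOY_DB = "((..((...))..((...))..((...))..))"


def test_toy_cloverleaf_regions_and_anticodon():
    st = tp.parse_structure(TOY_SEQ, TOY_DB)
    assert {k: len(v) for k, v in st.stem_pairs.items()} == {
        "acceptor_stem": 2, "DHU_stem": 2, "anticodon_stem": 2,
        "TpsiC_stem": 2}
    assert st.anticodon == "UCA"
    assert tp.detect_mismatches(st) == []
    assert len(st.regions["anticodon_loop"]) == 3
    assert st.anticodon == "".join(
        st.sequence[p] for p in st.regions["anticodon_loop"])
    # every paired position sits in exactly one stem region
    paired = [i for i, ch in enumerate(TOY_DB) if ch in "()"]
    stem_positions = sum((st.regions[s] for s in
                          ("acceptor_stem", "DHU_stem", "anticodon_stem",
                           "TpsiC_stem")), [])
    assert sorted(stem_positions) == paired


def test_generated_trna_parses_with_planted_anticodon():
    rng = np.random.default_rng(0)
    seq, db = build_trna(rng, "CAU")
    st = tp.parse_structure(seq, db)
    assert st.anticodon == "CAU"
    assert len(st.stem_pairs["DHU_stem"]) == 4
    assert tp.detect_mismatches(st) == []  # ancestors are Watson-Crick


def test_trns_agn_architecture_parses_as_three_stems():
    rng = np.random.default_rng(0)
    seq, db = build_trna(rng, "GCU", with_dhu=False)
    st = tp.parse_structure(seq, db)
    assert st.stem_pairs["DHU_stem"] == []
    assert len(st.regions["DHU_loop"]) > 0
    assert st.anticodon == "GCU"


def test_unbalanced_or_non_cloverleaf_structures_rejected():
    with pytest.raises(ValueError, match="unbalanced"):
        tp.parse_structure("ACGU", "((..")
    with pytest.raises(ValueError, match="non-cloverleaf"):
        tp.parse_structure("ACGUACGU", "((....))")  # a single hairpin


def test_mismatch_detection_examples_and_bruteforce_oracle():
    # break the outermost acceptor pair G-C into G-A
    seq = TOY_SEQ[:32] + "A"
    st = tp.parse_structure(seq, TOY_DB)
    hits = tp.detect_mismatches(st)
    assert [(m.pos5, m.pos3, m.pair, m.stem) for m in hits] == [
        (0, 32, "GA", "acceptor_stem")]
    # random sequences over the canonical template vs an exhaustive check
    rng = np.random.default_rng(3)
    valid = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
             ("G", "U"), ("U", "G")}
    for _ in range(20):
        seq, db = build_trna(rng, "CAU")
        noisy = list(seq.replace("T", "U"))
        for k in rng.integers(0, len(noisy), size=6):
            noisy[k] = "ACGU"[rng.integers(4)]
        noisy = "".join(noisy)
        st = tp.parse_structure(noisy, db)
        expected = set()
        stack = []
        for i, ch in enumerate(db):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                j = stack.pop()
                if (noisy[j], noisy[i]) not in valid:
                    expected.add((j, i))
        assert {(m.pos5, m.pos3) for m in tp.detect_mismatches(st)} == expected


# ---------------------------------------------------------------------------
# conservation


def test_identical_sequences_fully_conserved():
    prof = tp.conservation_profile([("a", "ACGU" * 10), ("b", "ACGU" * 10),
                                    ("c", "ACGU" * 10)])
    assert prof.per_site_identity == [1.0] * 40
    assert prof.mean_identity == 1.0


def test_single_difference_identity_under_both_statistics():
    a = "A" * 70
    b = "A" * 69 + "G"
    pair = [("x", a), ("y", b)]
    # mean pairwise identity reproduces the 69/70 arithmetic
    prof_pw = tp.conservation_profile(pair, prealigned=True, method="pairwise")
    assert prof_pw.mean_identity == pytest.approx(69 / 70)
    # the modal-residue statistic scores the split column 1/2
    prof_modal = tp.conservation_profile(pair, prealigned=True)
    assert prof_modal.mean_identity == pytest.approx(69.5 / 70)


def test_conservation_permutation_invariant_and_monotone():
    rng = random.Random(9)
    seqs = [("t%d" % i, "".join(rng.choice("ACGU") for _ in range(40)))
            for i in range(6)]
    base = tp.conservation_profile(seqs, prealigned=True)
    shuffled = seqs[::-1]
    assert tp.conservation_profile(shuffled, prealigned=True
                                   ).per_site_identity == base.per_site_identity
    # adding a sequence equal to the column-wise consensus never decreases
    # any column identity (duplicating a minority sequence may)
    from collections import Counter
    consensus = "".join(
        Counter(s[k] for _, s in seqs).most_common(1)[0][0]
        for k in range(40))
    ext = tp.conservation_profile(seqs + [("cons", consensus)],
                                  prealigned=True)
    assert all(e >= b - 1e-12 for e, b in
               zip(ext.per_site_identity, base.per_site_identity))


def test_region_means_recompute_from_per_site_values(ortholog_sets):
    oset = ortholog_sets["trnD"]
    ref = tp.parse_structure(oset.ancestor, oset.dotbracket)
    prof = tp.conservation_profile(
        [("anc", oset.ancestor)] + oset.sequences,
        prealigned=True, reference_structure=ref)
    for label, positions in ref.regions.items():
        if positions:
            mean = sum(prof.per_site_identity[p] for p in positions) / len(positions)
            assert prof.per_region_identity[label] == pytest.approx(mean)


def test_conservation_requires_two_sequences():
    with pytest.raises(ValueError):
        tp.conservation_profile([("a", "ACGU")])


def test_strand_comparison_toy_means():
    def prof(val, strand):
        return tp.ConservationProfile("g", 2, [val], {}, strand)
    cmp_ = tp.strand_conservation_compare(
        [prof(0.9, "J"), prof(0.8, "J"), prof(0.7, "N")])
    by = cmp_.by_strand.set_index("strand")
    assert by.loc["J", "mean_identity"] == pytest.approx(0.85)
    assert by.loc["N", "mean_identity"] == pytest.approx(0.70)
    assert cmp_.difference == pytest.approx(0.15)
    equal = tp.strand_conservation_compare([prof(0.8, "J"), prof(0.8, "N")])
    assert equal.difference == pytest.approx(0.0)


def test_mutation_free_orthologs_and_strand_rate_ordering(ortholog_sets):
    from mitocomp.synthetic_data import generate_ortholog_trnas
    quiet = generate_ortholog_trnas(
        GeneratorConfig(seed=3, trna_mutation_rate_j=0.0,
                        trna_mutation_rate_n=0.0))
    prof = tp.conservation_profile(quiet["trnA"].sequences, prealigned=True)
    assert prof.mean_identity == 1.0
    # default rates: J-strand tRNAs evolve slower, so they stay more conserved
    profs = [tp.conservation_profile(o.sequences, gene=n, strand=o.strand,
                                     prealigned=True)
             for n, o in ortholog_sets.items()]
    cmp_ = tp.strand_conservation_compare(profs)
    assert cmp_.difference > 0
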