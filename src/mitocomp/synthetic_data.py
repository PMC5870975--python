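"""Synthetic annotated mitogenomes with known ground truth.

The generator emulates a lepidopteran-style circular mitogenome: 37 genes
(13 PCGs, 22 tRNAs, 2 rRNAs) in the Ditrysia order plus an A+T-rich
control region, with configurable composition targets, an excluded-codon
set, a CGA start for COI, incomplete stop codons realised by abutting the
downstream feature, planted control-region motifs, an ATACTAW element in
the trnS-ND1 spacer, and a trnQ-ND2 spacer built as a decayed ND2
fragment.

Default parameters mirror the comparative study conditions for this
group: whole-family A+T around 0.80, mildly negative AT-skew, strongly
negative GC-skew, ~11.1 kb of protein-coding sequence (3,710 codons),
a ~340 bp control region, and a three-codon exclusion set typical of the
published missing-codon censuses.

Protein-coding sequence is drawn codon-by-codon from a multinomial over
the allowed sense codons whose base weights are calibrated (root solve)
so that the *restricted* codon distribution hits the A+T-content and
skew targets exactly in expectation.  Every allowed sense codon is then
seeded at least once, so the missing-codon set of the output equals the
exclusion set exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import optimize

from . import references
from .genetic_code import SENSE_CODONS, dna_to_rna, rna_to_dna
from .model import GeneFeature, MitoGenome, reverse_complement

# per-gene codon counts (start codon included, terminator excluded);
# realistic lepidopteran sizes totalling 3,710 codons (~11.1 kb + stops)
DEFAULT_PCG_CODONS: dict[str, int] = {
    "ND2": 334, "COI": 512, "COII": 227, "ATP8": 54, "ATP6": 225,
    "COIII": 262, "ND3": 117, "ND5": 575, "ND4": 447, "ND4L": 93,
    "ND6": 174, "CYTB": 378, "ND1": 312,
}

DEFAULT_START_CODONS: dict[str, str] = {
    name: "ATG" for name in DEFAULT_PCG_CODONS}
DEFAULT_START_CODONS["COI"] = "CGA"
DEFAULT_START_CODONS["ND2"] = "ATT"
DEFAULT_START_CODONS["ND5"] = "ATT"

#: terminator per gene, DNA: complete TAA/TAG or incomplete T/TA (the
#: downstream feature then abuts immediately, as in real annotations)
DEFAULT_TERMINATORS: dict[str, str] = {
    name: "TAA" for name in DEFAULT_PCG_CODONS}
DEFAULT_TERMINATORS.update({"COI": "T", "COII": "T", "ND5": "TA",
                            "ND4": "T", "ND1": "TAG"})

#: (motif_id, 1-based offset in the CR or None for "near the 3' end",
#:  literal planted string) — CBS1 + poly-T, CBS2 upstream of (AT)n,
#: CBS3 at the 3' end, matching the canonical CR layout of this group
DEFAULT_CR_MOTIFS: tuple[tuple[str, int | None, str], ...] = (
    ("CBS1", 10, "ATAGA"),
    ("POLY_T", 15, "TTTTTTTTT"),
    ("CBS2", 120, "ATTTA"),
    ("AT_MICROSAT", 130, "ATATATATATAT"),
    ("CBS3", None, "ACCAT"),
)


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_genomes: int = 5
    at_content: float = 0.80
    at_skew: float = -0.02
    gc_skew: float = -0.20
    pcg_codon_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PCG_CODONS))
    excluded_codons: frozenset[str] = frozenset({"AGG", "CGC", "CUG"})
    start_codons: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_START_CODONS))
    terminators: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TERMINATORS))
    rrnl_length: int = 1361
    rrns_length: int = 780
    cr_length: int = 340
    cr_motifs: tuple[tuple[str, int | None, str], ...] = DEFAULT_CR_MOTIFS
    annotate_cr: bool = True
    gene_order: str = "ditrysia"
    snd1_spacer_length: int = 20
    dmttf_offset: int = 6
    qnd2_spacer_length: int = 60
    qnd2_divergence: float = 0.10
    n_taxa: int = 10                      # ortholog-set generation
    trna_mutation_rate_j: float = 0.05
    trna_mutation_rate_n: float = 0.15
    seed_all_codons: bool = True

    def __post_init__(self) -> None:
        for p in (self.at_content, self.qnd2_divergence,
                  self.trna_mutation_rate_j, self.trna_mutation_rate_n):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for s in (self.at_skew, self.gc_skew):
            if not -1.0 <= s <= 1.0:
                raise ValueError(f"skew {s} outside [-1, 1]")
        for name, n in self.pcg_codon_lengths.items():
            if n < 2:
                raise ValueError(f"{name}: codon count must be >= 2")
        excluded = {c.upper() for c in self.excluded_codons}
        object.__setattr__(self, "excluded_codons", frozenset(excluded))
        starts = {dna_to_rna(c) for c in self.start_codons.values()}
        clash = excluded & starts
        if clash:
            raise ValueError(f"excluded codons clash with required start "
                             f"codons: {sorted(clash)}")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=int(seed) % (2 ** 31))


@dataclass
class GroundTruth:
    """Everything planted into one synthetic genome, sufficient to score
    every downstream pipeline stage."""

    identifier: str
    at_content: float
    at_skew: float
    gc_skew: float
    gene_order: str
    gene_spans: dict[str, tuple[int, int, str]]
    start_codons: dict[str, str]
    terminators: dict[str, str]
    excluded_codons: tuple[str, ...]
    cr_span: tuple[int, int]
    planted_cr_motifs: list[tuple[str, int, int, str]]  # id, start, end, literal (CR coords)
    snd1_spacer_span: tuple[int, int]
    dmttf_in_spacer: tuple[int, int, str]
    qnd2_spacer_span: tuple[int, int]
    nd2_source_slice: tuple[int, int]   # 1-based in ND2 sense sequence
    n_spacer_mutations: int
    trna_structures: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["excluded_codons"] = sorted(d["excluded_codons"])
        Path(path).write_text(json.dumps(d, indent=1))


# ---------------------------------------------------------------------------
# codon distribution calibration


def target_base_freqs(at_content: float, at_skew: float, gc_skew: float
                      ) -> np.ndarray:
    """Target (A, C, G, T) frequencies implied by content and skews."""
    at, gc = at_content, 1.0 - at_content
    return np.array([
        at * (1 + at_skew) / 2,
        gc * (1 - gc_skew) / 2,
        gc * (1 + gc_skew) / 2,
        at * (1 - at_skew) / 2,
    ])


def _codon_base_matrix(codons: list[str]) -> np.ndarray:
    """codons x 4 matrix of base counts (A, C, G, T order; RNA input)."""
    order = "ACGU"
    return np.array([[c.count(b) for b in order] for c in codons], float)


def codon_distribution(at_content: float, at_skew: float, gc_skew: float,
                       excluded_codons: frozenset[str] = frozenset()
                       ) -> tuple[list[str], np.ndarray]:
    """Allowed sense codons and sampling probabilities hitting the base
    composition targets in expectation.

    Codon weights are products of per-base weights; because stop codons
    and the exclusion set are removed before renormalisation, the base
    weights are calibrated numerically so the restricted distribution's
    expected base frequencies equal the targets.  Raises ``ValueError``
    for infeasible targets.
    """
    codons = [c for c in SENSE_CODONS if c not in excluded_codons]
    if not codons:
        raise ValueError("exclusion set removes every sense codon")
    target = target_base_freqs(at_content, at_skew, gc_skew)
    M = _codon_base_matrix(codons)          # (n_codons, 4)
    reachable = M.sum(axis=0) > 0
    if np.any((target > 1e-12) & ~reachable):
        raise ValueError("infeasible composition targets: a required base "
                         "occurs in no allowed codon")

    def expected_freqs(logw: np.ndarray) -> np.ndarray:
        w = np.exp(logw - logw.max())
        probs = np.exp(M @ np.log(np.maximum(w, 1e-300)))
        probs /= probs.sum()
        return (probs @ M) / 3.0

    def residual(x: np.ndarray) -> np.ndarray:
        logw = np.concatenate([x, [0.0]])
        return (expected_freqs(logw) - target)[:3]

    x0 = np.log(np.maximum(target[:3], 1e-6) / max(target[3], 1e-6))
    sol = optimize.root(residual, x0, method="hybr", tol=1e-12)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-8:
        raise ValueError("infeasible composition targets: calibration did "
                         "not converge")
    logw = np.concatenate([sol.x, [0.0]])
    w = np.exp(logw - logw.max())
    probs = np.exp(M @ np.log(np.maximum(w, 1e-300)))
    probs /= probs.sum()
    return codons, probs


# ---------------------------------------------------------------------------
# building blocks


def _random_bases(rng: np.random.Generator, n: int, freqs: np.ndarray) -> str:
    return "".join(rng.choice(list("ACGT"), size=n, p=freqs / freqs.sum()))


class _TrnaTemplate:
    """Canonical cloverleaf geometry used for all synthetic tRNAs."""

    ACCEPTOR = 7
    DHU = 4
    DHU_LOOP = 8
    AC_STEM = 5
    AC_LOOP = 7
    VAR = 4
    T_STEM = 5
    T_LOOP = 7


def build_trna(rng: np.random.Generator, anticodon_rna: str,
               with_dhu: bool = True, at_content: float = 0.8
               ) -> tuple[str, str]:
    """One synthetic cloverleaf tRNA: (DNA sense sequence, dot-bracket).

    Stems are Watson-Crick paired; loops are AT-biased random sequence;
    the anticodon occupies the centre of the anticodon loop.  With
    ``with_dhu=False`` the DHU arm is replaced by a 10-nt unpaired loop
    (the trnS^AGN architecture)."""
    t = _TrnaTemplate
    pair = {"A": "T", "T": "A", "G": "C", "C": "G"}
    base_p = np.array([at_content / 2, (1 - at_content) / 2,
                       (1 - at_content) / 2, at_content / 2])

    def stem(n: int) -> tuple[str, str]:
        five = _random_bases(rng, n, base_p)
        three = "".join(pair[b] for b in reversed(five))
        return five, three

    def loop(n: int) -> str:
        return _random_bases(rng, n, base_p)

    acc5, acc3 = stem(t.ACCEPTOR)
    ac5, ac3 = stem(t.AC_STEM)
    anticodon = rna_to_dna(anticodon_rna)
    ac_flank = (t.AC_LOOP - 3) // 2
    ac_loop = loop(ac_flank) + anticodon + loop(t.AC_LOOP - 3 - ac_flank)
    t5, t3 = stem(t.T_STEM)
    if with_dhu:
        d5, d3 = stem(t.DHU)
        dhu_seq = d5 + loop(t.DHU_LOOP) + d3
        dhu_db = "(" * t.DHU + "." * t.DHU_LOOP + ")" * t.DHU
    else:
        dhu_seq = loop(10)
        dhu_db = "." * 10
    seq = (acc5 + loop(2) + dhu_seq + loop(1)
           + ac5 + ac_loop + ac3 + loop(t.VAR)
           + t5 + loop(t.T_LOOP) + t3 + acc3 + loop(1))
    db = ("(" * t.ACCEPTOR + ".." + dhu_db + "."
          + "(" * t.AC_STEM + "." * t.AC_LOOP + ")" * t.AC_STEM
          + "." * t.VAR
          + "(" * t.T_STEM + "." * t.T_LOOP + ")" * t.T_STEM
          + ")" * t.ACCEPTOR + ".")
    assert len(seq) == len(db)
    return seq, db


def mutate(rng: np.random.Generator, seq: str, rate: float,
           alphabet: str = "ACGT") -> tuple[str, int]:
    """i.i.d. per-site substitution at the given rate; returns the mutated
    sequence and the realised substitution count."""
    out = list(seq)
    n_mut = 0
    hits = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hits):
        choices = [b for b in alphabet if b != seq[i]]
        out[i] = choices[rng.integers(len(choices))]
        n_mut += 1
    return "".join(out), n_mut


# ---------------------------------------------------------------------------
# genome generation


def _sample_pcgs(rng: np.random.Generator, config: GeneratorConfig
                 ) -> dict[str, list[str]]:
    """Sampled DNA codons per gene (start codon excluded here), with the
    whole-genome seeding pass guaranteeing every allowed codon occurs."""
    codons, probs = codon_distribution(config.at_content, config.at_skew,
                                       config.gc_skew, config.excluded_codons)
    genes: dict[str, list[str]] = {}
    slots: dict[str, list[tuple[str, int]]] = {c: [] for c in codons}
    for name in references.PCG_NAMES:
        n = config.pcg_codon_lengths[name] - 1  # start codon placed verbatim
        draw = rng.choice(len(codons), size=n, p=probs)
        gene_codons = [rna_to_dna(codons[k]) for k in draw]
        genes[name] = gene_codons
        for pos, k in enumerate(draw):
            slots[codons[k]].append((name, pos))
    if config.seed_all_codons:
        counts = {c: len(slots[c]) for c in codons}
        for codon in sorted(c for c in codons if counts[c] == 0):
            donor = max(codons, key=lambda c: (counts[c], c))
            if counts[donor] < 2:
                raise ValueError("PCG set too short to seed every allowed codon")
            pick = int(rng.integers(len(slots[donor])))
            gene, pos = slots[donor].pop(pick)
            genes[gene][pos] = rna_to_dna(codon)
            counts[donor] -= 1
            counts[codon] += 1
    return genes


def _build_cr(rng: np.random.Generator, config: GeneratorConfig,
              freqs: np.ndarray) -> tuple[str, list[tuple[str, int, int, str]]]:
    cr = list(_random_bases(rng, config.cr_length, freqs))
    planted = []
    for motif_id, offset, literal in config.cr_motifs:
        if offset is None:
            offset = config.cr_length - len(literal) - 14
        if offset < 1 or offset + len(literal) - 1 > config.cr_length:
            raise ValueError(f"planted motif {motif_id} outside the CR")
        cr[offset - 1: offset - 1 + len(literal)] = list(literal)
        planted.append((motif_id, offset, offset + len(literal) - 1, literal))
    return "".join(cr), planted


def generate_mitogenome(config: GeneratorConfig,
                        identifier: str | None = None
                        ) -> tuple[MitoGenome, GroundTruth]:
    """One annotated synthetic mitogenome plus its ground truth.

    Deterministic: the same config (including seed) yields a byte-identical
    genome.
    """
    rng = np.random.default_rng(config.seed)
    identifier = identifier or f"SYN{config.seed:06d}"
    freqs = target_base_freqs(config.at_content, config.at_skew,
                              config.gc_skew)
    pcg_codons = _sample_pcgs(rng, config)

    # sense-strand sequence (and structure) per gene
    sense: dict[str, str] = {}
    structures: dict[str, str] = {}
    for name in references.PCG_NAMES:
        sense[name] = (config.start_codons[name]
                       + "".join(pcg_codons[name])
                       + config.terminators[name])
    for name in references.TRNA_NAMES:
        seq, db = build_trna(rng, references.anticodon_map()[name],
                             with_dhu=(name != "trnS^AGN"),
                             at_content=config.at_content)
        sense[name] = seq
        structures[name] = db
    sense["rrnL"] = _random_bases(rng, config.rrnl_length, freqs)
    sense["rrnS"] = _random_bases(rng, config.rrns_length, freqs)
    cr_seq, planted = _build_cr(rng, config, freqs)

    # intergenic spacers
    snd1 = list(_random_bases(rng, config.snd1_spacer_length, freqs))
    dmttf = "ATACTA" + ("A" if rng.random() < 0.5 else "T")
    off = config.dmttf_offset
    snd1[off - 1: off - 1 + len(dmttf)] = list(dmttf)
    snd1_seq = "".join(snd1)

    nd2_sense = sense["ND2"]
    slice_start = 31  # 1-based, inside ND2
    slice_end = slice_start + config.qnd2_spacer_length - 1
    fragment = nd2_sense[slice_start - 1: slice_end]
    qnd2_seq, n_mut = mutate(rng, fragment, config.qnd2_divergence)

    # assemble the circle in the requested reference order
    order = references.reference_order(config.gene_order)
    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    gene_spans: dict[str, tuple[int, int, str]] = {}
    cr_span = (0, 0)
    snd1_span = (0, 0)
    qnd2_span = (0, 0)
    for name, strand in order:
        if name == "ND2" and "trnQ" in gene_spans:
            # trnQ-ND2 spacer (decayed ND2 fragment), J strand
            parts.append(qnd2_seq)
            qnd2_span = (pos + 1, pos + len(qnd2_seq))
            pos += len(qnd2_seq)
        if name == "CR":
            parts.append(cr_seq)
            cr_span = (pos + 1, pos + len(cr_seq))
            if config.annotate_cr:
                features.append(GeneFeature("CR", "CR", cr_span[0],
                                            cr_span[1], "J"))
            pos += len(cr_seq)
            continue
        block = sense[name] if strand == "J" else reverse_complement(sense[name])
        parts.append(block)
        start, end = pos + 1, pos + len(block)
        kind = references.kind_map()[name]
        features.append(GeneFeature(
            name=name, kind=kind, start=start, end=end, strand=strand,
            codon_start=0 if kind == "PCG" else None,
            structure=structures.get(name)))
        gene_spans[name] = (start, end, strand)
        pos = end
        if name == "trnS^UCN":
            parts.append(snd1_seq)
            snd1_span = (pos + 1, pos + len(snd1_seq))
            pos += len(snd1_seq)

    genome = MitoGenome(identifier=identifier, sequence="".join(parts),
                        features=features, is_circular=True,
                        taxon_labels={"organism": f"Synthetica {identifier}"})
    truth = GroundTruth(
        identifier=identifier,
        at_content=config.at_content, at_skew=config.at_skew,
        gc_skew=config.gc_skew, gene_order=config.gene_order,
        gene_spans=gene_spans,
        start_codons=dict(config.start_codons),
        terminators={g: dna_to_rna(t) if len(t) == 3 else t
                     for g, t in config.terminators.items()},
        excluded_codons=tuple(sorted(config.excluded_codons)),
        cr_span=cr_span,
        planted_cr_motifs=planted,
        snd1_spacer_span=snd1_span,
        dmttf_in_spacer=(off, off + len(dmttf) - 1, dmttf),
        qnd2_spacer_span=qnd2_span,
        nd2_source_slice=(slice_start, slice_end),
        n_spacer_mutations=n_mut,
        trna_structures=structures,
    )
    return genome, truth


def generate_cohort(config: GeneratorConfig
                    ) -> list[tuple[MitoGenome, GroundTruth]]:
    """``n_genomes`` independent genomes with per-genome derived seeds."""
    out = []
    for i in range(config.n_genomes):
        cfg = config.with_seed(config.seed * 1000 + i)
        out.append(generate_mitogenome(cfg, identifier=f"SYN{config.seed:04d}_{i:02d}"))
    return out


# ---------------------------------------------------------------------------
# ortholog tRNA sets


@dataclass
class OrthologSet:
    gene: str
    strand: str
    dotbracket: str
    ancestor: str                       # RNA
    sequences: list[tuple[str, str]]    # (taxon id, RNA sequence)
    mutation_rate: float


def generate_ortholog_trnas(config: GeneratorConfig) -> dict[str, OrthologSet]:
    """Per-tRNA ortholog sets: one ancestor cloverleaf per gene, descendants
    mutated i.i.d. at the strand-specific rate.

    Substitution-only evolution, so descendants stay alignment-free
    (equal length); trnS^AGN is built without a DHU stem.
    """
    rng = np.random.default_rng(config.seed + 7)
    strand_of = dict(references.genes_37(config.gene_order))
    out: dict[str, OrthologSet] = {}
    for name in references.TRNA_NAMES:
        strand = strand_of[name]
        rate = (config.trna_mutation_rate_j if strand == "J"
                else config.trna_mutation_rate_n)
        seq, db = build_trna(rng, references.anticodon_map()[name],
                             with_dhu=(name != "trnS^AGN"),
                             at_content=config.at_content)
        ancestor = dna_to_rna(seq)
        descendants = []
        for t in range(config.n_taxa):
            mutated, _ = mutate(rng, ancestor, rate, alphabet="ACGU")
            descendants.append((f"taxon{t + 1:02d}", mutated))
        out[name] = OrthologSet(name, strand, db, ancestor, descendants, rate)
    return out
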