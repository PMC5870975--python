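"""Read/write annotated mitogenomes and export phylogenetic supermatrices.

GenBank flat files are parsed with Biopython; raw annotation labels are
mapped to canonical gene symbols through a versioned alias table
(``data/gene_names.tsv``).  Serine/leucine tRNA isotypes are disambiguated
by the ``anticodon`` qualifier when the label alone is ambiguous.

All coordinates exposed here are 1-based inclusive on the majority (J)
strand, GenBank style.  Features spanning the circular origin keep
``start > end`` and are flagged ``wraps_origin``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from . import genetic_code, references
from .alignment_msa import DEFAULT_SCORES, Alignment, center_star_msa
from .model import GeneFeature, MitoGenome, reverse_complement

DATASET_CODES = ("PCG123", "PCG123R", "PCG12", "PCG12R")


class MissingGeneError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GenBank reading


def _resolve_trna_isotype(candidate: str | None, qualifiers: dict) -> str | None:
    """Disambiguate trnS/trnL isotypes from the anticodon qualifier."""
    anticodon = None
    for q in qualifiers.get("anticodon", []) + qualifiers.get("note", []):
        m = re.search(r"\(?\b(?:anticodon[:=\s]*)?([acgut]{3})\)?\s*$", q.lower())
        if m:
            anticodon = m.group(1).upper().replace("T", "U")
            break
        m = re.search(r"seq:([acgut]{3})", q.lower())
        if m:
            anticodon = m.group(1).upper().replace("T", "U")
            break
    if anticodon and anticodon in references.anticodon_to_trna():
        resolved = references.anticodon_to_trna()[anticodon]
        if candidate is None or candidate.split("^")[0] == resolved.split("^")[0]:
            return resolved
    return candidate


def _feature_name(feat: SeqFeature) -> str | None:
    for key in ("gene", "product", "note", "standard_name"):
        for raw in feat.qualifiers.get(key, []):
            canon = references.canonical_name(raw)
            if canon is not None:
                return canon
    return None


def _raw_label(feat: SeqFeature) -> str:
    for key in ("gene", "product", "note", "standard_name"):
        if feat.qualifiers.get(key):
            return feat.qualifiers[key][0]
    return feat.type


def _location_fields(feat: SeqFeature, genome_length: int):
    loc = feat.location
    strand = "N" if loc.strand == -1 else "J"
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if len(parts) == 2 and int(parts[-1].end) == genome_length and int(parts[0].start) == 0:
            # join(x..L,1..y): feature wraps the circular origin
            return int(parts[1].start) + 1, int(parts[0].end), strand, True
        return int(parts[0].start) + 1, int(parts[-1].end), strand, False
    return int(loc.start) + 1, int(loc.end), strand, False


_KIND_BY_TYPE = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_genbank(path: str | Path) -> MitoGenome:
    """Parse one GenBank flat-file record into a :class:`MitoGenome`.

    CDS/tRNA/rRNA features and the control region (``misc_feature`` or
    ``D-loop`` annotated "A+T-rich" / "control region") are mapped to
    canonical names; anything else with a location is kept as a
    spacer-kind feature under its raw label.  Unmapped gene labels warn
    rather than fail.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"malformed GenBank record {path}: {exc}") from exc
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"} and len(seq) < 2:
        raise ValueError(f"{path}: record has no ORIGIN sequence")
    topology = record.annotations.get("topology", "circular")
    features: list[GeneFeature] = []
    seen_gene_kinds = ("CDS", "tRNA", "rRNA")
    for feat in record.features:
        if feat.type == "source":
            continue
        start, end, strand, wraps = _location_fields(feat, len(seq))
        if feat.type in seen_gene_kinds:
            kind = _KIND_BY_TYPE[feat.type]
            name = _feature_name(feat)
            if kind == "tRNA":
                name = _resolve_trna_isotype(name, feat.qualifiers)
            if name is None:
                raw = _raw_label(feat)
                warnings.warn(
                    f"{record.id}: unmapped {feat.type} label {raw!r}; keeping raw name",
                    stacklevel=2,
                )
                name = raw
            codon_start = None
            if kind == "PCG":
                codon_start = int(feat.qualifiers.get("codon_start", ["1"])[0]) - 1
            structure = feat.qualifiers.get("secondary_structure", [None])[0]
            if structure:
                # GenBank wraps long qualifiers; dot-brackets have no spaces
                structure = structure.replace(" ", "")
            features.append(
                GeneFeature(name=name, kind=kind, start=start, end=end,
                            strand=strand, codon_start=codon_start,
                            structure=structure, wraps_origin=wraps)
            )
        elif feat.type in ("misc_feature", "D-loop"):
            label = _raw_label(feat)
            canon = references.canonical_name(label)
            if feat.type == "D-loop" or canon == "CR" or re.search(
                    r"A\+?T[- ]rich|control region", label, flags=re.I):
                features.append(GeneFeature(name="CR", kind="CR", start=start,
                                            end=end, strand=strand,
                                            wraps_origin=wraps))
            else:
                features.append(GeneFeature(name=label, kind="spacer",
                                            start=start, end=end, strand=strand,
                                            wraps_origin=wraps))
        elif feat.type == "gene":
            continue  # paired with its CDS/tRNA/rRNA feature
        else:
            features.append(GeneFeature(name=_raw_label(feat), kind="spacer",
                                        start=start, end=end, strand=strand,
                                        wraps_origin=wraps))
    features.sort(key=lambda f: (f.start, f.end))
    return MitoGenome(
        identifier=record.id or record.name or path.stem,
        sequence=seq,
        features=features,
        is_circular=(topology == "circular"),
        taxon_labels={"organism": record.annotations.get("organism", "")}
        if record.annotations.get("organism") else {},
    )


def read_genbank_dir(directory: str | Path) -> list[MitoGenome]:
    paths = sorted(Path(directory).glob("*.gb")) + sorted(Path(directory).glob("*.gbk"))
    if not paths:
        raise FileNotFoundError(f"no GenBank files (*.gb, *.gbk) in {directory}")
    return [read_genbank(p) for p in paths]


def write_genbank(genome: MitoGenome, path: str | Path) -> None:
    """Write a genome as a GenBank flat file (round-trips through
    :func:`read_genbank`)."""
    record = SeqRecord(Seq(genome.sequence), id=genome.identifier,
                       name=re.sub(r"\W", "_", genome.identifier)[:16],
                       description="synthetic mitochondrial genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.is_circular else "linear"
    if genome.taxon_labels.get("organism"):
        record.annotations["organism"] = genome.taxon_labels["organism"]
    n = len(genome.sequence)
    for f in genome.features:
        strand = -1 if f.strand == "N" else 1
        if f.wraps_origin:
            loc = CompoundLocation([
                FeatureLocation(f.start - 1, n, strand),
                FeatureLocation(0, f.end, strand),
            ])
        else:
            loc = FeatureLocation(f.start - 1, f.end, strand)
        if f.kind == "PCG":
            ftype = "CDS"
            quals = {"gene": [f.name], "codon_start": [str((f.codon_start or 0) + 1)]}
        elif f.kind == "tRNA":
            ftype = "tRNA"
            quals = {"gene": [f.name], "product": [f.name]}
            if f.structure:
                quals["secondary_structure"] = [f.structure]
            anticodon = references.anticodon_map().get(f.name)
            if anticodon:
                quals["anticodon"] = [anticodon.replace("U", "T").lower()]
        elif f.kind == "rRNA":
            ftype = "rRNA"
            quals = {"gene": [f.name], "product": [f.name]}
        elif f.kind == "CR":
            ftype = "misc_feature"
            quals = {"note": ["A+T-rich region (putative control region)"]}
        else:
            ftype = "misc_feature"
            quals = {"note": [f.name]}
        record.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write(record, str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA + feature-table input

TABLE_COLUMNS = ["name", "kind", "start", "end", "strand", "codon_start", "structure"]


def read_feature_table(fasta_path: str | Path, table_path: str | Path) -> MitoGenome:
    """Read a genome from FASTA plus a TSV feature table."""
    record = SeqIO.read(str(fasta_path), "fasta")
    df = pd.read_csv(table_path, sep="\t", dtype={"structure": "string"})
    features = []
    for row in df.itertuples(index=False):
        codon_start = None
        if not pd.isna(row.codon_start):
            codon_start = int(row.codon_start)
        structure = None if pd.isna(row.structure) else str(row.structure)
        start, end = int(row.start), int(row.end)
        features.append(GeneFeature(
            name=str(row.name), kind=str(row.kind), start=start, end=end,
            strand=str(row.strand), codon_start=codon_start,
            structure=structure, wraps_origin=start > end))
    return MitoGenome(identifier=record.id, sequence=str(record.seq).upper(),
                      features=features)


def write_feature_table(genome: MitoGenome, fasta_path: str | Path,
                        table_path: str | Path) -> None:
    SeqIO.write(SeqRecord(Seq(genome.sequence), id=genome.identifier,
                          description=""), str(fasta_path), "fasta")
    rows = [{
        "name": f.name, "kind": f.kind, "start": f.start, "end": f.end,
        "strand": f.strand,
        "codon_start": f.codon_start if f.kind == "PCG" else None,
        "structure": f.structure,
    } for f in genome.features]
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(table_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene extraction


def extract_gene(genome: MitoGenome, feature: GeneFeature) -> str:
    """5'->3' sense-strand sequence of a feature.

    J-strand slice of the genome for ``strand='J'``, its reverse complement
    for ``strand='N'``; wrapping of the circular origin is handled.
    """
    n = len(genome.sequence)
    if not (1 <= feature.start <= n and 1 <= feature.end <= n):
        raise ValueError(
            f"feature {feature.name} [{feature.start},{feature.end}] outside "
            f"genome of length {n}")
    if feature.wraps_origin:
        if not genome.is_circular:
            raise ValueError("wrapping feature on a linear genome")
        block = genome.sequence[feature.start - 1:] + genome.sequence[:feature.end]
    else:
        block = genome.sequence[feature.start - 1: feature.end]
    return reverse_complement(block) if feature.strand == "N" else block


def framed_cds(genome: MitoGenome, feature: GeneFeature) -> str:
    """Sense-strand CDS trimmed to its reading frame (codon_start applied,
    trailing partial codon kept — callers decide how to treat terminators)."""
    if feature.kind != "PCG":
        raise ValueError(f"{feature.name} is not a protein-coding gene")
    seq = extract_gene(genome, feature)
    return seq[feature.codon_start or 0:]


def sense_codons(genome: MitoGenome, feature: GeneFeature,
                 drop_terminator: bool = True) -> list[str]:
    """Complete DNA codons of a PCG, terminator excluded by default.

    The terminator is the trailing 1-2 bases left over after framing or,
    when the framed length is an exact codon multiple, a final UAA/UAG.
    """
    seq = framed_cds(genome, feature)
    ncod = len(seq) // 3
    codons = [seq[3 * i: 3 * i + 3] for i in range(ncod)]
    if drop_terminator and codons:
        if len(seq) % 3 == 0 and genetic_code.dna_to_rna(codons[-1]) in genetic_code.STOP_CODONS:
            codons = codons[:-1]
    return codons


# ---------------------------------------------------------------------------
# supermatrix


@dataclass
class PartitionRange:
    start: int  # 1-based inclusive column
    end: int
    stride: int = 1

    def columns(self) -> range:
        return range(self.start, self.end + 1, self.stride)

    def nexus(self) -> str:
        if self.stride == 1:
            return f"{self.start}-{self.end}"
        return f"{self.start}-{self.end}\\{self.stride}"


@dataclass
class Supermatrix:
    """Concatenated, partitioned multi-gene alignment.

    ``partitions`` is a list of ``(name, [PartitionRange, ...])``; codon
    position partitions use stride-3 (or stride-2 after third-position
    removal) ranges, so together all partitions tile the matrix exactly.
    """

    taxa: list[str]
    rows: list[str]
    partitions: list[tuple[str, list[PartitionRange]]]
    dataset_code: str
    gene_blocks: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("supermatrix rows differ in length")
        cols: set[int] = set()
        for name, ranges in self.partitions:
            for rng in ranges:
                cs = set(rng.columns())
                if cs & cols:
                    raise ValueError(f"partition {name} overlaps another partition")
                cols |= cs
        if self.rows and cols != set(range(1, len(self.rows[0]) + 1)):
            raise ValueError("partitions do not tile the matrix")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def _required_genes(dataset_code: str) -> list[str]:
    genes = list(references.PCG_NAMES)
    if dataset_code.endswith("R"):
        genes += list(references.RRNA_NAMES) + list(references.TRNA_NAMES)
    return genes


def _align_gene(genomes: list[MitoGenome], gene: str, scores,
                codon_aware: bool) -> list[str]:
    """Align one gene across genomes; returns rows in genome order."""
    if codon_aware:
        codon_lists = [sense_codons(g, g.feature(gene)) for g in genomes]
        aa = ["".join(genetic_code.amino_acid(genetic_code.dna_to_rna(c))
                      for c in codons) for codons in codon_lists]
        if len(aa) == 1:
            aln_rows = aa
        else:
            aln_rows = center_star_msa(aa, scores).rows
        rows = []
        for row, codons in zip(aln_rows, codon_lists):
            it = iter(codons)
            rows.append("".join("---" if ch == "-" else next(it) for ch in row))
        return rows
    seqs = [extract_gene(g, g.feature(gene)) for g in genomes]
    if len(seqs) == 1:
        return seqs
    return center_star_msa(seqs, scores).rows


def build_supermatrix(genomes: list[MitoGenome], dataset_code: str = "PCG123",
                      scores=DEFAULT_SCORES,
                      prealigned: dict[str, list[str]] | None = None) -> Supermatrix:
    """Concatenate per-gene alignments into a partitioned supermatrix.

    Dataset codes follow the usual mitogenomic naming: PCG123 (13 PCGs, all
    codon positions), PCG12 (third positions removed), and the R variants
    appending the two rRNAs and the 22 pooled tRNAs.  Genes are concatenated
    alphabetically by canonical name within each class.  Protein-coding
    genes are aligned codon-aware (translated under table 5, aligned as
    amino acids, back-threaded to nucleotides).

    ``prealigned`` maps gene name -> aligned rows (genome order) and
    bypasses the internal aligner for those genes.
    """
    if dataset_code not in DATASET_CODES:
        raise ValueError(f"dataset_code must be one of {DATASET_CODES}")
    if not genomes:
        raise ValueError("no genomes given")
    required = _required_genes(dataset_code)
    for g in genomes:
        missing = [name for name in required if not g.has_feature(name)]
        if missing:
            raise MissingGeneError(
                f"genome {g.identifier} is missing required gene(s): {missing}")
    drop_third = dataset_code in ("PCG12", "PCG12R")
    taxa = [g.identifier for g in genomes]
    chunks: list[list[str]] = [[] for _ in genomes]
    partitions: list[tuple[str, list[PartitionRange]]] = []
    gene_blocks: dict[str, tuple[int, int]] = {}
    col = 0  # columns written so far

    def append_block(gene: str, rows: list[str]):
        nonlocal col
        width = len(rows[0])
        if width == 0:
            raise ValueError(f"length-zero alignment for gene {gene}")
        for i, r in enumerate(rows):
            chunks[i].append(r)
        gene_blocks[gene] = (col + 1, col + width)
        col += width

    for gene in references.PCG_NAMES:
        rows = (prealigned[gene] if prealigned and gene in prealigned
                else _align_gene(genomes, gene, scores, codon_aware=True))
        if len(rows[0]) % 3:
            raise ValueError(f"codon-aware alignment of {gene} not divisible by 3")
        if drop_third:
            rows = ["".join(ch for k, ch in enumerate(r) if k % 3 != 2)
                    for r in rows]
        start = col + 1
        append_block(gene, rows)
        end = col
        if drop_third:
            partitions.append((f"{gene}_pos1", [PartitionRange(start, end - 1, 2)]))
            partitions.append((f"{gene}_pos2", [PartitionRange(start + 1, end, 2)]))
        else:
            partitions.append((f"{gene}_pos1", [PartitionRange(start, end - 2, 3)]))
            partitions.append((f"{gene}_pos2", [PartitionRange(start + 1, end - 1, 3)]))
            partitions.append((f"{gene}_pos3", [PartitionRange(start + 2, end, 3)]))

    if dataset_code.endswith("R"):
        for gene in references.RRNA_NAMES:
            rows = (prealigned[gene] if prealigned and gene in prealigned
                    else _align_gene(genomes, gene, scores, codon_aware=False))
            start = col + 1
            append_block(gene, rows)
            partitions.append((gene, [PartitionRange(start, col)]))
        trna_start = col + 1
        for gene in references.TRNA_NAMES:
            rows = (prealigned[gene] if prealigned and gene in prealigned
                    else _align_gene(genomes, gene, scores, codon_aware=False))
            append_block(gene, rows)
        partitions.append(("tRNAs", [PartitionRange(trna_start, col)]))

    rows = ["".join(parts) for parts in chunks]
    return Supermatrix(taxa=taxa, rows=rows, partitions=partitions,
                       dataset_code=dataset_code, gene_blocks=gene_blocks)


# ---------------------------------------------------------------------------
# writers


def write_phylip(matrix: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP: header 'ntaxa ncols', one 'name  sequence' per line."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.taxa)} {matrix.n_columns}\n")
        for taxon, row in zip(matrix.taxa, matrix.rows):
            fh.write(f"{taxon}  {row}\n")


def write_nexus(matrix: Supermatrix, path: str | Path) -> None:
    """NEXUS with a DATA block and one charset line per partition."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nbegin data;\n")
        fh.write(f"  dimensions ntax={len(matrix.taxa)} nchar={matrix.n_columns};\n")
        fh.write("  format datatype=dna missing=? gap=-;\n  matrix\n")
        for taxon, row in zip(matrix.taxa, matrix.rows):
            fh.write(f"  {taxon}  {row}\n")
        fh.write("  ;\nend;\n\nbegin sets;\n")
        for name, ranges in matrix.partitions:
            spans = " ".join(r.nexus() for r in ranges)
            fh.write(f"  charset {name} = {spans};\n")
        fh.write("end;\n")


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_alignment_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(aln.taxa, aln.rows):
            fh.write(f">{taxon}\n{row}\n")


def read_alignment_fasta(path: str | Path) -> Alignment:
    taxa, rows = [], []
    for record in SeqIO.parse(str(path), "fasta"):
        taxa.append(record.id)
        rows.append(str(record.seq).upper())
    return Alignment(taxa, rows)
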