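"""Core domain types for comparative transcriptome analysis.

Coordinates are 0-based half-open throughout; GTF I/O converts to and from
the 1-based inclusive convention at the file boundary. A transcript is an
ordered exon chain on one chromosome of one species; introns are the gaps
between successive exons and carry the splice-site dinucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Minimum intron length: the donor and acceptor dinucleotides must not overlap.
MIN_INTRON_LENGTH = 4

#: Splice-site dinucleotide pairs regarded as canonical (transcript orientation).
CANONICAL_PAIRS = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass
class GenomeSet:
    """Chromosome sequences of one species' assembly.

    Sequences are upper-cased on construction and restricted to A/C/G/T/N.
    """

    species_id: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        clean = {}
        for chrom, seq in self.sequences.items():
            seq = seq.upper()
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValidationError(
                    f"{self.species_id}/{chrom}: non-nucleotide characters {bad}"
                )
            clean[chrom] = seq
        self.sequences = clean

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand slice [start, end) of a chromosome."""
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq):
            raise ValidationError(
                f"{chrom}:{start}-{end} outside chromosome of length {len(seq)}"
            )
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass(frozen=True)
class TranscriptModel:
    """An exon chain on a genome; the atomic unit of every analysis."""

    transcript_id: str
    gene_id: str
    species_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: at least one exon required")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        prev_end = None
        for start, end in self.exons:
            if end - start < 1:
                raise ValidationError(f"{self.transcript_id}: empty exon [{start},{end})")
            if prev_end is not None:
                if start < prev_end:
                    raise ValidationError(
                        f"{self.transcript_id}: exons overlap or are unsorted at {start}"
                    )
                if start - prev_end < MIN_INTRON_LENGTH:
                    raise ValidationError(
                        f"{self.transcript_id}: intron [{prev_end},{start}) shorter "
                        f"than {MIN_INTRON_LENGTH}"
                    )
            prev_end = end

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic intron intervals (gaps between successive exons)."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_monoexonic(self) -> bool:
        return len(self.exons) == 1


@dataclass
class GeneModel:
    gene_id: str
    species_id: str
    chrom: str
    strand: str
    transcript_ids: set[str] = field(default_factory=set)
    orthogroup_id: str | None = None


@dataclass(frozen=True)
class SpliceJunction:
    """An intron with strand-oriented terminal dinucleotides.

    ``donor`` and ``acceptor`` are given in transcript orientation: on the
    minus strand they are taken from the reverse complement, so a genomic
    forward-strand ``CT...AC`` intron reads GT-AG.
    """

    chrom: str
    strand: str
    start: int
    end: int
    donor: str = ""
    acceptor: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start < MIN_INTRON_LENGTH:
            raise ValidationError(
                f"intron {self.chrom}:{self.start}-{self.end} shorter than "
                f"{MIN_INTRON_LENGTH}"
            )

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.start, self.end)

    @property
    def dinucleotide_pair(self) -> str:
        return f"{self.donor}-{self.acceptor}"


class Annotation:
    """A set of gene and transcript models for one species."""

    def __init__(self, species_id: str, transcripts: list[TranscriptModel]):
        self.species_id = species_id
        self.transcripts: dict[str, TranscriptModel] = {}
        self.genes: dict[str, GeneModel] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise ValidationError(f"duplicate transcript id {t.transcript_id}")
        self.transcripts[t.transcript_id] = t
        gene = self.genes.get(t.gene_id)
        if gene is None:
            gene = GeneModel(t.gene_id, t.species_id, t.chrom, t.strand)
            self.genes[t.gene_id] = gene
        else:
            if gene.chrom != t.chrom or gene.strand != t.strand:
                raise ValidationError(
                    f"gene {t.gene_id}: transcripts disagree on chrom/strand"
                )
        gene.transcript_ids.add(t.transcript_id)

    def by_gene(self, gene_id: str) -> list[TranscriptModel]:
        return [self.transcripts[tid] for tid in sorted(self.genes[gene_id].transcript_ids)]

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())


@dataclass
class ExpressionMatrix:
    """Transcript x sample abundance (TPM, optionally estimated counts).

    ``samples`` has one row per sample with columns sample_id, species,
    replicate, batch.
    """

    tpm: pd.DataFrame
    samples: pd.DataFrame
    counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.tpm.values < 0).any():
            raise ValidationError("negative TPM values")
        required = {"sample_id", "species", "replicate"}
        if not required <= set(self.samples.columns):
            raise ValidationError(f"sample metadata must have columns {sorted(required)}")
        missing = set(self.tpm.columns) - set(self.samples["sample_id"])
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")

    @property
    def species_of(self) -> dict[str, str]:
        return dict(zip(self.samples["sample_id"], self.samples["species"]))

    def samples_for(self, species: str) -> list[str]:
        rows = self.samples[self.samples["species"] == species]
        return [s for s in rows["sample_id"] if s in self.tpm.columns]

    @property
    def species_list(self) -> list[str]:
        seen: list[str] = []
        for sp in self.samples["species"]:
            if sp not in seen:
                seen.append(sp)
        return seen
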