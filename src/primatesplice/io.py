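"""Readers and writers for the external formats the pipeline consumes.

GTF exon records (Ensembl dialect, quoted gene_id/transcript_id attributes)
are converted between the file's 1-based inclusive coordinates and the
internal 0-based half-open convention. Abundance tables follow the
kallisto layout (target_id, est_counts, tpm); orthology tables are TSV with
one row per (feature, species).
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    Annotation,
    ExpressionMatrix,
    GenomeSet,
    SpliceJunction,
    TranscriptModel,
    ValidationError,
    reverse_complement,
)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    pass


def read_genome(path: str | Path, species_id: str | None = None) -> GenomeSet:
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return GenomeSet(species_id or Path(path).stem, records)


def write_genome(genome: GenomeSet, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in sorted(genome.sequences.items())
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_proteome(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_proteome(proteins: dict[str, str], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(proteins.items())
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_annotation(path: str | Path, species_id: str | None = None) -> Annotation:
    """Parse exon features of a GTF file into an :class:`Annotation`.

    Only ``exon`` features are used; gene_id and transcript_id attributes are
    required on each. Coordinates become 0-based half-open.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    species = species_id or Path(path).stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attr or "transcript_id" not in attr:
                raise GtfParseError(
                    f"{path}:{lineno}: exon feature lacks gene_id/transcript_id"
                )
            tid = attr["transcript_id"]
            iv = (int(start) - 1, int(end))
            exons.setdefault(tid, []).append(iv)
            key = (attr["gene_id"], chrom, strand)
            if meta.setdefault(tid, key) != key:
                raise GtfParseError(f"{path}:{lineno}: inconsistent records for {tid}")
    transcripts = []
    for tid, ivs in exons.items():
        gene, chrom, strand = meta[tid]
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValidationError(f"{tid}: overlapping exons [{s1},{e1}) [{s2},{e2})")
        transcripts.append(
            TranscriptModel(tid, gene, species, chrom, strand, tuple(ivs))
        )
    transcripts.sort(key=lambda t: t.transcript_id)
    return Annotation(species, transcripts)


def write_annotation(ann: Annotation, path: str | Path) -> None:
    """Write exon features, sorted by transcript id then coordinate."""
    with open(path, "w") as fh:
        for tid in sorted(ann.transcripts):
            t = ann.transcripts[tid]
            for start, end in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            "primatesplice",
                            "exon",
                            str(start + 1),
                            str(end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_expression(
    abundance_paths: dict[str, str | Path], metadata_path: str | Path
) -> ExpressionMatrix:
    """Assemble per-sample kallisto-style abundance files into one matrix.

    Every sample listed in the metadata must have an abundance file, and
    every file must quantify the full shared transcript set.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "species", "replicate"}
    if not required <= set(meta.columns):
        raise ValidationError(f"metadata must have columns {sorted(required)}")
    if "batch" not in meta.columns:
        meta["batch"] = "batch0"
    missing = set(meta["sample_id"]) - set(abundance_paths)
    if missing:
        raise ValidationError(f"samples in metadata without abundance file: {sorted(missing)}")

    tpm_cols, count_cols = {}, {}
    union_index: pd.Index | None = None
    for sample in meta["sample_id"]:
        tab = pd.read_csv(abundance_paths[sample], sep="\t")
        if tab["target_id"].duplicated().any():
            dup = tab["target_id"][tab["target_id"].duplicated()].iloc[0]
            raise ValidationError(f"{sample}: duplicated transcript id {dup}")
        if (tab["tpm"] < 0).any():
            raise ValidationError(f"{sample}: negative TPM")
        tab = tab.set_index("target_id")
        tpm_cols[sample] = tab["tpm"]
        count_cols[sample] = tab["est_counts"]
        union_index = tab.index if union_index is None else union_index.union(tab.index)
    assert union_index is not None
    for sample, col in tpm_cols.items():
        absent = union_index.difference(col.index)
        if len(absent):
            raise ValidationError(
                f"{sample}: transcripts missing from quantification: {list(absent)[:5]}"
            )
    union_index = union_index.sort_values()
    tpm = pd.DataFrame({s: tpm_cols[s].reindex(union_index) for s in meta["sample_id"]})
    counts = pd.DataFrame({s: count_cols[s].reindex(union_index) for s in meta["sample_id"]})
    return ExpressionMatrix(tpm=tpm, samples=meta, counts=counts)


def extract_junctions(t: TranscriptModel, genome: GenomeSet) -> list[SpliceJunction]:
    """Splice junctions of a transcript, in transcription order.

    Donor is the first two intron bases and acceptor the last two on the plus
    strand; on the minus strand the roles swap and both are
    reverse-complemented. Mono-exonic transcripts yield an empty list.
    """
    if t.chrom not in genome:
        raise ValidationError(f"{t.transcript_id}: chromosome {t.chrom} not in genome")
    out = []
    for start, end in t.introns:
        seq_start = genome.fetch(t.chrom, start, start + 2)
        seq_end = genome.fetch(t.chrom, end - 2, end)
        if t.strand == "+":
            donor, acceptor = seq_start, seq_end
        else:
            donor = reverse_complement(seq_end)
            acceptor = reverse_complement(seq_start)
        out.append(SpliceJunction(t.chrom, t.strand, start, end, donor, acceptor))
    if t.strand == "-":
        out.reverse()
    return out


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED6 intervals (e.g. repeat elements with family labels in the name column)."""
    tab = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    return tab


def write_bed(tab: pd.DataFrame, path: str | Path) -> None:
    tab.to_csv(path, sep="\t", header=False, index=False)


def read_orthology(path: str | Path) -> pd.DataFrame:
    """Orthology map: feature_id, feature_type, species, status, start, end, coverage."""
    tab = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "species": str})
    required = {"feature_id", "feature_type", "species", "status", "start", "end", "coverage"}
    if not required <= set(tab.columns):
        raise ValidationError(f"orthology table must have columns {sorted(required)}")
    return tab


def write_tables(tables: dict[str, pd.DataFrame], out_dir: str | Path, allow_empty=True) -> None:
    """Write result DataFrames as deterministic TSVs (sorted rows and columns kept)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, tab in tables.items():
        if tab.empty and not allow_empty:
            raise ValidationError(f"refusing to write empty table {name}")
        sort_cols = list(tab.columns[: min(2, len(tab.columns))])
        if len(tab) and sort_cols:
            tab = tab.sort_values(sort_cols, kind="mergesort")
        tab.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
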