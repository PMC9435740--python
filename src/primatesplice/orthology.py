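"""Cross-species exon orthology calls, exonic-part flattening, repeat overlap.

The pipeline consumes precomputed mapping tables (one row per feature and
species, with a MAPPED/UNMAPPED status and an alignment-coverage fraction)
rather than running a lift-over tool. The decision rules operate on those
tables: an exon is conserved when it maps in every assembly, and
species-specific when it fails to map outside its focal species with
alignment coverage below 0.5 in all four other assemblies.

Exonic parts are the DEXSeq-style counting units: the exon union of a gene
split at every distinct exon boundary, so that each part has a constant
transcript membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .models import TranscriptModel, ValidationError

COVERAGE_MAX = 0.5   # strict: species-specific requires coverage < 0.5 in all others


@dataclass(frozen=True)
class ExonicPart:
    gene_id: str
    part_index: int
    start: int
    end: int
    transcripts: frozenset[str]

    @property
    def part_id(self) -> str:
        return f"{self.gene_id}:part{self.part_index:03d}"


def call_exon_conservation(map_table: pd.DataFrame, focal_status="MAPPED") -> pd.DataFrame:
    """Conserved / species-specific / unresolved calls from an orthology map.

    One output row per exon feature. ``species`` column of the map names the
    assembly a mapping was attempted in; the feature's home species is the
    one whose row has coverage 1 by construction (the generator) or the
    ``home_species`` column when present.
    """
    rows = []
    exons = map_table[map_table["feature_type"] == "exon"]
    for fid, grp in exons.groupby("feature_id", sort=True):
        if "home_species" in grp.columns:
            home = grp["home_species"].iloc[0]
        else:
            home = grp.loc[grp["coverage"].idxmax(), "species"]
        others = grp[grp["species"] != home]
        mapped = others["status"] == "MAPPED"
        if mapped.all():
            status = "conserved"
        elif not mapped.any():
            cov = others["coverage"]
            if cov.isna().any():
                warnings.warn(f"{fid}: missing coverage for failed mapping")
                status = "unresolved"
            elif (cov < COVERAGE_MAX).all():
                status = "species_specific"
            else:
                status = "unresolved"
        else:
            status = "unresolved"
        rows.append(
            {"feature_id": fid, "status": status,
             "focal_species": home if status == "species_specific" else ""}
        )
    return pd.DataFrame(rows, columns=["feature_id", "status", "focal_species"])


def classify_exon_placement(
    exon: tuple[int, int], orf_cds: dict[str, tuple[int, int] | None]
) -> str:
    """UTR/CDS placement of an exon given genomic CDS intervals per containing
    transcript: full_UTR when disjoint from every CDS, CDS_only when inside
    every CDS, else partial_UTR. ``missing`` when no transcript has an ORF."""
    cds_list = [c for c in orf_cds.values() if c is not None]
    if not cds_list:
        return "missing"
    s, e = exon
    inside, outside = [], []
    for cs, ce in cds_list:
        if e <= cs or s >= ce:
            outside.append(True)
            inside.append(False)
        elif cs <= s and e <= ce:
            outside.append(False)
            inside.append(True)
        else:
            outside.append(False)
            inside.append(False)
    if all(outside):
        return "full_UTR"
    if all(inside):
        return "CDS_only"
    return "partial_UTR"


def flatten_exonic_parts(transcripts: list[TranscriptModel]) -> list[ExonicPart]:
    """Split a gene's exon union at every exon boundary into exonic parts.

    Parts tile the exon union, are pairwise disjoint, and each carries the
    set of transcripts whose exons cover it. Flattening is idempotent.
    """
    if not transcripts:
        return []
    strands = {t.strand for t in transcripts}
    if len(strands) > 1:
        raise ValidationError("transcripts of one gene on both strands")
    gene_id = transcripts[0].gene_id
    boundaries = sorted({b for t in transcripts for s, e in t.exons for b in (s, e)})
    parts = []
    idx = 0
    for lo, hi in zip(boundaries, boundaries[1:]):
        members = frozenset(
            t.transcript_id
            for t in transcripts
            if any(s <= lo and hi <= e for s, e in t.exons)
        )
        if members:
            parts.append(ExonicPart(gene_id, idx, lo, hi, members))
            idx += 1
    return parts


def parts_table(parts: list[ExonicPart]) -> pd.DataFrame:
    rows = [
        {"part_id": p.part_id, "gene_id": p.gene_id, "start": p.start, "end": p.end,
         "transcripts": ",".join(sorted(p.transcripts))}
        for p in parts
    ]
    return pd.DataFrame(rows, columns=["part_id", "gene_id", "start", "end", "transcripts"])


def annotate_repeats(
    exons: pd.DataFrame, repeats: pd.DataFrame | None
) -> pd.DataFrame:
    """Overlap flags of exons against repeat intervals (BED, name = family).

    ``exons`` needs columns feature_id, chrom, start, end. Returns per-exon
    overlap flag and the overlapping families (comma-joined).
    """
    out = exons[["feature_id", "chrom", "start", "end"]].copy()
    if repeats is None or not len(repeats):
        out["repeat_overlap"] = pd.NA
        out["repeat_families"] = pd.NA
        return out
    trees: dict[str, IntervalTree] = {}
    for _, r in repeats.iterrows():
        trees.setdefault(str(r["chrom"]), IntervalTree()).addi(
            int(r["start"]), int(r["end"]), str(r["name"])
        )
    flags, fams = [], []
    for _, r in exons.iterrows():
        tree = trees.get(str(r["chrom"]))
        hits = tree.overlap(int(r["start"]), int(r["end"])) if tree else set()
        families = sorted({h.data for h in hits})
        flags.append(bool(families))
        fams.append(",".join(families))
    out["repeat_overlap"] = flags
    out["repeat_families"] = fams
    return out


def repeat_enrichment(
    focal_ids: set[str], background_ids: set[str], overlap: pd.DataFrame, family: str | None = None
):
    """Fisher enrichment of repeat overlap in a focal exon set vs background.

    Delegates to the enrichment machinery; returns an EnrichmentResult.
    """
    from .stats import fisher_or_hypergeometric

    tab = overlap.set_index("feature_id")
    if family is None:
        hit = set(tab.index[tab["repeat_overlap"] == True])  # noqa: E712
    else:
        hit = set(
            tab.index[
                tab["repeat_families"].fillna("").str.split(",").apply(lambda fs: family in fs)
            ]
        )
    return fisher_or_hypergeometric(focal_ids, hit, background_ids | focal_ids, mode="fisher")
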