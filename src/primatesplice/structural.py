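"""Structural classification of transcript models against a reference annotation.

Transcripts are compared to a same-assembly reference by their intron chains,
in the spirit of long-read classifiers: full splice match (FSM), incomplete
splice match (ISM), novel-in-catalog (NIC: annotated splice sites in an
unannotated combination), novel-not-in-catalog (NNC: at least one unannotated
splice site), plus fusion, antisense, genic-intronic and intergenic classes.
FSM/ISM count as known, everything else as novel. Transcript 5'/3' ends are
ignored: identity is intron-chain identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .models import Annotation, TranscriptModel


class StructuralCategory(str, Enum):
    FSM = "FSM"
    ISM = "ISM"
    NIC = "NIC"
    NNC = "NNC"
    FUSION = "FUSION"
    ANTISENSE = "ANTISENSE"
    GENIC_INTRONIC = "GENIC_INTRONIC"
    INTERGENIC = "INTERGENIC"

    @property
    def is_known(self) -> bool:
        return self in (StructuralCategory.FSM, StructuralCategory.ISM)


@dataclass
class ReferenceIndex:
    """Precomputed lookup structures over a reference annotation."""

    chains: set[tuple]                       # (chrom, strand, intron chain)
    subchains: set[tuple]                    # consecutive sub-chains of reference chains
    junctions: set[tuple]                    # (chrom, strand, start, end)
    donor_sites: set[tuple]                  # (chrom, strand, coordinate)
    acceptor_sites: set[tuple]
    gene_spans: dict[str, tuple[str, str, int, int]]   # gene -> chrom,strand,span
    gene_exons: dict[str, list[tuple[int, int]]]
    gene_introns: dict[str, list[tuple[int, int]]]

    @classmethod
    def build(cls, ref: Annotation) -> "ReferenceIndex":
        chains, subchains, junctions = set(), set(), set()
        donors, acceptors = set(), set()
        gene_spans: dict[str, tuple[str, str, int, int]] = {}
        gene_exons: dict[str, list[tuple[int, int]]] = {}
        gene_introns: dict[str, list[tuple[int, int]]] = {}
        for t in ref:
            key = (t.chrom, t.strand)
            introns = t.introns
            chains.add(key + (introns,))
            for i in range(len(introns)):
                for j in range(i + 1, len(introns) + 1):
                    subchains.add(key + (introns[i:j],))
            for start, end in introns:
                junctions.add((t.chrom, t.strand, start, end))
                if t.strand == "+":
                    donors.add((t.chrom, t.strand, start))
                    acceptors.add((t.chrom, t.strand, end))
                else:
                    donors.add((t.chrom, t.strand, end))
                    acceptors.add((t.chrom, t.strand, start))
            g = gene_spans.get(t.gene_id)
            s, e = t.span
            if g is None:
                gene_spans[t.gene_id] = (t.chrom, t.strand, s, e)
            else:
                gene_spans[t.gene_id] = (g[0], g[1], min(g[2], s), max(g[3], e))
            gene_exons.setdefault(t.gene_id, []).extend(t.exons)
            gene_introns.setdefault(t.gene_id, []).extend(introns)
        return cls(
            chains, subchains, junctions, donors, acceptors,
            gene_spans, gene_exons, gene_introns,
        )

    def overlapping_genes(self, chrom: str, start: int, end: int, strand=None):
        out = []
        for gid, (c, st, gs, ge) in self.gene_spans.items():
            if c == chrom and start < ge and end > gs and (strand is None or st == strand):
                out.append(gid)
        return out


def _exonic_overlap(exons_a, exons_b) -> bool:
    for s1, e1 in exons_a:
        for s2, e2 in exons_b:
            if s1 < e2 and s2 < e1:
                return True
    return False


def classify_transcript(t: TranscriptModel, ref: Annotation | ReferenceIndex) -> StructuralCategory:
    """Assign exactly one structural category to a transcript.

    Priority: FSM > ISM > NIC > FUSION > NNC > ANTISENSE > GENIC_INTRONIC >
    INTERGENIC. Mono-exonic transcripts use overlap-based rules: FSM when
    contained in a same-strand reference exon; otherwise antisense, intronic
    (the same-strand genic catch-all) or intergenic.
    """
    idx = ref if isinstance(ref, ReferenceIndex) else ReferenceIndex.build(ref)
    chrom, strand = t.chrom, t.strand
    s, e = t.span

    if t.is_monoexonic:
        same = idx.overlapping_genes(chrom, s, e, strand)
        for gid in same:
            for xs, xe in idx.gene_exons[gid]:
                if xs <= s and e <= xe:
                    return StructuralCategory.FSM
        if same:
            for gid in same:
                for is_, ie in idx.gene_introns[gid]:
                    if is_ <= s and e <= ie:
                        return StructuralCategory.GENIC_INTRONIC
            return StructuralCategory.GENIC_INTRONIC
        anti = idx.overlapping_genes(chrom, s, e, "-" if strand == "+" else "+")
        for gid in anti:
            if _exonic_overlap(t.exons, idx.gene_exons[gid]):
                return StructuralCategory.ANTISENSE
        return StructuralCategory.INTERGENIC

    introns = t.introns
    key = (chrom, strand)
    if key + (introns,) in idx.chains:
        return StructuralCategory.FSM
    if key + (introns,) in idx.subchains:
        return StructuralCategory.ISM

    all_sites_known = True
    for start, end in introns:
        d = (chrom, strand, start if strand == "+" else end)
        a = (chrom, strand, end if strand == "+" else start)
        if d not in idx.donor_sites or a not in idx.acceptor_sites:
            all_sites_known = False
            break
    if all_sites_known:
        return StructuralCategory.NIC

    # fusion: junctions fall in >=2 reference genes whose spans do not overlap
    genes_hit: dict[str, tuple[int, int]] = {}
    for start, end in introns:
        for gid in idx.overlapping_genes(chrom, start, end, strand):
            gs, ge = idx.gene_spans[gid][2:]
            if gs <= start and end <= ge:
                genes_hit[gid] = (gs, ge)
    if len(genes_hit) >= 2:
        spans = sorted(genes_hit.values())
        disjoint = all(a_end <= b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))
        if disjoint:
            return StructuralCategory.FUSION
    if idx.overlapping_genes(chrom, s, e, strand):
        return StructuralCategory.NNC
    anti = idx.overlapping_genes(chrom, s, e, "-" if strand == "+" else "+")
    for gid in anti:
        if _exonic_overlap(t.exons, idx.gene_exons[gid]):
            return StructuralCategory.ANTISENSE
    return StructuralCategory.INTERGENIC


def classify_junctions(transcripts, ref: Annotation | ReferenceIndex) -> pd.DataFrame:
    """Deduplicated junction table with known/novel status.

    A junction is known iff the exact intron interval appears in a reference
    transcript on the same strand.
    """
    idx = ref if isinstance(ref, ReferenceIndex) else ReferenceIndex.build(ref)
    seen = {}
    for t in transcripts:
        for start, end in t.introns:
            k = (t.chrom, t.strand, start, end)
            if k not in seen:
                seen[k] = k in idx.junctions
    rows = [
        {"chrom": c, "strand": st, "start": s, "end": e,
         "status": "known" if known else "novel"}
        for (c, st, s, e), known in sorted(seen.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "strand", "start", "end", "status"])


def classify_annotation(ann: Annotation, ref: Annotation) -> pd.DataFrame:
    """Per-transcript category table for a whole annotation."""
    idx = ReferenceIndex.build(ref)
    rows = []
    for tid in sorted(ann.transcripts):
        t = ann.transcripts[tid]
        cat = classify_transcript(t, idx)
        rows.append(
            {"transcript_id": tid, "gene_id": t.gene_id, "species": t.species_id,
             "category": cat.value, "novelty": "known" if cat.is_known else "novel"}
        )
    return pd.DataFrame(rows)


def novelty_summary(categories: pd.DataFrame, junctions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-species known/novel proportions for transcripts (and junctions)."""
    rows = []
    for species, grp in categories.groupby("species"):
        frac_novel = (grp["novelty"] == "novel").mean()
        rows.append(
            {"species": species, "level": "transcript", "n": len(grp),
             "fraction_known": 1 - frac_novel, "fraction_novel": frac_novel}
        )
    if junctions is not None and len(junctions):
        frac_novel = (junctions["status"] == "novel").mean()
        rows.append(
            {"species": "all", "level": "junction", "n": len(junctions),
             "fraction_known": 1 - frac_novel, "fraction_novel": frac_novel}
        )
    return pd.DataFrame(rows)
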