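"""ORF prediction, in-silico tryptic digestion, and peptide novelty.

The ORF caller is the deterministic longest-ORF heuristic: the longest
sense-strand reading frame starting at ATG and ending at an in-frame stop
(or, incomplete, at the transcript end), with 5'-most tie-breaking. Tryptic
peptides are produced by cleavage after K or R except before P, allowing a
configurable number of missed cleavages. Peptide novelty against a reference
proteome is substring matching under isoleucine/leucine equivalence, since
the two residues are mass-indistinguishable to a search engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .models import GenomeSet, TranscriptModel, reverse_complement

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ORFRecord:
    transcript_id: str
    cds_start: int          # transcript coordinates, 0-based half-open
    cds_end: int
    protein: str
    has_start: bool
    has_stop: bool

    def __post_init__(self):
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError("CDS length not divisible by 3")


@dataclass(frozen=True)
class PeptideRecord:
    sequence: str
    protein_id: str
    missed_cleavages: int
    novelty: str = ""       # annotated / novel


def transcript_cdna(t: TranscriptModel, genome: GenomeSet) -> str:
    """Spliced transcript sequence in transcription orientation."""
    seq = "".join(genome.fetch(t.chrom, s, e) for s, e in t.exons)
    return reverse_complement(seq) if t.strand == "-" else seq


def predict_orf(
    seq: str, transcript_id: str = "", min_aa: int = 50
) -> ORFRecord | None:
    """Longest ATG-initiated ORF on the sense strand; ties go 5'-most.

    An ORF without an in-frame stop runs to the last complete codon and is
    flagged incomplete. Returns None when no ORF reaches ``min_aa`` residues.
    """
    seq = seq.upper()
    best: tuple[int, int, bool] | None = None   # start, end(codon-exclusive), has_stop
    n = len(seq)
    # earliest ATG per frame is enough for the longest ORF within that stop-free
    # stretch, but internal stops reset the search, so scan every ATG
    i = seq.find("ATG")
    while i != -1:
        j = i
        has_stop = False
        while j + 3 <= n:
            if seq[j:j + 3] in STOP_CODONS:
                has_stop = True
                break
            j += 3
        end = j + 3 if has_stop else j
        aa_len = (end - i) // 3 - (1 if has_stop else 0)
        if aa_len >= min_aa:
            cur_len = end - i
            if best is None or cur_len > best[1] - best[0]:
                best = (i, end, has_stop)
        i = seq.find("ATG", i + 1)
    if best is None:
        return None
    start, end, has_stop = best
    cds = seq[start:end]
    protein = str(Seq(cds).translate()).rstrip("*")
    return ORFRecord(transcript_id, start, end, protein, True, has_stop)


def cds_genomic_interval(t: TranscriptModel, orf: ORFRecord) -> tuple[int, int]:
    """Genomic span of an ORF's CDS (outer bounds across exons)."""
    # map transcript positions to genomic positions
    positions = []
    for s, e in t.exons:
        positions.extend(range(s, e))
    if t.strand == "-":
        positions = positions[::-1]
    g = [positions[i] for i in range(orf.cds_start, orf.cds_end)]
    return (min(g), max(g) + 1)


def digest_tryptic(
    protein: str,
    protein_id: str = "",
    missed_max: int = 2,
    len_min: int = 7,
    len_max: int = 40,
) -> list[PeptideRecord]:
    """Tryptic fragments of a protein.

    Cleavage occurs after K or R unless the next residue is P; all fragments
    spanning at most ``missed_max`` internal cleavage sites and with length
    in [len_min, len_max] are emitted, deduplicated by (sequence, missed).
    """
    if not protein:
        return []
    cut_after = [
        i for i in range(len(protein) - 1)
        if protein[i] in "KR" and protein[i + 1] != "P"
    ]
    bounds = [0] + [i + 1 for i in cut_after] + [len(protein)]
    out, seen = [], set()
    for bi in range(len(bounds) - 1):
        for bj in range(bi + 1, min(bi + missed_max + 2, len(bounds))):
            frag = protein[bounds[bi]:bounds[bj]]
            missed = bj - bi - 1
            if len_min <= len(frag) <= len_max and (frag, missed) not in seen:
                seen.add((frag, missed))
                out.append(PeptideRecord(frag, protein_id, missed))
    return out


def _canon_il(seq: str) -> str:
    return seq.replace("I", "L")


def classify_peptide_novelty(
    peptides: list[PeptideRecord],
    reference_proteome: dict[str, str],
    il_equivalence: bool = True,
) -> list[PeptideRecord]:
    """Label peptides annotated when they occur as a substring of any
    reference protein (under I/L equivalence by default), else novel."""
    if il_equivalence:
        haystack = "#".join(_canon_il(p) for p in reference_proteome.values())
    else:
        haystack = "#".join(reference_proteome.values())
    out = []
    for pep in peptides:
        q = _canon_il(pep.sequence) if il_equivalence else pep.sequence
        status = "annotated" if q in haystack else "novel"
        out.append(PeptideRecord(pep.sequence, pep.protein_id, pep.missed_cleavages, status))
    return out


def peptide_table(peptides: list[PeptideRecord], gene_of: dict[str, str] | None = None) -> pd.DataFrame:
    rows = [
        {"peptide": p.sequence, "protein_id": p.protein_id,
         "missed_cleavages": p.missed_cleavages, "novelty": p.novelty,
         "gene_id": gene_of.get(p.protein_id, "") if gene_of else ""}
        for p in peptides
    ]
    return pd.DataFrame(
        rows, columns=["peptide", "protein_id", "missed_cleavages", "novelty", "gene_id"]
    )


def genes_with_novel_peptides(table: pd.DataFrame) -> set[str]:
    novel = table[(table["novelty"] == "novel") & (table["gene_id"] != "")]
    return set(novel["gene_id"])


def compare_domain_combinations(
    query_combinations: dict[str, tuple],
    reference_combinations: set[tuple],
) -> dict[str, str]:
    """known_combination when the ordered domain-label tuple occurs among the
    reference combinations, else novel_combination. The empty combination is
    known iff an undomained reference ORF exists."""
    out = {}
    for key, combo in query_combinations.items():
        if combo is None:
            out[key] = "missing"
        else:
            out[key] = (
                "known_combination" if tuple(combo) in reference_combinations
                else "novel_combination"
            )
    return out
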