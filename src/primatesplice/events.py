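"""Local alternative-splicing events and splice-site canonicity.

Events are detected between isoform pairs of one gene and deduplicated at the
gene level by (class, defining intervals):

* SE  — an exon of one isoform is spliced directly across by the other
        (matching outer splice sites).
* RI  — one isoform keeps as exonic sequence exactly the intron the other
        splices out (matching outer exon boundaries).
* A5SS/A3SS — two junctions share one boundary and differ at the other;
        the 5'/3' naming follows transcription orientation.
* MEX — two non-overlapping exons, each individually skippable against the
        same flanking junction pair, never observed together in any isoform
        of the gene.

Canonicity of a junction is a pure function of its strand-oriented terminal
dinucleotides: GT-AG, GC-AG and AT-AC are canonical, everything else
(including anything containing N) is not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .models import CANONICAL_PAIRS, GenomeSet, SpliceJunction, TranscriptModel, reverse_complement
from .io import extract_junctions


@dataclass
class ASEvent:
    gene_id: str
    event_class: str                       # SE, RI, A5SS, A3SS, MEX
    intervals: tuple                       # class-specific defining intervals
    inclusion: set[str] = field(default_factory=set)
    exclusion: set[str] = field(default_factory=set)

    @property
    def key(self):
        return (self.event_class, self.intervals)


def _pair_events(a: TranscriptModel, b: TranscriptModel):
    """Events distinguishing transcript a from b (a = inclusion side for SE/RI)."""
    events = []
    introns_b = set(b.introns)
    exons_b = set(b.exons)

    # SE: internal exon of a flanked by introns whose outer ends form one intron of b
    for i in range(1, len(a.exons) - 1):
        left = (a.exons[i - 1][1], a.exons[i][0])
        right = (a.exons[i][1], a.exons[i + 1][0])
        if (left[0], right[1]) in introns_b:
            events.append(("SE", (a.exons[i],), a, b))

    # RI: exon of a spans exactly the two exons of b around one intron
    for j in range(len(b.exons) - 1):
        outer = (b.exons[j][0], b.exons[j + 1][1])
        intron = (b.exons[j][1], b.exons[j + 1][0])
        if outer in set(a.exons):
            events.append(("RI", (intron,), a, b))

    # A5SS / A3SS: junction pairs sharing one boundary and differing at the
    # other, where the longer junction's boundary falls strictly inside the
    # exon flanking the shorter junction (otherwise the difference is a whole
    # spliced-out exon, i.e. an SE configuration, not an alternative site).
    # The isoform with the shorter intron (more exonic sequence) is the
    # inclusion side.
    for ia in a.introns:
        for ib in b.introns:
            if ia == ib:
                continue
            if ia[1] == ib[1] and ia[0] != ib[0]:
                # shared genomic end; on + this is the acceptor -> donors differ
                short_t, short_i, long_i = (a, ia, ib) if ia[0] > ib[0] else (b, ib, ia)
                exon = next(e for e in short_t.exons if e[1] == short_i[0])
                if not exon[0] < long_i[0]:
                    continue
                cls = "A5SS" if a.strand == "+" else "A3SS"
            elif ia[0] == ib[0] and ia[1] != ib[1]:
                short_t, short_i, long_i = (a, ia, ib) if ia[1] < ib[1] else (b, ib, ia)
                exon = next(e for e in short_t.exons if e[0] == short_i[1])
                if not long_i[1] < exon[1]:
                    continue
                cls = "A3SS" if a.strand == "+" else "A5SS"
            else:
                continue
            iv = (min(ia, ib), max(ia, ib))
            long_t = b if short_t is a else a
            events.append((cls, iv, short_t, long_t))
    return events


def detect_as_events(transcripts: list[TranscriptModel]) -> list[ASEvent]:
    """Detect AS events among the isoforms of one gene.

    Returns gene-level events, deduplicated by (class, defining intervals),
    with inclusion/exclusion transcript id sets merged across pairs.
    """
    if len(transcripts) < 2:
        return []
    gene_id = transcripts[0].gene_id
    merged: dict[tuple, ASEvent] = {}

    def add(cls, intervals, inc_ids, exc_ids):
        ev = merged.get((cls, intervals))
        if ev is None:
            ev = ASEvent(gene_id, cls, intervals)
            merged[(cls, intervals)] = ev
        ev.inclusion.update(inc_ids)
        ev.exclusion.update(exc_ids)

    for i, a in enumerate(transcripts):
        for b in transcripts[i + 1:]:
            for cls, intervals, ta, tb in _pair_events(a, b) + _pair_events(b, a):
                add(cls, intervals, {ta.transcript_id}, {tb.transcript_id})

    # MEX: pairs of SE-like exons with common flanking context, never co-occurring
    se_candidates: dict[tuple, set[tuple]] = {}   # (left_anchor,right_anchor) -> exons
    for t in transcripts:
        for i in range(1, len(t.exons) - 1):
            ctx = (t.exons[i - 1][1], t.exons[i + 1][0])
            se_candidates.setdefault(ctx, set()).add(t.exons[i])
    tx_exons = {t.transcript_id: set(t.exons) for t in transcripts}
    skip_junctions = {t.transcript_id: set(t.introns) for t in transcripts}
    mex_added = set()
    for (lo, hi), exset in se_candidates.items():
        exs = sorted(exset)
        for x in range(len(exs)):
            for y in range(x + 1, len(exs)):
                e1, e2 = exs[x], exs[y]
                if e1[1] > e2[0]:      # overlapping candidates excluded
                    continue
                # each must be individually skippable: some transcript splices lo->hi
                skipped = any((lo, hi) in sj for sj in skip_junctions.values())
                each_present = (
                    any(e1 in xs and e2 not in xs for xs in tx_exons.values())
                    and any(e2 in xs and e1 not in xs for xs in tx_exons.values())
                )
                cooccur = any(e1 in xs and e2 in xs for xs in tx_exons.values())
                if each_present and not cooccur and not skipped:
                    key = (e1, e2)
                    if key in mex_added:
                        continue
                    mex_added.add(key)
                    inc = {tid for tid, xs in tx_exons.items() if e1 in xs}
                    exc = {tid for tid, xs in tx_exons.items() if e2 in xs}
                    add("MEX", (e1, e2), inc, exc)
    out = sorted(merged.values(), key=lambda e: (e.event_class, e.intervals))
    return out


def events_table(events: list[ASEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append(
            {
                "gene_id": ev.gene_id,
                "event_class": ev.event_class,
                "intervals": ";".join(f"{s}-{e}" for s, e in ev.intervals),
                "inclusion": ",".join(sorted(ev.inclusion)),
                "exclusion": ",".join(sorted(ev.exclusion)),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "event_class", "intervals", "inclusion", "exclusion"]
    )


def classify_canonicity(junction: SpliceJunction) -> str:
    """'canonical' iff the (donor, acceptor) pair is GT-AG, GC-AG or AT-AC."""
    pair = (junction.donor, junction.acceptor)
    if "N" in junction.donor + junction.acceptor:
        warnings.warn(f"N in splice-site dinucleotides at {junction.key}")
        return "noncanonical"
    return "canonical" if pair in CANONICAL_PAIRS else "noncanonical"


def detect_canonicity_changes(
    junction_map: pd.DataFrame, genomes: dict[str, GenomeSet]
) -> pd.DataFrame:
    """Per-species canonicity of orthologous junctions and a change flag.

    ``junction_map`` has one row per (feature_id, species) with columns
    status (MAPPED/UNMAPPED), start, end, chrom, strand. Dinucleotides are
    read from each species' genome at the mapped coordinates; unmappable
    junctions are labelled missing and ignored for the change flag, which is
    set when at least two present species disagree.
    """
    rows = []
    for fid, grp in junction_map.groupby("feature_id", sort=True):
        labels, pairs = {}, {}
        for _, r in grp.iterrows():
            sp = r["species"]
            if r["status"] != "MAPPED":
                labels[sp] = "missing"
                pairs[sp] = ""
                continue
            g = genomes[sp]
            start, end = int(r["start"]), int(r["end"])
            d = g.fetch(r["chrom"], start, start + 2)
            a = g.fetch(r["chrom"], end - 2, end)
            if r["strand"] == "-":
                d, a = reverse_complement(a), reverse_complement(d)
            j = SpliceJunction(r["chrom"], r["strand"], start, end, d, a)
            labels[sp] = classify_canonicity(j)
            pairs[sp] = j.dinucleotide_pair
        present = [v for v in labels.values() if v != "missing"]
        change = len(set(present)) > 1 and len(present) >= 2
        row = {"feature_id": fid, "change": change}
        for sp in sorted(labels):
            row[f"label_{sp}"] = labels[sp]
            row[f"pair_{sp}"] = pairs[sp]
        rows.append(row)
    return pd.DataFrame(rows)


def canonical_only_in(record: pd.Series, species: str, all_species: list[str]) -> bool:
    """True when a junction is canonical in ``species`` and noncanonical in
    every other species where it is present."""
    if record.get(f"label_{species}") != "canonical":
        return False
    others = [record.get(f"label_{sp}") for sp in all_species if sp != species]
    others = [o for o in others if o not in (None, "missing")]
    return len(others) > 0 and all(o == "noncanonical" for o in others)


def assign_gain_mechanism(
    species_specific: dict[str, set[str]],
    transcripts: dict[str, TranscriptModel],
    expressed_junctions: dict[str, set[tuple]],
    canonicity: pd.DataFrame,
    junction_feature_ids: dict[tuple, str],
    as_events_by_gene: dict[str, list[ASEvent]] | None = None,
) -> pd.DataFrame:
    """Mechanism labels for species-specific transcripts.

    For each species-specific transcript: does it use a junction expressed in
    no other species; the dominant AS class among its distinguishing
    junctions; is it canonicity-driven (a distinguishing junction canonical
    only in the expressing species); and does it have conserved canonicity
    (all junctions canonical in all five species).
    """
    canon_by_id = canonicity.set_index("feature_id") if len(canonicity) else pd.DataFrame()
    all_species = sorted(expressed_junctions)
    rows = []
    for species in sorted(species_specific):
        other_junc = set()
        for sp, js in expressed_junctions.items():
            if sp != species:
                other_junc |= js
        for tid in sorted(species_specific[species]):
            t = transcripts.get(tid)
            if t is None:
                raise KeyError(f"species-specific transcript {tid} absent from models")
            juncs = [(t.chrom, t.strand) + iv for iv in t.introns]
            distinguishing = [j for j in juncs if j not in other_junc]
            canonicity_driven = False
            conserved = len(juncs) > 0
            for j in juncs:
                fid = junction_feature_ids.get(j)
                if fid is None or fid not in getattr(canon_by_id, "index", []):
                    conserved = False
                    continue
                rec = canon_by_id.loc[fid]
                if not all(
                    rec.get(f"label_{sp}") == "canonical" for sp in all_species
                ):
                    conserved = False
                if j in distinguishing and canonical_only_in(rec, species, all_species):
                    canonicity_driven = True
            dom_class = ""
            if as_events_by_gene is not None:
                classes = []
                for ev in as_events_by_gene.get(t.gene_id, []):
                    if tid in ev.inclusion or tid in ev.exclusion:
                        classes.append(ev.event_class)
                if classes:
                    dom_class = pd.Series(classes).mode().iloc[0]
            rows.append(
                {
                    "transcript_id": tid,
                    "species": species,
                    "uses_species_specific_junction": len(distinguishing) > 0,
                    "n_distinguishing_junctions": len(distinguishing),
                    "dominant_as_class": dom_class,
                    "canonicity_driven": canonicity_driven,
                    "conserved_canonicity": conserved,
                }
            )
    return pd.DataFrame(rows)


def junction_canonicity_table(
    transcripts, genome: GenomeSet
) -> pd.DataFrame:
    """Canonicity labels for the deduplicated junctions of a transcript set."""
    seen = {}
    for t in transcripts:
        for j in extract_junctions(t, genome):
            seen.setdefault(j.key, j)
    rows = [
        {"chrom": k[0], "strand": k[1], "start": k[2], "end": k[3],
         "pair": j.dinucleotide_pair, "label": classify_canonicity(j)}
        for k, j in sorted(seen.items())
    ]
    return pd.DataFrame(rows)
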