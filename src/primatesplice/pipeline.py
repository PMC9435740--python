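"""End-to-end orchestration: run every analysis on a dataset and, for
synthetic fixtures, score recovery of the planted events.

The recovery functions compare pipeline calls against the generator's truth
ledger. Sensitivity for a class is the fraction of its planted events
recovered by key. For the empirical false-discovery rate, a call counts as
false when its gene carries no planted perturbation for the called species
at all: planted classes are not independent (a transcript gain or a
dominance switch genuinely changes isoform usage in its gene), so calls of
one usage class on a gene planted with another are real signal, not error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import events as ev
from . import orthology as orth
from . import parsimony as pars
from . import proteomics as prot
from . import structural as struct
from . import usage as us
from .models import ExpressionMatrix
from .simulate import SPECIES, SimReference


def _sens_fdr(truth: set, called: set, allowed: set | None = None):
    """Sensitivity over ``truth`` and FDR over ``called``; calls inside
    ``allowed`` (cross-class genuine perturbations) are not false."""
    allowed = allowed if allowed is not None else truth
    tp = len(truth & called)
    fp = len({c for c in called if c not in allowed})
    sens = tp / len(truth) if truth else float("nan")
    fdr = fp / len(called) if called else 0.0
    return sens, fdr


def perturbed_pairs(ref: SimReference) -> set[tuple[str, str]]:
    """(gene, species) pairs with any planted usage-affecting event."""
    out = set()
    for g in ref.genes:
        if g.event in ("gain", "ss_exon", "diu", "deu", "rank_switch") and g.focal:
            out.add((g.gene_id, g.focal))
    return out


def classify_fixture(ref: SimReference) -> pd.DataFrame:
    """Structural categories of every species' models vs its prior catalog."""
    frames = []
    for sp in SPECIES:
        frames.append(struct.classify_annotation(ref.annotations[sp],
                                                 ref.reference_annotation[sp]))
    return pd.concat(frames, ignore_index=True)


@dataclass
class SpeciesSpecificRecovery:
    presence: pd.DataFrame
    called: dict[str, set[str]]
    mechanism: pd.DataFrame
    events: pd.DataFrame
    sensitivity: float
    fdr: float
    canonicity_sensitivity: float
    canonicity_fdr: float
    confound: pd.DataFrame


def recover_species_specific(ref: SimReference, expr: ExpressionMatrix) -> SpeciesSpecificRecovery:
    """Presence profiles, parsimony events, species-specific transcripts and
    their mechanisms, scored against the truth ledger."""
    presence = pars.build_presence_matrix(expr, criterion="strict")
    called = pars.call_species_specific(presence, list(SPECIES))
    called_pairs = {(tid, sp) for sp, tids in called.items() for tid in tids}

    truth = ref.truth
    t_ss = truth[truth["event_class"] == "species_specific_transcript"]
    truth_pairs = set(zip(t_ss["feature_id"], t_ss["focal_species"]))
    sens, fdr = _sens_fdr(truth_pairs, called_pairs)

    events = pars.reconstruct_gain_loss(presence)

    # mechanism assignment for the called transcripts
    models = ref.transcript_models
    expressed_junctions: dict[str, set[tuple]] = {}
    for sp in SPECIES:
        junc = set()
        expressed = presence.index[(presence[sp] == 1) & ~presence["ambiguous"]]
        for tid in expressed:
            t = models.get(tid)
            if t is None:
                continue
            for iv in t.introns:
                junc.add((t.chrom, t.strand) + iv)
        expressed_junctions[sp] = junc

    jmap = ref.orthology[ref.orthology["feature_type"] == "junction"]
    canon = ev.detect_canonicity_changes(jmap, ref.genomes)
    feature_ids = {}
    anchor = jmap[jmap["species"] == SPECIES[0]]
    for _, r in anchor.iterrows():
        feature_ids[(r["chrom"], r["strand"], int(r["start"]), int(r["end"]))] = r["feature_id"]
    as_by_gene = {}
    for g in ref.genes:
        ts = [models[t] for t in sorted(g.transcripts) if t in models]
        as_by_gene[g.gene_id] = ev.detect_as_events(ts)
    mech = ev.assign_gain_mechanism(
        called, models, expressed_junctions, canon, feature_ids, as_by_gene
    )

    t_canon = t_ss[t_ss["mechanism"] == "canonicity"]
    truth_canon = set(zip(t_canon["feature_id"], t_canon["focal_species"]))
    if len(mech):
        called_canon = set(
            zip(mech.loc[mech["canonicity_driven"], "transcript_id"],
                mech.loc[mech["canonicity_driven"], "species"])
        )
    else:
        called_canon = set()
    csens, cfdr = _sens_fdr(truth_canon, called_canon)

    # gene-level up-regulation confound check on the genes with called transcripts
    gene_of = ref.gene_of
    genes = pd.Series({t: gene_of[t] for t in expr.tpm.index})
    gene_tpm = expr.tpm.groupby(genes).sum()
    focal_by_gene = {}
    for sp, tids in called.items():
        for tid in tids:
            focal_by_gene[gene_of[tid]] = sp
    confound = pars.check_upregulation_confound(gene_tpm, expr.samples, focal_by_gene)

    return SpeciesSpecificRecovery(
        presence, called, mech, events, sens, fdr, csens, cfdr, confound
    )


@dataclass
class ExonRecovery:
    calls: pd.DataFrame
    sensitivity: float
    fdr: float
    repeat_or: float
    repeat_p: float


def recover_exon_conservation(ref: SimReference) -> ExonRecovery:
    calls = orth.call_exon_conservation(ref.orthology)
    ss = calls[calls["status"] == "species_specific"]
    called = set(zip(ss["feature_id"], ss["focal_species"]))
    t_ex = ref.truth[ref.truth["event_class"] == "species_specific_exon"]
    truth = set(zip(t_ex["feature_id"], t_ex["focal_species"]))
    sens, fdr = _sens_fdr(truth, called)

    anchor = ref.orthology[
        (ref.orthology["feature_type"] == "exon")
        & (ref.orthology["species"] == ref.orthology["home_species"])
    ][["feature_id", "chrom", "start", "end"]].drop_duplicates("feature_id")
    overlap = orth.annotate_repeats(anchor, ref.repeats)
    focal_ids = {fid for fid, _ in called} or {fid for fid, _ in truth}
    background = set(anchor["feature_id"]) - focal_ids
    res = orth.repeat_enrichment(focal_ids, background, overlap, family="Alu")
    return ExonRecovery(calls, sens, fdr, res.odds_ratio, res.p)


@dataclass
class UsageRecovery:
    diu: pd.DataFrame
    deu: pd.DataFrame
    diu_sensitivity: float
    diu_fdr: float
    deu_sensitivity: float
    deu_fdr: float
    rank_sensitivity: float
    rank_fdr: float
    sharing_curve: pd.DataFrame
    n_diu_tested: int
    n_deu_tested: int


def recover_usage(ref: SimReference, expr: ExpressionMatrix, fdr_level=0.05) -> UsageRecovery:
    gene_of = ref.gene_of
    models = ref.transcript_models
    metadata = expr.samples
    perturbed = perturbed_pairs(ref)

    # quantification-ambiguous genes are excluded from usage analyses
    by_gene: dict[str, list] = {}
    for tid, t in models.items():
        by_gene.setdefault(t.gene_id, []).append(t)
    ambiguous = us.flag_ambiguous_genes(by_gene)

    keep = expr.tpm.index[[not ambiguous.get(gene_of[t], False) for t in expr.tpm.index]]
    tpm = expr.tpm.loc[keep]
    iu = us.compute_iu(tpm, gene_of)
    eligible = us.expression_filter(tpm, gene_of, metadata)
    diu = us.test_species_specific_usage(iu[eligible], metadata, fdr=fdr_level)
    diu["gene_id"] = [gene_of[t] for t in diu.index]

    called_diu = {
        (tid, r["focal_species"])
        for tid, r in diu.iterrows() if r["call"] in ("up", "down")
    }
    t_diu = ref.truth[ref.truth["event_class"] == "diu"]
    truth_diu = set(zip(t_diu["feature_id"], t_diu["focal_species"]))
    allowed = {
        (tid, sp) for (tid, _) in called_diu | truth_diu for (gene, sp) in perturbed
        if gene_of.get(tid) == gene
    }
    diu_sens, diu_fdr = _sens_fdr(truth_diu, called_diu, allowed)

    # exonic parts from the shared models; counts sum member transcripts
    assert expr.counts is not None
    part_rows, part_gene = [], {}
    part_counts = {}
    for gene, ts in sorted(by_gene.items()):
        if ambiguous.get(gene, False):
            continue
        for p in orth.flatten_exonic_parts(sorted(ts, key=lambda t: t.transcript_id)):
            key = f"{p.gene_id}:part:{p.start}-{p.end}"
            members = [t for t in p.transcripts if t in expr.counts.index]
            part_counts[key] = expr.counts.loc[members].sum(axis=0)
            part_gene[key] = gene
    parts_df = pd.DataFrame(part_counts).T
    part_usage = us.exonic_part_usage(parts_df, part_gene)
    deu = us.test_species_specific_usage(part_usage, metadata, fdr=fdr_level)
    deu["gene_id"] = [part_gene[p] for p in deu.index]

    called_deu = {
        (pid, r["focal_species"])
        for pid, r in deu.iterrows() if r["call"] in ("up", "down")
    }
    t_deu = ref.truth[ref.truth["event_class"] == "deu"]
    truth_deu = set(zip(t_deu["feature_id"], t_deu["focal_species"]))
    allowed_deu = {
        (pid, sp) for (pid, _) in called_deu | truth_deu for (gene, sp) in perturbed
        if part_gene.get(pid) == gene
    }
    deu_sens, deu_fdr = _sens_fdr(truth_deu, called_deu, allowed_deu)

    # dominant-isoform switches: one species deviates from the other four and
    # its dominance is decisive (rank-1/rank-2 fold change >= 1.5), so that
    # near-tied genes whose rank order flips by sampling noise are not called
    records = us.rank_dominance(iu, tpm, gene_of, metadata)
    called_rank = set()
    for rec in records:
        r1 = pd.Series(rec.rank1)
        counts = r1.value_counts()
        if len(counts) == 2 and counts.iloc[0] == len(SPECIES) - 1:
            deviant = r1[r1 == counts.index[-1]].index[0]
            if rec.rank_fc.get(deviant, 0.0) >= 1.5:
                called_rank.add((rec.gene_id, deviant))
    t_rank = ref.truth[ref.truth["event_class"] == "rank_switch"]
    truth_rank = set(zip(t_rank["gene_id"], t_rank["focal_species"]))
    allowed_rank = {(g, sp) for (g, sp) in called_rank | truth_rank if (g, sp) in perturbed}
    rank_sens, rank_fdr = _sens_fdr(truth_rank, called_rank, allowed_rank)

    curve = us.dominance_sharing_curve(records)

    return UsageRecovery(
        diu, deu, diu_sens, diu_fdr, deu_sens, deu_fdr, rank_sens, rank_fdr,
        curve, int(eligible.sum()), len(parts_df),
    )


@dataclass
class PeptideRecovery:
    table: pd.DataFrame
    sensitivity: float
    fdr: float


def recover_peptides(ref: SimReference, species: str = "H") -> PeptideRecovery:
    """Digest predicted ORFs of one species' models against its reference
    proteome; genes with at least one novel peptide are flagged."""
    genome = ref.genomes[species]
    ann = ref.annotations[species]
    gene_of_protein = {}
    peptides = []
    for tid in sorted(ann.transcripts):
        t = ann.transcripts[tid]
        orf = prot.predict_orf(prot.transcript_cdna(t, genome), tid)
        if orf is None:
            continue
        pid = f"{tid}_prot"
        gene_of_protein[pid] = t.gene_id
        peptides.extend(prot.digest_tryptic(orf.protein, pid))
    labeled = prot.classify_peptide_novelty(peptides, ref.proteomes[species])
    table = prot.peptide_table(labeled, gene_of_protein)
    called = prot.genes_with_novel_peptides(table)
    t_pep = ref.truth[ref.truth["event_class"] == "novel_peptide_gene"]
    truth = set(t_pep["gene_id"])
    sens, fdr = _sens_fdr(truth, called)
    return PeptideRecovery(table, sens, fdr)


def run_recovery(
    ref: SimReference,
    expr_main: ExpressionMatrix,
    expr_usage: ExpressionMatrix | None = None,
) -> dict:
    """Full planted-event recovery; returns a flat metric dictionary."""
    cats = classify_fixture(ref)
    truth = ref.truth
    novel_ids = set(truth.loc[truth["event_class"] == "species_specific_transcript",
                              "feature_id"])
    planted_rows = cats[cats["transcript_id"].isin(novel_ids)]
    nnc_fraction = float((planted_rows["category"] == "NNC").mean()) if len(planted_rows) else float("nan")
    base_rows = cats[~cats["transcript_id"].isin(novel_ids)]
    fsm_fraction = float((base_rows["category"] == "FSM").mean()) if len(base_rows) else float("nan")

    ss = recover_species_specific(ref, expr_main)
    exons = recover_exon_conservation(ref)
    usage_expr = expr_usage if expr_usage is not None else expr_main
    usg = recover_usage(ref, usage_expr)
    pep = recover_peptides(ref)

    n_conf = int(ss.confound["confounded"].sum()) if len(ss.confound) else 0
    return {
        "planted_novel_nnc_fraction": nnc_fraction,
        "annotated_fsm_fraction": fsm_fraction,
        "species_specific_sensitivity": ss.sensitivity,
        "species_specific_fdr": ss.fdr,
        "canonicity_driven_sensitivity": ss.canonicity_sensitivity,
        "canonicity_driven_fdr": ss.canonicity_fdr,
        "ss_exon_sensitivity": exons.sensitivity,
        "ss_exon_fdr": exons.fdr,
        "alu_enrichment_or": exons.repeat_or,
        "diu_sensitivity": usg.diu_sensitivity,
        "diu_fdr": usg.diu_fdr,
        "deu_sensitivity": usg.deu_sensitivity,
        "deu_fdr": usg.deu_fdr,
        "rank_switch_sensitivity": usg.rank_sensitivity,
        "rank_switch_fdr": usg.rank_fdr,
        "peptide_gene_sensitivity": pep.sensitivity,
        "peptide_gene_fdr": pep.fdr,
        "confounded_genes": n_conf,
        "n_species_specific_called": sum(len(v) for v in ss.called.values()),
    }
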