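"""Download-free five-species synthetic fixture with a planted-event ledger.

The generator emulates the study design the pipeline targets: five primate
genomes (human H, chimpanzee C, gorilla G, orangutan O, macaque M) derived
from one ancestral sequence by neutral substitutions, a shared set of
projected transcript models, per-sample negative-binomial expression over
three replicates per species, and auxiliary tables (orthology map, repeats,
proteomes, protein domains).

Every event class the analyses are meant to recover can be planted with a
configurable count, and every planted event is written to a machine-readable
truth ledger keyed by the same feature identifiers the pipeline emits:

* species-specific transcript gains, a configurable subset driven by splice
  sites that are canonical only in the expressing species (the others use a
  species-specific junction with conserved canonicity);
* species-specific exonizations (unmappable in the other four assemblies,
  with sub-0.5 simulated alignment coverage), optionally overlapping a
  planted Alu repeat;
* differential isoform usage (DIU) shifts at constant gene totals;
* differential exonic-part usage (DEU) via transcript-mixture changes;
* dominant-isoform (rank-1) switches;
* genes absent from the reference proteome (peptide novelty).

Genomes are colinear across species (substitutions only, no indels), all
simulated genes sit on the plus strand, and simulated alignment coverage is
drawn rather than computed: the generator's contract is to exercise the
pipeline's decision rules, not to model a lift-over tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import Annotation, ExpressionMatrix, GenomeSet, TranscriptModel
from . import io as psio
from .proteomics import predict_orf, transcript_cdna

SPECIES = ("H", "C", "G", "O", "M")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimConfig:
    """Study conditions of the synthetic fixture.

    Defaults reproduce the default recovery fixture: 300 genes, 5 species x
    3 replicates, with 30 transcript gains (10 canonicity-driven), 15
    species-specific exons, 30 DIU shifts of 0.4, 40 DEU parts, 10 rank-1
    switches and 5 proteome-absent genes.
    """

    seed: int = 1
    n_genes: int = 300
    n_replicates: int = 3
    # gene architecture
    exon_count_range: tuple[int, int] = (5, 8)
    exon_length_range: tuple[int, int] = (90, 210)     # rounded to codons
    intron_length_range: tuple[int, int] = (150, 400)
    flank: int = 300
    substitution_rate: float = 0.003
    # expression model
    gene_mean_log2: float = 11.0        # ~2000 counts per gene and sample
    gene_sd_log2: float = 1.0
    nb_dispersion: float = 0.1
    usage_jitter_sd: float = 0.15       # logit-scale replicate usage noise
    batch_effect_sd: float = 0.0        # log2 multiplicative batch effect
    # planted events
    n_gain: int = 30
    n_gain_canonicity: int = 10         # subset of n_gain
    n_ss_exon: int = 15
    alu_fraction: float = 0.8
    n_diu: int = 30
    diu_delta: float = 0.4
    n_deu: int = 40
    n_rank_switch: int = 10
    n_novel_peptide: int = 5
    # planted usage levels
    gain_usage: float = 0.3
    diu_base_usage: float = 0.3
    deu_high_usage: float = 0.85
    deu_low_usage: float = 0.15
    rank_major_usage: float = 0.75

    def __post_init__(self):
        n_events = (
            self.n_gain + self.n_ss_exon + self.n_diu + self.n_deu
            + self.n_rank_switch + self.n_novel_peptide
        )
        if n_events > self.n_genes:
            raise ValueError(
                f"{n_events} planted events exceed {self.n_genes} genes"
            )
        if self.n_gain_canonicity > self.n_gain:
            raise ValueError("canonicity-driven gains exceed total gains")
        if not 0 < self.diu_delta < 1:
            raise ValueError("diu_delta must be in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("NB dispersion must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("exon_count_range", "exon_length_range", "intron_length_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class GeneSim:
    """Internal bookkeeping for one simulated gene."""

    gene_id: str
    chrom: str
    exons: list[tuple[int, int]]
    introns: list[tuple[int, int]]
    transcripts: dict[str, tuple[tuple[int, int], ...]]
    event: str = "background"           # background / gain / ss_exon / diu / ...
    focal: str = ""
    mechanism: str = ""
    skip_exon_index: int = -1           # internal exon skipped by the t2 variant
    gain_junction: tuple[int, int] | None = None
    ss_exon: tuple[int, int] | None = None
    usage: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class SimReference:
    config: SimConfig
    genomes: dict[str, GenomeSet]
    annotations: dict[str, Annotation]      # full projected models per species
    reference_annotation: dict[str, Annotation]  # pre-existing catalog (no planted novelty)
    orthology: pd.DataFrame
    repeats: pd.DataFrame
    domains: pd.DataFrame
    proteomes: dict[str, dict[str, str]]
    truth: pd.DataFrame
    genes: list[GeneSim]

    @property
    def gene_of(self) -> dict[str, str]:
        out = {}
        for g in self.genes:
            for tid in g.transcripts:
                out[tid] = g.gene_id
        return out

    @property
    def transcript_models(self) -> dict[str, TranscriptModel]:
        """Anchor-frame transcript models (coordinates shared by all species).

        The union over species: exonized transcripts are annotated only in
        their focal species but are quantified (at zero) everywhere.
        """
        out: dict[str, TranscriptModel] = {}
        for sp in SPECIES:
            for tid, t in self.annotations[sp].transcripts.items():
                out.setdefault(tid, t)
        return out


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _write(arr: np.ndarray, pos: int, s: str) -> None:
    arr[pos:pos + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)


def _plant_cds(arr: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> None:
    """Write an ATG...stop reading frame over ~60% of a transcript's spliced
    positions so every base model has a predictable ORF."""
    n = len(positions)
    cds_start = 9
    n_codons = max(55, int(0.6 * n) // 3)
    if cds_start + 3 * n_codons + 3 > n:
        n_codons = (n - cds_start - 3) // 3
    # keep the leader free of ATG
    _write_positions(arr, positions[:cds_start], "C" * cds_start)
    codons = []
    while len(codons) < n_codons - 1:
        c = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3))
        if c not in _STOPS:
            codons.append(c)
    frame = "ATG" + "".join(codons) + "TGA"
    _write_positions(arr, positions[cds_start:cds_start + len(frame)], frame)


def _write_positions(arr: np.ndarray, positions: np.ndarray, s: str) -> None:
    arr[positions] = np.frombuffer(s.encode(), dtype=np.uint8)


def simulate_reference(config: SimConfig) -> SimReference:
    """Build the five genomes, annotations and auxiliary tables."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    n = config.n_genes
    genes: list[GeneSim] = []

    # --- assign planted event classes to disjoint gene blocks
    order = rng.permutation(n)
    classes = (
        ["gain"] * config.n_gain
        + ["ss_exon"] * config.n_ss_exon
        + ["diu"] * config.n_diu
        + ["deu"] * config.n_deu
        + ["rank_switch"] * config.n_rank_switch
        + ["novel_peptide"] * config.n_novel_peptide
    )
    event_of = {}
    for gi, cls in zip(order, classes):
        event_of[int(gi)] = cls
    canonicity_set = set(order[: config.n_gain_canonicity].tolist())
    focal_cycle = rng.integers(0, len(SPECIES), size=n)

    ancestral: dict[str, np.ndarray] = {}
    locked: dict[str, np.ndarray] = {}
    overrides: dict[str, list[tuple[str, int, str]]] = {sp: [] for sp in SPECIES}
    truth_rows: list[dict] = []
    repeat_rows: list[dict] = []

    lo_ex, hi_ex = config.exon_count_range
    lo_el, hi_el = config.exon_length_range
    lo_il, hi_il = config.intron_length_range

    for gi in range(n):
        gene_id = f"g{gi:04d}"
        chrom = f"chr{gi:04d}"
        event = event_of.get(gi, "background")
        focal = SPECIES[focal_cycle[gi]]

        n_ex = int(rng.integers(lo_ex, hi_ex + 1))
        exon_lens = (rng.integers(lo_el // 3, hi_el // 3 + 1, size=n_ex) * 3).tolist()
        intron_lens = rng.integers(lo_il, hi_il + 1, size=n_ex - 1).tolist()
        # events needing room inside an intron
        if event in ("gain", "ss_exon"):
            intron_lens[1] = max(intron_lens[1], 260)

        exons, introns = [], []
        pos = config.flank
        for k in range(n_ex):
            exons.append((pos, pos + exon_lens[k]))
            pos += exon_lens[k]
            if k < n_ex - 1:
                introns.append((pos, pos + intron_lens[k]))
                pos += intron_lens[k]
        length = pos + config.flank

        arr = _random_seq(rng, length)
        lock = np.zeros(length, dtype=bool)
        for (istart, iend) in introns:
            _write(arr, istart, "GT")
            _write(arr, iend - 2, "AG")
            lock[istart:istart + 2] = True
            lock[iend - 2:iend] = True

        # base isoforms: t1 = all exons, t2 skips one internal exon
        skip_idx = int(rng.integers(1, n_ex - 1))
        t1 = tuple(exons)
        t2 = tuple(e for k, e in enumerate(exons) if k != skip_idx)
        tids = {f"{gene_id}t1": t1, f"{gene_id}t2": t2}

        g = GeneSim(gene_id, chrom, exons, introns, tids, event, focal,
                    skip_exon_index=skip_idx)

        if event == "gain":
            # extend exon 1 into intron 1 -> novel donor (past the 30-nt
            # near-identity window of the quantification-ambiguity filter)
            ext = 45
            e1s, e1e = exons[1]
            i1s, i1e = introns[1]
            new_exons = list(exons)
            new_exons[1] = (e1s, e1e + ext)
            tid = f"{gene_id}tG"
            tids[tid] = tuple(new_exons)
            g.gain_junction = (e1e + ext, i1e)
            donor_pos = e1e + ext
            lock[donor_pos:donor_pos + 2] = True
            mech = "canonicity" if gi in canonicity_set else "ss_junction"
            g.mechanism = mech
            if mech == "canonicity":
                for sp in SPECIES:
                    overrides[sp].append((chrom, donor_pos, "GT" if sp == focal else "CA"))
            else:
                _write(arr, donor_pos, "GT")
            truth_rows.append(
                {"event_class": "species_specific_transcript", "gene_id": gene_id,
                 "feature_id": tid, "focal_species": focal,
                 "effect": config.gain_usage, "mechanism": mech}
            )
            if mech == "canonicity":
                truth_rows.append(
                    {"event_class": "canonicity_change", "gene_id": gene_id,
                     "feature_id": f"{gene_id}:J{donor_pos}-{i1e}",
                     "focal_species": focal, "effect": np.nan, "mechanism": "donor"}
                )
        elif event == "ss_exon":
            i1s, i1e = introns[1]
            nes = i1s + 60
            nee = nes + 90
            g.ss_exon = (nes, nee)
            _write(arr, nes - 2, "AG")
            _write(arr, nee, "GT")
            lock[nes - 2:nes] = True
            lock[nee:nee + 2] = True
            new_exons = sorted(exons + [(nes, nee)])
            tid = f"{gene_id}tX"
            tids[tid] = tuple(new_exons)
            g.mechanism = "exonization"
            truth_rows.append(
                {"event_class": "species_specific_transcript", "gene_id": gene_id,
                 "feature_id": tid, "focal_species": focal,
                 "effect": config.gain_usage, "mechanism": "exonization"}
            )
            truth_rows.append(
                {"event_class": "species_specific_exon", "gene_id": gene_id,
                 "feature_id": f"{gene_id}:ssx", "focal_species": focal,
                 "effect": np.nan, "mechanism": "exonization"}
            )
            if rng.random() < config.alu_fraction:
                repeat_rows.append(
                    {"chrom": chrom, "start": nes - 20, "end": nee + 20,
                     "name": "Alu", "score": 0, "strand": "+"}
                )
        elif event == "diu":
            truth_rows.append(
                {"event_class": "diu", "gene_id": gene_id,
                 "feature_id": f"{gene_id}t1", "focal_species": focal,
                 "effect": config.diu_delta, "mechanism": "usage_shift"}
            )
        elif event == "deu":
            part = exons[skip_idx]
            truth_rows.append(
                {"event_class": "deu", "gene_id": gene_id,
                 "feature_id": f"{gene_id}:part:{part[0]}-{part[1]}",
                 "focal_species": focal,
                 "effect": config.deu_high_usage - config.deu_low_usage,
                 "mechanism": "mixture_shift"}
            )
        elif event == "rank_switch":
            truth_rows.append(
                {"event_class": "rank_switch", "gene_id": gene_id,
                 "feature_id": f"{gene_id}t2", "focal_species": focal,
                 "effect": np.nan, "mechanism": "dominance_switch"}
            )
        elif event == "novel_peptide":
            truth_rows.append(
                {"event_class": "novel_peptide_gene", "gene_id": gene_id,
                 "feature_id": gene_id, "focal_species": "",
                 "effect": np.nan, "mechanism": "unannotated_gene"}
            )

        # plant a clean reading frame on the full-length isoform
        t1_positions = np.concatenate(
            [np.arange(s, e) for s, e in tids[f"{gene_id}t1"]]
        )
        _plant_cds(arr, t1_positions, rng)

        # occasional background repeat away from exons
        if config.flank > 170 and rng.random() < 0.3:
            rstart = int(rng.integers(0, config.flank - 160))
            family = ["L1", "MIR", "LTR"][int(rng.integers(0, 3))]
            repeat_rows.append(
                {"chrom": chrom, "start": rstart, "end": rstart + 150,
                 "name": family, "score": 0, "strand": "+"}
            )
        # rare ancient exonized Alu overlapping a conserved exon, so repeat
        # enrichment of new exons is tested against a nonzero background rate
        if rng.random() < 0.05:
            k = int(rng.integers(0, n_ex))
            repeat_rows.append(
                {"chrom": chrom, "start": max(0, exons[k][1] - 30),
                 "end": exons[k][1] + 60, "name": "Alu", "score": 0,
                 "strand": "+"}
            )

        ancestral[chrom] = arr
        locked[chrom] = lock
        genes.append(g)

    # --- species genomes: neutral substitutions away from locked positions
    genomes = {}
    for sp in SPECIES:
        seqs = {}
        for chrom, arr in ancestral.items():
            derived = arr.copy()
            mask = (rng.random(len(arr)) < config.substitution_rate) & ~locked[chrom]
            idx = np.nonzero(mask)[0]
            if len(idx):
                shift = rng.integers(1, 4, size=len(idx))
                cur = np.searchsorted(_BASES, derived[idx])
                derived[idx] = _BASES[(cur + shift) % 4]
            seqs[chrom] = derived.tobytes().decode()
        for chrom, pos, s in overrides[sp]:
            seq = seqs[chrom]
            seqs[chrom] = seq[:pos] + s + seq[pos + len(s):]
        genomes[sp] = GenomeSet(sp, seqs)

    # --- annotations: shared projected models; planted exonizations focal-only
    annotations = {}
    reference_annotation = {}
    for sp in SPECIES:
        models, ref_models = [], []
        for g in genes:
            for tid, exs in g.transcripts.items():
                t = TranscriptModel(tid, g.gene_id, sp, g.chrom, "+", exs)
                novel = tid.endswith(("tG", "tX"))
                if tid.endswith("tX") and sp != g.focal:
                    continue
                models.append(t)
                if not novel:
                    ref_models.append(t)
        annotations[sp] = Annotation(sp, models)
        reference_annotation[sp] = Annotation(sp, ref_models)

    # --- orthology map: exon + junction features, colinear coordinates
    orth_rows = []
    for g in genes:
        for k, (s, e) in enumerate(g.exons):
            fid = f"{g.gene_id}:exon{k}"
            for sp in SPECIES:
                orth_rows.append(
                    {"feature_id": fid, "feature_type": "exon", "species": sp,
                     "home_species": SPECIES[0], "status": "MAPPED",
                     "chrom": g.chrom, "strand": "+", "start": s, "end": e,
                     "coverage": 1.0}
                )
        if g.ss_exon is not None:
            s, e = g.ss_exon
            fid = f"{g.gene_id}:ssx"
            for sp in SPECIES:
                mapped = sp == g.focal
                orth_rows.append(
                    {"feature_id": fid, "feature_type": "exon", "species": sp,
                     "home_species": g.focal,
                     "status": "MAPPED" if mapped else "UNMAPPED",
                     "chrom": g.chrom, "strand": "+", "start": s, "end": e,
                     "coverage": 1.0 if mapped else float(rng.uniform(0, 0.45))}
                )
        juncs = set()
        for exs in g.transcripts.values():
            t = TranscriptModel("tmp", g.gene_id, "anc", g.chrom, "+", exs)
            juncs.update(t.introns)
        for (s, e) in sorted(juncs):
            fid = f"{g.gene_id}:J{s}-{e}"
            for sp in SPECIES:
                orth_rows.append(
                    {"feature_id": fid, "feature_type": "junction", "species": sp,
                     "home_species": SPECIES[0], "status": "MAPPED",
                     "chrom": g.chrom, "strand": "+", "start": s, "end": e,
                     "coverage": 1.0}
                )
    orthology = pd.DataFrame(orth_rows)

    repeats = pd.DataFrame(
        repeat_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )

    # --- usage vectors per species
    for g in genes:
        t1, t2 = f"{g.gene_id}t1", f"{g.gene_id}t2"
        base_major = float(rng.uniform(0.55, 0.8))
        usage = {}
        for sp in SPECIES:
            if g.event == "diu":
                u1 = config.diu_base_usage + (config.diu_delta if sp == g.focal else 0.0)
                usage[sp] = {t1: u1, t2: 1 - u1}
            elif g.event == "deu":
                u1 = config.deu_low_usage if sp == g.focal else config.deu_high_usage
                usage[sp] = {t1: u1, t2: 1 - u1}
            elif g.event == "rank_switch":
                u1 = (1 - config.rank_major_usage) if sp == g.focal else config.rank_major_usage
                usage[sp] = {t1: u1, t2: 1 - u1}
            elif g.event in ("gain", "ss_exon"):
                tg = f"{g.gene_id}tG" if g.event == "gain" else f"{g.gene_id}tX"
                if sp == g.focal:
                    scale = 1 - config.gain_usage
                    usage[sp] = {t1: base_major * scale, t2: (1 - base_major) * scale,
                                 tg: config.gain_usage}
                else:
                    usage[sp] = {t1: base_major, t2: 1 - base_major, tg: 0.0}
            else:
                usage[sp] = {t1: base_major, t2: 1 - base_major}
        g.usage = usage

    # --- protein domain table and per-species proteomes
    domain_rows = []
    proteomes: dict[str, dict[str, str]] = {sp: {} for sp in SPECIES}
    novel_genes = {g.gene_id for g in genes if g.event == "novel_peptide"}
    for g in genes:
        for tid in sorted(g.transcripts):
            combo = f"{g.gene_id}:A,{g.gene_id}:B" if tid.endswith("t1") else f"{g.gene_id}:A"
            domain_rows.append({"transcript_id": tid, "gene_id": g.gene_id, "domains": combo})
    for sp in SPECIES:
        ann = annotations[sp]
        for tid in sorted(ann.transcripts):
            t = ann.transcripts[tid]
            if t.gene_id in novel_genes:
                continue
            orf = predict_orf(transcript_cdna(t, genomes[sp]), tid)
            if orf is not None:
                proteomes[sp][f"{tid}_prot"] = orf.protein
    domains = pd.DataFrame(domain_rows)

    truth = pd.DataFrame(
        truth_rows,
        columns=["event_class", "gene_id", "feature_id", "focal_species",
                 "effect", "mechanism"],
    ).sort_values(["event_class", "gene_id"], kind="mergesort").reset_index(drop=True)

    return SimReference(config, genomes, annotations, reference_annotation,
                        orthology, repeats, domains, proteomes, truth, genes)


def simulate_expression(
    ref: SimReference, n_replicates: int | None = None
) -> ExpressionMatrix:
    """Draw counts and TPM for the replicate design.

    Per sample and gene, a negative-binomial total (gene-level biological
    variability) is allocated to the gene's transcripts by a multinomial
    draw under the species' usage vector with logit-normal replicate jitter.
    Planted gains have usage exactly zero outside the focal species, so
    their counts are exactly zero there. TPM divides counts by transcript
    length (no fragment-length model) and rescales to one million.
    """
    config = ref.config
    n_rep = n_replicates or config.n_replicates
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 1, int(n_rep)])
    )
    models = ref.transcript_models
    tids = sorted(models)
    lengths = np.array([models[t].length for t in tids], float)
    gene_means = 2.0 ** rng.normal(config.gene_mean_log2, config.gene_sd_log2,
                                   size=len(ref.genes))

    samples, meta_rows = [], []
    for sp in SPECIES:
        for r in range(n_rep):
            sid = f"{sp}{r + 1}"
            samples.append(sid)
            meta_rows.append(
                {"sample_id": sid, "species": sp, "replicate": r + 1,
                 "batch": f"b{r + 1}"}
            )
    metadata = pd.DataFrame(meta_rows)

    if config.batch_effect_sd > 0:
        batch_fac = {
            (f"b{r + 1}", gi): 2.0 ** rng.normal(0, config.batch_effect_sd)
            for r in range(n_rep) for gi in range(len(ref.genes))
        }
    else:
        batch_fac = None

    counts = np.zeros((len(tids), len(samples)), dtype=float)
    index_of = {t: i for i, t in enumerate(tids)}
    disp = config.nb_dispersion
    nb_n = 1.0 / disp
    for si, sid in enumerate(samples):
        sp = metadata.loc[si, "species"]
        batch = metadata.loc[si, "batch"]
        for gi, g in enumerate(ref.genes):
            mu = gene_means[gi]
            if batch_fac is not None:
                mu *= batch_fac[(batch, gi)]
            total = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))
            u = g.usage[sp]
            keys = sorted(u)
            w = np.array([u[k] for k in keys], float)
            pos = w > 0
            if pos.any() and total > 0:
                jitter = np.exp(rng.normal(0, config.usage_jitter_sd, size=pos.sum()))
                wj = w[pos] * jitter
                wj /= wj.sum()
                alloc = rng.multinomial(total, wj)
                for k, c in zip(np.array(keys)[pos], alloc):
                    counts[index_of[k], si] = c

    counts_df = pd.DataFrame(counts, index=tids, columns=samples)
    rate = counts_df.div(lengths, axis=0)
    tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
    return ExpressionMatrix(tpm=tpm, samples=metadata, counts=counts_df)


def emit_fixture(config: SimConfig, out_dir, force: bool = False) -> SimReference:
    """Write every interface file the pipeline consumes, plus truth TSVs."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    ref = simulate_reference(config)
    expr = simulate_expression(ref)

    for sp in SPECIES:
        psio.write_genome(ref.genomes[sp], out / f"genome_{sp}.fa")
        psio.write_annotation(ref.annotations[sp], out / f"models_{sp}.gtf")
        psio.write_annotation(ref.reference_annotation[sp], out / f"reference_{sp}.gtf")
        psio.write_proteome(ref.proteomes[sp], out / f"proteome_{sp}.fa")
    ref.orthology.to_csv(out / "orthology.tsv", sep="\t", index=False)
    psio.write_bed(ref.repeats, out / "repeats.bed")
    ref.domains.to_csv(out / "domains.tsv", sep="\t", index=False)
    ref.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    expr.samples.to_csv(out / "metadata.tsv", sep="\t", index=False)
    for sid in expr.tpm.columns:
        tab = pd.DataFrame(
            {"target_id": expr.tpm.index,
             "est_counts": expr.counts[sid].to_numpy(),
             "tpm": expr.tpm[sid].to_numpy()}
        )
        tab.to_csv(out / f"abundance_{sid}.tsv", sep="\t", index=False)
    config.to_yaml(out / "config.yaml")
    return ref
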