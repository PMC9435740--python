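"""Expression normalization and isoform/exon usage dynamics.

Isoform usage (IU) is the fraction a transcript contributes to its gene's
total abundance in one sample; exonic-part usage coefficients are the
analogous fractions over a gene's exonic parts. Between-sample composition
bias in count data is corrected by trimmed-mean-of-M-values (TMM)
normalization. Species-specific differential isoform usage (DIU) and
differential exonic-part usage (DEU) are called from all ten pairwise
species comparisons of logit-transformed usage, with a consistency rule:
a feature is species-specific for species S when every comparison involving
S is significant with a consistent direction and no comparison among the
remaining species is.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import ExpressionMatrix, TranscriptModel, ValidationError
from .stats import bh_adjust

LOGIT_EPS = 0.01


def tmm_normalize(
    counts: pd.DataFrame,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> tuple[pd.Series, pd.DataFrame]:
    """TMM scaling factors and the normalized count matrix.

    The reference sample is the one whose upper quartile of library-size-
    scaled nonzero counts lies closest to the mean upper quartile. For each
    sample, per-gene M (log2 expression ratio to the reference) and A (mean
    log2 abundance) are computed on doubly-positive genes; the most extreme
    ``trim_m`` of M values and ``trim_a`` of A values are removed from each
    tail, and the factor is 2 to the precision-weighted mean of the retained
    M values (weights from the binomial delta-method variance). Factors are
    rescaled to geometric mean one; normalized counts divide each column by
    (library size x factor), rescaled to the mean library size.
    """
    if counts.shape[1] < 2:
        raise ValidationError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValidationError("sample with all-zero counts")
    scaled = counts.div(lib, axis=1)
    uq = scaled.apply(lambda col: np.quantile(col[col > 0], 0.75))
    ref = (uq - uq.mean()).abs().idxmin()
    r = counts[ref].to_numpy(float)
    nr = lib[ref]
    factors = {}
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        x = counts[s].to_numpy(float)
        n = lib[s]
        ok = (x > 0) & (r > 0)
        xs, rs = x[ok], r[ok]
        m = np.log2((xs / n) / (rs / nr))
        a = 0.5 * np.log2((xs / n) * (rs / nr))
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            factors[s] = 1.0
            continue
        w = 1.0 / ((n - xs[keep]) / (n * xs[keep]) + (nr - rs[keep]) / (nr * rs[keep]))
        factors[s] = float(2 ** (np.sum(w * m[keep]) / np.sum(w)))
    f = pd.Series(factors)[counts.columns]
    f = f / np.exp(np.log(f).mean())
    eff = lib * f
    norm = counts.div(eff, axis=1) * lib.mean()
    return f, norm


def batch_correct(log_expr: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-batch median-centering of log-scale expression (per feature).

    A deliberately simple location correction applied when the metadata
    carries more than one batch label; it removes additive batch offsets and
    nothing else.
    """
    if "batch" not in metadata.columns or metadata["batch"].nunique() <= 1:
        return log_expr
    out = log_expr.copy()
    batch_of = dict(zip(metadata["sample_id"], metadata["batch"]))
    grand = log_expr.median(axis=1)
    for batch in sorted(set(batch_of.values())):
        cols = [s for s in log_expr.columns if batch_of.get(s) == batch]
        offset = log_expr[cols].median(axis=1) - grand
        out[cols] = log_expr[cols].sub(offset, axis=0)
    return out


def compute_iu(expr: pd.DataFrame, gene_of: dict[str, str]) -> pd.DataFrame:
    """Isoform-usage fractions: expr / per-gene column totals; NaN when a
    gene's total is zero in a sample."""
    missing = [t for t in expr.index if t not in gene_of]
    if missing:
        raise ValidationError(f"transcripts without gene assignment: {missing[:5]}")
    genes = pd.Series({t: gene_of[t] for t in expr.index})
    totals = expr.groupby(genes).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        iu = expr / totals
    return iu.where(totals > 0)


def flag_ambiguous_genes(
    transcripts_by_gene: dict[str, list[TranscriptModel]], shift_max: int = 30
) -> dict[str, bool]:
    """Flag genes containing near-identical transcript pairs.

    A pair is ambiguous for quantification when both have the same number of
    introns and corresponding intron boundaries all lie within ``shift_max``
    nucleotides (no junction gained or lost) — including exact duplicates.
    """
    out = {}
    for gene, ts in transcripts_by_gene.items():
        flagged = False
        for a, b in itertools.combinations(ts, 2):
            ia, ib = a.introns, b.introns
            if len(ia) != len(ib) or len(ia) == 0:
                if a.exons == b.exons:
                    flagged = True
                    break
                continue
            if all(
                abs(x[0] - y[0]) <= shift_max and abs(x[1] - y[1]) <= shift_max
                for x, y in zip(ia, ib)
            ):
                flagged = True
                break
        out[gene] = flagged
    return out


@dataclass
class DominanceRecord:
    gene_id: str
    rank1: dict[str, str]
    rank2: dict[str, str | None]
    rank_fc: dict[str, float]
    shared_rank1: bool
    shared_orf: bool | None = None
    shared_domains: bool | None = None


def rank_dominance(
    iu: pd.DataFrame,
    expr: pd.DataFrame,
    gene_of: dict[str, str],
    metadata: pd.DataFrame,
    orf_proteins: dict[str, str] | None = None,
    domain_combinations: dict[str, tuple] | None = None,
) -> list[DominanceRecord]:
    """Rank transcripts by mean IU per species; find shared dominance.

    Rank ties are broken by higher total expression, then lexicographic
    transcript id. ``rank_fc`` stores the rank-1/rank-2 mean expression fold
    change per species (inf for single-isoform species).
    """
    species = []
    for sp in metadata["species"]:
        if sp not in species:
            species.append(sp)
    samples_of = {
        sp: [s for s in metadata.loc[metadata["species"] == sp, "sample_id"] if s in iu.columns]
        for sp in species
    }
    total_expr = expr.sum(axis=1)
    by_gene: dict[str, list[str]] = {}
    for t in iu.index:
        by_gene.setdefault(gene_of[t], []).append(t)
    records = []
    for gene in sorted(by_gene):
        tids = by_gene[gene]
        rank1, rank2, fc = {}, {}, {}
        for sp in species:
            mean_iu = iu.loc[tids, samples_of[sp]].mean(axis=1)
            mean_expr = expr.loc[tids, samples_of[sp]].mean(axis=1)
            order = sorted(
                tids,
                key=lambda t: (-np.nan_to_num(mean_iu[t]), -total_expr[t], t),
            )
            rank1[sp] = order[0]
            rank2[sp] = order[1] if len(order) > 1 else None
            if rank2[sp] is not None and mean_expr[order[1]] > 0:
                fc[sp] = float(mean_expr[order[0]] / mean_expr[order[1]])
            else:
                fc[sp] = float("inf")
        shared = len(set(rank1.values())) == 1
        shared_orf = shared_dom = None
        if orf_proteins is not None:
            prots = {orf_proteins.get(rank1[sp]) for sp in species}
            shared_orf = len(prots) == 1 and None not in prots
        if domain_combinations is not None:
            combos = {domain_combinations.get(rank1[sp]) for sp in species}
            shared_dom = len(combos) == 1 and None not in combos
        records.append(DominanceRecord(gene, rank1, rank2, fc, shared, shared_orf, shared_dom))
    return records


def dominance_sharing_curve(
    records: list[DominanceRecord], fc_thresholds=(1.0, 1.5, 2.0, 3.0, 5.0)
) -> pd.DataFrame:
    """Fraction of genes with a shared rank-1 isoform, restricted to genes
    whose rank-1/rank-2 fold change exceeds each threshold in every species."""
    rows = []
    for thr in fc_thresholds:
        eligible = [r for r in records if all(v >= thr for v in r.rank_fc.values())]
        shared = sum(r.shared_rank1 for r in eligible)
        rows.append(
            {"fc_threshold": thr, "n_genes": len(eligible),
             "fraction_shared": shared / len(eligible) if eligible else np.nan}
        )
    return pd.DataFrame(rows)


def _logit_usage(u: np.ndarray) -> np.ndarray:
    clipped = np.clip(u, LOGIT_EPS, 1 - LOGIT_EPS)
    return np.log(clipped / (1 - clipped))


def expression_filter(
    expr: pd.DataFrame,
    gene_of: dict[str, str],
    metadata: pd.DataFrame,
    gene_min_tpm: float = 1.0,
    min_samples: int = 2,
) -> pd.Series:
    """Features eligible for usage testing: gene expressed (TPM >= gene_min in
    >= min_samples per species) and feature nonzero in >= min_samples of at
    least one species."""
    genes = pd.Series({t: gene_of[t] for t in expr.index})
    gene_tot = expr.groupby(genes).transform("sum")
    sp_groups = metadata.groupby("species")["sample_id"].apply(list)
    gene_ok = pd.Series(True, index=expr.index)
    feat_ok = pd.Series(False, index=expr.index)
    for sp, samples in sp_groups.items():
        samples = [s for s in samples if s in expr.columns]
        gene_ok &= (gene_tot[samples] >= gene_min_tpm).sum(axis=1) >= min_samples
        feat_ok |= (expr[samples] > 0).sum(axis=1) >= min_samples
    return gene_ok & feat_ok


def test_species_specific_usage(
    usage: pd.DataFrame,
    metadata: pd.DataFrame,
    fdr: float = 0.05,
    method: str = "welch",
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pairwise species comparisons of usage with a species-specific call.

    For every feature and every pair of species, a two-sided test on
    logit-transformed usage across replicates (Welch t by default, or a
    permutation test on the mean difference); p-values are BH-adjusted
    across features within each pair. Feature rows with fewer than two
    non-missing replicates in a group are skipped for that pair. The final
    call is ``up``/``down`` for species S when all comparisons involving S
    are significant with the sign of S's offset agreeing, and no comparison
    among the other species is significant.
    """
    species = []
    for sp in metadata["species"]:
        if sp not in species:
            species.append(sp)
    samples_of = {
        sp: [s for s in metadata.loc[metadata["species"] == sp, "sample_id"] if s in usage.columns]
        for sp in species
    }
    pairs = list(itertools.combinations(species, 2))
    pvals = pd.DataFrame(np.nan, index=usage.index, columns=[f"{a}|{b}" for a, b in pairs])
    delta = pd.DataFrame(np.nan, index=usage.index, columns=pvals.columns)
    if method == "permutation" and rng is None:
        rng = np.random.default_rng(0)
    for a, b in pairs:
        xa = usage[samples_of[a]].to_numpy(float)
        xb = usage[samples_of[b]].to_numpy(float)
        la, lb = _logit_usage(xa), _logit_usage(xb)
        la[np.isnan(xa)] = np.nan
        lb[np.isnan(xb)] = np.nan
        na = np.sum(~np.isnan(la), axis=1)
        nb = np.sum(~np.isnan(lb), axis=1)
        ok = (na >= 2) & (nb >= 2)
        col = f"{a}|{b}"
        if method == "welch":
            import warnings

            with np.errstate(invalid="ignore"), warnings.catch_warnings():
                # zero-variance rows (constant usage) yield NaN p-values, which
                # is the wanted outcome; silence scipy's precision warning
                warnings.simplefilter("ignore", RuntimeWarning)
                res = sps.ttest_ind(la, lb, axis=1, equal_var=False, nan_policy="omit")
            p = np.asarray(res.pvalue, float)
        elif method == "permutation":
            p = np.full(len(usage), np.nan)
            both = np.concatenate([la, lb], axis=1)
            for i in np.nonzero(ok)[0]:
                vals = both[i][~np.isnan(both[i])]
                n_a = int(na[i])
                obs = abs(np.nanmean(la[i]) - np.nanmean(lb[i]))
                cnt = 0
                for _ in range(n_permutations):
                    perm = rng.permutation(vals)
                    d = abs(perm[:n_a].mean() - perm[n_a:].mean())
                    if d >= obs - 1e-12:
                        cnt += 1
                p[i] = (cnt + 1) / (n_permutations + 1)
        else:
            raise ValueError(f"unknown method {method}")
        p[~ok] = np.nan
        pvals[col] = p
        with np.errstate(invalid="ignore"):
            delta[col] = np.nanmean(la, axis=1) - np.nanmean(lb, axis=1)
    padj = pvals.apply(lambda col: pd.Series(bh_adjust(col.to_numpy()), index=col.index))
    sig = padj < fdr

    calls, focal_col = [], []
    for i in range(len(usage)):
        call, focal = "none", ""
        for sp in species:
            inv = [c for c in pvals.columns if sp in c.split("|")]
            othr = [c for c in pvals.columns if sp not in c.split("|")]
            row_sig = sig.iloc[i]
            if not all(row_sig.get(c, False) for c in inv):
                continue
            if any(row_sig.get(c, False) for c in othr):
                continue
            signs = []
            for c in inv:
                a, b = c.split("|")
                d = delta.iloc[i][c]
                signs.append(np.sign(d) if a == sp else -np.sign(d))
            if all(s > 0 for s in signs):
                call, focal = "up", sp
            elif all(s < 0 for s in signs):
                call, focal = "down", sp
            break
        calls.append(call)
        focal_col.append(focal)

    out = pd.DataFrame(index=usage.index)
    for c in pvals.columns:
        out[f"p_{c}"] = pvals[c]
        out[f"padj_{c}"] = padj[c]
    out["call"] = calls
    out["focal_species"] = focal_col
    for sp in species:
        out[f"mean_usage_{sp}"] = usage[samples_of[sp]].mean(axis=1)
    return out


def exonic_part_usage(part_counts: pd.DataFrame, gene_of: dict[str, str]) -> pd.DataFrame:
    """Usage coefficients of exonic parts: per-sample fraction of the gene's
    total part counts; NaN where the gene total is zero."""
    return compute_iu(part_counts, gene_of)


def inclusion_fraction(
    part_usage: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Mean usage per species (the descriptive per-part inclusion fraction)."""
    out = {}
    for sp, grp in metadata.groupby("species"):
        cols = [s for s in grp["sample_id"] if s in part_usage.columns]
        out[sp] = part_usage[cols].mean(axis=1)
    return pd.DataFrame(out)
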