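"""TMM normalization, isoform usage, DIU/DEU testing and dominance."""

import numpy as np
import pandas as pd
import pytest

from primatesplice.models import TranscriptModel, ValidationError
from primatesplice.usage import (
    batch_correct,
    compute_iu,
    dominance_sharing_curve,
    exonic_part_usage,
    expression_filter,
    flag_ambiguous_genes,
    inclusion_fraction,
    rank_dominance,
    tmm_normalize,
)
from primatesplice.usage import test_species_specific_usage as usage_test
from oracles import tmm_straight_line

SPECIES = ["H", "C", "G", "O", "M"]


def _meta(n_rep=3, species=SPECIES):
    return pd.DataFrame(
        [{"sample_id": f"{sp}{r + 1}", "species": sp, "replicate": r + 1,
          "batch": "b1"} for sp in species for r in range(n_rep)]
    )


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 40, 7, 300, 25, 90],
                               "b": [10, 40, 7, 300, 25, 90]})
        f, _ = tmm_normalize(counts)
        assert np.allclose(f, 1.0)

    def test_pure_depth_difference_gives_unit_factors(self):
        col = np.array([10, 40, 7, 300, 25, 90])
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        f, _ = tmm_normalize(counts)
        assert np.allclose(f, 1.0)

    def test_factors_multiply_to_one(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(rng.integers(1, 500, size=(30, 5)))
        f, _ = tmm_normalize(counts)
        assert np.isclose(np.prod(f), 1.0)

    def test_matches_straight_line_oracle(self):
        """Factors equal an independent step-by-step computation within 1e-9
        on random small count matrices."""
        rng = np.random.default_rng(10)
        for _ in range(30):
            n_g = int(rng.integers(8, 21))
            n_s = int(rng.integers(2, 7))
            counts = rng.integers(0, 400, size=(n_g, n_s)).astype(float)
            counts[rng.random(counts.shape) < 0.1] = 0
            counts[0] = rng.integers(1, 400, size=n_s)   # keep libraries nonzero
            df = pd.DataFrame(counts)
            f, _ = tmm_normalize(df)
            expected = tmm_straight_line(counts)
            assert np.max(np.abs(f.to_numpy() - expected)) < 1e-9

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValidationError):
            tmm_normalize(counts)

    def test_composition_bias_detected(self):
        # one hugely inflated gene should not drag the factor with it
        col = np.array([50, 60, 40, 55, 45, 50, 65, 35, 50, 52], float)
        inflated = col.copy()
        inflated[0] *= 10
        counts = pd.DataFrame({"a": col, "b": inflated})
        _, norm = tmm_normalize(counts)
        # the inflated gene is trimmed away, so the effective library sizes
        # line the other genes back up between samples
        ratio = norm.iloc[1:]["b"] / norm.iloc[1:]["a"]
        assert np.allclose(ratio, ratio.iloc[0])
        assert abs(np.log2(ratio.iloc[0])) < 0.05


class TestIU:
    def test_fractions_within_gene(self):
        expr = pd.DataFrame({"s1": [6.0, 2.0]}, index=["t1", "t2"])
        iu = compute_iu(expr, {"t1": "g1", "t2": "g1"})
        assert iu["s1"].tolist() == [0.75, 0.25]

    def test_zero_gene_total_is_missing(self):
        expr = pd.DataFrame({"s1": [0.0, 0.0]}, index=["t1", "t2"])
        iu = compute_iu(expr, {"t1": "g1", "t2": "g1"})
        assert iu["s1"].isna().all()

    def test_single_transcript_gene_has_iu_one(self):
        expr = pd.DataFrame({"s1": [4.0]}, index=["t1"])
        assert compute_iu(expr, {"t1": "g1"})["s1"].iloc[0] == 1.0

    def test_unassigned_transcript_rejected(self):
        expr = pd.DataFrame({"s1": [4.0]}, index=["t1"])
        with pytest.raises(ValidationError):
            compute_iu(expr, {})

    def test_iu_sums_to_one_where_defined(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.random((12, 6)), index=[f"t{i}" for i in range(12)])
        gene_of = {f"t{i}": f"g{i % 4}" for i in range(12)}
        iu = compute_iu(expr, gene_of)
        sums = iu.groupby(pd.Series(gene_of)).sum()
        assert np.allclose(sums.to_numpy(), 1.0)


def T(tid, exons):
    return TranscriptModel(tid, "g1", "H", "chr1", "+", tuple(exons))


class TestAmbiguityFlag:
    def test_small_internal_shift_flagged(self):
        a = T("a", [(0, 100), (200, 300), (400, 500)])
        b = T("b", [(0, 100), (209, 300), (400, 500)])   # 9-nt acceptor shift
        assert flag_ambiguous_genes({"g1": [a, b]})["g1"]

    def test_skipped_exon_not_flagged(self):
        a = T("a", [(0, 100), (200, 300), (400, 500)])
        b = T("b", [(0, 100), (400, 500)])
        assert not flag_ambiguous_genes({"g1": [a, b]})["g1"]

    def test_exact_duplicate_flagged(self):
        a = T("a", [(0, 100), (200, 300)])
        b = T("b", [(0, 100), (200, 300)])
        assert flag_ambiguous_genes({"g1": [a, b]})["g1"]

    def test_large_shift_not_flagged(self):
        a = T("a", [(0, 100), (200, 300), (400, 500)])
        b = T("b", [(0, 100), (250, 300), (400, 500)])   # 50 nt > default 30
        assert not flag_ambiguous_genes({"g1": [a, b]})["g1"]


class TestDominance:
    @staticmethod
    def _iu(values_by_species, n_rep=3):
        meta = _meta(n_rep)
        cols = {}
        for sp in SPECIES:
            for r in range(n_rep):
                cols[f"{sp}{r + 1}"] = values_by_species[sp]
        tids = [f"t{i}" for i in range(len(next(iter(values_by_species.values()))))]
        return pd.DataFrame(cols, index=tids), meta

    def test_identical_profiles_share_rank1(self):
        iu, meta = self._iu({sp: [0.7, 0.3] for sp in SPECIES})
        recs = rank_dominance(iu, iu * 10, {"t0": "g1", "t1": "g1"}, meta)
        assert recs[0].shared_rank1

    def test_switch_in_one_species_detected(self):
        vals = {sp: [0.7, 0.3] for sp in SPECIES}
        vals["G"] = [0.3, 0.7]
        iu, meta = self._iu(vals)
        recs = rank_dominance(iu, iu * 10, {"t0": "g1", "t1": "g1"}, meta)
        assert not recs[0].shared_rank1
        assert recs[0].rank1["G"] == "t1" and recs[0].rank1["H"] == "t0"

    def test_rank_tie_broken_by_expression_then_name(self):
        iu, meta = self._iu({sp: [0.5, 0.5] for sp in SPECIES})
        expr = iu.copy()
        expr.loc["t1"] *= 3            # higher absolute expression wins the tie
        recs = rank_dominance(iu, expr, {"t0": "g1", "t1": "g1"}, meta)
        assert recs[0].rank1["H"] == "t1"

    def test_sharing_curve_monotone_on_conserved_fixture(self):
        rng = np.random.default_rng(6)
        gene_of, frames = {}, {}
        meta = _meta()
        for sid in meta["sample_id"]:
            frames[sid] = []
        tids = []
        for g in range(30):
            u = rng.uniform(0.5, 0.95)
            for k, frac in enumerate([u, 1 - u]):
                tids.append(f"g{g}_t{k}")
                gene_of[f"g{g}_t{k}"] = f"g{g}"
                for sid in meta["sample_id"]:
                    frames[sid].append(np.clip(frac + rng.normal(0, 0.05), 0.01, 0.99))
        iu = pd.DataFrame(frames, index=tids)
        recs = rank_dominance(iu, iu * 100, gene_of, meta)
        curve = dominance_sharing_curve(recs, fc_thresholds=(1.0, 1.5, 2.0, 3.0))
        fractions = curve["fraction_shared"].dropna().to_numpy()
        assert (np.diff(fractions) >= -1e-12).all()


class TestUsageTesting:
    @staticmethod
    def _usage(shift_species=None, delta=0.4, n_rep=6, n_feat=20, seed=0):
        rng = np.random.default_rng(seed)
        meta = _meta(n_rep)
        base = 0.3
        rows = {}
        for i in range(n_feat):
            vals = {}
            for sp in SPECIES:
                mu = base + (delta if sp == shift_species and i == 0 else 0.0)
                vals[sp] = np.clip(mu + rng.normal(0, 0.05, n_rep), 0.01, 0.99)
            rows[f"f{i}"] = np.concatenate([vals[sp] for sp in SPECIES])
        return pd.DataFrame(rows).T.set_axis(meta["sample_id"], axis=1), meta

    def test_planted_shift_called_up(self):
        usage, meta = self._usage(shift_species="G")
        out = usage_test(usage, meta)
        assert out.loc["f0", "call"] == "up"
        assert out.loc["f0", "focal_species"] == "G"

    def test_null_makes_no_calls(self):
        usage, meta = self._usage(shift_species=None)
        out = usage_test(usage, meta)
        assert (out["call"] == "none").all()

    def test_shift_in_two_species_not_species_specific(self):
        usage, meta = self._usage(shift_species="G")
        # add the same shift to H for feature f0
        h_cols = [c for c in usage.columns if c.startswith("H")]
        usage.loc["f0", h_cols] = usage.loc["f0", [c for c in usage.columns if c.startswith("G")]].to_numpy()
        out = usage_test(usage, meta)
        assert out.loc["f0", "call"] == "none"

    def test_permutation_method_agrees_on_strong_effect(self):
        # the permutation p has a combinatorial floor of 2/C(12,6), so keep
        # the feature count small enough for BH to resolve it
        usage, meta = self._usage(shift_species="M", delta=0.5, n_feat=8)
        rng = np.random.default_rng(1)
        out = usage_test(
            usage, meta, method="permutation", n_permutations=1999, rng=rng
        )
        assert out.loc["f0", "call"] == "up"

    def test_type_i_error_controlled_on_null(self):
        """Across many null features, the fraction called at FDR 0.05 stays
        at or below 0.08."""
        rng = np.random.default_rng(3)
        meta = _meta(6)
        n_feat = 200
        rows = {
            f"f{i}": np.clip(0.4 + rng.normal(0, 0.08, 30), 0.01, 0.99)
            for i in range(n_feat)
        }
        usage = pd.DataFrame(rows).T.set_axis(meta["sample_id"], axis=1)
        out = usage_test(usage, meta)
        assert (out["call"] != "none").mean() <= 0.08


class TestExonicParts:
    def test_equal_parts_split_evenly(self):
        counts = pd.DataFrame({"s1": [10.0, 10.0]}, index=["p1", "p2"])
        u = exonic_part_usage(counts, {"p1": "g1", "p2": "g1"})
        assert u["s1"].tolist() == [0.5, 0.5]

    def test_zero_part_has_zero_coefficient(self):
        counts = pd.DataFrame({"s1": [10.0, 0.0]}, index=["p1", "p2"])
        u = exonic_part_usage(counts, {"p1": "g1", "p2": "g1"})
        assert u["s1"].tolist() == [1.0, 0.0]

    def test_inclusion_fraction_reflects_planted_drop(self):
        meta = _meta(2)
        cols = {}
        for sp in SPECIES:
            for r in range(2):
                inc = 0.2 if sp == "O" else 0.8
                cols[f"{sp}{r + 1}"] = [inc, 1 - inc]
        u = pd.DataFrame(cols, index=["p_se", "p_other"])
        frac = inclusion_fraction(u, meta)
        assert frac.loc["p_se", "O"] < frac.loc["p_se", "H"]


class TestFiltersAndBatch:
    def test_expression_filter_removes_low_genes(self):
        meta = _meta(2)
        tpm = pd.DataFrame(
            {sid: [5.0, 5.0, 0.1, 0.0] for sid in meta["sample_id"]},
            index=["t1", "t2", "t3", "t4"],
        )
        gene_of = {"t1": "g1", "t2": "g1", "t3": "g2", "t4": "g2"}
        ok = expression_filter(tpm, gene_of, meta)
        assert ok["t1"] and ok["t2"]
        assert not ok["t3"] and not ok["t4"]

    def test_batch_correction_removes_additive_offset(self):
        meta = _meta(2)
        meta["batch"] = ["b1", "b2"] * 5
        rng = np.random.default_rng(0)
        base = rng.random((10, 10)) + 1
        log_expr = pd.DataFrame(base, columns=meta["sample_id"])
        shifted = log_expr.copy()
        b2 = [s for s, b in zip(meta["sample_id"], meta["batch"]) if b == "b2"]
        shifted[b2] += 0.7
        corrected = batch_correct(shifted, meta)
        gap = (corrected[b2].median(axis=1)
               - corrected.drop(columns=b2).median(axis=1)).abs().max()
        assert gap < 0.15
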