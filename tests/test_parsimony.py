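"""Presence criteria, Sankoff gain/loss reconstruction, species-specific calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from primatesplice.models import ExpressionMatrix, ValidationError
from primatesplice.parsimony import (
    PhylogenyTree,
    build_presence_matrix,
    call_species_specific,
    check_upregulation_confound,
    reconstruct_gain_loss,
    sankoff,
)
from oracles import brute_sankoff, fitch

SPECIES = ["H", "C", "G", "O", "M"]


def _expr(tpm_by_species, n_rep=3):
    cols, meta = {}, []
    for sp in SPECIES:
        for r in range(n_rep):
            sid = f"{sp}{r + 1}"
            cols[sid] = [v[r] for v in tpm_by_species[sp]]
            meta.append({"sample_id": sid, "species": sp, "replicate": r + 1,
                         "batch": "b1"})
    n = len(next(iter(tpm_by_species.values())))
    tpm = pd.DataFrame(cols, index=[f"t{i}" for i in range(n)])
    return ExpressionMatrix(tpm=tpm, samples=pd.DataFrame(meta))


class TestPresenceMatrix:
    def test_expressed_in_all_replicates(self):
        expr = _expr({sp: [(0.5, 1.2, 0.8)] for sp in SPECIES})
        strict = build_presence_matrix(expr, "strict")
        lenient = build_presence_matrix(expr, "lenient")
        assert (strict.loc["t0", SPECIES] == 1).all()
        assert (lenient.loc["t0", SPECIES] == 1).all()

    def test_one_zero_replicate_is_ambiguous_under_strict(self):
        tpm = {sp: [(0.5, 1.2, 0.8)] for sp in SPECIES}
        tpm["H"] = [(0.0, 1.2, 0.8)]
        expr = _expr(tpm)
        strict = build_presence_matrix(expr, "strict")
        lenient = build_presence_matrix(expr, "lenient")
        assert strict.loc["t0", "H"] == -1 and strict.loc["t0", "ambiguous"]
        assert lenient.loc["t0", "H"] == 1

    def test_all_zero_is_absent_under_both(self):
        tpm = {sp: [(0.5, 1.2, 0.8)] for sp in SPECIES}
        tpm["M"] = [(0.0, 0.0, 0.0)]
        for criterion in ("strict", "lenient"):
            mat = build_presence_matrix(_expr(tpm), criterion)
            assert mat.loc["t0", "M"] == 0

    def test_single_replicate_rejected_under_strict(self):
        cols = {f"{sp}1": [1.0] for sp in SPECIES}
        meta = pd.DataFrame(
            [{"sample_id": f"{sp}1", "species": sp, "replicate": 1} for sp in SPECIES]
        )
        expr = ExpressionMatrix(tpm=pd.DataFrame(cols, index=["t0"]), samples=meta)
        with pytest.raises(ValidationError):
            build_presence_matrix(expr, "strict")


@pytest.fixture(scope="module")
def tree():
    return PhylogenyTree()


class TestSankoff:

    def test_all_present_no_events(self, tree):
        res = sankoff(dict(zip(SPECIES, [1, 1, 1, 1, 1])), tree)
        assert res.score == 0 and res.events == []

    def test_gain_on_human_chimp_ancestor(self, tree):
        res = sankoff(dict(zip(SPECIES, [1, 1, 0, 0, 0])), tree)
        assert res.score == 1
        assert len(res.events) == 1
        ev = res.events[0]
        assert ev["type"] == "gain" and "C+H" in ev["branch"]
        assert not ev["ambiguous_direction"]

    def test_macaque_only_profile_is_direction_ambiguous(self, tree):
        """Present only in macaque: a macaque gain and a great-ape-stem loss
        are equally parsimonious, so the direction is undetermined."""
        res = sankoff(dict(zip(SPECIES, [0, 0, 0, 0, 1])), tree)
        assert res.score == 1
        assert res.n_optimal_labelings == 2
        assert {e["type"] for e in res.events} == {"gain", "loss"}
        assert all(e["ambiguous_direction"] for e in res.events)
        assert res.root_states == {0, 1}

    def test_ambiguous_leaf_state_rejected(self, tree):
        with pytest.raises(ValidationError):
            sankoff(dict(zip(SPECIES, [1, 1, 0, 0, -1])), tree)

    @pytest.mark.parametrize("costs", [(1.0, 1.0), (2.0, 1.0)])
    def test_equals_exhaustive_enumeration_for_all_profiles(self, tree, costs):
        """Sankoff DP score, optimal event sets and root states equal the
        brute-force enumeration over all 16 internal labelings, for every one
        of the 32 binary leaf profiles."""
        gain_cost, loss_cost = costs
        for states in itertools.product((0, 1), repeat=5):
            profile = dict(zip(SPECIES, states))
            res = sankoff(profile, tree, gain_cost, loss_cost)
            b_score, b_event_sets, b_roots = brute_sankoff(
                profile, gain_cost, loss_cost
            )
            assert res.score == b_score, profile
            assert res.root_states == b_roots, profile
            b_union = set().union(*b_event_sets)
            b_common = frozenset.intersection(*b_event_sets)
            got = {(_strip(e["branch"]), e["type"]) for e in res.events}
            assert got == {(b, t) for b, t in b_union}, profile
            got_ambig = {
                (_strip(e["branch"]), e["type"])
                for e in res.events if e["ambiguous_direction"]
            }
            assert got_ambig == {bt for bt in b_union if bt not in b_common}, profile

    def test_equal_costs_match_fitch(self, tree):
        for states in itertools.product((0, 1), repeat=5):
            profile = dict(zip(SPECIES, states))
            assert sankoff(profile, tree).score == fitch(profile), profile


def _strip(branch: str) -> str:
    """Map package branch labels to the oracle's clade labels."""
    if "(" in branch:
        inner = branch[branch.index("(") + 1:-1]
        return "".join(sorted(inner.split("+")))
    return branch


class TestSpeciesSpecific:
    def test_single_species_profile_called(self):
        tpm = {sp: [(0.0, 0.0, 0.0)] for sp in SPECIES}
        tpm["H"] = [(2.0, 1.0, 3.0)]
        calls = call_species_specific(build_presence_matrix(_expr(tpm), "strict"))
        assert calls["H"] == {"t0"}
        assert all(not calls[sp] for sp in SPECIES if sp != "H")

    def test_two_species_profile_not_called(self):
        tpm = {sp: [(0.0, 0.0, 0.0)] for sp in SPECIES}
        tpm["H"] = tpm["C"] = [(2.0, 1.0, 3.0)]
        calls = call_species_specific(build_presence_matrix(_expr(tpm), "strict"))
        assert all(not v for v in calls.values())

    def test_ambiguous_profile_excluded(self):
        tpm = {sp: [(0.0, 0.0, 0.0)] for sp in SPECIES}
        tpm["H"] = [(2.0, 1.0, 3.0)]
        tpm["M"] = [(0.0, 0.5, 0.0)]       # neither present nor absent
        calls = call_species_specific(build_presence_matrix(_expr(tpm), "strict"))
        assert all(not v for v in calls.values())

    def test_species_specific_event_is_on_focal_branch(self):
        """A species-specific profile reconstructs to a single unambiguous
        terminal event, except the macaque profile whose direction is
        undetermined against the great-ape stem."""
        tree = PhylogenyTree()
        for focal in SPECIES:
            profile = {sp: int(sp == focal) for sp in SPECIES}
            res = sankoff(profile, tree)
            if focal == "M":
                assert all(e["ambiguous_direction"] for e in res.events)
                assert any(e["branch"] == "M" for e in res.events)
            else:
                assert len(res.events) == 1
                assert res.events[0]["branch"] == focal
                assert res.events[0]["type"] == "gain"

    def test_tightening_presence_threshold_shrinks_calls(self):
        rng = np.random.default_rng(4)
        tpm = {
            sp: [tuple(rng.uniform(0, 1, 3) * (rng.random() < 0.4)) for _ in range(40)]
            for sp in SPECIES
        }
        expr = _expr(tpm)
        sizes = []
        for thr in (0.0, 0.2, 0.5):
            mat = build_presence_matrix(expr, "strict", presence_threshold=thr)
            calls = call_species_specific(mat)
            sizes.append({sp: set(v) for sp, v in calls.items()})
        for lo, hi in zip(sizes[1:], sizes[:-1]):
            for sp in SPECIES:
                assert lo[sp] <= hi[sp]


class TestConfoundCheck:
    @staticmethod
    def _gene_tpm(focal_vals, rest_val=10.0, n_genes=20, rng=None):
        rng = rng or np.random.default_rng(0)
        cols, meta = {}, []
        for sp in SPECIES:
            for r in range(3):
                sid = f"{sp}{r + 1}"
                base = focal_vals if sp == "H" else rest_val
                vals = np.full(n_genes, float(base)) * rng.uniform(0.95, 1.05, n_genes)
                cols[sid] = vals
                meta.append({"sample_id": sid, "species": sp, "replicate": r + 1})
        return (pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)]),
                pd.DataFrame(meta))

    def test_identical_means_not_confounded(self):
        tpm, meta = self._gene_tpm(10.0)
        out = check_upregulation_confound(tpm, meta, {"g0": "H"})
        assert not out["confounded"].iloc[0]

    def test_strong_upregulation_flagged(self):
        tpm, meta = self._gene_tpm(80.0)
        out = check_upregulation_confound(tpm, meta, {f"g{i}": "H" for i in range(5)})
        assert out["confounded"].all()

    def test_downregulation_never_flagged(self):
        tpm, meta = self._gene_tpm(1.0)
        out = check_upregulation_confound(tpm, meta, {"g0": "H"})
        assert not out["confounded"].iloc[0]
        assert out["log2fc"].iloc[0] < 0


def test_fixture_branch_events_recover_planted_gains(small_sim):
    """Planted focal-only transcripts reconstruct as terminal events on (or
    ambiguously attributable to) the focal branch."""
    ref, expr = small_sim
    presence = build_presence_matrix(expr, "strict")
    events = reconstruct_gain_loss(presence)
    truth = ref.truth
    planted = truth[truth["event_class"] == "species_specific_transcript"]
    for _, row in planted.iterrows():
        sub = events[events["transcript_id"] == row["feature_id"]]
        assert len(sub), row["feature_id"]
        assert (sub["branch"] == row["focal_species"]).any()
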