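"""Model enumeration, Akaike weighting and the averaging methods."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boargrowth.mixed_models import FittedModel, ModelSpec
from boargrowth.model_averaging import (
    AveragingResult,
    ModelSet,
    akaike_weights,
    average_all,
    average_natural,
    average_zero,
    build_table,
    conditional_average,
    enumerate_models,
    rvi,
)


def brute_force_subsets(terms):
    """Independent oracle: generate every subset of the power set and keep
    those where each interaction comes with both parent mains."""
    keep = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            ok = True
            for t in combo:
                if ":" in t:
                    a, b = t.split(":")
                    ok = ok and a in combo and b in combo
            if ok:
                keep.append(frozenset(combo))
    return set(keep)


class TestEnumeration:
    def test_single_interaction_gives_five_models(self):
        subsets = enumerate_models(("A", "B", "A:B"))
        assert len(subsets) == 5
        expected = [frozenset(), frozenset({"A"}), frozenset({"B"}),
                    frozenset({"A", "B"}), frozenset({"A", "B", "A:B"})]
        assert {frozenset(s) for s in subsets} == set(expected)

    @pytest.mark.parametrize("m", [0, 1, 3, 5])
    def test_mains_only_power_set(self, m):
        terms = tuple(f"t{i}" for i in range(m))
        assert len(enumerate_models(terms)) == 2**m

    @pytest.mark.parametrize("terms", [
        ("A", "B", "C", "A:B", "A:C"),
        ("A", "B", "C", "D", "A:B", "C:D"),
        ("A", "B", "A:B", "C"),
    ])
    def test_matches_brute_force_oracle(self, terms):
        got = {frozenset(s) for s in enumerate_models(terms)}
        assert got == brute_force_subsets(terms)

    def test_cap_enforced(self):
        with pytest.raises(ValueError, match="cap"):
            enumerate_models(tuple(f"t{i}" for i in range(10)), max_models=100)


class TestAkaikeWeights:
    def test_equal_aiccs_split_evenly(self):
        assert np.allclose(akaike_weights([10.0, 10.0]), [0.5, 0.5])

    def test_delta_two(self):
        w = akaike_weights([0.0, 2.0])
        e = np.exp(-1.0)
        assert np.allclose(w, [1 / (1 + e), e / (1 + e)])
        assert w[0] == pytest.approx(0.731, abs=1e-3)

    def test_single_model(self):
        assert akaike_weights([123.4]) == pytest.approx([1.0])

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=12),
           st.floats(-1000, 1000))
    def test_shift_invariance_and_normalization(self, aiccs, shift):
        w0 = akaike_weights(aiccs)
        w1 = akaike_weights([a + shift for a in aiccs])
        assert abs(w0.sum() - 1.0) < 1e-10
        assert np.allclose(w0, w1, atol=1e-10)


def toy_model(terms, beta, se, aicc_val, n=100):
    """Hand-built FittedModel for averaging-rule unit tests."""
    spec = ModelSpec("y", tuple(terms))
    return FittedModel(
        spec=spec, beta=dict(beta), se=dict(se), vcov=np.eye(len(beta)),
        sigma2=1.0, tau2={}, loglik=0.0, k=len(beta) + 1, n=n, aicc=aicc_val,
        converged=True, residuals=np.zeros(n))


def toy_set(members, weights=None):
    base = max((m.spec.fixed_terms for m in members), key=len)
    return ModelSet(base, list(members), weights)


class TestRVIAndAverages:
    def make_pair(self):
        m1 = toy_model(("A",), {"(Intercept)": 0.0, "A": 1.0}, {"(Intercept)": 0.1, "A": 0.0}, 10.0)
        m2 = toy_model(("A",), {"(Intercept)": 0.0, "A": 3.0}, {"(Intercept)": 0.1, "A": 0.0}, 10.0)
        m3 = toy_model((), {"(Intercept)": 0.0}, {"(Intercept)": 0.1}, 10.0)
        return m1, m2, m3

    def test_rvi_additivity(self):
        m1, m2, m3 = self.make_pair()
        ms = toy_set([m1, m2, m3], weights=[0.4, 0.2, 0.4])
        assert rvi(ms, "A") == pytest.approx(0.6)

    def test_rvi_everywhere_and_nowhere(self):
        m1, m2, m3 = self.make_pair()
        assert rvi(toy_set([m1, m2]), "A") == pytest.approx(1.0)

    def test_natural_single_member_passthrough(self):
        m1, _, m3 = self.make_pair()
        ms = toy_set([m1, m3], weights=[0.3, 0.7])
        est, se = average_natural(ms, "A")
        assert est == pytest.approx(1.0) and se == pytest.approx(0.0)

    def test_natural_two_members_unconditional_se(self):
        # equal weights, estimates 1 and 3 with zero within-model SE:
        # mean 2, unconditional SE = mean |beta - mean| = 1
        m1, m2, _ = self.make_pair()
        ms = toy_set([m1, m2], weights=[0.5, 0.5])
        est, se = average_natural(ms, "A")
        assert est == pytest.approx(2.0) and se == pytest.approx(1.0)

    def test_duplicating_member_and_halving_weight_invariant(self):
        m1, m2, m3 = self.make_pair()
        a = toy_set([m1, m2, m3], weights=[0.5, 0.25, 0.25])
        b = toy_set([m1, m1, m2, m3], weights=[0.25, 0.25, 0.25, 0.25])
        assert average_natural(a, "A") == pytest.approx(average_natural(b, "A"))
        assert average_zero(a, "A") == pytest.approx(average_zero(b, "A"))

    def test_zero_equals_natural_times_rvi(self):
        m1, m2, m3 = self.make_pair()
        ms = toy_set([m1, m2, m3], weights=[0.4, 0.2, 0.4])
        nat, _ = average_natural(ms, "A")
        zero, _ = average_zero(ms, "A")
        assert zero == pytest.approx(nat * rvi(ms, "A"), abs=1e-14)
        assert zero == pytest.approx(0.6 * nat)

    def test_absent_term_rejected(self):
        _, _, m3 = self.make_pair()
        with pytest.raises(ValueError):
            average_natural(toy_set([m3]), "A")


class TestIdentityOnFittedSets:
    def test_zero_equals_natural_times_rvi_everywhere(self, small_model_set):
        from boargrowth.studies import averaging_identity_audit

        assert averaging_identity_audit(small_model_set) < 1e-10

    def test_weights_sum_to_one(self, small_model_set):
        assert abs(small_model_set.weights.sum() - 1.0) < 1e-10

    def test_delta_subsets_stable(self, small_model_set):
        """Averages over delta-AICc < 4 and < 10 subsets stay within 10%
        of the full-set averages for well-supported terms."""
        full = average_all(small_model_set, "natural")
        a = np.array([m.aicc for m in small_model_set.members])
        for cut in (4.0, 10.0):
            keep = a - a.min() < cut
            sub = ModelSet(small_model_set.base_terms,
                           [m for m, k in zip(small_model_set.members, keep) if k])
            part = average_all(sub, "natural")
            for term in small_model_set.base_terms:
                if full.table.loc[term, "rvi"] > 0.9 and term in part.table.index:
                    f, p = full.estimate(term), part.estimate(term)
                    assert abs(p - f) <= 0.1 * max(abs(f), 1e-6)


class TestConditionalRule:
    def interaction_set(self, p_inter_small=True):
        """Three members: full model (interaction significant or not),
        mains-only, single-main."""
        se_int = 0.1 if p_inter_small else 10.0
        full = toy_model(("A", "B", "A:B"),
                         {"(Intercept)": 0, "A": 1.0, "B": 0.5, "A:B": 0.8},
                         {"(Intercept)": 0.1, "A": 0.1, "B": 0.1, "A:B": se_int}, 10.0)
        mains = toy_model(("A", "B"),
                          {"(Intercept)": 0, "A": 2.0, "B": 0.7},
                          {"(Intercept)": 0.1, "A": 0.1, "B": 0.1}, 10.0)
        single = toy_model(("A",), {"(Intercept)": 0, "A": 3.0},
                           {"(Intercept)": 0.1, "A": 0.1}, 10.0)
        return toy_set([full, mains, single], weights=[1 / 3] * 3)

    def test_no_interactions_equals_natural(self):
        m1 = toy_model(("A", "B"), {"(Intercept)": 0, "A": 1.0, "B": 2.0},
                       {"(Intercept)": 0.1, "A": 0.2, "B": 0.2}, 10.0)
        m2 = toy_model(("A",), {"(Intercept)": 0, "A": 1.5}, {"(Intercept)": 0.1, "A": 0.2}, 11.0)
        ms = toy_set([m1, m2])
        cond = conditional_average(ms)
        nat = average_all(ms, "natural")
        for t in ("A", "B"):
            assert cond.estimate(t) == pytest.approx(nat.estimate(t))
            assert cond.se(t) == pytest.approx(nat.se(t))

    def test_significant_interaction_selects_significant_members(self):
        # the interaction is significant overall and within the only model
        # containing it, so A and B take exactly that member's estimates
        ms = self.interaction_set(p_inter_small=True)
        cond = conditional_average(ms)
        assert cond.estimate("A") == pytest.approx(1.0)
        assert cond.estimate("B") == pytest.approx(0.5)
        assert "significant" in cond.table.loc["A", "selection_note"]

    def test_nonsignificant_interaction_excludes_it(self):
        # non-significant interaction: mains averaged over members without
        # it plus members where it is itself non-significant (here: all)
        ms = self.interaction_set(p_inter_small=False)
        cond = conditional_average(ms)
        # A appears in all three members; all qualify (interaction n.s.)
        w = ms.weights
        expect_a = np.average([1.0, 2.0, 3.0], weights=w)
        assert cond.estimate("A") == pytest.approx(expect_a)


class TestBuildTable:
    def test_ordering_and_schema(self, small_model_set):
        res = conditional_average(small_model_set)
        tab = build_table(res)
        assert list(tab.columns) == ["term", "estimate", "se", "p", "rvi", "significant"]
        rv = tab["rvi"].to_numpy()
        assert all(rv[i] >= rv[i + 1] - 1e-12 for i in range(len(rv) - 1))

    def test_empty_result(self):
        res = AveragingResult("natural", pd.DataFrame(
            columns=["estimate", "se", "z", "p", "rvi", "selection_note"]))
        assert len(build_table(res)) == 0

    def test_all_rvi_one_orders_by_magnitude(self):
        df = pd.DataFrame(
            dict(estimate=[0.1, -0.5, 0.3], se=[0.1] * 3, z=[1, -5, 3],
                 p=[0.3, 0.001, 0.01], rvi=[1.0, 1.0, 1.0], selection_note=""),
            index=pd.Index(["a", "b", "c"], name="term"))
        tab = build_table(AveragingResult("natural", df))
        assert list(tab["term"]) == ["b", "c", "a"]
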