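import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smoltcjs.cjs_engine import (
    ModelSpecError,
    build_design,
    cell_estimates,
    cjs_loglik_real,
    fit,
    neg_loglik,
    parse_model,
    profile_confounding,
)
from smoltcjs.io_model import EncounterHistory, Population
from smoltcjs.synthetic_data import simulate_histories

from conftest import histories_from_matrix, make_record


# ---------------------------------------------------------------------------
# independent oracle: exhaustive enumeration over all fate sequences
# ---------------------------------------------------------------------------

def brute_force_history_prob(history, phi, p):
    """P(history | phi, p) by summing over every (death segment, detection
    outcome) fate compatible with the observed history."""
    T = len(phi)
    total = 0.0
    for death_after in range(T + 1):  # alive through occasions 1..death_after
        prob_path = 1.0
        for s in range(death_after):
            prob_path *= phi[s]
        if death_after < T:
            prob_path *= 1.0 - phi[death_after]
        for dets in itertools.product((0, 1), repeat=death_after):
            prob = prob_path
            for j, d in enumerate(dets):
                prob *= p[j] if d else 1.0 - p[j]
            observed = list(dets) + [0] * (T - death_after)
            if observed == list(history[1:]):
                total += prob
    return total


class TestLikelihoodOracle:
    def test_forced_path(self):
        # "11", phi=0.5, p=1 -> P = 0.5
        ll = cjs_loglik_real([[0.5]], [[1.0]], np.array([[1, 1]]))
        assert -ll == pytest.approx(-np.log(0.5), abs=1e-9)

    def test_chi_closed_form(self):
        # "10", phi=0.5, p=0.5 -> P = (1-phi) + phi(1-p) = 0.75
        ll = cjs_loglik_real([[0.5]], [[0.5]], np.array([[1, 0]]))
        assert ll == pytest.approx(np.log(0.75), abs=1e-12)

    @pytest.mark.parametrize("T", [1, 2, 3, 4])
    def test_matches_enumeration_all_histories(self, T, rng):
        for _ in range(20):
            phi = rng.uniform(0.05, 0.99, size=T)
            p = rng.uniform(0.05, 0.99, size=T)
            for bits in itertools.product((0, 1), repeat=T):
                h = np.array([[1, *bits]])
                expected = brute_force_history_prob(h[0], phi, p)
                got = cjs_loglik_real(phi[None, :], p[None, :], h)
                assert got == pytest.approx(np.log(expected), abs=1e-10)

    def test_total_probability_is_one(self, rng):
        # all 2^T histories partition the sample space
        T = 4
        phi = rng.uniform(0.1, 0.95, size=T)
        p = rng.uniform(0.1, 0.95, size=T)
        total = sum(
            brute_force_history_prob([1, *bits], phi, p)
            for bits in itertools.product((0, 1), repeat=T)
        )
        assert total == pytest.approx(1.0, abs=1e-12)


class TestModelGrammar:
    def test_star_expansion(self):
        spec = parse_model("phi ~ segment * SkokH; p ~ segment")
        assert ("segment",) in spec.phi_terms
        assert ("SkokH",) in spec.phi_terms
        assert ("segment", "SkokH") in spec.phi_terms

    def test_fixed_clause(self):
        spec = parse_model("phi ~ segment; p ~ segment; fix p[JDF]=0.685")
        assert spec.fixed == (("p", "JDF", 0.685),)

    def test_unknown_term_rejected(self):
        with pytest.raises(ModelSpecError, match="wibble"):
            parse_model("phi ~ wibble; p ~ segment")

    def test_missing_p_rejected(self):
        with pytest.raises(ModelSpecError):
            parse_model("phi ~ segment")


class TestBuildDesign:
    def make_histories(self, n=8):
        pops = [Population.BigBeefW, Population.SkokomishW, Population.SkokomishH,
                Population.DuckabushH]
        out = []
        for i in range(n):
            rec = make_record(i, population=pops[i % 4], year=2008 + i % 3, rd=100 + i)
            out.append(EncounterHistory(rec.fish_id, [1, 1, 0, 1, 0], record=rec))
        return out

    def test_phi_segment_four_columns(self):
        hs = self.make_histories()
        d = build_design(parse_model("phi ~ segment; p ~ segment"), hs)
        assert len(d.phi_names) == 4

    def test_factorial_expansion_eight_cells(self):
        hs = self.make_histories()
        d = build_design(parse_model("phi ~ segment * SkokH; p ~ segment"), hs)
        assert len(d.phi_names) == 8

    def test_top_model_parameter_count_is_15(self):
        hs = self.make_histories(24)
        d = build_design(
            parse_model("phi ~ segment * SkokH + rd; p ~ segment + RM:line; fix p[JDF]=0.685"),
            hs,
        )
        assert d.k_total == 15

    def test_aliased_column_dropped_deterministically(self):
        hs = self.make_histories(24)
        d = build_design(parse_model("phi ~ segment; p ~ segment + RM:line"), hs)
        # one RM:line level is redundant with the occasion-1 baseline
        assert len(d.dropped) == 1
        assert d.dropped[0].startswith("p:RM:line[")

    def test_covariates_standardized(self):
        hs = self.make_histories(16)
        d = build_design(parse_model("phi ~ rd + L + K; p ~ segment"), hs)
        for name in ("rd", "L", "K"):
            assert name in d.transforms
        j = d.phi_names.index("rd")
        col = d.X_phi[:, 0, j]
        assert col.mean() == pytest.approx(0.0, abs=1e-9)
        assert col.std() == pytest.approx(1.0, abs=1e-9)


class TestFit:
    def closed_form_phi(self, hist):
        """Saturated-MLE oracle for p=1 data: survivor ratios."""
        alive = hist[:, 1:]
        counts = alive.sum(axis=0)
        n = hist.shape[0]
        prev = np.concatenate([[n], counts[:-1]])
        return counts / prev

    def test_p1_fit_matches_survivor_ratios(self, rng):
        hist = simulate_histories(800, (0.9, 0.7, 0.5, 0.6), (1, 1, 1, 1), rng)
        hs = histories_from_matrix(hist)
        fr = fit("phi ~ segment; p ~ segment; fix p[1]=1.0; fix p[2]=1.0; fix p[3]=1.0; fix p[JDF]=1.0", hs)
        expected = self.closed_form_phi(hist)
        np.testing.assert_allclose(fr.real_phi[0], expected, atol=1e-4)

    def test_parameter_recovery_large_n(self, rng):
        phi_true = (0.969, 0.892, 0.389, 0.457)
        p_true = (0.928, 0.767, 0.757, 0.685)
        hist = simulate_histories(10_000, phi_true, p_true, rng)
        fr = fit("phi ~ segment; p ~ segment; fix p[JDF]=0.685",
                 histories_from_matrix(hist))
        assert fr.converged
        np.testing.assert_allclose(fr.real_phi[0], phi_true, atol=0.03)
        np.testing.assert_allclose(fr.real_p[0, :3], p_true[:3], atol=0.03)
        assert fr.real_p[0, 3] == pytest.approx(0.685)

    def test_permutation_invariance(self, rng):
        hist = simulate_histories(300, (0.9, 0.8, 0.5, 0.5), (0.9, 0.7, 0.7, 0.685), rng)
        hs = histories_from_matrix(hist)
        fr1 = fit("phi ~ segment; p ~ segment; fix p[JDF]=0.685", hs)
        perm = list(np.random.default_rng(5).permutation(len(hs)))
        fr2 = fit("phi ~ segment; p ~ segment; fix p[JDF]=0.685", [hs[i] for i in perm])
        np.testing.assert_allclose(fr1.real_phi[0], fr2.real_phi[0], atol=1e-6)

    def test_duplication_halves_variance(self, rng):
        hist = simulate_histories(400, (0.9, 0.8, 0.5, 0.5), (0.9, 0.7, 0.7, 0.685), rng)
        hs = histories_from_matrix(hist)
        doubled = histories_from_matrix(np.vstack([hist, hist]))
        fr1 = fit("phi ~ segment; p ~ segment; fix p[JDF]=0.685", hs)
        fr2 = fit("phi ~ segment; p ~ segment; fix p[JDF]=0.685", doubled)
        np.testing.assert_allclose(fr1.real_phi[0], fr2.real_phi[0], atol=1e-5)
        np.testing.assert_allclose(fr2.se_phi[0], fr1.se_phi[0] / np.sqrt(2), rtol=0.02)

    def test_no_detections_raises(self):
        hs = histories_from_matrix(np.array([[1, 0, 0, 0, 0]] * 5))
        with pytest.raises(ValueError, match="no detections"):
            fit("phi ~ segment; p ~ segment", hs)

    def test_neg_loglik_penalizes_nonfinite_beta(self, rng):
        hist = simulate_histories(50, (0.9,) * 4, (0.9,) * 4, rng)
        hs = histories_from_matrix(hist)
        d = build_design(parse_model("phi ~ segment; p ~ segment"), hs)
        bad = np.full(d.k_total, np.nan)
        assert neg_loglik(bad, d, hist) == pytest.approx(1e10)

    def test_cell_estimates_grouping(self, rng):
        phi = {"other": (0.95, 0.85, 0.4, 0.45), "SkokH": (0.6, 0.3, 0.45, 0.3)}
        h_w = simulate_histories(2000, phi["other"], (0.9, 0.75, 0.75, 0.685), rng)
        h_h = simulate_histories(2000, phi["SkokH"], (0.9, 0.75, 0.75, 0.685), rng)
        hs = histories_from_matrix(h_w, population=Population.BigBeefW) + \
            histories_from_matrix(h_h, population=Population.SkokomishH)
        fr = fit("phi ~ segment * SkokH; p ~ segment; fix p[JDF]=0.685", hs)
        est = cell_estimates(fr, "phi")
        assert set(est["SkokH"]) == {"other", "SkokH"}
        tolerances = (0.05, 0.05, 0.05, 0.1)  # later segments are sparser
        for grp, truth in phi.items():
            sub = est[est["SkokH"] == grp].set_index("cell")
            for cell, val, tol in zip(fr.design.segment_labels, truth, tolerances):
                assert sub.loc[cell, "estimate"] == pytest.approx(val, abs=tol)


class TestConfounding:
    def test_two_occasion_ridge(self, rng):
        hist = simulate_histories(500, (0.8, 0.6), (0.9, 0.5), rng)
        hs = histories_from_matrix(hist)
        fr = fit("phi ~ segment; p ~ segment", hs)
        report = profile_confounding(fr, hist)
        assert not report["terminal_p_fixed"]
        assert report["ridge_flat"]
        assert report["loglik_variation"] < 1e-6

    def test_fixing_terminal_p_removes_ridge(self, rng):
        hist = simulate_histories(500, (0.8, 0.6), (0.9, 0.5), rng)
        hs = histories_from_matrix(hist)
        fr = fit("phi ~ segment; p ~ segment; fix p[2]=0.5", hs)
        report = profile_confounding(fr, hist)
        assert report["terminal_p_fixed"]
        assert report["identifiable"]
        assert report["loglik_variation"] > 1e-3


@settings(max_examples=30, deadline=None)
@given(
    T=st.integers(1, 5),
    seed=st.integers(0, 10_000),
)
def test_likelihood_enumeration_property(T, seed):
    """neg_loglik == brute-force enumeration on all histories of length <= 5."""
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0.02, 0.98, size=T)
    p = rng.uniform(0.02, 0.98, size=T)
    for bits in itertools.product((0, 1), repeat=T):
        h = np.array([[1, *bits]])
        expected = brute_force_history_prob(h[0], phi, p)
        got = cjs_loglik_real(phi[None, :], p[None, :], h)
        assert got == pytest.approx(np.log(expected), abs=1e-10)
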