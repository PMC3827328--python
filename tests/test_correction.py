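"""The indirect range-restriction correction chain and its propagation."""

import math

import numpy as np
import pytest

from clpv.correction import (CLPVEstimate, ReliabilitySpec, SelectionRatio,
                             clpv_with_uncertainty, equivalent_n, hsl_case_iv,
                             restrict_reliability, selection_ratio,
                             DEFAULT_SELECTION_RATIOS)
from clpv.mcmc import Chain, ChainConfig


def _hand_hsl(r_i, r_xxa, r_yyi, u):
    """Step-by-step spreadsheet-style oracle for the Case IV chain."""
    r_xxi = 1 - (1 - r_xxa) / u ** 2
    u_t = math.sqrt((u ** 2 - (1 - r_xxa)) / r_xxa)
    r_tpi = r_i / math.sqrt(r_xxi * r_yyi)
    return (r_tpi / u_t) / math.sqrt(1 + r_tpi ** 2 * (1 / u_t ** 2 - 1))


class TestSelectionRatio:
    def test_equal_sds_mean_no_selection(self):
        assert selection_ratio(2.5, 2.5).u == 1.0

    def test_division(self):
        assert selection_ratio(3.87, 5.89).u == pytest.approx(0.657, abs=0.001)

    def test_default_lookup_table(self):
        assert DEFAULT_SELECTION_RATIOS["A-levels"] == 0.664
        assert DEFAULT_SELECTION_RATIOS["GCSEs/O-levels"] == 0.690
        assert DEFAULT_SELECTION_RATIOS["aptitude"] == 0.750

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            selection_ratio(0.0, 1.0)

    def test_u_above_one_warns(self):
        with pytest.warns(UserWarning, match="exceeds 1"):
            selection_ratio(1.2, 1.0)


class TestRestrictReliability:
    def test_no_restriction_identity(self):
        assert restrict_reliability(0.8, 1.0) == pytest.approx(0.8)

    def test_variance_bookkeeping_oracle(self):
        # true variance 0.8, error 0.2; restriction scales only the true part
        r_xxa, u = 0.8, 0.656
        got = restrict_reliability(r_xxa, u)
        true_var_restricted = r_xxa * u ** 2 - (1 - r_xxa) * (1 - u ** 2)
        # bookkeeping: total restricted variance is u^2 of the original;
        # error variance is unchanged at 1 - r_xxa
        assert got == pytest.approx((u ** 2 - (1 - r_xxa)) / u ** 2)
        assert got == pytest.approx(1 - (1 - r_xxa) / u ** 2)
        assert got == pytest.approx(0.535, abs=0.005)
        del true_var_restricted

    def test_near_degenerate_boundary_warns(self):
        # 1 - r_XXa = .4 < u^2 = .4303: allowed but nearly degenerate
        with pytest.warns(UserWarning, match="near-degenerate"):
            got = restrict_reliability(0.6, 0.656)
        assert got == pytest.approx(0.0705, abs=0.002)

    def test_precondition_violation_reports_values(self):
        with pytest.raises(ValueError, match="u\\^2"):
            restrict_reliability(0.5, 0.656)


class TestHslCaseIv:
    def test_identity_when_nothing_to_correct(self):
        for r in np.linspace(-0.9, 0.9, 19):
            assert hsl_case_iv(float(r), 1.0, 1.0, 1.0) == pytest.approx(
                float(r), abs=1e-12)

    def test_worked_example_against_hand_oracle(self):
        got = hsl_case_iv(0.2, 0.8, 0.84, 0.656)
        assert got == pytest.approx(_hand_hsl(0.2, 0.8, 0.84, 0.656), abs=1e-12)
        assert got == pytest.approx(0.503, abs=0.001)

    def test_monotone_increasing_in_r(self):
        grid = np.linspace(0.01, 0.5, 40)
        vals = [hsl_case_iv(float(r), 0.8, 0.84, 0.7) for r in grid]
        assert np.all(np.diff(vals) > 0)

    def test_correction_only_enlarges(self):
        for r_i in (0.05, 0.2, 0.4):
            for rel in (0.7, 0.9, 1.0):
                for u in (0.6, 0.8, 1.0):
                    if u ** 2 <= 1 - rel:
                        continue
                    r_xxi = 1 - (1 - rel) / u ** 2
                    if abs(r_i) >= math.sqrt(r_xxi * rel):
                        continue    # disattenuation out of range: invalid input
                    assert hsl_case_iv(r_i, rel, rel, u) >= r_i - 1e-12

    def test_lower_reliability_and_selection_never_decrease_rho(self):
        r_i = 0.25
        rels = [1.0, 0.9, 0.8, 0.7]
        us = [1.0, 0.9, 0.8, 0.7]
        prev_grid = None
        for u in us:
            for i in range(len(rels) - 1):
                hi = hsl_case_iv(r_i, rels[i], rels[i], u)
                lo = hsl_case_iv(r_i, rels[i + 1], rels[i + 1], u)
                assert lo >= hi - 1e-12
        for rel in rels:
            for i in range(len(us) - 1):
                wide = hsl_case_iv(r_i, rel, rel, us[i])
                tight = hsl_case_iv(r_i, rel, rel, us[i + 1])
                assert tight >= wide - 1e-12
        del prev_grid

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError, match="r_TPi"):
            hsl_case_iv(0.9, 0.8, 0.5, 0.9)


def _chain_from_draws(draws):
    draws = np.asarray(draws, dtype=float)
    cfg = ChainConfig(length=max(1000, draws.shape[0]),
                      use_last=draws.shape[0] - 1 if draws.shape[0] >= 1000 else draws.shape[0],
                      seed=0)
    # pad so retained == provided draws
    if draws.shape[0] < cfg.length:
        pad = np.repeat(draws[:1], cfg.length - draws.shape[0], axis=0)
        full = np.vstack([pad, draws])
        cfg = ChainConfig(length=full.shape[0], use_last=draws.shape[0], seed=0)
        return Chain(full, np.zeros(full.shape[0]), 0.3, cfg)
    return Chain(draws, np.zeros(draws.shape[0]), 0.3, cfg)


class TestClpvWithUncertainty:
    def test_degenerate_chain_equals_point_evaluation(self):
        row = [0.0, 1.0, 0.5, 0.7, 0.0, 1.0, 0.3]
        chain = _chain_from_draws([row] * 100)
        rel = ReliabilitySpec(r_XXa=0.815, r_YYi=0.834)
        est = clpv_with_uncertainty(chain, rel)
        assert est.se == pytest.approx(0.0, abs=1e-12)
        assert est.rho == pytest.approx(hsl_case_iv(0.3, 0.815, 0.834, 0.7))
        assert est.ci[0] == pytest.approx(est.rho, abs=1e-12)
        assert est.ci[1] == pytest.approx(est.rho, abs=1e-12)

    def test_identity_chain_mean_when_no_correction(self, rng):
        rows = np.tile([0.0, 1.0, 0.5, 1.0, 0.0, 1.0, 0.0], (200, 1))
        rows[:, 6] = 0.4 + 0.01 * rng.standard_normal(200)
        chain = _chain_from_draws(rows)
        est = clpv_with_uncertainty(chain, ReliabilitySpec(1.0, 1.0))
        assert est.rho == pytest.approx(rows[:, 6].mean(), abs=1e-12)

    def test_flags_unreliable_when_draws_rejected(self, rng):
        rows = np.tile([0.0, 1.0, 0.5, 0.7, 0.0, 1.0, 0.3], (100, 1))
        rows[:10, 3] = 0.1     # u too small: precondition violated
        chain = _chain_from_draws(rows)
        est = clpv_with_uncertainty(chain, ReliabilitySpec(0.815, 0.834))
        assert est.n_rejected == 10
        assert not est.reliable


class TestEquivalentN:
    def test_direct_inversion(self):
        assert equivalent_n(0.45, 0.06) == pytest.approx(177.7, abs=0.1)

    def test_round_trip_identity(self):
        rho, n = 0.3, 250.0
        se = (1 - rho ** 2) / math.sqrt(n - 1)
        assert equivalent_n(rho, se) == pytest.approx(n, abs=1e-9)

    def test_zero_rho(self):
        assert equivalent_n(0.0, 0.1) == pytest.approx(101.0)

    def test_tiny_implied_n_flagged(self):
        with pytest.warns(UserWarning, match="below 4"):
            equivalent_n(0.1, 0.9)
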