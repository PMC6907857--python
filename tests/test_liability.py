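import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from penliab.errors import (
    IdentifiabilityError,
    SaturationError,
    ValidationError,
)
from penliab.liability import (
    LiabilityValue,
    fit_multiple_threshold,
    incidence_to_liability,
    liability_to_incidence,
    liability_trajectory,
    strain_liability_difference,
)


class TestProbitTransforms:
    @pytest.mark.parametrize(
        "p,x", [(0.5, 0.0), (0.32, 0.468), (0.070, 1.476), (0.860, -1.080)]
    )
    def test_incidence_to_liability(self, p, x):
        assert incidence_to_liability(p).x == pytest.approx(x, abs=5e-4)

    @pytest.mark.parametrize("x,p", [(0.0, 0.5), (1.476, 0.070), (-1.08, 0.860)])
    def test_liability_to_incidence(self, x, p):
        assert liability_to_incidence(x) == pytest.approx(p, abs=5e-4)

    def test_saturated_incidences_are_capped(self):
        hi = incidence_to_liability(1.0, cap=4.0)
        lo = incidence_to_liability(0.0, cap=4.0)
        assert (hi.x, hi.capped) == (-4.0, True)
        assert (lo.x, lo.capped) == (4.0, True)

    def test_out_of_range_rejected(self):
        for bad in (-0.1, 1.1, float("nan")):
            with pytest.raises(ValidationError):
                incidence_to_liability(bad)
        with pytest.raises(ValidationError):
            liability_to_incidence(float("inf"))

    def test_continuity_correction_option(self):
        lv = incidence_to_liability(0.0, continuity=(0, 25))
        assert not lv.capped
        assert lv.x == pytest.approx(float(norm.isf(0.5 / 26)))

    def test_round_trip_on_dense_grid(self):
        grid = np.linspace(0.0001, 0.9999, 2001)
        for p in grid:
            lv = incidence_to_liability(float(p))
            assert liability_to_incidence(lv.x) == pytest.approx(p, abs=1e-9)

    @given(st.floats(1e-4, 1 - 1e-4), st.floats(1e-4, 1 - 1e-4))
    def test_strictly_decreasing_in_incidence(self, p1, p2):
        if p1 == p2:
            return
        lo, hi = sorted((p1, p2))
        assert incidence_to_liability(hi).x < incidence_to_liability(lo).x


class TestStrainDifference:
    def test_equal_values_differ_by_zero(self):
        v = incidence_to_liability(0.3)
        assert strain_liability_difference(v, v) == 0.0

    def test_reported_strain_separation(self):
        """Low vs high strain: 1.476 - (-1.08) = 2.556, i.e. 2.6 SD."""
        low = LiabilityValue(x=1.476, incidence=0.070)
        high = LiabilityValue(x=-1.08, incidence=0.860)
        diff = strain_liability_difference(low, high)
        assert diff == pytest.approx(2.556)
        assert round(diff, 1) == 2.6

    def test_alternative_panel_values(self):
        diff = strain_liability_difference(
            LiabilityValue(x=1.918, incidence=0.0276),
            LiabilityValue(x=-1.080, incidence=0.860),
        )
        assert diff == pytest.approx(2.998)

    def test_capped_input_raises_without_override(self):
        capped = incidence_to_liability(1.0)
        ok = incidence_to_liability(0.3)
        with pytest.raises(SaturationError, match="bound"):
            strain_liability_difference(ok, capped)
        assert strain_liability_difference(ok, capped, allow_capped=True) == pytest.approx(
            ok.x + 4.0
        )


def lstsq_oracle(cells, anchor):
    """Brute-force normal-equations oracle for the multiple-threshold fit."""
    strains = sorted({s for s, _ in cells})
    phens = sorted({k for _, k in cells})
    free = [s for s in strains if s != anchor]
    params = free + phens
    a = np.zeros((len(cells), len(params)))
    y = np.zeros(len(cells))
    for i, ((s, k), x) in enumerate(cells.items()):
        a[i, params.index(k)] = 1.0
        if s != anchor:
            a[i, params.index(s)] = -1.0
        y[i] = x
    beta = np.linalg.solve(a.T @ a, a.T @ y)
    mu = {anchor: 0.0, **{s: beta[params.index(s)] for s in free}}
    t = {k: beta[params.index(k)] for k in phens}
    return mu, t


class TestMultipleThresholdFit:
    def test_exact_recovery_of_consistent_system(self):
        mu = {"low": 0.0, "high": 2.0}
        t = {"op": 1.0, "jaw": -1.0}
        cells = {
            (s, k): LiabilityValue(x=t[k] - mu[s], incidence=0.5)
            for s in mu
            for k in t
        }
        model = fit_multiple_threshold(cells, anchor="low")
        assert model.strain_means == pytest.approx(mu)
        assert model.thresholds == pytest.approx(t)
        assert model.residuals["residual"].abs().max() < 1e-12

    def test_capped_cell_excluded_leaves_op_row_to_set_separation(self):
        cells = {
            ("low", "op"): LiabilityValue(1.476, 0.070),
            ("high", "op"): LiabilityValue(-1.08, 0.860),
            ("low", "jaw"): LiabilityValue(-0.806, 0.790),
            ("high", "jaw"): LiabilityValue(-4.0, 1.0, capped=True),
        }
        model = fit_multiple_threshold(cells, anchor="low")
        assert model.excluded == [("high", "jaw")]
        assert model.mean_separation("high", "low") == pytest.approx(2.556)

    def test_including_the_capped_bound_pulls_the_high_mean_further(self):
        cells = {
            ("low", "op"): LiabilityValue(1.476, 0.070),
            ("high", "op"): LiabilityValue(-1.08, 0.860),
            ("low", "jaw"): LiabilityValue(-0.806, 0.790),
            ("high", "jaw"): LiabilityValue(-4.0, 1.0, capped=True),
        }
        model = fit_multiple_threshold(cells, anchor="low", include_capped=True)
        assert model.strain_means["high"] > 2.556
        mu, t = lstsq_oracle({c: lv.x for c, lv in cells.items()}, "low")
        assert model.strain_means["high"] == pytest.approx(mu["high"])
        assert model.thresholds == pytest.approx(t)

    def test_disconnected_design_raises_identifiability_error(self):
        cells = {
            ("low", "op"): LiabilityValue(1.0, 0.2),
            ("high", "jaw"): LiabilityValue(-1.0, 0.8),
        }
        with pytest.raises(IdentifiabilityError, match="components"):
            fit_multiple_threshold(cells, anchor="low")

    @pytest.mark.parametrize("n_strains,n_phens", list(itertools.product([2, 3], [2, 3, 4])))
    def test_matches_normal_equations_oracle(self, n_strains, n_phens):
        rng = np.random.default_rng(n_strains * 10 + n_phens)
        strains = [f"s{i}" for i in range(n_strains)]
        phens = [f"k{i}" for i in range(n_phens)]
        cells = {
            (s, k): LiabilityValue(float(rng.normal()), 0.5)
            for s in strains
            for k in phens
        }
        model = fit_multiple_threshold(cells, anchor="s0")
        mu, t = lstsq_oracle({c: lv.x for c, lv in cells.items()}, "s0")
        for s in strains:
            assert model.strain_means[s] == pytest.approx(mu[s], abs=1e-9)
        for k in phens:
            assert model.thresholds[k] == pytest.approx(t[k], abs=1e-9)


class TestLiabilityTrajectory:
    def test_constant_incidence_has_zero_response(self):
        traj = liability_trajectory([(0, 0.3), (1, 0.3), (2, 0.3)])
        assert traj.table["delta_x"].iloc[1:].tolist() == pytest.approx([0.0, 0.0])
        assert traj.cumulative_response == 0.0

    def test_probit_per_generation_and_cumulative_response(self):
        traj = liability_trajectory([(0, 0.32), (1, 0.14), (2, 0.05)])
        assert traj.table["x"].tolist() == pytest.approx([0.468, 1.080, 1.645], abs=5e-4)
        assert traj.cumulative_response == pytest.approx(1.177, abs=5e-4)
        assert not traj.cumulative_is_bound

    def test_capped_generation_turns_response_into_bound(self):
        traj = liability_trajectory([(0, 0.32), (1, 0.0)], cap=4.0)
        assert traj.table["x"].iloc[1] == 4.0
        assert traj.table["capped"].iloc[1]
        assert np.isnan(traj.table["delta_x"].iloc[1])
        assert traj.cumulative_is_bound

    def test_single_generation_rejected(self):
        with pytest.raises(ValidationError):
            liability_trajectory([(0, 0.5)])
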