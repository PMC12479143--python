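"""Field metrics and the point-cloud gamma index."""

import numpy as np
import pytest

from hypersar import (
    GammaCriteria,
    RegionMask,
    SARField,
    SteeringTarget,
    field_metrics,
    gamma_index,
    make_region_masks,
)
from hypersar.errors import InvalidArgumentError, ZeroFieldError


def brute_force_gamma(points_mm, pred, truth, criteria):
    """O(N^2) reference: unrestricted minimisation over all evaluated points."""
    tmax = truth.max()
    dose_p = 100.0 * pred / tmax
    dose_t = 100.0 * truth / tmax
    gam = np.empty(len(truth))
    for i in range(len(truth)):
        best = np.inf
        for j in range(len(pred)):
            dd = np.linalg.norm(points_mm[j] - points_mm[i]) / criteria.dta_crit
            dD = (dose_p[j] - dose_t[i]) / criteria.dose_crit
            best = min(best, dd * dd + dD * dD)
        gam[i] = np.sqrt(best)
    return gam, 100.0 * np.mean(gam <= 1.0 + 1e-9)


@pytest.fixture()
def masked_pair(phantom, rng):
    wb, _ = make_region_masks(phantom, SteeringTarget(0, 0, 0), radius=2.5)
    truth = np.abs(rng.normal(10, 4, phantom.n_points)) + 0.5
    pred = truth + rng.normal(0, 1.0, phantom.n_points)
    return np.clip(pred, 0, None), truth, wb


class TestFieldMetrics:
    def test_identical_fields(self, masked_pair):
        _, truth, wb = masked_pair
        m = field_metrics(truth, truth, wb)
        assert m["MAE"] == 0 and m["RMSE"] == 0
        assert m["SSIM"] == pytest.approx(1.0)
        assert m["PSNR"] == np.inf

    def test_unit_offset_psnr(self, phantom):
        wb, _ = make_region_masks(phantom, SteeringTarget(0, 0, 0), radius=2.5)
        truth = np.ones(phantom.n_points)
        truth[wb.indices[0]] = 100.0  # mask max = 100
        pred = truth + 1.0
        m = field_metrics(pred, truth, wb)
        assert m["MAE"] == pytest.approx(1.0)
        assert m["RMSE"] == pytest.approx(1.0)
        assert m["PSNR"] == pytest.approx(40.0)  # 20 log10(100/1)
        assert m["relRMSE"] == pytest.approx(0.01)

    def test_constant_fields(self, phantom):
        wb, _ = make_region_masks(phantom, SteeringTarget(0, 0, 0), radius=2.5)
        m = field_metrics(np.full(phantom.n_points, 12.0), np.full(phantom.n_points, 10.0), wb)
        assert m["MAE"] == pytest.approx(2.0) and m["RMSE"] == pytest.approx(2.0)

    def test_accepts_sar_fields(self, records):
        r = records[0]
        wb, _ = make_region_masks(r.sar_truth.phantom, r.target, radius=2.0)
        m = field_metrics(r.sar_truth, r.sar_truth, wb)
        assert m["SSIM"] == pytest.approx(1.0)


class TestGammaIndex:
    def test_identical_fields_all_pass(self, masked_pair, phantom):
        _, truth, wb = masked_pair
        gam, rate = gamma_index(truth, truth, GammaCriteria(3, 3), wb, points=phantom.points)
        assert np.allclose(gam, 0.0)
        assert rate == 100.0

    def test_uniform_dose_boundary(self, phantom):
        """Uniform 10 vs 10.3 at 3%/3mm: dose difference exactly at the
        criterion, gamma = 1 everywhere, boundary passes."""
        wb = RegionMask(indices=np.arange(phantom.n_points), kind="whole-brain")
        truth = np.full(phantom.n_points, 10.0)
        pred = np.full(phantom.n_points, 10.3)
        gam, rate = gamma_index(pred, truth, GammaCriteria(3, 3), wb, points=phantom.points)
        assert np.allclose(gam, 1.0)
        assert rate == 100.0

    @pytest.mark.parametrize("crit", [GammaCriteria(2, 2), GammaCriteria(3, 3)])
    def test_matches_brute_force(self, phantom, rng, crit):
        """Accelerated gamma equals the O(N^2) all-pairs oracle exactly for
        every reference point (the search cap covers gamma <= cap factor)."""
        idx = np.arange(120)
        mask = RegionMask(indices=idx, kind="whole-brain")
        truth = np.abs(rng.normal(10, 4, phantom.n_points)) + 1
        pred = truth + rng.normal(0, 0.8, phantom.n_points)
        gam, rate = gamma_index(pred, truth, crit, mask, points=phantom.points)
        ref_g, ref_rate = brute_force_gamma(
            phantom.points[idx] * 10.0, pred[idx], truth[idx], crit
        )
        assert rate == ref_rate
        # per-point values agree wherever the capped search resolves them
        resolved = ref_g <= crit.search_cap_factor
        assert np.allclose(gam[resolved], ref_g[resolved], atol=1e-10)
        assert np.all(gam[~resolved] > 1.0) and np.all(ref_g[~resolved] > 1.0)

    def test_monotone_in_criteria(self, phantom, rng):
        """pass(2/2) <= pass(3/3) <= pass(3/5) on random field pairs."""
        wb = RegionMask(indices=np.arange(phantom.n_points), kind="whole-brain")
        for seed in range(3):
            r = np.random.default_rng(seed)
            truth = np.abs(r.normal(10, 5, phantom.n_points)) + 1
            pred = truth + r.normal(0, 1.2, phantom.n_points)
            rates = [
                gamma_index(pred, truth, c, wb, points=phantom.points)[1]
                for c in (GammaCriteria(2, 2), GammaCriteria(3, 3), GammaCriteria(3, 5))
            ]
            assert rates[0] <= rates[1] <= rates[2]

    def test_directional(self, phantom, rng):
        """gamma(pred | truth) differs from gamma(truth | pred) in general."""
        wb = RegionMask(indices=np.arange(150), kind="whole-brain")
        truth = np.abs(rng.normal(10, 4, phantom.n_points)) + 1
        pred = truth * rng.uniform(0.7, 1.4, phantom.n_points)
        _, r1 = gamma_index(pred, truth, GammaCriteria(2, 2), wb, points=phantom.points)
        _, r2 = gamma_index(truth, pred, GammaCriteria(2, 2), wb, points=phantom.points)
        assert r1 != r2

    def test_zero_truth_rejected(self, phantom):
        wb = RegionMask(indices=np.arange(50), kind="whole-brain")
        with pytest.raises(ZeroFieldError):
            gamma_index(
                np.ones(phantom.n_points),
                np.zeros(phantom.n_points),
                GammaCriteria(3, 3),
                wb,
                points=phantom.points,
            )


class TestRegionMasks:
    def test_wb_is_brain_and_tr_subset(self, phantom):
        wb, tr = make_region_masks(phantom, SteeringTarget(0, 0, 0), radius=1.5)
        assert np.array_equal(wb.indices, np.flatnonzero(phantom.brain_mask))
        assert set(tr.indices) <= set(wb.indices)

    def test_tr_matches_direct_distance_filter(self, phantom):
        target = SteeringTarget(0, 0, 0)
        _, tr = make_region_masks(phantom, target, radius=1.5)
        d = np.linalg.norm(phantom.points - target.xyz, axis=1)
        expected = np.flatnonzero(phantom.brain_mask & (d <= 1.5))
        assert np.array_equal(np.sort(tr.indices), expected)

    def test_infinite_radius_gives_whole_brain(self, phantom):
        wb, tr = make_region_masks(phantom, SteeringTarget(0, 0, 0), radius=np.inf)
        assert np.array_equal(np.sort(tr.indices), np.sort(wb.indices))

    def test_target_outside_brain_rejected(self, phantom):
        with pytest.raises(InvalidArgumentError):
            make_region_masks(phantom, SteeringTarget(20, 0, 0), radius=1.5)

    def test_empty_target_region_rejected(self, phantom):
        with pytest.raises(InvalidArgumentError):
            make_region_masks(phantom, SteeringTarget(0, 0, 0), radius=1e-6)
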