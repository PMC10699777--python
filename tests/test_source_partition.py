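"""Endmember correction, Rayleigh trajectories, attribution, uncertainty."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from n2opulse import (
    EndmemberBox,
    MixtureScenario,
    RayleighParams,
    SubstrateSignatures,
    build_endmembers,
    classify_point,
    gen_isotopocule_samples,
    invert_f_remaining,
    partition_uncertainty,
    rayleigh_shift,
)
from n2opulse.errors import ConfigError, InsufficientDataError


def _point_box(name, point):
    """Zero-width box pinning a known endmember point."""
    return EndmemberBox(name, sp=(point[0], point[0]), d15n=(point[1], point[1]),
                        d18o=(point[2], point[2]))


class TestBuildEndmembers:
    def test_water_and_nitrate_shifts(self, cfg):
        boxes = build_endmembers(cfg.endmembers, cfg.substrates)
        raw = cfg.endmembers["bacterial_denitrification"]
        corr = boxes["bacterial_denitrification"]
        # -9‰ water is *added*, lowering the d18O range; +7.2‰ NO3 raises d15N
        assert corr.d18o == (raw.d18o[0] - 9.0, raw.d18o[1] - 9.0)
        assert corr.d15n == (raw.d15n[0] + 7.2, raw.d15n[1] + 7.2)
        assert corr.sp == raw.sp   # SP is never substrate-shifted

    def test_zero_substrates_are_identity(self, cfg):
        zeros = SubstrateSignatures(d18o_h2o=0.0, d15n_no3=0.0, d15n_no2=0.0,
                                    d15n_nh4=0.0)
        boxes = build_endmembers(cfg.endmembers, zeros)
        for name, box in boxes.items():
            assert box.ranges == cfg.endmembers[name].ranges

    @given(w=st.floats(-30.0, 30.0), n=st.floats(-30.0, 30.0))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_translation_conserves_widths(self, w, n):
        from n2opulse.config import default_endmembers

        raw_boxes = default_endmembers()
        subs = SubstrateSignatures(d18o_h2o=w, d15n_no3=n, d15n_no2=n, d15n_nh4=n)
        for name, box in build_endmembers(raw_boxes, subs).items():
            raw = raw_boxes[name]
            for axis in ("sp", "d15n", "d18o"):
                lo, hi = box.ranges[axis]
                rlo, rhi = raw.ranges[axis]
                assert hi - lo == pytest.approx(rhi - rlo, abs=1e-12)

    def test_missing_substrate_for_declared_basis(self, cfg):
        subs = SubstrateSignatures(d15n_no3=None)
        with pytest.raises(ConfigError, match="no3"):
            build_endmembers(cfg.endmembers, subs)


class TestRayleigh:
    def test_no_reduction_is_identity(self):
        p = RayleighParams()
        assert rayleigh_shift((1.0, 2.0, 3.0), p, 1.0) == (1.0, 2.0, 3.0)

    def test_closed_form_worked_case(self):
        p = RayleighParams(eps_sp=-6.0, eps_15=-6.0, eps_18=-6.0, mode="closed")
        sp, _, _ = rayleigh_shift((-1.9, 0.0, 0.0), p, 0.0855)
        assert sp == pytest.approx(-1.9 - 6.0 * np.log(0.0855), abs=1e-12)
        assert sp == pytest.approx(12.85, abs=0.01)

    def test_open_shift_is_bounded_and_enriching(self):
        p = RayleighParams(eps_sp=-6.0, eps_15=-6.0, eps_18=-6.0, mode="open")
        sp, _, _ = rayleigh_shift((0.0, 0.0, 0.0), p, 1e-9)
        assert sp == pytest.approx(6.0, abs=1e-6)   # bounded at -eps as f -> 0

    @pytest.mark.parametrize("mode", ["closed", "open"])
    @given(f=st.floats(0.001, 1.0), start=st.floats(-50.0, 50.0),
           eps=st.floats(-30.0, -0.5))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_shift_invert_round_trip(self, mode, f, start, eps):
        p = RayleighParams(eps_sp=eps, eps_15=eps, eps_18=eps, mode=mode)
        measured = rayleigh_shift((start, start, start), p, f)[0]
        res = invert_f_remaining(measured, start, eps, mode)
        assert res.f_rem == pytest.approx(f, abs=1e-12)
        assert not res.flagged

    def test_invert_worked_case(self):
        res = invert_f_remaining(12.8, -1.9, -6.0, "closed")
        assert res.f_rem == pytest.approx(0.0863, abs=5e-5)

    def test_measured_equals_start_gives_one(self):
        assert invert_f_remaining(5.0, 5.0, -6.0, "closed").f_rem == 1.0

    def test_wrong_direction_flags_not_raises(self):
        # measured lighter than start cannot come from reduction: f > 1
        res = invert_f_remaining(-10.0, 0.0, -6.0, "closed")
        assert res.flagged and res.f_rem == 1.0

    def test_f_zero_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_shift((0.0, 0.0, 0.0), RayleighParams(), 0.0)


class TestClassifyPoint:
    def test_point_inside_box_needs_no_reduction(self, cfg):
        boxes = build_endmembers(cfg.endmembers, cfg.substrates)
        target = boxes["bacterial_denitrification"].centroid()
        res = classify_point(tuple(target), boxes, cfg.rayleigh)
        assert res.process == "bacterial_denitrification"
        assert res.f_rem == pytest.approx(1.0)
        assert res.residual == pytest.approx(0.0, abs=1e-9)
        assert all(res.membership["bacterial_denitrification"].values())

    def test_box_corner_exact_match(self, cfg):
        boxes = build_endmembers(cfg.endmembers, cfg.substrates)
        fd = boxes["fungal_denitrification"]
        corner = (fd.sp[1], fd.d15n[1], fd.d18o[1])
        res = classify_point(corner, boxes, cfg.rayleigh, f_min=1.0, n_grid=1)
        assert res.process == "fungal_denitrification"
        assert res.residual == pytest.approx(0.0, abs=1e-9)

    def test_elevated_sp_attributed_to_denitrification_plus_reduction(self, cfg):
        # SP-only reading at 12.8‰ against the bacterial denitrification box
        boxes = {"bacterial_denitrification":
                 build_endmembers(cfg.endmembers, cfg.substrates)["bacterial_denitrification"]}
        params = dataclasses.replace(cfg.rayleigh, eps_sp=-6.0)
        res = classify_point((12.8, None, None), boxes, params)
        assert res.process == "bacterial_denitrification"
        assert res.f_rem < 1.0
        assert res.residual == pytest.approx(0.0, abs=1e-9)
        assert not res.membership["bacterial_denitrification"]["sp"]

    def test_residual_zero_iff_on_trajectory(self, cfg):
        boxes = build_endmembers(cfg.endmembers, cfg.substrates)
        start = boxes["bacterial_denitrification"].centroid()
        on = rayleigh_shift(start, cfg.rayleigh, 0.3)
        off = (on[0] + 5.0, on[1] - 5.0, on[2])
        assert classify_point(on, boxes, cfg.rayleigh).residual == pytest.approx(0.0, abs=1e-9)
        assert classify_point(off, boxes, cfg.rayleigh).residual > 1.0

    def test_no_axes_raises(self, cfg):
        boxes = build_endmembers(cfg.endmembers, cfg.substrates)
        with pytest.raises(InsufficientDataError):
            classify_point((None, None, None), boxes, cfg.rayleigh)

    def test_f_recovery_with_known_start(self, cfg):
        # 2‰ noise, known starting point: f recovered within 0.1 across (0.05, 1]
        rng = np.random.default_rng(42)
        raw = build_endmembers(cfg.endmembers, cfg.substrates)["bacterial_denitrification"]
        lo = np.array([raw.sp[0], raw.d15n[0], raw.d18o[0]])
        hi = np.array([raw.sp[1], raw.d15n[1], raw.d18o[1]])
        for f_true in (0.05, 0.1, 0.2, 0.5, 0.8, 1.0):
            for rep in range(5):
                start = rng.uniform(lo, hi)
                truth = np.array(rayleigh_shift(start, cfg.rayleigh, f_true))
                reading = truth + rng.normal(0.0, 2.0, 3) / np.sqrt(10)  # mean of 10 obs
                res = classify_point(
                    tuple(reading), {"bD": _point_box("bD", start)}, cfg.rayleigh
                )
                assert abs(res.f_rem - f_true) <= 0.1


class TestPartitionUncertainty:
    def test_zero_width_boxes_collapse_to_classify(self, cfg):
        point = (5.0, -10.0, 30.0)
        boxes = {"bacterial_denitrification": _point_box("bacterial_denitrification", point)}
        params = dataclasses.replace(
            cfg.rayleigh, eps_sp_range=None, eps_15_range=None, eps_18_range=None
        )
        reading = rayleigh_shift(point, params, 0.4)
        dist = partition_uncertainty([reading], boxes, params, n_draws=50, seed=1)
        ref = classify_point(reading, boxes, params)
        assert np.allclose(dist.f_samples, ref.f_rem, atol=1e-9)
        assert dist.process_weights == {"bacterial_denitrification": 1.0}

    def test_same_seed_same_quantiles(self, cfg):
        boxes = build_endmembers(cfg.endmembers, cfg.substrates)
        reading = (12.8, 18.6, 47.5)
        d1 = partition_uncertainty([reading], boxes, cfg.rayleigh, n_draws=200, seed=9)
        d2 = partition_uncertainty([reading], boxes, cfg.rayleigh, n_draws=200, seed=9)
        assert d1.f_quantiles == d2.f_quantiles
        assert d1.process_weights == d2.process_weights

    def test_interval_covers_known_f(self, cfg):
        # 90% interval from box/epsilon propagation covers truth >= 85% of 200 reps
        rng = np.random.default_rng(7)
        box = build_endmembers(cfg.endmembers, cfg.substrates)["bacterial_denitrification"]
        lo = np.array([box.sp[0], box.d15n[0], box.d18o[0]])
        hi = np.array([box.sp[1], box.d15n[1], box.d18o[1]])
        hits = 0
        for rep in range(200):
            start = rng.uniform(lo, hi)
            f_true = rng.uniform(0.1, 0.9)
            reading = np.array(rayleigh_shift(start, cfg.rayleigh, f_true))
            reading = reading + rng.normal(0.0, 1.0, 3)
            dist = partition_uncertainty(
                [tuple(reading)], {"bacterial_denitrification": box},
                cfg.rayleigh, n_draws=300, seed=rep,
            )
            if dist.f_quantiles[0.05] <= f_true <= dist.f_quantiles[0.95]:
                hits += 1
        assert hits >= 170


class TestGeneratorConsistency:
    def test_pure_process_no_reduction_stays_in_box(self, cfg):
        scn = MixtureScenario(fractions={"bacterial_denitrification": 1.0},
                              f_rem=1.0, noise_sd=0.0, seed=3)
        for r in gen_isotopocule_samples(scn, cfg):
            assert -7.5 <= r.sp <= 3.7

    def test_pinned_point_is_returned_exactly(self, cfg):
        scn = MixtureScenario(points={"bacterial_denitrification": (-1.9, 0.0, 20.0)},
                              f_rem=1.0, noise_sd=0.0, n_samples=2)
        for r in gen_isotopocule_samples(scn, cfg):
            assert r.point == pytest.approx((-1.9, 0.0, 20.0), abs=1e-12)

    def test_reduction_overprint_matches_closed_form(self, cfg):
        params = dataclasses.replace(cfg.rayleigh, eps_sp=-6.0)
        cfg2 = dataclasses.replace(cfg, rayleigh=params)
        scn = MixtureScenario(points={"bacterial_denitrification": (-1.9, 0.0, 20.0)},
                              f_rem=0.0855, noise_sd=0.0, n_samples=1)
        (r,) = gen_isotopocule_samples(scn, cfg2)
        assert r.sp == pytest.approx(-1.9 - 6.0 * np.log(0.0855), abs=1e-9)

    def test_f_zero_rejected(self, cfg):
        with pytest.raises(ValueError):
            MixtureScenario(f_rem=0.0).validate()
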