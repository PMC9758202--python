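"""Normalisation chain, averaging, dip extraction and classification."""

import dataclasses
import warnings

import numpy as np
import pytest
from scipy import stats

from mochafrap import processing as proc
from mochafrap import synthetic as syn
from mochafrap import theory as th


def _trace(spec, **kw):
    return syn.simulate_traces(spec, 1, **kw)[0]


@pytest.fixture(scope="module")
def free_full_spec():
    """Noise-free full-bleach-like free-diffusion ground truth."""
    p = th.FreeDiffusionParams(R_C=1.0, R_L=2.0, D_app=0.02)
    return syn.SyntheticTraceSpec(params=p, noise_sd=0.0, n_frames=200, seed=0)


class TestClassicNormalization:
    def test_round_trip_full_bleach_curve(self, free_full_spec):
        """The classic double normalisation recovers the closed-form
        full-bleach recovery of the permeable-circle model."""
        tr = _trace(free_full_spec)
        # build a trace whose bleached-ROI intensity follows S_full
        times = tr.times[tr.bleach_frame :] - tr.times[tr.bleach_frame]
        mc = th.free_diffusion_curves(free_full_spec.params, times)
        I_B = tr.I_B.copy()
        I_B[tr.bleach_frame :] = 100.0 + 1000.0 * (
            1 - 0.5 * (1 - mc.S_full)
        )
        tr2 = dataclasses.replace(tr, I_B=I_B)
        curve = proc.normalize_classic(tr2)
        np.testing.assert_allclose(curve.post_b, mc.S_full, atol=1e-9)

    def test_shared_decay_cancels_exactly(self, free_full_spec):
        short = dataclasses.replace(free_full_spec, n_frames=60)
        spec_dec = dataclasses.replace(short, acq_bleach_rate=0.2)
        c_plain = proc.normalize_classic(_trace(short))
        c_decay = proc.normalize_classic(_trace(spec_dec))
        np.testing.assert_allclose(c_decay.frap_b, c_plain.frap_b, atol=1e-6)

    def test_constant_trace_raises(self, free_full_spec):
        tr = _trace(free_full_spec)
        flat = dataclasses.replace(
            tr, I_B=np.full_like(tr.I_B, 600.0), I_NB=np.full_like(tr.I_NB, 600.0)
        )
        with pytest.raises(ValueError, match="no bleach detected"):
            proc.normalize_classic(flat)


class TestHalfNormalization:
    def test_leak_correction_restores_prebleach_level(self, llps_params_dip030):
        spec = syn.SyntheticTraceSpec(
            params=llps_params_dip030, noise_sd=0.0, bleach_leak=0.05, seed=1
        )
        tr = _trace(spec)
        c = proc.normalize_half(tr)
        _, nb1 = c.stages["I"]
        nb0 = (tr.I_NB - tr.I_BG) / (tr.I_REF - tr.I_BG)
        assert nb1[tr.bleach_frame] == pytest.approx(nb0[tr.i_pre], abs=1e-12)

    def test_equal_rois_weighted_half(self, llps_params_dip030):
        spec = syn.SyntheticTraceSpec(params=llps_params_dip030, noise_sd=0.0, seed=1)
        tr = _trace(spec)
        c = proc.normalize_half(tr)
        b1, _ = c.stages["I"]
        b2, _ = c.stages["II"]
        np.testing.assert_allclose(b2, b1 / 2.0)

    def test_double_normalisation_anchors(self, llps_params_dip030):
        spec = syn.SyntheticTraceSpec(params=llps_params_dip030, noise_sd=0.0, seed=1)
        c = proc.normalize_half(_trace(spec))
        assert c.frap_b[c.bleach_index] == pytest.approx(0.0, abs=1e-12)
        assert c.frap_nb[c.bleach_index] == pytest.approx(1.0, abs=1e-12)


class TestImmobileCorrection:
    def test_zero_immobile_fraction_is_identity(self, llps_params_dip030):
        spec = syn.SyntheticTraceSpec(
            params=llps_params_dip030, noise_sd=0.0, n_frames=500, seed=1
        )
        c4 = proc.normalize_half(_trace(spec))
        c5 = proc.correct_immobile(c4)
        assert c5.X_immobile == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(c5.frap_nb, c4.frap_nb, atol=1e-6)

    def test_programmed_immobile_fraction_recovered_with_noise(
        self, llps_params_dip030
    ):
        spec = syn.SyntheticTraceSpec(
            params=llps_params_dip030,
            noise_sd=0.02,
            immobile_fraction=0.20,
            n_frames=240,
            seed=21,
        )
        traces = syn.simulate_traces(spec, 20)
        xs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for tr in traces:
                xs.append(proc.correct_immobile(proc.normalize_half(tr)).X_immobile)
        assert np.mean(xs) == pytest.approx(0.20, abs=0.03)

    def test_truncated_trace_flags_plateau(self, llps_params_dip030):
        spec = syn.SyntheticTraceSpec(
            params=llps_params_dip030, noise_sd=0.0, n_frames=60, seed=1
        )
        c4 = proc.normalize_half(_trace(spec))
        with pytest.warns(UserWarning, match="plateau not reached"):
            c5 = proc.correct_immobile(c4)
        assert c5.plateau_reached is False


class TestAveraging:
    def test_identical_curves_average_to_input(self, llps_params_dip030):
        spec = syn.SyntheticTraceSpec(params=llps_params_dip030, noise_sd=0.0, seed=1)
        c = proc.correct_immobile(proc.normalize_half(_trace(spec)))
        avg = proc.average_curves([c, c])
        np.testing.assert_allclose(avg.sem_nb, 0.0, atol=1e-12)
        np.testing.assert_allclose(
            np.interp(avg.times, c.post_times, c.post_nb), avg.frap_nb, atol=1e-9
        )

    def test_radius_rescaling_collapses_curves(self, llps_params_dip030):
        """Noise-free curves from 1 µm and 2 µm structures collapse onto the
        same master curve after t/R² normalisation."""
        spec = syn.SyntheticTraceSpec(
            params=llps_params_dip030, noise_sd=0.0, n_frames=280, seed=1
        )
        traces = syn.simulate_traces(spec, 2, radii=[1.0, 2.0])
        curves = [proc.correct_immobile(proc.normalize_half(t)) for t in traces]
        avg = proc.average_curves(curves)
        p_ref = dataclasses.replace(
            llps_params_dip030,
            R=avg.mean_radius_um,
            h=llps_params_dip030.h
            * llps_params_dip030.R
            / avg.mean_radius_um,
        )
        mc = th.llps_curves(p_ref, np.maximum(avg.times, 0))
        coarse_step = spec.frame_interval_s * avg.mean_radius_um**2
        sel = avg.times > 2 * coarse_step
        assert np.max(np.abs(avg.frap_nb[sel] - mc.S_NB[sel])) < 1e-3

    def test_sem_scales_with_replicates(self, llps_params_dip030):
        spec = syn.SyntheticTraceSpec(params=llps_params_dip030, noise_sd=0.02, seed=2)
        curves = [
            proc.correct_immobile(proc.normalize_half(t))
            for t in syn.simulate_traces(spec, 16)
        ]
        a4 = proc.average_curves(curves[:4])
        a16 = proc.average_curves(curves)
        ratio = np.median(a4.sem_nb) / np.median(a16.sem_nb)
        assert ratio == pytest.approx(2.0, rel=0.4)

    def test_average_clipped_to_common_support(self, llps_params_dip030):
        spec = syn.SyntheticTraceSpec(params=llps_params_dip030, noise_sd=0.0, seed=1)
        traces = syn.simulate_traces(spec, 2, radii=[1.0, 3.0])
        curves = [proc.correct_immobile(proc.normalize_half(t)) for t in traces]
        avg = proc.average_curves(curves)
        norm_max = min(c.post_times[-1] / c.radius_um**2 for c in curves)
        assert avg.times[-1] / avg.mean_radius_um**2 <= norm_max + 1e-9


class TestDipDepth:
    def test_constant_curve_has_zero_dip(self):
        c = proc.AveragedCurve(
            times=np.linspace(0, 10, 100),
            frap_b=np.linspace(0, 1, 100),
            frap_nb=np.ones(100),
            sem_b=np.zeros(100),
            sem_nb=np.zeros(100),
            n=3,
            mean_radius_um=1.0,
        )
        res = proc.dip_depth(c)
        assert res.dip == 0.0 and res.flat

    def test_quadratic_minimum_reproduced_exactly(self):
        # a Savitzky-Golay filter of order 2 leaves quadratics untouched
        t = np.linspace(0, 10, 400)
        nb = 0.70 + 0.30 * np.minimum(((t - 4.0) / 3.0) ** 2, 1.0)
        c = proc.AveragedCurve(t, nb, nb, np.zeros_like(t), np.zeros_like(t), 3, 1.0)
        res = proc.dip_depth(c)
        assert res.dip == pytest.approx(0.30, abs=1e-5)
        assert res.argmin_time_s == pytest.approx(4.0, abs=0.05)

    def test_v_shaped_minimum_small_filter_bias(self):
        t = np.linspace(0, 10, 2000)
        nb = 0.70 + 0.30 * np.minimum(np.abs(t - 4.0) / 3.0, 1.0)
        c = proc.AveragedCurve(t, nb, nb, np.zeros_like(t), np.zeros_like(t), 3, 1.0)
        res = proc.dip_depth(c)
        assert res.dip == pytest.approx(0.30, abs=0.005)

    def test_short_curve_suggests_window_override(self):
        c = proc.AveragedCurve(
            times=np.linspace(0, 1, 10),
            frap_b=np.zeros(10),
            frap_nb=np.ones(10),
            sem_b=np.zeros(10),
            sem_nb=np.zeros(10),
            n=2,
            mean_radius_um=1.0,
        )
        with pytest.raises(ValueError, match="sg_window"):
            proc.dip_depth(c)


class TestSignificance:
    def test_identical_summaries_give_half(self):
        s = proc.ReferenceSummary(0.10, 0.03, 7)
        assert proc.dip_significance(s, s) == pytest.approx(0.5)

    def test_strong_separation(self):
        s = proc.ReferenceSummary(0.45, 0.001, 7)
        r = proc.ReferenceSummary(0.10, 0.001, 7)
        assert proc.dip_significance(s, r) < 1e-6

    def test_summary_path_equals_full_sample_path(self, rng):
        a = rng.normal(0.3, 0.05, 9)
        b = rng.normal(0.1, 0.04, 7)
        p_summary = proc.dip_significance(
            a, proc.ReferenceSummary(b.mean(), b.std(ddof=1), b.size)
        )
        p_full = stats.ttest_ind(a, b, equal_var=True, alternative="greater").pvalue
        assert abs(p_summary - p_full) < 1e-12

    def test_zero_variance_equal_means_convention(self):
        s = proc.ReferenceSummary(0.10, 0.0, 5)
        assert proc.dip_significance(s, s) == 0.5


class TestClassification:
    def _result(self, dip):
        return proc.DipDepthResult(dip=dip, sem=None, n=10, argmin_time_s=1.0)

    def test_deep_dip_called_llps(self):
        res = self._result(0.45)
        res.p_value = 1e-8
        assert proc.classify(res).classification == "LLPS"

    def test_shallow_dip_called_icbs_consistent(self):
        res = self._result(0.05)
        res.p_value = 0.5
        assert proc.classify(res).classification == "ICBS-consistent"

    def test_gray_zone_inconclusive(self):
        res = self._result(0.12)
        res.p_value = 0.2
        assert proc.classify(res).classification == "inconclusive"


class TestStackExtraction:
    def _stack(self, values, shape=(12, 20, 20)):
        stack = np.zeros(shape)
        masks = {}
        regions = {
            "B": (slice(2, 8), slice(2, 8)),
            "NB": (slice(2, 8), slice(10, 16)),
            "BG": (slice(16, 19), slice(0, 4)),
            "REF": (slice(16, 19), slice(10, 16)),
        }
        for name, region in regions.items():
            m = np.zeros(shape[1:], dtype=bool)
            m[region] = True
            masks[name] = m
            stack[:, m] = values[name][:, None]
        return stack, masks

    def test_constant_rois_extracted_exactly(self):
        n = 12
        values = {
            "B": np.full(n, 300.0),
            "NB": np.full(n, 700.0),
            "BG": np.full(n, 50.0),
            "REF": np.full(n, 900.0),
        }
        stack, masks = self._stack(values)
        tr = proc.roi_traces_from_stack(
            stack, masks["B"], masks["NB"], masks["BG"], masks["REF"],
            times=np.arange(n, dtype=float), radius_um=2.0,
            pre_bleach_frames=3, bleach_frame=3,
        )
        np.testing.assert_allclose(tr.I_B, 300.0)
        np.testing.assert_allclose(tr.I_REF, 900.0)
        assert tr.N_B == masks["B"].sum() and tr.N_NB == masks["NB"].sum()

    def test_rendered_model_round_trip(self, llps_params_dip030):
        """A stack rendered from a model curve reproduces it through the
        whole extraction + normalisation pipeline."""
        spec = syn.SyntheticTraceSpec(
            params=llps_params_dip030, noise_sd=0.0, n_frames=500, seed=1
        )
        ref_tr = syn.simulate_traces(spec, 1)[0]
        n = ref_tr.times.size
        values = {
            "B": ref_tr.I_B, "NB": ref_tr.I_NB,
            "BG": ref_tr.I_BG, "REF": ref_tr.I_REF,
        }
        stack, masks = self._stack(values, shape=(n, 20, 20))
        tr = proc.roi_traces_from_stack(
            stack, masks["B"], masks["NB"], masks["BG"], masks["REF"],
            times=ref_tr.times, radius_um=ref_tr.radius_um,
            pre_bleach_frames=ref_tr.pre_bleach_frames,
            bleach_frame=ref_tr.bleach_frame,
        )
        tr = dataclasses.replace(tr, N_B=ref_tr.N_B, N_NB=ref_tr.N_NB)
        c5 = proc.correct_immobile(proc.normalize_half(tr))
        times = ref_tr.times[ref_tr.bleach_frame:] - ref_tr.times[ref_tr.bleach_frame]
        mc = th.llps_curves(spec.params, times)
        assert np.max(np.abs(c5.post_nb - mc.S_NB)) < 1e-3

    def test_empty_mask_rejected(self):
        stack = np.ones((5, 10, 10))
        m = np.zeros((10, 10), dtype=bool)
        good = m.copy(); good[0, 0] = True
        good2 = m.copy(); good2[1, 1] = True
        good3 = m.copy(); good3[2, 2] = True
        with pytest.raises(ValueError, match="empty"):
            proc.roi_traces_from_stack(
                stack, good, good2, good3, m,
                times=np.arange(5.0), radius_um=1.0,
                pre_bleach_frames=2, bleach_frame=2,
            )
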