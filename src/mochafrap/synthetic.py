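"""Synthetic raw data emulating half-FRAP, coalescence and FCS acquisitions.

Every pipeline stage in this package can be exercised without microscope
data: this module renders ground-truth model curves into per-frame ROI
intensity traces with the experimental artifacts the processing chain is
built to remove (acquisition photobleaching, bleach leakage into the
non-bleached half, an immobile fraction, multiplicative shot-noise), plus
exponential droplet-coalescence relaxations and FCS correlation curves.

With all artifact knobs at zero the traces round-trip through the
processing chain to the exact model curve; the knobs therefore serve as
controlled perturbations whose removal can be verified.

Artifact model (per frame index j, bleach at frame ``b``):

* acquisition bleaching multiplies every fluorescent ROI (bleached half,
  non-bleached half and the reference structure, but not the background)
  by ``exp(-lambda j)`` — cancelled exactly by the per-frame reference
  division,
* the bleach pulse removes a fraction ``bleach_depth`` of the fluorophores
  in the bleached half and depresses the non-bleached ROI by the constant
  fraction ``bleach_leak`` — the additive leak correction restores it,
* a fraction ``immobile_fraction`` of molecules never exchanges,
* multiplicative Gaussian noise of relative SD ``noise_sd`` on each ROI
  signal above background (a shot-noise proxy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np

from .processing import RawTrace
from .theory import (
    FreeDiffusionParams,
    ICBSModelParams,
    LLPSModelParams,
    ModelCurve,
    SeriesSettings,
    free_diffusion_curves,
    icbs_curves,
    llps_curves,
)

__all__ = [
    "SyntheticTraceSpec",
    "simulate_traces",
    "simulate_coalescence",
    "simulate_fcs",
    "fcs_model",
]

AnyParams = Union[LLPSModelParams, FreeDiffusionParams, ICBSModelParams]


@dataclass(frozen=True)
class SyntheticTraceSpec:
    """Ground truth plus acquisition artifacts for one experiment family.

    Defaults follow a typical confocal half-FRAP acquisition: a handful of
    pre-bleach frames, 300 frames in total, ~50% bleach depth and 2%
    relative intensity noise.
    """

    params: AnyParams
    frame_interval_s: float = 0.8
    n_frames: int = 300
    pre_bleach_frames: int = 5
    bleach_depth: float = 0.5
    bleach_leak: float = 0.0
    acq_bleach_rate: float = 0.0
    immobile_fraction: float = 0.0
    noise_sd: float = 0.02
    seed: int = 0
    base_intensity: float = 1000.0
    background: float = 100.0
    ref_intensity: float = 800.0
    n_pixels_b: int = 600
    n_pixels_nb: int = 600

    def __post_init__(self) -> None:
        for name in (
            "bleach_depth",
            "bleach_leak",
            "acq_bleach_rate",
            "immobile_fraction",
            "noise_sd",
        ):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.bleach_depth == 0:
            raise ValueError("bleach_depth must be > 0")
        if self.n_frames <= self.pre_bleach_frames + 10:
            raise ValueError("n_frames must exceed pre_bleach_frames + 10")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")


def _model_curve_uncached(
    params: AnyParams, times: np.ndarray, settings: Optional[SeriesSettings]
) -> ModelCurve:
    if isinstance(params, LLPSModelParams):
        return llps_curves(params, times, settings)
    if isinstance(params, FreeDiffusionParams):
        return free_diffusion_curves(params, times, settings)
    if isinstance(params, ICBSModelParams):
        return icbs_curves(params, times, settings)
    raise TypeError(f"unsupported parameter type {type(params)!r}")


_CURVE_CACHE: dict = {}


def _model_curve(
    params: AnyParams, times: np.ndarray, settings: Optional[SeriesSettings]
) -> ModelCurve:
    # repeated Monte-Carlo draws share one deterministic ground-truth curve
    key = (params, settings, times.tobytes())
    if key not in _CURVE_CACHE:
        if len(_CURVE_CACHE) > 64:
            _CURVE_CACHE.clear()
        _CURVE_CACHE[key] = _model_curve_uncached(params, times, settings)
    return _CURVE_CACHE[key]


def _with_radius(params: AnyParams, radius: float) -> AnyParams:
    if isinstance(params, LLPSModelParams):
        # keep the dimensionless boundary strength h*R fixed so the
        # programmed dip is radius independent
        return replace(params, R=radius, h=params.h * params.R / radius)
    scale = radius / params.R_C
    return replace(params, R_C=radius, R_L=params.R_L * scale)


def simulate_traces(
    spec: SyntheticTraceSpec,
    n_experiments: int = 1,
    radii: Optional[Sequence[float]] = None,
    settings: Optional[SeriesSettings] = None,
) -> list[RawTrace]:
    """Render ``n_experiments`` noisy ROI traces from the ground truth.

    ``radii`` optionally cycles per-experiment structure radii; the
    dimensionless model shape (boundary strength, domain ratio) is kept so
    all experiments share the same programmed dip while recovery times scale
    with radius².
    """
    rng = np.random.default_rng(spec.seed)
    n_post = spec.n_frames - spec.pre_bleach_frames
    post_times = np.arange(n_post) * spec.frame_interval_s
    frames = np.arange(spec.n_frames)
    times = frames * spec.frame_interval_s

    curves: dict[float, ModelCurve] = {}
    traces = []
    for i in range(n_experiments):
        radius = (
            float(radii[i % len(radii)])
            if radii is not None
            else (spec.params.R if isinstance(spec.params, LLPSModelParams) else spec.params.R_C)
        )
        if radius not in curves:
            p = _with_radius(spec.params, radius)
            eval_times = post_times.copy()
            eval_times[0] = 0.0
            curves[radius] = _model_curve(p, eval_times, settings)
        mc = curves[radius]
        S_B, S_NB = mc.S_B, mc.S_NB

        X = spec.immobile_fraction
        b = spec.bleach_depth
        mobile_b = 1.0 - b * (1.0 - S_B)
        mobile_nb = 1.0 - b * (1.0 - S_NB)
        fluor_b = X * (1.0 - b) + (1.0 - X) * mobile_b
        fluor_nb = (1.0 - X) * mobile_nb + X * 1.0 - spec.bleach_leak

        f_b = np.ones(spec.n_frames)
        f_nb = np.ones(spec.n_frames)
        f_b[spec.pre_bleach_frames :] = fluor_b
        f_nb[spec.pre_bleach_frames :] = fluor_nb

        decay = np.exp(-spec.acq_bleach_rate * frames)
        sig_b = spec.base_intensity * f_b * decay
        sig_nb = spec.base_intensity * f_nb * decay
        sig_ref = spec.ref_intensity * decay
        if spec.noise_sd > 0:
            sig_b = sig_b * (1.0 + spec.noise_sd * rng.standard_normal(spec.n_frames))
            sig_nb = sig_nb * (1.0 + spec.noise_sd * rng.standard_normal(spec.n_frames))
            sig_ref = sig_ref * (1.0 + spec.noise_sd * rng.standard_normal(spec.n_frames))
        traces.append(
            RawTrace(
                frames=frames,
                times=times,
                I_B=spec.background + sig_b,
                I_NB=spec.background + sig_nb,
                I_BG=np.full(spec.n_frames, spec.background),
                I_REF=spec.background + sig_ref,
                N_B=spec.n_pixels_b,
                N_NB=spec.n_pixels_nb,
                radius_um=radius,
                pre_bleach_frames=spec.pre_bleach_frames,
                bleach_frame=spec.pre_bleach_frames,
                experiment_id=f"sim-{spec.seed}-{i:03d}",
            )
        )
    return traces


# ---------------------------------------------------------------------------
# droplet coalescence
# ---------------------------------------------------------------------------


def simulate_coalescence(
    eta_over_gamma: float,
    radii: Sequence[float],
    e_pre: float = 0.6,
    e_post: float = 0.02,
    noise_sd: float = 0.0,
    n_points: int = 80,
    span_tau: float = 5.0,
    seed: int = 0,
):
    """Eccentricity relaxations of droplet-fusion events.

    Each event decays as ``e(t) = e_post + (e_pre - e_post) exp(-t/tau_e)``
    with ``tau_e = (eta/gamma) * R_final`` — the linear size dependence that
    yields the inverse capillary velocity.  Returns a list of
    ``(times, eccentricities, R_final)`` tuples; noise is additive Gaussian
    with SD ``noise_sd * e_pre``.
    """
    if eta_over_gamma <= 0:
        raise ValueError("eta_over_gamma must be positive")
    rng = np.random.default_rng(seed)
    events = []
    for r in radii:
        tau = eta_over_gamma * float(r)
        t = np.linspace(0.0, span_tau * tau, n_points)
        e = e_post + (e_pre - e_post) * np.exp(-t / tau)
        if noise_sd > 0:
            e = e + noise_sd * e_pre * rng.standard_normal(n_points)
        events.append((t, e, float(r)))
    return events


# ---------------------------------------------------------------------------
# fluorescence correlation spectroscopy
# ---------------------------------------------------------------------------


def fcs_model(
    tau: np.ndarray,
    N: float,
    tau_d: float,
    alpha: float = 1.0,
    kappa: float = 5.0,
    f_T: float = 0.0,
    tau_T: float = 5e-6,
) -> np.ndarray:
    """Anomalous-diffusion FCS autocorrelation with a triplet term.

    ``G(tau) = (1/N) (1 + (tau/tau_d)^alpha)^-1
    (1 + kappa^-2 (tau/tau_d)^alpha)^-1/2 (1 + f_T exp(-tau/tau_T))``
    with ``N`` particles in the focal volume, diffusion time ``tau_d``,
    anomaly exponent ``alpha`` and structural parameter ``kappa``.
    """
    tau = np.asarray(tau, dtype=float)
    x = (tau / tau_d) ** alpha
    g = (1.0 / N) / (1.0 + x) / np.sqrt(1.0 + x / kappa**2)
    if f_T > 0:
        g = g * (1.0 + f_T * np.exp(-tau / tau_T))
    return g


def simulate_fcs(
    N: float,
    tau_d: float,
    alpha: float = 1.0,
    kappa: float = 5.0,
    f_T: float = 0.0,
    tau_T: float = 5e-6,
    lags: Optional[np.ndarray] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """A noisy FCS correlation curve on a log-spaced lag grid.

    Noise is additive Gaussian with SD ``noise_sd * G(0+)`` (correlator
    noise is roughly amplitude-proportional at short lags).  Returns
    ``(lags, G)``.
    """
    if lags is None:
        lags = np.logspace(-6.5, 1, 160)
    lags = np.asarray(lags, dtype=float)
    g = fcs_model(lags, N, tau_d, alpha, kappa, f_T, tau_T)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        g = g + noise_sd * (1.0 + f_T) / N * rng.standard_normal(lags.size)
    return lags, g
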