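"""Condensate material properties and the dip-depth <-> energy master curve.

The calibration chain turns three desk measurements into the interfacial
energy a molecule pays when crossing a condensate boundary:

1. droplet-fusion relaxation times scale linearly with the final droplet
   radius; the slope is the inverse capillary velocity ``eta/gamma`` (s/µm),
2. the condensate viscosity ``eta`` follows from intra-condensate diffusion
   times (FCS or the half-minus-full FRAP difference) referenced against a
   calibration series of known viscosity,
3. the interfacial tension is ``gamma = eta / (eta/gamma)`` and the energy
   per molecule ``dG = gamma * 2 pi R_h²`` (half the surface of a sphere of
   hydrodynamic radius ``R_h``).

Plotting the half-FRAP dip depth against ``dG`` for a panel of condensates
yields a sigmoidal master curve; inverting it converts a measured dip into
an apparent interfacial energy (and tension), the quantitative output of
the calibrated half-bleach workflow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import special
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

__all__ = [
    "CoalescenceEvent",
    "FcsFit",
    "InterfacialProperties",
    "CalibrationCurve",
    "BarrierResult",
    "K_BOLTZMANN",
    "fit_coalescence",
    "inverse_capillary_velocity",
    "fit_fcs",
    "viscosity_from_tau",
    "tau_from_half_frap",
    "interfacial_tension",
    "energy_per_molecule",
    "fit_master_curve",
    "invert_master_curve",
    "example_master_curve_points",
]

K_BOLTZMANN = 1.380649e-23  # J/K
DEFAULT_TEMPERATURE = 298.15  # K, in vitro room temperature


@dataclass
class CoalescenceEvent:
    """One droplet-fusion event and its fitted exponential relaxation."""

    times: np.ndarray
    eccentricity: np.ndarray
    R_final_um: float
    e_pre: Optional[float] = None
    e_post: Optional[float] = None
    tau_e: Optional[float] = None
    residual_rms: Optional[float] = None


@dataclass
class FcsFit:
    """Fitted FCS parameters (structural parameter kappa held fixed)."""

    N: float
    tau_d: float
    alpha: float
    kappa: float
    f_T: float
    tau_T: float
    covariance: Optional[np.ndarray] = None

    @property
    def g0(self) -> float:
        """Zero-lag amplitude (1/N)(1 + f_T)."""
        return (1.0 + self.f_T) / self.N


@dataclass
class InterfacialProperties:
    inverse_capillary_velocity_s_per_um: float
    viscosity_pa_s: float
    interfacial_tension_uJ_per_m2: float
    hydrodynamic_radius_nm: float
    temperature_K: float
    delta_g_J: float
    delta_g_kT: float


@dataclass
class CalibrationCurve:
    """Monotone log-logistic master relation dip(dG) with bootstrap spread.

    ``dip(E) = d0 + (d_inf - d0) / (1 + (E50/E)^s)`` — baseline ``d0`` near
    the free-diffusion dip, plateau ``d_inf <= 0.5``, midpoint energy
    ``E50`` (kT) and steepness ``s``.
    """

    d0: float
    d_inf: float
    e50_kT: float
    steepness: float
    points_dip: np.ndarray = field(default=None, repr=False)
    points_energy_kT: np.ndarray = field(default=None, repr=False)
    bootstrap: Optional[np.ndarray] = field(default=None, repr=False)

    def __call__(self, energy_kT) -> np.ndarray | float:
        out = _sigmoid(
            np.asarray(energy_kT, dtype=float),
            self.d0,
            self.d_inf - self.d0,
            self.e50_kT,
            self.steepness,
        )
        return out if np.ndim(energy_kT) else float(out)

    def invert(self, dip: float) -> float:
        """Energy (kT) at which the fitted curve equals ``dip``."""
        if not self.d0 < dip < self.d_inf:
            raise ValueError(
                f"dip {dip:.3f} outside the invertible range "
                f"({self.d0:.3f}, {self.d_inf:.3f})"
            )
        frac = (self.d_inf - self.d0) / (dip - self.d0) - 1.0
        return self.e50_kT / frac ** (1.0 / self.steepness)


@dataclass
class BarrierResult:
    status: str  # "ok", "no-barrier", "above-range"
    energy_kT: Optional[float] = None
    ci_kT: Optional[tuple] = None
    gamma_app_uJ_per_m2: Optional[float] = None


# ---------------------------------------------------------------------------
# coalescence
# ---------------------------------------------------------------------------


def fit_coalescence(
    times, eccentricity, R_final_um: float
) -> CoalescenceEvent:
    """Exponential fit e(t) = e_post + (e_pre - e_post) exp(-t/tau_e)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(eccentricity, dtype=float)
    if t.size < 10:
        raise ValueError("need at least 10 time points per fusion event")
    drop = e[: max(t.size // 5, 2)].mean() - e[-max(t.size // 5, 2) :].mean()
    if drop <= 1e-12:
        raise ValueError("eccentricity series does not decay; no relaxation to fit")

    def model(t, e_post, amp, tau):
        return e_post + amp * np.exp(-t / tau)

    p0 = (float(e[-1]), float(e[0] - e[-1]), float(t[-1] / 3.0))
    popt, _ = curve_fit(
        model,
        t,
        e,
        p0=p0,
        bounds=([-0.2, 1e-9, 1e-12], [1.0, 1.5, np.inf]),
        maxfev=10000,
    )
    e_post, amp, tau = popt
    if t[-1] < 2.0 * tau:
        warnings.warn(
            f"event spans only {t[-1] / tau:.1f} relaxation times (< 2); "
            "tau_e may be poorly constrained",
            stacklevel=2,
        )
    resid = e - model(t, *popt)
    return CoalescenceEvent(
        times=t,
        eccentricity=e,
        R_final_um=float(R_final_um),
        e_pre=float(e_post + amp),
        e_post=float(e_post),
        tau_e=float(tau),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def inverse_capillary_velocity(
    events: Sequence[CoalescenceEvent],
) -> tuple[float, float]:
    """Through-origin slope of tau_e versus R_final: eta/gamma in s/µm."""
    fitted = [ev for ev in events if ev.tau_e is not None]
    radii = np.array([ev.R_final_um for ev in fitted])
    taus = np.array([ev.tau_e for ev in fitted])
    keep = radii > 0
    radii, taus = radii[keep], taus[keep]
    if np.unique(np.round(radii, 9)).size < 3:
        raise ValueError("need >= 3 events with distinct final radii")
    slope = float(np.sum(radii * taus) / np.sum(radii**2))
    if slope <= 0:
        raise ValueError(f"non-physical negative slope {slope:.3g}")
    resid = taus - slope * radii
    se = float(
        math.sqrt(np.sum(resid**2) / (radii.size - 1) / np.sum(radii**2))
    )
    return slope, se


# ---------------------------------------------------------------------------
# FCS and viscosity
# ---------------------------------------------------------------------------


def fit_fcs(
    lags,
    G,
    kappa: float = 5.0,
    fit_triplet: bool = True,
    weights=None,
) -> FcsFit:
    """Least-squares fit of the anomalous-diffusion FCS model (kappa fixed)."""
    from .synthetic import fcs_model

    lags = np.asarray(lags, dtype=float)
    G = np.asarray(G, dtype=float)
    g0 = max(float(G[: max(3, lags.size // 50)].mean()), 1e-12)
    i_half = int(np.argmin(np.abs(G - g0 / 2.0)))
    p0_tau = float(lags[i_half]) if lags[i_half] > 0 else 1e-3

    if fit_triplet:

        def model(t, N, tau_d, alpha, f_T, tau_T):
            return fcs_model(t, N, tau_d, alpha, kappa, f_T, tau_T)

        p0 = (1.0 / g0, p0_tau, 1.0, 0.05, 5e-6)
        lb = (1e-9, 1e-12, 0.05, 0.0, 1e-9)
        ub = (np.inf, np.inf, 2.0, 0.999, p0_tau)
    else:

        def model(t, N, tau_d, alpha):
            return fcs_model(t, N, tau_d, alpha, kappa, 0.0, 1.0)

        p0 = (1.0 / g0, p0_tau, 1.0)
        lb = (1e-9, 1e-12, 0.05)
        ub = (np.inf, np.inf, 2.0)

    sigma = None if weights is None else 1.0 / np.asarray(weights, dtype=float)
    popt, pcov = curve_fit(
        model, lags, G, p0=p0, bounds=(lb, ub), sigma=sigma, maxfev=20000
    )
    alpha = popt[2]
    if alpha <= lb[2] + 1e-6 or alpha >= ub[2] - 1e-6:
        warnings.warn(
            f"anomaly exponent pinned at its bound (alpha={alpha:.3f})",
            stacklevel=2,
        )
    if fit_triplet:
        N, tau_d, alpha, f_T, tau_T = popt
    else:
        (N, tau_d, alpha), f_T, tau_T = popt, 0.0, 0.0
    return FcsFit(
        N=float(N),
        tau_d=float(tau_d),
        alpha=float(alpha),
        kappa=float(kappa),
        f_T=float(f_T),
        tau_T=float(tau_T),
        covariance=pcov,
    )


def viscosity_from_tau(
    tau_d: float, calibration: Sequence[tuple[float, float]]
) -> float:
    """Viscosity (Pa s) from a diffusion time via a known-viscosity series.

    ``calibration`` holds (viscosity Pa s, tau_d s) pairs from reference
    fluids; tau_d is proportional to viscosity (Stokes-Einstein), so a
    through-origin fit gives s = tau per unit viscosity and
    ``eta = tau_d / s``.
    """
    cal = np.asarray(calibration, dtype=float)
    if cal.ndim != 2 or cal.shape[1] != 2 or cal.shape[0] < 3:
        raise ValueError("need >= 3 (viscosity, tau_d) calibration pairs")
    eta_c, tau_c = cal[:, 0], cal[:, 1]
    order = np.argsort(eta_c)
    if np.any(np.diff(tau_c[order]) <= 0):
        raise ValueError("calibration table is not monotone in viscosity")
    slope = float(np.sum(eta_c * tau_c) / np.sum(eta_c**2))
    eta = tau_d / slope
    if eta > 2.0 * eta_c.max() or eta < 0.5 * eta_c.min():
        warnings.warn(
            f"viscosity {eta:.3g} Pa s extrapolates beyond the calibration "
            f"range [{eta_c.min():.3g}, {eta_c.max():.3g}]",
            stacklevel=2,
        )
    return float(eta)


def tau_from_half_frap(
    times, F_half, F_full, R_um: float
) -> tuple[float, float]:
    """Internal diffusion time from the half-minus-full recovery difference.

    ``F_diff = F_half - F_full`` isolates mixing inside the condensate from
    exchange across its boundary; it is fitted with the circular-spot
    recovery ``A exp(-2 tau/t) [I0(2 tau/t) + I1(2 tau/t)]`` whose long-time
    limit is ``A``.  Returns ``(A, tau_d)``; ``tau_d = R²/(4 D)`` with R the
    bleach-region radius.
    """
    t = np.asarray(times, dtype=float)
    diff = np.asarray(F_half, dtype=float) - np.asarray(F_full, dtype=float)
    keep = t > 0
    t, diff = t[keep], diff[keep]
    if np.all(diff <= 0):
        raise ValueError("difference curve is non-positive; nothing to fit")

    def model(t, A, tau):
        x = 2.0 * tau / t
        return A * (special.i0e(x) + special.i1e(x))

    p0 = (float(diff.max()), R_um**2 / 4.0)
    popt, _ = curve_fit(
        model, t, diff, p0=p0, bounds=([1e-9, 1e-12], [2.0, np.inf]),
        maxfev=20000,
    )
    return float(popt[0]), float(popt[1])


# ---------------------------------------------------------------------------
# tension and energy per molecule
# ---------------------------------------------------------------------------


def interfacial_tension(
    viscosity_pa_s: float, icv_s_per_um: float
) -> float:
    """gamma = eta / (eta/gamma), returned in µJ/m² (= µN/m).

    1 s/µm = 1e6 s/m, and Pa s / (s/m) = N/m, so the numeric value of
    eta[Pa s] / icv[s/µm] is already in µN/m.
    """
    if viscosity_pa_s <= 0 or icv_s_per_um <= 0:
        raise ValueError("viscosity and inverse capillary velocity must be > 0")
    return viscosity_pa_s / icv_s_per_um


def energy_per_molecule(
    gamma_uJ_per_m2: float,
    R_h_nm: float,
    temperature_K: float = DEFAULT_TEMPERATURE,
) -> tuple[float, float]:
    """Interfacial energy per molecule: dG = gamma * (4 pi R_h²)/2.

    Each molecule at the interface contributes half the surface of a sphere
    of its hydrodynamic radius.  Returns ``(dG in J, dG in kT)``.
    """
    if gamma_uJ_per_m2 < 0 or R_h_nm <= 0 or temperature_K <= 0:
        raise ValueError("gamma must be >= 0 and R_h, T positive")
    dg_J = (gamma_uJ_per_m2 * 1e-6) * 2.0 * math.pi * (R_h_nm * 1e-9) ** 2
    return dg_J, dg_J / (K_BOLTZMANN * temperature_K)


# ---------------------------------------------------------------------------
# master curve
# ---------------------------------------------------------------------------


def _sigmoid(e, d0, span, e50, s):
    e = np.asarray(e, dtype=float)
    with np.errstate(divide="ignore"):
        z = np.clip(s * (math.log(e50) - np.log(np.maximum(e, 0.0))), -700, 700)
    return d0 + span / (1.0 + np.exp(z))


def fit_master_curve(
    dips,
    energies_kT,
    dip_errs=None,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> CalibrationCurve:
    """Fit the monotone log-logistic dip(dG) master relation.

    Points at zero energy anchor the baseline ``d0``.  Bootstrap parameter
    samples (pair resampling, or parametric when ``dip_errs`` is given) are
    stored for the inversion confidence intervals.
    """
    dips = np.asarray(dips, dtype=float)
    energies = np.asarray(energies_kT, dtype=float)
    if dips.size != energies.size or dips.size < 4:
        raise ValueError("need >= 4 (dip, energy) points")
    pos = energies > 0
    if pos.sum() >= 3:
        rho = spearmanr(energies[pos], dips[pos]).statistic
        if rho < -0.2:
            raise ValueError(
                "dip depths decrease with energy beyond noise; a monotone "
                "master curve cannot represent these points"
            )

    def do_fit(d, e):
        base = d[e <= 0].mean() if np.any(e <= 0) else d.min()
        p0 = (
            min(max(base, 1e-3), 0.149),
            min(max(d.max() - base, 0.05), 0.49),
            float(np.median(e[e > 0])),
            1.5,
        )
        popt, _ = curve_fit(
            _sigmoid,
            e,
            d,
            p0=p0,
            bounds=([0.0, 0.0, 1e-9, 0.2], [0.15, 0.5, 1e3, 10.0]),
            maxfev=20000,
        )
        return popt

    d0, span, e50, s = do_fit(dips, energies)
    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_bootstrap):
        try:
            if dip_errs is not None:
                d_b = dips + np.asarray(dip_errs, dtype=float) * rng.standard_normal(
                    dips.size
                )
                boot.append(do_fit(d_b, energies))
            else:
                idx = rng.integers(0, dips.size, dips.size)
                if np.unique(energies[idx]).size < 4:
                    continue
                boot.append(do_fit(dips[idx], energies[idx]))
        except RuntimeError:
            continue
    return CalibrationCurve(
        d0=float(d0),
        d_inf=float(d0 + span),
        e50_kT=float(e50),
        steepness=float(s),
        points_dip=dips,
        points_energy_kT=energies,
        bootstrap=np.asarray(boot) if boot else None,
    )


def invert_master_curve(
    curve: CalibrationCurve,
    dip: float,
    dip_sem: float = 0.0,
    R_h_nm: Optional[float] = None,
    temperature_K: float = DEFAULT_TEMPERATURE,
) -> BarrierResult:
    """Apparent interfacial energy (and tension) from a measured dip depth.

    Dips at or below the fitted baseline (within one SEM) are reported as
    ``no-barrier`` — the regime of clustered binding sites — and dips at or
    above the plateau as ``above-range`` rather than as numbers.
    """
    if dip <= curve.d0 + dip_sem:
        return BarrierResult(status="no-barrier")
    if dip >= curve.d_inf - dip_sem:
        return BarrierResult(status="above-range")
    energy = curve.invert(dip)
    los, his = [], []
    for d in (dip - dip_sem, dip + dip_sem):
        params = (
            curve.bootstrap
            if curve.bootstrap is not None and len(curve.bootstrap)
            else np.array([[curve.d0, curve.d_inf - curve.d0, curve.e50_kT, curve.steepness]])
        )
        vals = []
        for d0, span, e50, s in params:
            if d0 < d < d0 + span:
                frac = span / (d - d0) - 1.0
                vals.append(e50 / frac ** (1.0 / s))
        if vals:
            los.append(np.percentile(vals, 2.5))
            his.append(np.percentile(vals, 97.5))
    ci = (float(min(los)), float(max(his))) if los else None
    gamma = None
    if R_h_nm is not None:
        dg_J = energy * K_BOLTZMANN * temperature_K
        gamma = dg_J / (2.0 * math.pi * (R_h_nm * 1e-9) ** 2) * 1e6
    return BarrierResult(
        status="ok", energy_kT=energy, ci_kT=ci, gamma_app_uJ_per_m2=gamma
    )


def example_master_curve_points():
    """A synthetic example calibration table (not experimental data).

    Eight (dip, energy) points drawn from a representative log-logistic with
    baseline 0.10, plateau 0.48, midpoint 0.045 kT and steepness 1.6,
    mimicking the magnitudes of in vitro condensate panels.  Useful for
    demonstrations and round-trip tests; real analyses should supply their
    own measured points.
    """
    energies = np.array([0.0, 0.005, 0.01, 0.02, 0.045, 0.08, 0.12, 0.2])
    truth = CalibrationCurve(d0=0.10, d_inf=0.48, e50_kT=0.045, steepness=1.6)
    dips = np.array([truth(e) for e in energies])
    sems = np.full_like(dips, 0.012)
    return dips, energies, sems
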