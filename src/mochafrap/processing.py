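"""Raw ROI traces -> normalised FRAP curves -> dip depth and mechanism call.

The processing chain mirrors how half-bleach experiments are quantified on a
confocal microscope.  Per frame, mean intensities of four regions are
recorded: the bleached half (``I_B``), the non-bleached half (``I_NB``), the
image background (``I_BG``) and an unbleached reference structure
(``I_REF``).  From these the pipeline computes, in order:

I    background/reference-corrected curves (cancels acquisition bleaching),
II   correction of bleach leakage into the nominal non-bleached half,
     then weighting by ROI pixel counts (particle-number proportional),
III  double normalisation by the number of bleached molecules,
IV   additive offset bringing the non-bleached half to 1 pre-bleach,
V    rescaling by 1/(1 - X_immobile) once both halves reached a plateau.

The dip depth — the maximum fractional decrease of the stage-V non-bleached
signal, located on a Savitzky-Golay smoothed curve — is the model-free
statistic: values significantly above the free-diffusion reference indicate
an interfacial barrier (LLPS), values at or below it are consistent with
binding to clustered sites (ICBS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter
from scipy import stats

__all__ = [
    "RawTrace",
    "HalfFrapCurve",
    "AveragedCurve",
    "ReferenceSummary",
    "DipDepthResult",
    "DEFAULT_REFERENCE",
    "normalize_classic",
    "normalize_half",
    "correct_immobile",
    "average_curves",
    "dip_depth",
    "dips_per_experiment",
    "dip_significance",
    "classify",
    "roi_traces_from_stack",
]

CLASS_LABELS = ("LLPS", "ICBS-consistent", "inconclusive")


@dataclass
class RawTrace:
    """Per-frame ROI intensities plus the geometry of one experiment."""

    frames: np.ndarray
    times: np.ndarray
    I_B: np.ndarray
    I_NB: np.ndarray
    I_BG: np.ndarray
    I_REF: np.ndarray
    N_B: int
    N_NB: int
    radius_um: float
    pre_bleach_frames: int
    bleach_frame: int
    experiment_id: str = ""

    def __post_init__(self) -> None:
        for name in ("frames", "times", "I_B", "I_NB", "I_BG", "I_REF"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.times.size
        for name in ("frames", "I_B", "I_NB", "I_BG", "I_REF"):
            if getattr(self, name).size != n:
                raise ValueError(f"column {name} has wrong length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.I_REF <= self.I_BG):
            raise ValueError("I_REF must exceed I_BG in every frame")
        if not (0 < self.pre_bleach_frames <= self.bleach_frame):
            raise ValueError(
                "bleach_frame must come after the pre-bleach frames "
                f"(pre={self.pre_bleach_frames}, bleach={self.bleach_frame})"
            )
        if self.bleach_frame >= n:
            raise ValueError("bleach_frame outside the recorded range")
        if self.N_B < 0 or self.N_NB < 0 or self.N_B + self.N_NB == 0:
            raise ValueError("ROI pixel counts must be positive")
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")

    @property
    def i_pre(self) -> int:
        """Index of the last pre-bleach frame."""
        return self.pre_bleach_frames - 1


@dataclass
class HalfFrapCurve:
    """Normalised half-FRAP curves with all intermediate stages kept."""

    times: np.ndarray
    frap_b: np.ndarray
    frap_nb: np.ndarray
    radius_um: float
    bleach_index: int
    stage: str
    stages: dict = field(default_factory=dict)
    X_immobile: Optional[float] = None
    plateau_reached: Optional[bool] = None
    experiment_id: str = ""

    @property
    def post_times(self) -> np.ndarray:
        """Times since the bleach frame, post-bleach part of the curve."""
        return self.times[self.bleach_index :] - self.times[self.bleach_index]

    @property
    def post_nb(self) -> np.ndarray:
        return self.frap_nb[self.bleach_index :]

    @property
    def post_b(self) -> np.ndarray:
        return self.frap_b[self.bleach_index :]


@dataclass
class AveragedCurve:
    """Replicate-averaged curve on a common (radius-normalised) time grid."""

    times: np.ndarray
    frap_b: np.ndarray
    frap_nb: np.ndarray
    sem_b: np.ndarray
    sem_nb: np.ndarray
    n: int
    mean_radius_um: float


@dataclass(frozen=True)
class ReferenceSummary:
    """Summary statistics of the free-diffusion dip-depth reference."""

    mean: float
    sd: float
    n: int


#: Free-diffusion reference dip measured for freely diffusing molecules in
#: the one-phase regime (mean 10%, SD 3%, 7 experiments).  Replace with a
#: lab-specific measurement where available.
DEFAULT_REFERENCE = ReferenceSummary(mean=0.10, sd=0.03, n=7)


@dataclass
class DipDepthResult:
    dip: float
    sem: Optional[float]
    n: int
    argmin_time_s: float
    flat: bool = False
    p_value: Optional[float] = None
    reference: Optional[ReferenceSummary] = None
    classification: Optional[str] = None
    sample_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dip < -0.05 or self.dip > 0.6:
            warnings.warn(
                f"dip depth {self.dip:.3f} outside the plausible range "
                "[-0.05, 0.6]; check the normalisation",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------


def _reference_corrected(trace: RawTrace, signal: np.ndarray) -> np.ndarray:
    return (signal - trace.I_BG) / (trace.I_REF - trace.I_BG)


def normalize_classic(trace: RawTrace) -> HalfFrapCurve:
    """Double-normalised full/partial-FRAP curve of the bleached ROI.

    Background and reference corrected per frame, then scaled so the curve is
    1 before the bleach and 0 in the first post-bleach frame.
    """
    frap = _reference_corrected(trace, trace.I_B)
    pre, blc = frap[trace.i_pre], frap[trace.bleach_frame]
    denom = pre - blc
    if abs(denom) < 1e-9 * abs(pre):
        raise ValueError("no bleach detected: pre- and post-bleach levels equal")
    curve = (frap - blc) / denom
    return HalfFrapCurve(
        times=trace.times,
        frap_b=curve,
        frap_nb=np.full_like(curve, np.nan),
        radius_um=trace.radius_um,
        bleach_index=trace.bleach_frame,
        stage="classic",
        stages={"classic": (curve.copy(), None)},
        experiment_id=trace.experiment_id,
    )


def normalize_half(trace: RawTrace) -> HalfFrapCurve:
    """Half-FRAP normalisation through stages I-IV (leak corrected,
    particle-number weighted, double normalised, non-bleached half at 1)."""
    b0 = _reference_corrected(trace, trace.I_B)
    nb0 = _reference_corrected(trace, trace.I_NB)
    ip, ib = trace.i_pre, trace.bleach_frame

    leak = nb0[ip] - nb0[ib]
    b1, nb1 = b0 + leak, nb0 + leak                      # stage I
    wtot = trace.N_B + trace.N_NB
    b2 = b1 * trace.N_B / wtot                           # stage II
    nb2 = nb1 * trace.N_NB / wtot
    denom = b2[ip] - b2[ib]
    if abs(denom) < 1e-9 * abs(b2[ip]):
        raise ValueError("no bleach detected: pre- and post-bleach levels equal")
    b3 = (b2 - b2[ib]) / denom                           # stage III
    nb3 = (nb2 - nb2[ib]) / denom
    nb4 = 1.0 + nb3                                      # stage IV
    return HalfFrapCurve(
        times=trace.times,
        frap_b=b3,
        frap_nb=nb4,
        radius_um=trace.radius_um,
        bleach_index=ib,
        stage="IV",
        stages={
            "I": (b1, nb1),
            "II": (b2, nb2),
            "III": (b3, nb3),
            "IV": (b3, nb4),
        },
        experiment_id=trace.experiment_id,
    )


def correct_immobile(
    curve: HalfFrapCurve,
    plateau_window: float = 0.1,
    slope_tol: float = 1e-3,
) -> HalfFrapCurve:
    """Immobile-fraction correction (stage V).

    ``X_immobile`` is the mean offset between the non-bleached and bleached
    curves over the trailing ``plateau_window`` fraction of frames; both
    curves are rescaled by ``1/(1 - X)``.  If either curve still drifts by
    more than ``slope_tol`` per frame over that window the plateau is deemed
    not reached and the curve is flagged (the correction is still applied).
    """
    if curve.stage != "IV":
        raise ValueError("correct_immobile expects a stage-IV curve")
    n = curve.times.size
    k = max(int(round(plateau_window * n)), 3)
    sl = slice(n - k, n)
    x_frames = np.arange(k, dtype=float)
    plateau = True
    for y in (curve.frap_nb[sl], curve.frap_b[sl]):
        slope = np.polyfit(x_frames, y, 1)[0]
        if abs(slope) > slope_tol:
            plateau = False
    X = float(np.mean(curve.frap_nb[sl] - curve.frap_b[sl]))
    if X >= 1.0:
        raise ValueError(f"immobile fraction {X:.3f} >= 1; curves unusable")
    if X < -0.05:
        warnings.warn(
            f"plateau offset {X:.3f} < -0.05 (non-bleached below bleached); "
            "clamping the immobile fraction to 0",
            stacklevel=2,
        )
        X = 0.0
    X = max(X, 0.0)
    if not plateau:
        warnings.warn(
            "plateau not reached within the trailing window; the immobile "
            "fraction estimate may be biased",
            stacklevel=2,
        )
    b5 = curve.frap_b / (1.0 - X)
    nb5 = (curve.frap_nb - 1.0) / (1.0 - X) + 1.0
    stages = dict(curve.stages)
    stages["V"] = (b5, nb5)
    return HalfFrapCurve(
        times=curve.times,
        frap_b=b5,
        frap_nb=nb5,
        radius_um=curve.radius_um,
        bleach_index=curve.bleach_index,
        stage="V",
        stages=stages,
        X_immobile=X,
        plateau_reached=plateau,
        experiment_id=curve.experiment_id,
    )


def average_curves(curves: Sequence[HalfFrapCurve]) -> AveragedCurve:
    """Average replicate curves after normalising time by each radius².

    Each curve's post-bleach time axis is divided by its structure radius
    squared, all curves are linearly interpolated onto the union grid within
    the common support, and the averaged time axis is multiplied back by the
    squared mean radius.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves to average")
    norm_times = [c.post_times / c.radius_um**2 for c in curves]
    lo = max(t[0] for t in norm_times)
    hi = min(t[-1] for t in norm_times)
    if hi <= lo:
        spans = ", ".join(f"[{t[0]:.3g}, {t[-1]:.3g}]" for t in norm_times)
        raise ValueError(f"curves have no overlapping time range: {spans}")
    grid = np.unique(np.concatenate(norm_times))
    grid = grid[(grid >= lo) & (grid <= hi)]
    B = np.vstack(
        [np.interp(grid, t, c.post_b) for t, c in zip(norm_times, curves)]
    )
    NB = np.vstack(
        [np.interp(grid, t, c.post_nb) for t, c in zip(norm_times, curves)]
    )
    n = len(curves)
    mean_r = float(np.mean([c.radius_um for c in curves]))
    sem = lambda a: a.std(axis=0, ddof=1) / np.sqrt(n)
    return AveragedCurve(
        times=grid * mean_r**2,
        frap_b=B.mean(axis=0),
        frap_nb=NB.mean(axis=0),
        sem_b=sem(B),
        sem_nb=sem(NB),
        n=n,
        mean_radius_um=mean_r,
    )


# ---------------------------------------------------------------------------
# dip depth and significance
# ---------------------------------------------------------------------------


def _smoothed_minimum(
    times: np.ndarray,
    nb: np.ndarray,
    sg_window: int,
    sg_order: int,
):
    if nb.size < sg_window:
        raise ValueError(
            f"curve has {nb.size} post-bleach points but the smoothing "
            f"window is {sg_window}; pass a smaller sg_window"
        )
    smooth = savgol_filter(nb, sg_window, sg_order)
    edge = sg_window // 2
    interior = slice(edge, nb.size - edge if nb.size - edge > edge else nb.size)
    idx = np.arange(nb.size)[interior]
    i = idx[int(np.argmin(smooth[interior]))]
    return smooth, i


def dip_depth(
    curve: AveragedCurve | HalfFrapCurve,
    sg_window: int = 21,
    sg_order: int = 2,
) -> DipDepthResult:
    """Dip depth of a (typically averaged) half-FRAP curve.

    The stage-V non-bleached signal is smoothed with a Savitzky-Golay filter
    (order 2, window 21 by default) and the dip is one minus the minimum of
    the smoothed curve, searched over the post-bleach interior (half a
    window away from either end).
    """
    if isinstance(curve, AveragedCurve):
        times, nb, n = curve.times, curve.frap_nb, curve.n
        sems = curve.sem_nb
    else:
        times, nb, n = curve.post_times, curve.post_nb, 1
        sems = None
    smooth, i = _smoothed_minimum(times, nb, sg_window, sg_order)
    dip = float(1.0 - smooth[i])
    flat = dip <= 1e-9
    return DipDepthResult(
        dip=0.0 if flat else dip,
        sem=float(sems[i]) if sems is not None else None,
        n=n,
        argmin_time_s=float(times[i]),
        flat=flat,
    )


def dips_per_experiment(
    curves: Sequence[HalfFrapCurve],
    sg_window: int = 21,
    sg_order: int = 2,
) -> np.ndarray:
    """Dip depth of each replicate, smoothed individually."""
    return np.array(
        [dip_depth(c, sg_window, sg_order).dip for c in curves], dtype=float
    )


def dip_significance(
    sample,
    reference: ReferenceSummary = DEFAULT_REFERENCE,
) -> float:
    """One-sided two-sample Student's t-test of dip > reference.

    ``sample`` is either an array of per-experiment dips or a
    :class:`ReferenceSummary`-like (mean, sd, n) summary; the test is
    computed from summary statistics with pooled variance, so both input
    forms give identical p-values.  A Welch variant is available through
    ``dip_significance_welch``.
    """
    return _ttest_from_summary(sample, reference, equal_var=True)


def dip_significance_welch(
    sample, reference: ReferenceSummary = DEFAULT_REFERENCE
) -> float:
    return _ttest_from_summary(sample, reference, equal_var=False)


def _as_summary(sample) -> ReferenceSummary:
    if isinstance(sample, ReferenceSummary):
        return sample
    arr = np.asarray(sample, dtype=float)
    if arr.ndim == 0 or arr.size < 2:
        raise ValueError("need at least 2 per-experiment dips for the t-test")
    return ReferenceSummary(
        mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=int(arr.size)
    )


def _ttest_from_summary(sample, reference, equal_var: bool) -> float:
    s = _as_summary(sample)
    if s.n < 2 or reference.n < 2:
        raise ValueError("both samples must have n >= 2")
    if s.sd == 0.0 and reference.sd == 0.0:
        # degenerate: no variance on either side
        return 0.5 if s.mean == reference.mean else (0.0 if s.mean > reference.mean else 1.0)
    res = stats.ttest_ind_from_stats(
        mean1=s.mean,
        std1=s.sd,
        nobs1=s.n,
        mean2=reference.mean,
        std2=reference.sd,
        nobs2=reference.n,
        equal_var=equal_var,
        alternative="greater",
    )
    return float(res.pvalue)


def classify(
    result: DipDepthResult,
    alpha: float = 0.05,
    reference: ReferenceSummary = DEFAULT_REFERENCE,
    sample_sd: Optional[float] = None,
    sample_n: Optional[int] = None,
) -> DipDepthResult:
    """Mechanism call from a dip depth and its significance.

    * ``LLPS`` — dip above the reference mean *and* significantly so
      (p < alpha): an interfacial barrier is detected.
    * ``ICBS-consistent`` — dip within the reference's standard-error
      envelope and not significant: indistinguishable from free diffusion.
    * ``inconclusive`` — anything in between.
    """
    if result.p_value is None:
        if sample_sd is None or sample_n is None:
            raise ValueError(
                "p_value missing: provide sample_sd and sample_n or set "
                "result.p_value first"
            )
        result.p_value = dip_significance(
            ReferenceSummary(result.dip, sample_sd, sample_n), reference
        )
    result.reference = reference
    envelope = reference.mean + reference.sd / np.sqrt(reference.n)
    if result.dip > reference.mean and result.p_value < alpha:
        result.classification = "LLPS"
    elif result.dip <= envelope and result.p_value >= alpha:
        result.classification = "ICBS-consistent"
    else:
        result.classification = "inconclusive"
    return result


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------


def roi_traces_from_stack(
    stack: np.ndarray,
    mask_b: np.ndarray,
    mask_nb: np.ndarray,
    mask_bg: np.ndarray,
    mask_ref: np.ndarray,
    times: np.ndarray,
    radius_um: float,
    pre_bleach_frames: int,
    bleach_frame: int,
    experiment_id: str = "",
) -> RawTrace:
    """Per-frame mean ROI intensities from an image stack and four masks."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be a (frames, y, x) array")
    masks = {"B": mask_b, "NB": mask_nb, "BG": mask_bg, "REF": mask_ref}
    means = {}
    for name, m in masks.items():
        m = np.asarray(m, dtype=bool)
        if m.shape != stack.shape[1:]:
            raise ValueError(f"mask {name} does not match the frame geometry")
        if not m.any():
            raise ValueError(f"mask {name} is empty")
        masks[name] = m
        means[name] = stack[:, m].mean(axis=1)
    overlap = (
        masks["B"].astype(int)
        + masks["NB"].astype(int)
        + masks["BG"].astype(int)
        + masks["REF"].astype(int)
    )
    if np.any(overlap > 1):
        raise ValueError("ROI masks must be disjoint")
    return RawTrace(
        frames=np.arange(stack.shape[0]),
        times=times,
        I_B=means["B"],
        I_NB=means["NB"],
        I_BG=means["BG"],
        I_REF=means["REF"],
        N_B=int(masks["B"].sum()),
        N_NB=int(masks["NB"].sum()),
        radius_um=radius_um,
        pre_bleach_frames=pre_bleach_frames,
        bleach_frame=bleach_frame,
        experiment_id=experiment_id,
    )
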