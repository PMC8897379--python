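"""Forward simulation of ¹²³I-IMP kinetics and dynamic planar scintigraphy.

The tracer system is the minimal one that reproduces the features the
quantifiers rely on: a gamma-variate bolus transiting the pulmonary artery,
a single lung compartment that traps a large fraction of the tracer on first
pass and releases it slowly into the systemic circulation, and a one-tissue
brain compartment whose influx is proportional to cerebral blood flow (CBF)
and whose washout rate is f/Vd.  Rest and acetazolamide-stress sessions
differ only in the true flow ``f_true``; the vasodilator's pharmacology is
not modelled.

Units
-----
* time: seconds on the simulation grid; sampling times in minutes where the
  clinical protocol speaks in minutes (blood sample at 10 min).
* ``f_true``: mL/(100 g·min); internally converted to mL/(g·min) assuming a
  brain density of 1 g/mL, so the washout rate is k2 = (f_true/100)/Vd per
  minute.
* activities: arbitrary activity units proportional to the injected dose;
  ROI sensitivities convert activity to detector counts/s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import gamma as _gamma_fn

import numpy as np

__all__ = [
    "KineticGroundTruth",
    "ContinuousCurves",
    "DynamicScan",
    "RoiMask",
    "BloodSample",
    "StudySession",
    "StudyBundle",
    "make_bolus",
    "simulate_kinetics",
    "default_layout",
    "render_frames",
    "draw_blood_sample",
    "simulate_session",
    "simulate_study",
]

REGION_LABELS = ("pulmonary_artery", "lung", "brain")


@dataclass
class KineticGroundTruth:
    """Ground-truth parameters of one simulated acquisition.

    Parameters
    ----------
    f_true : float
        True mean cerebral blood flow, mL/(100 g·min).
    vd : float
        Distribution volume of the tracer in brain, mL/g.  Sets the tissue
        washout rate k2 = (f_true/100)/vd per minute.
    lambda_lipo : float
        Lipophilic (brain-available) fraction of blood activity, in (0, 1].
    eps_lung : float
        Lung first-pass trapping fraction, in (0, 1].
    k_lung : float
        Lung washout rate, 1/min.
    bolus_t0, bolus_alpha, bolus_beta : float
        Gamma-variate bolus appearance time (s), shape and scale (s).
    dose : float
        Injected activity, MBq.
    sens_pa, sens_lung, sens_brain : float
        ROI sensitivity factors (counts/s per activity unit); they absorb
        region size, depth and collimator response.
    cbv_frac : float
        Cerebral blood volume fraction contributing a vascular term to the
        measured brain signal, in [0, 0.1].
    first_pass_frac : float
        Weight of the direct (pre-lung-washout) arterial term.
    """

    f_true: float = 50.0
    vd: float = 40.0
    lambda_lipo: float = 0.8
    eps_lung: float = 0.8
    k_lung: float = 0.1
    bolus_t0: float = 5.0
    bolus_alpha: float = 2.0
    bolus_beta: float = 4.0
    dose: float = 167.0
    # defaults give ~20 kcounts/s over the field of view, typical of planar
    # scintigraphy of the chest at this dose
    sens_pa: float = 800.0
    sens_lung: float = 120.0
    sens_brain: float = 12000.0
    cbv_frac: float = 0.04
    first_pass_frac: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda_lipo <= 1.0):
            raise ValueError(f"lambda_lipo must be in (0, 1], got {self.lambda_lipo}")
        if not (0.0 < self.eps_lung <= 1.0):
            raise ValueError(f"eps_lung must be in (0, 1], got {self.eps_lung}")
        if self.vd <= 0:
            raise ValueError(f"vd must be positive, got {self.vd}")
        if self.f_true < 0:
            raise ValueError(f"f_true must be nonnegative, got {self.f_true}")
        if not (0.0 <= self.cbv_frac <= 0.1):
            raise ValueError(f"cbv_frac must be in [0, 0.1], got {self.cbv_frac}")
        if self.bolus_alpha <= 0 or self.bolus_beta <= 0:
            raise ValueError("gamma-variate shape/scale must be positive")
        for name in ("k_lung", "dose", "first_pass_frac", "sens_pa", "sens_lung", "sens_brain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def with_flow(self, f_true: float) -> "KineticGroundTruth":
        """Copy with a different true CBF (same protocol and physiology)."""
        return replace(self, f_true=f_true)


@dataclass
class ContinuousCurves:
    """Noise-free model curves on a fine time grid (seconds).

    ``pa_conc`` is the pulmonary-artery bolus concentration, ``lung_act`` the
    lung compartment content, ``art_conc`` the *lipophilic* systemic arterial
    concentration, and ``brain_conc`` the measured brain concentration
    (parenchymal tracer plus the vascular blood-volume term).
    """

    times: np.ndarray
    pa_conc: np.ndarray
    lung_act: np.ndarray
    art_conc: np.ndarray
    brain_conc: np.ndarray
    truth: KineticGroundTruth | None = None

    def arterial_total(self) -> np.ndarray:
        """Whole-blood arterial concentration: lipophilic / lambda."""
        lam = self.truth.lambda_lipo if self.truth is not None else 1.0
        return self.art_conc / lam

    def at(self, which: str, t: float | np.ndarray) -> float | np.ndarray:
        return np.interp(t, self.times, getattr(self, which))


@dataclass
class DynamicScan:
    """Dynamic planar acquisition: ``counts[frame, row, col]``.

    Defaults mirror the clinical protocol: 2 s/frame, 60 frames,
    3.9 mm/pixel.
    """

    counts: np.ndarray
    frame_duration: float = 2.0
    pixel_size: float = 3.9

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        """Frame mid-points, seconds from injection."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_duration

    def __post_init__(self) -> None:
        if self.counts.ndim != 3:
            raise ValueError("counts must be a 3-D (time, rows, cols) array")
        if self.counts.shape[0] < 1:
            raise ValueError("scan needs at least one frame")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")


@dataclass
class RoiMask:
    label: str
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if not self.grid.any():
            raise ValueError(f"ROI mask '{self.label}' selects no pixels")


@dataclass
class BloodSample:
    """Arterial sample drawn ``t_sample`` minutes post-injection.

    ``conc`` is the whole-blood activity concentration per 1.0 g, averaged
    over ``n_replicates`` well-counter measurements.
    """

    t_sample: float = 10.0
    conc: float = 0.0
    n_replicates: int = 4

    def __post_init__(self) -> None:
        if self.t_sample <= 0:
            raise ValueError("t_sample must be positive (minutes)")
        if self.conc < 0:
            raise ValueError("conc must be nonnegative")


def make_bolus(truth: KineticGroundTruth, time_grid: np.ndarray) -> np.ndarray:
    """Gamma-variate pulmonary-artery bolus evaluated on ``time_grid`` (s).

    pa(t) = A (t − t0)^α exp(−(t − t0)/β) for t > t0, 0 before; A is chosen
    so the analytic integral over (t0, ∞) equals the injected dose, making
    every downstream curve linear in the dose.
    """
    if truth.bolus_alpha <= 0 or truth.bolus_beta <= 0:
        raise ValueError("gamma-variate shape/scale must be positive")
    t = np.asarray(time_grid, dtype=float)
    a, b = truth.bolus_alpha, truth.bolus_beta
    amp = truth.dose / (_gamma_fn(a + 1.0) * b ** (a + 1.0))
    dt = t - truth.bolus_t0
    out = np.zeros_like(t)
    pos = dt > 0
    out[pos] = amp * dt[pos] ** a * np.exp(-dt[pos] / b)
    return out


def simulate_kinetics(
    truth: KineticGroundTruth,
    horizon: float,
    dt: float = 0.1,
    delay: float = 3.0,
    kappa: float = 1.0,
) -> ContinuousCurves:
    """Integrate the lung + brain compartment system with fixed-step RK4.

    Lung:   dL/dt = eps_lung · pa(t) − k_lung · L,            L(0) = 0
    Input:  Ca(t) = first_pass_frac · pa(t − delay) + kappa · k_lung · L(t)
    Brain:  dB/dt = f_g · Ca(t) − (f_g/Vd) · B,               B(0) = 0

    with f_g = f_true/100 in mL/(g·min) and all rates converted to per
    second on the grid.  The reported brain curve adds the vascular term
    cbv_frac · Ca/λ (whole-blood activity occupying the cerebral blood
    volume).

    Parameters
    ----------
    horizon : float
        End of integration, seconds; must cover at least the 120 s dynamic
        scan.
    dt : float
        RK4 step, seconds; capped at 0.5 s.
    delay : float
        Pulmonary-to-systemic transit delay of the first-pass term, s.
    kappa : float
        Dilution constant mapping the lung release rate to arterial
        concentration.
    """
    if dt > 0.5 or dt <= 0:
        raise ValueError("dt must be in (0, 0.5] s")
    if horizon < 120.0:
        raise ValueError("horizon must cover the 120 s dynamic acquisition")

    n = int(round(horizon / dt))
    times = np.arange(n + 1) * dt
    half_times = np.arange(2 * n + 1) * (dt / 2.0)
    pa_half = make_bolus(truth, half_times)
    pa_del_half = make_bolus(truth, half_times - delay)

    k_l = truth.k_lung / 60.0          # 1/s
    f_g = truth.f_true / 100.0         # mL/(g·min)
    fin = f_g / 60.0                   # influx factor, 1/s
    k2 = f_g / truth.vd / 60.0         # 1/s
    eps = truth.eps_lung
    fp = truth.first_pass_frac

    L = np.empty(n + 1)
    B = np.empty(n + 1)
    L[0] = B[0] = 0.0
    lv = bv = 0.0
    for j in range(n):
        pa0, pam, pa1 = pa_half[2 * j], pa_half[2 * j + 1], pa_half[2 * j + 2]
        pd0, pdm, pd1 = pa_del_half[2 * j], pa_del_half[2 * j + 1], pa_del_half[2 * j + 2]

        def deriv(lval, bval, pa, pd):
            dl = eps * pa - k_l * lval
            ca = fp * pd + kappa * k_l * lval
            db = fin * ca - k2 * bval
            return dl, db

        k1l, k1b = deriv(lv, bv, pa0, pd0)
        k2l, k2b = deriv(lv + 0.5 * dt * k1l, bv + 0.5 * dt * k1b, pam, pdm)
        k3l, k3b = deriv(lv + 0.5 * dt * k2l, bv + 0.5 * dt * k2b, pam, pdm)
        k4l, k4b = deriv(lv + dt * k3l, bv + dt * k3b, pa1, pd1)
        lv += dt / 6.0 * (k1l + 2 * k2l + 2 * k3l + k4l)
        bv += dt / 6.0 * (k1b + 2 * k2b + 2 * k3b + k4b)
        L[j + 1] = lv
        B[j + 1] = bv

    pa = pa_half[::2]
    art = fp * pa_del_half[::2] + kappa * k_l * L
    brain = B + truth.cbv_frac * art / truth.lambda_lipo
    return ContinuousCurves(times, pa, L, art, brain, truth=truth)


def default_layout(shape: tuple[int, int] = (64, 64)) -> dict[str, tuple[int, int, int, int]]:
    """Three disjoint rectangles (r0, r1, c0, c1), half-open, on ``shape``.

    Brain at the top of the field of view, lungs in the middle, pulmonary
    artery trunk as a small box below, echoing a frontal planar view.
    """
    rows, cols = shape
    return {
        "brain": (rows // 16, rows * 4 // 16, cols * 5 // 16, cols * 11 // 16),
        "lung": (rows * 6 // 16, rows * 11 // 16, cols * 3 // 16, cols * 13 // 16),
        "pulmonary_artery": (rows * 12 // 16, rows * 14 // 16, cols * 7 // 16, cols * 9 // 16),
    }


def _region_curve(curves: ContinuousCurves, label: str) -> tuple[np.ndarray, float]:
    truth = curves.truth
    if truth is None:
        raise ValueError("curves must carry their ground truth to be rendered")
    if label == "pulmonary_artery":
        return curves.pa_conc, truth.sens_pa
    if label == "lung":
        return curves.lung_act, truth.sens_lung
    if label == "brain":
        return curves.brain_conc, truth.sens_brain
    raise ValueError(f"unknown region label '{label}'")


def render_frames(
    curves: ContinuousCurves,
    layout: dict[str, tuple[int, int, int, int]] | None = None,
    seed: int | np.random.Generator | None = None,
    shape: tuple[int, int] = (64, 64),
    frame_duration: float = 2.0,
    n_frames: int = 60,
    pixel_size: float = 3.9,
    noise: bool = True,
) -> tuple[DynamicScan, dict[str, RoiMask]]:
    """Project the region curves onto planar frames with Poisson counting.

    Expected counts in each pixel of a region for frame k are
    sensitivity × ∫_frame curve dt / (pixels in region); realized counts are
    Poisson draws from that expectation (``noise=False`` returns the
    expectations themselves).
    """
    if layout is None:
        layout = default_layout(shape)
    rows, cols = shape
    occupancy = np.zeros(shape, dtype=int)
    masks: dict[str, RoiMask] = {}
    for label, (r0, r1, c0, c1) in layout.items():
        if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
            raise ValueError(f"region '{label}' {layout[label]} outside the {shape} grid")
        grid = np.zeros(shape, dtype=bool)
        grid[r0:r1, c0:c1] = True
        occupancy += grid
        masks[label] = RoiMask(label, grid)
    if occupancy.max() > 1:
        raise ValueError("ROI rectangles overlap")

    scan_end = n_frames * frame_duration
    if scan_end > curves.times[-1] + 1e-9:
        raise ValueError("simulated curves end before the scan does")

    edges = np.arange(n_frames + 1) * frame_duration
    expected = np.zeros((n_frames, rows, cols))
    for label, mask in masks.items():
        curve, sens = _region_curve(curves, label)
        cum = np.concatenate([[0.0], np.cumsum(np.diff(curves.times) * (curve[1:] + curve[:-1]) / 2.0)])
        frame_integral = np.diff(np.interp(edges, curves.times, cum))
        per_pixel = sens * frame_integral / mask.grid.sum()
        expected[:, mask.grid] = per_pixel[:, None]

    if noise:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(np.int64)
    else:
        counts = expected
    return DynamicScan(counts, frame_duration=frame_duration, pixel_size=pixel_size), masks


def draw_blood_sample(
    curves: ContinuousCurves,
    truth: KineticGroundTruth | None = None,
    t_sample: float = 10.0,
    n_replicates: int = 4,
    noise_cv: float = 0.02,
    seed: int | np.random.Generator | None = None,
    noise: bool = True,
) -> BloodSample:
    """Arterial whole-blood sample at ``t_sample`` minutes.

    The measured quantity is the total arterial concentration, i.e. the
    lipophilic model concentration divided by λ; the reported value averages
    ``n_replicates`` well-counter draws with multiplicative Gaussian noise
    of coefficient of variation ``noise_cv``.
    """
    truth = truth if truth is not None else curves.truth
    if truth is None:
        raise ValueError("ground truth required to form the whole-blood concentration")
    t_s = t_sample * 60.0
    if t_s > curves.times[-1] + 1e-9:
        raise ValueError(f"sample time {t_sample} min is beyond the simulated horizon")
    total = float(np.interp(t_s, curves.times, curves.art_conc)) / truth.lambda_lipo
    if noise:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        draws = total * (1.0 + noise_cv * rng.standard_normal(n_replicates))
        conc = float(np.clip(draws, 0.0, None).mean())
    else:
        conc = total
    return BloodSample(t_sample=t_sample, conc=conc, n_replicates=n_replicates)


@dataclass
class StudySession:
    """Everything one acquisition produces: frames, masks, sample, static uptake."""

    truth: KineticGroundTruth
    curves: ContinuousCurves
    scan: DynamicScan
    masks: dict[str, RoiMask]
    blood: BloodSample
    static_conc: float
    static_time: float  # minutes


@dataclass
class StudyBundle:
    rest: StudySession
    stress: StudySession
    true_cvr: float


def simulate_session(
    truth: KineticGroundTruth,
    seed: int | np.random.SeedSequence | None = None,
    noise: bool = True,
    static_time: float = 30.0,
    t_sample: float = 10.0,
    dt: float = 0.1,
    shape: tuple[int, int] = (64, 64),
    layout: dict | None = None,
    frame_duration: float = 2.0,
    n_frames: int = 60,
) -> StudySession:
    """Simulate one acquisition end to end.

    Produces the dynamic planar scan with its ROI masks, the 10-min
    arterial sample, and the late static brain concentration the ARG
    method reads (at ``static_time`` minutes, with 1% measurement noise
    when ``noise`` is on).
    """
    rng = np.random.default_rng(seed)
    horizon = max(static_time * 60.0, t_sample * 60.0, n_frames * frame_duration) + 1.0
    curves = simulate_kinetics(truth, horizon, dt=dt)
    scan, masks = render_frames(
        curves, layout=layout, seed=rng, shape=shape,
        frame_duration=frame_duration, n_frames=n_frames, noise=noise,
    )
    blood = draw_blood_sample(curves, truth, t_sample=t_sample, seed=rng, noise=noise)
    static = float(curves.at("brain_conc", static_time * 60.0))
    if noise:
        static = max(0.0, static * (1.0 + 0.01 * rng.standard_normal()))
    return StudySession(truth, curves, scan, masks, blood, static, static_time)


def simulate_study(
    truth_rest: KineticGroundTruth,
    truth_stress: KineticGroundTruth,
    seed: int | None = None,
    noise: bool = True,
    static_time: float = 30.0,
    t_sample: float = 10.0,
    dt: float = 0.1,
    shape: tuple[int, int] = (64, 64),
    layout: dict | None = None,
    frame_duration: float = 2.0,
    n_frames: int = 60,
) -> StudyBundle:
    """Simulate a paired rest / acetazolamide-stress study.

    Stress is modelled purely as an elevated ``f_true``; both sessions share
    the injection protocol.  The two sessions use independent child seeds of
    ``seed`` so a study is reproducible from one master seed.
    """
    if truth_rest.dose != truth_stress.dose:
        raise ValueError("rest and stress sessions must share the injection protocol (dose)")
    ss = np.random.SeedSequence(seed)
    child_rest, child_stress = ss.spawn(2)

    def one(truth: KineticGroundTruth, child: np.random.SeedSequence) -> StudySession:
        return simulate_session(
            truth, seed=child, noise=noise, static_time=static_time,
            t_sample=t_sample, dt=dt, shape=shape, layout=layout,
            frame_duration=frame_duration, n_frames=n_frames,
        )

    rest = one(truth_rest, child_rest)
    stress = one(truth_stress, child_stress)
    true_cvr = 100.0 * (truth_stress.f_true - truth_rest.f_true) / truth_rest.f_true
    return StudyBundle(rest=rest, stress=stress, true_cvr=true_cvr)
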