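"""The three mCBF quantifiers: REICA, Graph-Plot (GP), and ARG.

REICA is a graphical analysis of the dynamic planar study that uses the
lungs as a surrogate tracer reservoir: it plots

    ( ∫₀ᵗ C_r(τ)dτ / l(t),  C_b(t) / (λ l(t)) )

and takes the slope of the linear section, avoiding arterial sampling.  GP
is the classical Patlak-type analysis with the pulmonary-artery TAC as the
input function; its slope-derived flow index SFR converts to absolute flow
through the published regression mCBF = 1.87·SFR + 21.2.  ARG is the
autoradiographic standard: a one-tissue compartment model with fixed
distribution volume Vd = 40 mL/g, calibrated by a single 10-min arterial
sample and inverted through a precomputed uptake table.

Both graphical plots are invariant to a common rescaling of the three TACs,
so camera sensitivity cancels; REICA's absolute scale comes from a
cross-calibration factor, GP's from the printed conversion line, ARG's from
the blood sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .simulate import BloodSample, StudySession
from .tac import RegionTacs, preprocess

__all__ = [
    "GraphPlot",
    "SlopeFit",
    "GpConfig",
    "ArgConfig",
    "QuantResult",
    "reica_plot",
    "gp_plot",
    "find_linear_window",
    "fit_line",
    "reica_mcbf",
    "calibrate_reica",
    "gp_sfr",
    "gp_convert",
    "arg_uptake",
    "arg_mcbf",
    "quantify_session",
]


@dataclass
class GraphPlot:
    """Point set of a graphical analysis; only ``valid`` points enter fits."""

    x: np.ndarray
    y: np.ndarray
    method: str
    valid: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.y) == len(self.valid)):
            raise ValueError("x, y, valid must have equal lengths")


@dataclass
class SlopeFit:
    slope: float
    intercept: float
    r_squared: float
    window: tuple[int, int]     # inclusive frame indices of the fitted section
    flagged: bool = False       # set when no window met the linearity threshold


@dataclass
class GpConfig:
    """GP conversion: mCBF = conversion_slope · SFR + conversion_intercept."""

    conversion_slope: float = 1.87
    conversion_intercept: float = 21.2
    sfr_scale: float = 1.0


@dataclass
class ArgConfig:
    """One-tissue table-lookup settings.

    ``standard_input`` is the standardized arterial input shape, a pair
    (times in minutes, whole-blood concentration) covering [0, scan_time];
    it is rescaled to the patient through the 10-min blood sample.
    """

    vd: float = 40.0
    scan_time: float = 30.0                      # min
    f_grid: np.ndarray = field(default_factory=lambda: np.arange(5.0, 120.0 + 1e-9, 0.5))
    standard_input: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.vd <= 0:
            raise ValueError("vd must be positive")
        g = np.asarray(self.f_grid, dtype=float)
        if g.ndim != 1 or len(g) < 2 or not np.all(np.diff(g) > 0):
            raise ValueError("f_grid must be 1-D and strictly increasing")
        if g[0] > 5.0 or g[-1] < 120.0:
            raise ValueError("f_grid must cover at least 5-120 mL/100 g/min")
        self.f_grid = g


@dataclass
class QuantResult:
    method: str
    mcbf: float
    diagnostics: dict = field(default_factory=dict)
    flagged: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.mcbf):
            raise ValueError("mCBF must be finite")
        if self.mcbf < 0:
            self.flagged = True


# ----------------------------------------------------------------------
# graphical plots

def reica_plot(tacs: RegionTacs, lambda_lipo: float) -> GraphPlot:
    """REICA coordinates: x = ∫₀ᵗ C_r / l(t), y = C_b / (λ l(t)).

    Frames where the lung activity is not positive are marked invalid.
    """
    if not (0.0 < lambda_lipo <= 1.0):
        raise ValueError(f"lambda_lipo must be in (0, 1], got {lambda_lipo}")
    t = tacs.times
    cum_cr = cumulative_trapezoid(tacs.c_r.values, t, initial=0.0)
    lung = tacs.l.values
    valid = lung > 0
    if not valid.any():
        raise ValueError("no frames with positive lung activity")
    x = np.full_like(cum_cr, np.nan)
    y = np.full_like(cum_cr, np.nan)
    x[valid] = cum_cr[valid] / lung[valid]
    y[valid] = tacs.c_b.values[valid] / (lambda_lipo * lung[valid])
    return GraphPlot(x, y, "REICA", valid)


def gp_plot(tacs: RegionTacs, floor_frac: float = 0.05) -> GraphPlot:
    """Patlak-type coordinates: x = ∫₀ᵗ C_r / C_r(t), y = C_b / C_r(t).

    Frames where the pulmonary-artery activity has fallen below
    ``floor_frac`` of its peak (essentially the post-bolus tail) are
    invalid — there the normalization is dominated by noise.
    """
    t = tacs.times
    cr = tacs.c_r.values
    peak = cr.max() if len(cr) else 0.0
    if peak <= 0:
        raise ValueError("pulmonary-artery TAC has no positive activity")
    cum_cr = cumulative_trapezoid(cr, t, initial=0.0)
    valid = cr > floor_frac * peak
    if not valid.any():
        raise ValueError("no frames above the input-function floor")
    x = np.full_like(cum_cr, np.nan)
    y = np.full_like(cum_cr, np.nan)
    x[valid] = cum_cr[valid] / cr[valid]
    y[valid] = tacs.c_b.values[valid] / cr[valid]
    return GraphPlot(x, y, "GP", valid)


# ----------------------------------------------------------------------
# linear-section selection and fitting

def _r2_of(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    ym = y - y.mean()
    sxx = float(xm @ xm)
    if sxx == 0.0:
        return -np.inf          # vertical: not fittable as y(x)
    syy = float(ym @ ym)
    if syy == 0.0:
        return 1.0              # flat line is perfectly linear
    sxy = float(xm @ ym)
    return sxy * sxy / (sxx * syy)


def _valid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    idx = np.flatnonzero(valid)
    if len(idx) == 0:
        return runs
    start = prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((start, prev))
            start = i
        prev = i
    runs.append((start, prev))
    return runs


def find_linear_window(
    plot: GraphPlot,
    min_points: int = 10,
    r2_threshold: float = 0.99,
) -> tuple[tuple[int, int], bool]:
    """Locate the linear section: the longest contiguous run of valid points
    whose OLS r² reaches ``r2_threshold``, ties broken toward the later
    (larger-x) window.

    If no window of at least ``min_points`` reaches the threshold, the best
    r² window of exactly ``min_points`` is returned with a flag.  Returns
    ``((first, last), flagged)`` with inclusive frame indices.
    """
    runs = _valid_runs(plot.valid)
    max_run = max((b - a + 1 for a, b in runs), default=0)
    if max_run < min_points:
        raise ValueError(
            f"need at least {min_points} contiguous valid points, longest run has {max_run}"
        )
    for length in range(max_run, min_points - 1, -1):
        best = None
        for a, b in runs:
            for s in range(a, b - length + 2):
                r2 = _r2_of(plot.x[s:s + length], plot.y[s:s + length])
                if r2 >= r2_threshold and (best is None or s >= best[0]):
                    best = (s, s + length - 1)
        if best is not None:
            return best, False
    # fallback: most linear short window, flagged for inspection
    best_r2, best = -np.inf, None
    for a, b in runs:
        for s in range(a, b - min_points + 2):
            r2 = _r2_of(plot.x[s:s + min_points], plot.y[s:s + min_points])
            if r2 > best_r2:
                best_r2, best = r2, (s, s + min_points - 1)
    return best, True


def fit_line(plot: GraphPlot, window: tuple[int, int]) -> SlopeFit:
    """Ordinary least squares of y on x over the inclusive ``window``."""
    s, e = window
    x = plot.x[s:e + 1]
    y = plot.y[s:e + 1]
    if len(x) < 2:
        raise ValueError("window must contain at least 2 points")
    xm = x - x.mean()
    sxx = float(xm @ xm)
    if sxx == 0.0:
        raise ValueError("degenerate window: all x values identical")
    slope = float(xm @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    return SlopeFit(slope, intercept, _r2_of(x, y), (int(s), int(e)))


# ----------------------------------------------------------------------
# REICA

def reica_mcbf(fit: SlopeFit, calibration_factor: float = 1.0) -> QuantResult:
    """Scale the REICA slope to absolute flow.

    The plot's slope is proportional to CBF within a fixed acquisition
    protocol; ``calibration_factor`` (mL/100 g/min per slope unit) carries
    the absolute scale obtained by cross-calibration.
    """
    if calibration_factor <= 0:
        raise ValueError("calibration_factor must be positive")
    mcbf = fit.slope * calibration_factor
    return QuantResult(
        "REICA",
        mcbf,
        diagnostics={
            "slope": fit.slope,
            "r_squared": fit.r_squared,
            "window": fit.window,
            "calibration_factor": calibration_factor,
        },
        flagged=fit.flagged or fit.slope < 0,
    )


def calibrate_reica(pairs: list[tuple[float, float]]) -> float:
    """Least-squares-through-the-origin factor from (slope, true flow) pairs.

    factor = Σ slope·f / Σ slope², the minimizer of Σ (f − factor·slope)².
    """
    if len(pairs) == 0:
        raise ValueError("need at least one (slope, f) pair")
    s = np.asarray([p[0] for p in pairs], dtype=float)
    f = np.asarray([p[1] for p in pairs], dtype=float)
    if np.all(s == 0):
        raise ValueError("all slopes are zero; cannot calibrate")
    if np.any(s < 0):
        raise ValueError("calibration slopes must be positive")
    return float((s @ f) / (s @ s))


# ----------------------------------------------------------------------
# GP

def gp_sfr(fit: SlopeFit, cfg: GpConfig | None = None) -> float:
    """Standardized flow index from the Patlak slope."""
    cfg = cfg or GpConfig()
    return fit.slope * cfg.sfr_scale


def gp_convert(sfr: float, cfg: GpConfig | None = None) -> float:
    """Published GP conversion to absolute flow: mCBF = 1.87·SFR + 21.2."""
    cfg = cfg or GpConfig()
    return cfg.conversion_slope * sfr + cfg.conversion_intercept


# ----------------------------------------------------------------------
# ARG

def arg_uptake(
    f: float,
    cfg: ArgConfig,
    scaled_input: tuple[np.ndarray, np.ndarray],
) -> float:
    """One-tissue model tissue concentration at the static scan time.

    m(f) = f_g ∫₀ᵀ Ca(t) exp(−(f_g/Vd)(T−t)) dt, with f_g = f/100 in
    mL/(g·min), Ca the (scaled) arterial input in the table's units, and T
    the scan time in minutes.  Trapezoidal quadrature on the input grid.
    """
    if f < 0:
        raise ValueError("flow must be nonnegative")
    t, ca = scaled_input
    return float(_uptake_table(np.asarray([f]), cfg, t, ca)[0])


def _uptake_table(f_values: np.ndarray, cfg: ArgConfig,
                  t: np.ndarray, ca: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    ca = np.asarray(ca, dtype=float)
    T = cfg.scan_time
    if t[-1] < T - 1e-9:
        raise ValueError(f"input curve ends at {t[-1]:.2f} min, before scan time {T} min")
    # truncate to [0, T], landing exactly on T
    ca_T = np.interp(T, t, ca)
    keep = t < T - 1e-12
    tt = np.concatenate([t[keep], [T]])
    cc = np.concatenate([ca[keep], [ca_T]])
    f_g = np.asarray(f_values, dtype=float) / 100.0         # mL/(g·min)
    k2 = f_g / cfg.vd                                       # 1/min
    decay = np.exp(-np.outer(k2, T - tt))
    return f_g * np.trapezoid(cc[None, :] * decay, tt, axis=1)


def arg_mcbf(
    measured_conc: float,
    sample: BloodSample,
    cfg: ArgConfig,
    lambda_lipo: float,
) -> QuantResult:
    """Invert the one-tissue uptake table through the 10-min blood sample.

    The standardized input shape is rescaled so that its value at the
    sampling time equals the patient's brain-available arterial
    concentration (λ × whole-blood sample), the uptake table m(f) is built
    over ``cfg.f_grid``, and the measured static brain concentration is
    inverted by monotone linear interpolation.  The table is anchored at
    m(0) = 0, so concentrations below the lowest grid node interpolate
    toward zero flow and are flagged.
    """
    if measured_conc < 0:
        raise ValueError("measured concentration must be nonnegative")
    if cfg.standard_input is None:
        raise ValueError("ArgConfig.standard_input is required")
    t, std = cfg.standard_input
    std_at_sample = float(np.interp(sample.t_sample, t, std))
    if std_at_sample <= 0:
        raise ValueError("standard input is not positive at the sampling time")
    scale = lambda_lipo * sample.conc / std_at_sample
    ca = np.asarray(std, dtype=float) * scale

    table = _uptake_table(cfg.f_grid, cfg, t, ca)
    if measured_conc > table[-1]:
        raise ValueError(
            f"measured concentration {measured_conc:.4g} exceeds the uptake table's "
            f"saturation value {table[-1]:.4g} at f = {cfg.f_grid[-1]} mL/100 g/min"
        )
    f_nodes = np.concatenate([[0.0], cfg.f_grid])
    m_nodes = np.concatenate([[0.0], table])
    mcbf = float(np.interp(measured_conc, m_nodes, f_nodes))
    return QuantResult(
        "ARG",
        mcbf,
        diagnostics={
            "scale": scale,
            "vd": cfg.vd,
            "scan_time": cfg.scan_time,
            "table_max": float(table[-1]),
        },
        flagged=measured_conc < table[0],
    )


# ----------------------------------------------------------------------
# session-level convenience

def quantify_session(
    session: StudySession,
    lambda_lipo: float = 0.8,
    reica_calibration: float = 1.0,
    gp_cfg: GpConfig | None = None,
    arg_cfg: ArgConfig | None = None,
    filter_width: int = 5,
    time_zero_frac: float = 0.1,
    min_points: int = 10,
    r2_threshold: float = 0.99,
) -> dict[str, QuantResult]:
    """Run all three quantifiers on one simulated acquisition.

    If ``arg_cfg`` carries no standardized input, the session's own
    simulated arterial curve is used (the simulator stands in for the
    population-standard input shape).
    """
    tacs = preprocess(session.scan, session.masks,
                      filter_width=filter_width, time_zero_frac=time_zero_frac)

    rp = reica_plot(tacs, lambda_lipo)
    rw, rflag = find_linear_window(rp, min_points=min_points, r2_threshold=r2_threshold)
    rfit = fit_line(rp, rw)
    rfit.flagged = rflag
    reica = reica_mcbf(rfit, reica_calibration)

    gp = gp_plot(tacs)
    gw, gflag = find_linear_window(gp, min_points=min_points, r2_threshold=r2_threshold)
    gfit = fit_line(gp, gw)
    gfit.flagged = gflag
    gcfg = gp_cfg or GpConfig()
    sfr = gp_sfr(gfit, gcfg)
    gp_res = QuantResult(
        "GP", gp_convert(sfr, gcfg),
        diagnostics={"slope": gfit.slope, "sfr": sfr, "window": gfit.window,
                     "r_squared": gfit.r_squared},
        flagged=gflag,
    )

    acfg = arg_cfg or ArgConfig(scan_time=session.static_time)
    if acfg.standard_input is None:
        c = session.curves
        acfg = ArgConfig(vd=acfg.vd, scan_time=acfg.scan_time, f_grid=acfg.f_grid,
                         standard_input=(c.times / 60.0, c.arterial_total()))
    arg = arg_mcbf(session.static_conc, session.blood, acfg, lambda_lipo)

    return {"REICA": reica, "GP": gp_res, "ARG": arg}
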