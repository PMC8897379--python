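"""ROI time-activity curves: extraction, smoothing, time-zero adjustment.

The graphical quantifiers consume three curves from one dynamic planar
acquisition — pulmonary-artery trunk C_r(t), lung l(t), brain C_b(t) — in
counts/s at frame mid-points.  Raw curves are low-pass filtered to tame
Poisson noise, then jointly re-timed so the sharp arrival of the bolus in
the pulmonary artery defines t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .simulate import DynamicScan, RoiMask

__all__ = ["Tac", "RegionTacs", "extract_tac", "lowpass", "adjust_time_zero", "preprocess"]


@dataclass
class Tac:
    """One region's time-activity curve: counts/s at frame mid-points (s)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TAC values must be finite")


@dataclass
class RegionTacs:
    """The (C_r, l, C_b) triple on one common time grid.

    ``meta`` carries processing provenance (filter width, time-zero shift).
    """

    c_r: Tac
    l: Tac
    c_b: Tac
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.array_equal(self.c_r.times, self.l.times)
                and np.array_equal(self.c_r.times, self.c_b.times)):
            raise ValueError("c_r, l, c_b must share one time grid")

    @property
    def times(self) -> np.ndarray:
        return self.c_r.times


def extract_tac(scan: DynamicScan, mask: RoiMask) -> Tac:
    """Sum masked pixels per frame and divide by frame duration.

    Returns counts/s at frame mid-points.
    """
    if mask.grid.shape != scan.counts.shape[1:]:
        raise ValueError(
            f"mask shape {mask.grid.shape} does not match frame shape {scan.counts.shape[1:]}"
        )
    if not mask.grid.any():
        raise ValueError("empty ROI mask")
    values = scan.counts[:, mask.grid].sum(axis=1) / scan.frame_duration
    return Tac(scan.frame_times, values.astype(float), label=mask.label)


def lowpass(tac: Tac, width: int = 5) -> Tac:
    """Centered moving average of odd ``width`` frames.

    At the boundaries the window shrinks to the available samples (edge
    truncation), so a constant curve passes unchanged and the filter has
    unit DC gain everywhere.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError(f"filter width must be odd and positive, got {width}")
    if width == 1:
        return replace(tac)
    h = width // 2
    n = len(tac.values)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        out[i] = tac.values[lo:hi].mean()
    return Tac(tac.times.copy(), out, label=tac.label)


def adjust_time_zero(tacs: RegionTacs, frac: float = 0.1) -> RegionTacs:
    """Re-time all three curves so bolus arrival in the pulmonary artery is t = 0.

    The arrival frame k is the first where C_r reaches ``frac`` of its
    maximum; frames before k are discarded and the grid shifted so frame k
    sits at t = 0.  k is recorded in ``meta['time_zero_frame']``.
    """
    peak = tacs.c_r.values.max() if len(tacs.c_r.values) else 0.0
    if peak <= 0:
        raise ValueError("pulmonary-artery TAC has no positive activity; cannot set time zero")
    k = int(np.argmax(tacs.c_r.values >= frac * peak))
    t0 = tacs.times[k]
    meta = dict(tacs.meta)
    meta["time_zero_frame"] = k
    meta["time_zero_shift_s"] = float(t0)

    def shift(tac: Tac) -> Tac:
        return Tac(tac.times[k:] - t0, tac.values[k:].copy(), label=tac.label)

    return RegionTacs(shift(tacs.c_r), shift(tacs.l), shift(tacs.c_b), meta=meta)


def preprocess(
    scan: DynamicScan,
    masks: dict[str, RoiMask],
    filter_width: int = 5,
    time_zero_frac: float = 0.1,
) -> RegionTacs:
    """Extract, smooth, and time-zero-adjust the three region TACs.

    Smoothing precedes the time-zero adjustment so the arrival detection
    sees the denoised pulmonary-artery curve.
    """
    c_r = lowpass(extract_tac(scan, masks["pulmonary_artery"]), filter_width)
    l = lowpass(extract_tac(scan, masks["lung"]), filter_width)
    c_b = lowpass(extract_tac(scan, masks["brain"]), filter_width)
    tacs = RegionTacs(c_r, l, c_b, meta={"filter_width": filter_width,
                                         "time_zero_frac": time_zero_frac})
    return adjust_time_zero(tacs, frac=time_zero_frac)
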