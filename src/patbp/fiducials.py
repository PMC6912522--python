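"""Fiducial-point detection on ensemble-averaged ABP and PPG cycles.

All times are seconds relative to the cycle's R-peak (the first sample).
The ABP systolic foot is the diastolic minimum within a gating window; the
systolic peak is the global maximum after it.  On the PPG the same valley /
peak logic applies, the maximum-derivative point is located between them by
central differences, and the intersecting-tangent (IT) onset is the
intersection of the tangent through the maximum-upslope point with the
horizontal tangent through the diastolic minimum:

    t_IT = t_md - (y(t_md) - y_min) / y'(t_md)

kept as a real (sub-sample) time, since snapping it to a 100 Hz grid would
add 10 ms quantization on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from patbp.preprocessing import EnsembledCycle

#: default per-point gating ranges, ms relative to the R-peak (wide PPG
#: bounds accommodate a constant inter-device delay on the PPG channel)
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "abp_valley": (50.0, 400.0),
    "abp_peak": (50.0, 1200.0),
    "ppg_valley": (50.0, 1200.0),
    "ppg_peak": (50.0, 1200.0),
    "ppg_maxderiv": (50.0, 1200.0),
    "ppg_it": (50.0, 1200.0),
}


@dataclass
class FiducialSet:
    """Per-cycle fiducial times (s relative to the R-peak), optional with
    reason.  When all PPG points are present they satisfy
    valley <= IT <= maxderiv <= peak."""

    abp_peak: float | None = None
    abp_valley: float | None = None
    ppg_valley: float | None = None
    ppg_peak: float | None = None
    ppg_maxderiv: float | None = None
    ppg_it: float | None = None
    reason: str = ""

    def as_dict(self) -> dict[str, float | None]:
        return {
            "abp_peak": self.abp_peak,
            "abp_valley": self.abp_valley,
            "ppg_valley": self.ppg_valley,
            "ppg_peak": self.ppg_peak,
            "ppg_maxderiv": self.ppg_maxderiv,
            "ppg_it": self.ppg_it,
        }

    def complete(self) -> bool:
        return all(v is not None for v in self.as_dict().values())


def _find_valley(cycle: np.ndarray, fs: float, lo_s: float,
                 hi_s: float) -> int | None:
    """Index of the pulse foot: the minimum within [lo_s, hi_s] that is a
    genuine local minimum of the cycle (None for monotone segments)."""
    n = len(cycle)
    lo = max(1, int(np.ceil(lo_s * fs)))
    hi = min(n - 1, int(np.floor(hi_s * fs)) + 1)
    if hi <= lo:
        return None
    window = cycle[lo:hi]
    i = lo + int(np.argmin(window))
    if cycle[i - 1] < cycle[i] or cycle[i + 1] < cycle[i]:
        return None  # minimum sits on a slope, not at a trough
    if cycle[i - 1] == cycle[i] and cycle[i + 1] == cycle[i]:
        return None  # flat segment, no extremum
    return i


def detect_abp_fiducials(cycle: EnsembledCycle, fs: float,
                         valley_lo_s: float = 0.05,
                         valley_hi_s: float = 0.40) -> FiducialSet:
    """Systolic foot (valley) and systolic peak of an averaged ABP cycle."""
    x = cycle.abp_cycle
    if len(x) < int(0.25 * fs):
        return FiducialSet(reason="no_extremum_abp")
    imax = int(np.argmax(x))  # the foot must precede the systolic peak
    iv = _find_valley(x, fs, valley_lo_s, min(valley_hi_s, (imax - 1) / fs))
    if iv is None:
        return FiducialSet(reason="no_extremum_abp")
    ip = iv + 1 + int(np.argmax(x[iv + 1:]))
    if x[ip] <= x[iv]:
        return FiducialSet(reason="no_extremum_abp")
    return FiducialSet(abp_valley=iv / fs, abp_peak=ip / fs)


def detect_ppg_fiducials(cycle: EnsembledCycle, fs: float,
                         valley_lo_s: float = 0.05,
                         valley_hi_s: float | None = None) -> FiducialSet:
    """Valley, peak, maximum-derivative and IT points of an averaged PPG
    cycle.  All four are absent (with a reason) if the upstroke slope is not
    positive."""
    y = cycle.ppg_cycle
    if len(y) < int(0.25 * fs):
        return FiducialSet(reason="no_extremum_ppg")
    if valley_hi_s is None:
        valley_hi_s = (len(y) - 2) / fs
    imax = int(np.argmax(y))
    iv = _find_valley(y, fs, valley_lo_s, min(valley_hi_s, (imax - 1) / fs))
    if iv is None:
        return FiducialSet(reason="no_extremum_ppg")
    ip = iv + 1 + int(np.argmax(y[iv + 1:]))
    if y[ip] <= y[iv]:
        return FiducialSet(reason="no_extremum_ppg")
    deriv = np.gradient(y) * fs
    imd = iv + int(np.argmax(deriv[iv: ip + 1]))
    slope = deriv[imd]
    if slope <= 0:
        return FiducialSet(reason="nonpositive_slope")
    t_md = imd / fs
    t_it = t_md - (y[imd] - y[iv]) / slope
    t_it = float(np.clip(t_it, iv / fs, t_md))
    return FiducialSet(ppg_valley=iv / fs, ppg_peak=ip / fs,
                       ppg_maxderiv=t_md, ppg_it=t_it)


def merge_fiducials(abp: FiducialSet, ppg: FiducialSet) -> FiducialSet:
    reason = abp.reason or ppg.reason
    return FiducialSet(abp_peak=abp.abp_peak, abp_valley=abp.abp_valley,
                       ppg_valley=ppg.ppg_valley, ppg_peak=ppg.ppg_peak,
                       ppg_maxderiv=ppg.ppg_maxderiv, ppg_it=ppg.ppg_it,
                       reason=reason)


def gate_fiducials(fset: FiducialSet,
                   ranges: dict[str, tuple[float, float]] | None = None
                   ) -> tuple[bool, str]:
    """True iff every fiducial is present and inside its configured range
    (ms relative to the R-peak); otherwise the failing point's reason."""
    ranges = DEFAULT_RANGES if ranges is None else {**DEFAULT_RANGES, **ranges}
    points = fset.as_dict()
    for name, value in points.items():
        if value is None:
            return False, fset.reason or f"range_{name}"
        lo, hi = ranges[name]
        if not lo <= value * 1000.0 <= hi:
            return False, f"range_{name}"
    return True, ""
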