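"""Periodic pulse-shape templates with analytically known landmarks.

Each pressure / volume pulse is modelled as a periodic sum of Gaussians on the
unit cycle (phase in [0, 1)).  Because the function and its derivative are
analytic, the landmark phases -- diastolic minimum, systolic peak, point of
maximum upslope and the intersecting-tangent (IT) onset -- can be located once
to near machine precision and reused as exact ground truth when the template
is warped onto each cardiac cycle.  Warping the template linearly in time
scales every landmark offset by the cycle length and leaves the IT
construction invariant, so the simulator knows the exact continuous-time
location of every fiducial it renders.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar

# (amplitude, center phase, width) triplets
AbpComponents = tuple[tuple[float, float, float], ...]

#: default ABP pulse: systolic upstroke plus dicrotic bump
ABP_COMPONENTS: AbpComponents = ((1.0, 0.30, 0.09), (0.40, 0.58, 0.13))
#: default PPG pulse: slightly broader, delayed dicrotic component
PPG_COMPONENTS: AbpComponents = ((1.0, 0.33, 0.11), (0.45, 0.68, 0.16))
#: single-Gaussian QRS complex (seconds, not phase): (amp, offset_s, sigma_s)
QRS_COMPONENTS = ((1.0, 0.0, 0.012),)
#: low-amplitude P and T waves for morphological realism
PT_WAVE_COMPONENTS = ((0.12, -0.18, 0.030), (0.25, 0.28, 0.060))

_WRAPS = (-1.0, 0.0, 1.0)


def _periodic_value(components: AbpComponents, phase: np.ndarray) -> np.ndarray:
    phase = np.mod(phase, 1.0)
    out = np.zeros_like(phase, dtype=float)
    for a, m, s in components:
        for k in _WRAPS:
            out += a * np.exp(-((phase - m - k) ** 2) / (2.0 * s * s))
    return out


def _periodic_deriv(components: AbpComponents, phase: np.ndarray) -> np.ndarray:
    phase = np.mod(phase, 1.0)
    out = np.zeros_like(phase, dtype=float)
    for a, m, s in components:
        for k in _WRAPS:
            d = phase - m - k
            out += -a * d / (s * s) * np.exp(-(d * d) / (2.0 * s * s))
    return out


def _refine(fun, lo: float, hi: float) -> float:
    res = minimize_scalar(fun, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


@dataclass(frozen=True)
class Landmarks:
    """Template landmark phases in valley-anchored coordinates.

    Phase 0 is the diastolic minimum (pulse foot).  ``v_it`` is where the
    tangent through the maximum-upslope point meets the horizontal tangent
    through the minimum; it always lies in (0, v_md).
    """

    v_peak: float
    v_md: float
    v_it: float
    y_min: float
    y_max: float
    mean_norm: float  # cycle mean of the min/max-normalized template


class CycleTemplate:
    """A periodic pulse template anchored so that phase 0 is the pulse foot."""

    def __init__(self, components: AbpComponents):
        self.components = tuple(tuple(map(float, c)) for c in components)
        self._u_min, self.landmarks = _compute_landmarks(self.components)

    def value(self, phase: np.ndarray) -> np.ndarray:
        """Min/max-normalized template value at valley-anchored *phase*."""
        lm = self.landmarks
        raw = _periodic_value(self.components, np.asarray(phase, float) + self._u_min)
        return (raw - lm.y_min) / (lm.y_max - lm.y_min)

    def deriv(self, phase: np.ndarray) -> np.ndarray:
        lm = self.landmarks
        raw = _periodic_deriv(self.components, np.asarray(phase, float) + self._u_min)
        return raw / (lm.y_max - lm.y_min)


@lru_cache(maxsize=None)
def _compute_landmarks(components: AbpComponents) -> tuple[float, Landmarks]:
    grid = np.linspace(0.0, 1.0, 4097, endpoint=False)
    vals = _periodic_value(components, grid)
    step = grid[1] - grid[0]

    u0 = grid[int(np.argmin(vals))]
    u_min = _refine(lambda u: _periodic_value(components, np.array([u]))[0],
                    u0 - 2 * step, u0 + 2 * step)
    y_min = float(_periodic_value(components, np.array([u_min]))[0])

    # valley-anchored coordinates from here on
    def H(v):
        return float(_periodic_value(components, np.array([v + u_min]))[0])

    def Hp(v):
        return float(_periodic_deriv(components, np.array([v + u_min]))[0])

    vgrid = np.linspace(0.0, 1.0, 4097, endpoint=False)
    hv = _periodic_value(components, vgrid + u_min)
    v0 = vgrid[int(np.argmax(hv))]
    v_peak = _refine(lambda v: -H(v), v0 - 2 * step, v0 + 2 * step)
    y_max = H(v_peak)

    up = vgrid[(vgrid > 0) & (vgrid < v_peak)]
    dv = _periodic_deriv(components, up + u_min)
    vmd0 = up[int(np.argmax(dv))]
    v_md = _refine(lambda v: -Hp(v), max(vmd0 - 2 * step, 0.0),
                   min(vmd0 + 2 * step, v_peak))
    v_it = v_md - (H(v_md) - y_min) / Hp(v_md)

    mean_norm = float(np.mean((hv - y_min) / (y_max - y_min)))
    return u_min, Landmarks(v_peak=v_peak, v_md=v_md, v_it=v_it,
                            y_min=y_min, y_max=y_max, mean_norm=mean_norm)


def render_pulse_train(
    t: np.ndarray,
    anchor_times: np.ndarray,
    template: CycleTemplate,
    anchor_phase: float,
    lo: np.ndarray,
    hi: np.ndarray,
) -> np.ndarray:
    """Evaluate a warped periodic pulse train on the sample grid *t*.

    ``anchor_times[i]`` is the absolute time at which the template phase
    equals *anchor_phase* for beat i (e.g. 0 for a foot-anchored ABP train,
    ``v_it`` for an IT-anchored PPG train).  Between consecutive anchors the
    template is warped linearly; before the first / after the last anchor the
    neighbouring warp is extrapolated.  ``lo``/``hi`` give the per-beat value
    range: output = lo + (hi - lo) * normalized template.
    """
    anchor_times = np.asarray(anchor_times, float)
    n = len(anchor_times)
    if n < 2:
        raise ValueError("need at least two beats to render a pulse train")
    # extend one synthetic beat on each side so the record edges are covered
    bounds = np.concatenate((
        [anchor_times[0] - (anchor_times[1] - anchor_times[0])],
        anchor_times,
        [anchor_times[-1] + (anchor_times[-1] - anchor_times[-2])],
    ))
    seg = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, len(bounds) - 2)
    u = (t - bounds[seg]) / (bounds[seg + 1] - bounds[seg])
    beat = np.clip(seg - 1, 0, n - 1)
    shape = template.value(u + anchor_phase)
    lo = np.asarray(lo, float)[beat]
    hi = np.asarray(hi, float)[beat]
    return lo + (hi - lo) * shape


def render_ecg(t: np.ndarray, r_times: np.ndarray, t_wave: bool = True) -> np.ndarray:
    """Sum of per-beat Gaussian QRS complexes (plus small P/T waves)."""
    out = np.zeros_like(t, dtype=float)
    comps = QRS_COMPONENTS + (PT_WAVE_COMPONENTS if t_wave else ())
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    for r in np.asarray(r_times, float):
        for a, off, sig in comps:
            c = r + off
            i0 = max(0, int((c - 5 * sig - t[0]) / dt))
            i1 = min(len(t), int((c + 5 * sig - t[0]) / dt) + 2)
            if i1 > i0:
                out[i0:i1] += a * np.exp(-((t[i0:i1] - c) ** 2) / (2 * sig * sig))
    return out
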