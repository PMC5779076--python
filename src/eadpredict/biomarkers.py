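"""Comparator pro-arrhythmia biomarkers.

Simulated action-potential duration (APD at any repolarisation fraction),
diastolic intracellular calcium, and the classical hERG safety factor
log10(hERG IC50 / EFTPC_max).  APD and diastolic Ca are computed on the
final paced beat of a trace; both feed the risk classifiers ordinally, so
small convention differences (upstroke definition, repolarisation fraction
bookkeeping) do not affect how drugs rank.
"""

from __future__ import annotations

import math

import numpy as np

from .drugs import DrugProfile
from .engine import VoltageTrace

#: returned when the AP never recrosses the repolarisation level
REPOLARISATION_FAILURE = float("nan")

#: dV/dt defining the paced upstroke, mV/ms
UPSTROKE_SLOPE = 10.0


def _final_pace_slice(trace: VoltageTrace) -> slice:
    """Samples from the last stimulus (or the whole trace if unpaced)."""
    if len(trace.stimulus_times) == 0:
        return slice(0, len(trace.time))
    last = trace.stimulus_times[-1]
    start = int(np.searchsorted(trace.time, last))
    return slice(start, len(trace.time))


def apd(trace: VoltageTrace, repolarisation_fraction: float = 0.9) -> float:
    """Action-potential duration (ms) at the given repolarisation fraction.

    Measured on the final pace: from the first sample whose slope exceeds
    +10 mV/ms (the paced upstroke) to the first subsequent downward crossing
    of ``peak - fraction * amplitude``, where amplitude = peak minus the
    pre-upstroke diastolic potential.  Returns NaN ("repolarisation
    failure") when the crossing never happens.
    """
    if not (0.0 < repolarisation_fraction < 1.0):
        raise ValueError("repolarisation fraction must be in (0, 1)")
    sl = _final_pace_slice(trace)
    t = trace.time[sl]
    v = trace.vm[sl]
    if len(t) < 3:
        raise ValueError("trace too short to contain an action potential")
    dt = t[1] - t[0]
    slopes = np.diff(v) / dt
    above = np.flatnonzero(slopes > UPSTROKE_SLOPE)
    if above.size == 0:
        raise ValueError("no action-potential upstroke (dV/dt > 10 mV/ms) found")
    k_up = int(above[0])
    diastolic = v[k_up]  # last pre-upstroke sample
    peak_idx = k_up + int(np.argmax(v[k_up:]))
    peak = float(v[peak_idx])
    level = peak - repolarisation_fraction * (peak - diastolic)
    below = np.flatnonzero(v[peak_idx:] <= level)
    if below.size == 0:
        return REPOLARISATION_FAILURE
    k_cross = peak_idx + int(below[0])
    # linear interpolation onto the crossing level
    if k_cross > 0 and v[k_cross - 1] > level >= v[k_cross] and v[k_cross - 1] != v[k_cross]:
        frac = (v[k_cross - 1] - level) / (v[k_cross - 1] - v[k_cross])
        t_cross = t[k_cross - 1] + frac * dt
    else:
        t_cross = t[k_cross]
    return float(t_cross - t[k_up])


def diastolic_calcium(trace: VoltageTrace) -> float:
    """Minimum intracellular calcium (mM) over the final pace."""
    sl = _final_pace_slice(trace)
    return float(np.min(trace.cai[sl]))


def herg_safety_factor(profile: DrugProfile) -> float:
    """Redfern-style safety margin log10(hERG IC50 / EFTPC_max), dimensionless.

    Raises if the drug has no hERG pIC50 (no sensible margin exists).
    """
    if "IKr" not in profile.pIC50:
        raise ValueError(f"{profile.name}: no hERG data, safety factor undefined")
    return float(math.log10(profile.ic50_nM("IKr") / profile.eftpc_nM))
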