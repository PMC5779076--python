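"""Early-afterdepolarisation detection on sampled voltage traces.

The rule is deliberately simple and purely slope-based: any strictly
positive voltage slope above +1 mV/ms between adjacent samples flags a
depolarisation, and depolarisations within 50 ms before to 100 ms after a
stimulus are ignored (those are the paced upstrokes).  Being slope-based,
the verdict is unchanged by constant voltage offsets, and it catches single
EADs, trains of EADs, and EADs riding on a failed repolarisation alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import VoltageTrace

#: slope above which a depolarisation is reported (strict inequality), mV/ms
SLOPE_THRESHOLD = 1.0
#: exclusion window around each stimulus, ms
WINDOW_BEFORE = 50.0
WINDOW_AFTER = 100.0


@dataclass
class EadReport:
    has_ead: bool
    event_times: np.ndarray  # ms; left endpoint of each supra-threshold interval sample

    def __bool__(self) -> bool:  # convenience: ``if detect_eads(trace): ...``
        return self.has_ead

    @property
    def n_events(self) -> int:
        """Number of distinct supra-threshold upstrokes (contiguous runs merged)."""
        if len(self.event_times) == 0:
            return 0
        # samples are uniform; a gap larger than one sample starts a new event
        gaps = np.diff(self.event_times)
        step = np.min(gaps) if len(gaps) else 0.0
        return int(1 + np.sum(gaps > 1.5 * step)) if len(gaps) else 1


def detect_eads(
    trace: VoltageTrace,
    slope_threshold: float = SLOPE_THRESHOLD,
    window_before: float = WINDOW_BEFORE,
    window_after: float = WINDOW_AFTER,
) -> EadReport:
    """Classify a trace as containing EADs.

    The slope between adjacent samples is assigned to the left sample time
    ``t``; ``t`` is an event iff slope > ``slope_threshold`` (strictly) and
    ``t`` is outside ``[s - window_before, s + window_after]`` for every
    stimulus time ``s``.
    """
    if len(trace.time) < 2:
        return EadReport(False, np.empty(0))
    dt = np.diff(trace.time)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
        raise ValueError("detect_eads requires a uniformly sampled trace")

    slopes = np.diff(trace.vm) / dt[0]
    t_left = trace.time[:-1]
    candidate = slopes > slope_threshold
    for s in trace.stimulus_times:
        candidate &= ~((t_left >= s - window_before) & (t_left <= s + window_after))
    events = t_left[candidate]
    return EadReport(bool(events.size), events)


def repolarisation_failure(trace: VoltageTrace, v_threshold: float = -40.0) -> bool:
    """True if any beat fails to repolarise before the following stimulus.

    Checked as the minimum voltage over the last 500 ms of each diastolic
    interval (ending 50 ms before the next stimulus, or at the end of the
    trace) staying above ``v_threshold``.  This identifies the sustained
    depolarised-plateau phenotype — the extreme end of the EAD spectrum —
    even when no discrete supra-threshold upstroke rides on the plateau.
    Kept separate from :func:`detect_eads`: threshold bisection uses the
    slope rule only, while the zero-intervention (baseline) classification
    considers either sign of afterdepolarisation pathology.
    """
    if len(trace.time) < 2:
        return False
    marks = [s - WINDOW_BEFORE for s in trace.stimulus_times if s > trace.time[0]]
    marks.append(trace.time[-1])
    for end in marks:
        lo = np.searchsorted(trace.time, end - 500.0)
        hi = np.searchsorted(trace.time, end)
        if hi > lo and float(np.min(trace.vm[lo:hi])) > v_threshold:
            return True
    return False
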