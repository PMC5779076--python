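"""Synthetic fixtures: stylised voltage traces and separable metric tables.

These generators exist so the detector, biomarker and classification layers
can be tested against inputs whose ground truth is known by construction —
piecewise-linear action-potential-like traces with injected depolarising
bumps of chosen slope, and Gaussian per-category metric tables with
controllable separation.  They emulate the *geometry* the real simulations
produce (sampling, stimulus timing, EAD-like upstrokes, ordered category
means), not the electrophysiology itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import VoltageTrace

BASELINE_MV = -87.0


@dataclass
class BumpSpec:
    """A triangular depolarising bump: linear rise at ``slope`` for
    ``rise_ms``, then a symmetric fall."""

    start_ms: float
    slope: float  # mV/ms during the rise
    rise_ms: float = 20.0

    @property
    def end_ms(self) -> float:
        return self.start_ms + 2.0 * self.rise_ms


@dataclass
class TraceSpec:
    """Recipe for a synthetic trace with known EAD ground truth."""

    duration_ms: float = 3000.0
    dt_ms: float = 0.1
    stimulus_times: tuple = (0.0,)
    bumps: tuple = ()
    with_ap: bool = True  # draw a stylised AP after each stimulus
    baseline_mV: float = BASELINE_MV

    def _ap_slope_at(self, t: float) -> float:
        """Closed-form slope contribution of the stylised APs at time t."""
        if not self.with_ap:
            return 0.0
        total = 0.0
        for s in self.stimulus_times:
            if s <= t < s + 2.0:
                total += 60.0
            elif s + 82.0 <= t < s + 302.0:
                total += -120.0 / 220.0
        return total

    def expected_ead(
        self, slope_threshold: float = 1.0, before: float = 50.0, after: float = 100.0
    ) -> bool:
        """Ground truth by construction, never by running the detector: a
        sample is an event iff the summed slope of the segments active there
        (bump rise plus any stylised-AP phase) exceeds the threshold and the
        sample lies outside every stimulus window.  Bump and AP breakpoints
        are aligned to the sample grid, so each sample interval has a single
        well-defined slope."""
        for b in self.bumps:
            k0 = int(round(b.start_ms / self.dt_ms))
            n_rise = int(round(b.rise_ms / self.dt_ms))
            for k in range(k0, k0 + n_rise):
                t = k * self.dt_ms
                if t + self.dt_ms > self.duration_ms:
                    break
                if b.slope + self._ap_slope_at(t) <= slope_threshold:
                    continue
                if all(
                    not (s - before <= t <= s + after) for s in self.stimulus_times
                ):
                    return True
        return False


def generate_synthetic_trace(spec: TraceSpec) -> VoltageTrace:
    """Build the piecewise-linear trace a :class:`TraceSpec` describes.

    The stylised AP rises 120 mV in 2 ms from each stimulus, holds a short
    plateau and ramps back to baseline within 300 ms — entirely inside /
    slow enough for the detector's exclusion logic, so injected bumps fully
    control the EAD ground truth.  Overlapping bumps are rejected.
    """
    bumps = sorted(spec.bumps, key=lambda b: b.start_ms)
    for a, b in zip(bumps, bumps[1:]):
        if b.start_ms < a.end_ms:
            raise ValueError(
                f"overlapping bumps at {a.start_ms} ms and {b.start_ms} ms"
            )
    n = int(round(spec.duration_ms / spec.dt_ms)) + 1
    dt = spec.dt_ms
    t = np.arange(n) * dt
    v = np.full(n, spec.baseline_mV)

    def _span(start_ms, length_ms):
        k0 = max(int(round(start_ms / dt)), 0)
        k1 = min(k0 + int(round(length_ms / dt)), n)
        return k0, k1

    if spec.with_ap:
        for s in spec.stimulus_times:
            # upstroke: 2 ms at 60 mV/ms; plateau 80 ms; ramp down over 220 ms
            k0, k1 = _span(s, 2.0)
            v[k0:k1] = spec.baseline_mV + 60.0 * (t[k0:k1] - s)
            k0, k1 = _span(s + 2.0, 80.0)
            v[k0:k1] = spec.baseline_mV + 120.0
            k0, k1 = _span(s + 82.0, 220.0)
            v[k0:k1] = spec.baseline_mV + 120.0 * (1.0 - (t[k0:k1] - s - 82.0) / 220.0)

    for b in bumps:
        k0, k1 = _span(b.start_ms, b.rise_ms)
        v[k0:k1] += b.slope * (t[k0:k1] - b.start_ms)
        k0, k1 = _span(b.start_ms + b.rise_ms, b.rise_ms)
        v[k0:k1] += b.slope * (b.end_ms - t[k0:k1])

    cai = np.full(n, 1e-4)
    return VoltageTrace(
        time=t, vm=v, cai=cai, stimulus_times=np.asarray(spec.stimulus_times, float)
    )


def random_trace_specs(
    n: int,
    seed: int,
    duration_ms: float = 3000.0,
    max_bumps: int = 3,
) -> list[TraceSpec]:
    """Reproducible batch of random specs spanning sub- and supra-threshold
    bump slopes, inside and outside stimulus exclusion windows."""
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        stim = (0.0,) if rng.random() < 0.5 else (0.0, duration_ms / 2.0)
        k = int(rng.integers(0, max_bumps + 1))
        starts = np.sort(rng.uniform(0.0, duration_ms - 60.0, size=k))
        bumps = []
        prev_end = -np.inf
        for s in starts:
            # breakpoints aligned to the sample grid so per-sample slopes
            # are exact (see TraceSpec.expected_ead)
            b = BumpSpec(
                start_ms=round(float(s), 1),
                slope=float(rng.uniform(0.2, 3.0)),  # straddles the 1 mV/ms rule
                rise_ms=round(float(rng.uniform(5.0, 25.0)), 1),
            )
            if b.start_ms >= prev_end:
                bumps.append(b)
                prev_end = b.end_ms
        specs.append(
            TraceSpec(
                duration_ms=duration_ms,
                stimulus_times=stim,
                bumps=tuple(bumps),
                with_ap=bool(rng.random() < 0.8),
            )
        )
    return specs


def generate_synthetic_metric_table(
    n_drugs: int = 40,
    n_metrics: int = 3,
    category_separation: float = 1.0,
    noise_sd: float = 0.25,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gaussian per-category metric table with strictly ordered means.

    Categories 2..5 are assigned round-robin; metric ``j`` for a category
    ``c`` drug is drawn from N((c-2) * separation, sd).  Larger separation
    (or zero sd) makes the classes more separable, so cross-validated MAE
    decreases monotonically with effect size; identical means (separation
    0) reduce the problem to the label-frequency null.
    """
    if n_drugs < 4:
        raise ValueError("need at least one drug per category")
    rng = np.random.default_rng(seed)
    cats = np.array([2 + (i % 4) for i in range(n_drugs)])
    names = [f"drug{i:03d}" for i in range(n_drugs)]
    data = {}
    for j in range(n_metrics):
        means = (cats - 2) * category_separation
        data[f"metric{j}"] = means + rng.normal(0.0, noise_sd, size=n_drugs)
    table = pd.DataFrame(data, index=names)
    labels = pd.Series(cats, index=names, name="risk_category")
    return table, labels
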