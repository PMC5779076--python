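"""EAD threshold search: minimal disease-mimicking intervention per drug.

For a drug-blocked, steady-state-paced cell, three interventions can push
the model towards early afterdepolarisations:

* ``ICaL_scale`` — multiply the L-type Ca conductance (LQT8-like gain of
  function); EADs appear at HIGH multipliers, searched on [1, 80];
* ``INa_shift`` — depolarising shift (mV) of fast-Na steady-state
  inactivation (Brugada-like); EADs at HIGH shifts, searched on [0, 20];
* ``IKr_scale`` — multiply the rapid delayed-rectifier conductance
  (LQT2-like loss of function); EADs at LOW remaining fractions, searched
  on [0, 1] and reported as the conductance fraction remaining.

The threshold is found by interval bisection on a 12 s test simulation per
iterate, always restarting from the saved steady state.  Interventions are
applied on top of drug block (block first, intervention second).

Three subtleties complement the plain bisection.  First, the
no-intervention model is tested up front: if it already shows
afterdepolarisation pathology the result is ``ead_at_baseline``.  Second,
the slope-detectable EAD region need not extend to the severe end of the
interval: for the inactivation-shift intervention it is an interior window
(very large shifts depolarise the cell into a smooth, slope-sub-threshold
creep instead of discrete upstrokes).  When a bisection midpoint lands
inside the window, bisection converges onto the window's lower edge — the
minimal provoking intervention; when every midpoint misses it (narrow
windows), a uniform bracket-recovery sweep locates the first EAD-positive
level and the bisection restarts on that bracket.  Third, for strong
repolarisation impairment (notably the I_Kr intervention) the cell can go
straight from normal APs to a sustained depolarised plateau with no
discrete slope-detectable upstrokes at any level; when no slope EAD exists
anywhere, the search repeats with the failed-repolarisation criterion and
reports the onset of that third EAD morphology (``mode =
"repolarisation_failure"``).  Only if both searches find nothing is the
drug ``not_provokable``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .drugs import DrugProfile, apply_drug
from .ead import detect_eads, repolarisation_failure
from .engine import SolverError, run_to_steady_state, simulate
from .params import (
    DEFAULT_PACING,
    DEFAULT_SETTINGS,
    ModelParameters,
    PacingProtocol,
    SolverSettings,
)

logger = logging.getLogger(__name__)

INTERVENTION_KINDS = ("ICaL_scale", "INa_shift", "IKr_scale")

#: duration of each bisection test simulation, ms (four paces at 3 s)
TEST_DURATION = 12000.0


@dataclass
class InterventionSpec:
    """One bisected intervention: interval, severity orientation, stop gap."""

    kind: str
    interval: tuple[float, float]  # (low, high) in intervention units
    eads_at_high: bool  # True if EADs appear toward the high end
    gap: float = 1e-4
    #: points in the bracket-recovery sweep used when plain bisection finds
    #: no EAD anywhere (narrow interior EAD windows)
    fallback_points: int = 80

    def __post_init__(self) -> None:
        if self.kind not in INTERVENTION_KINDS:
            raise ValueError(f"kind must be one of {INTERVENTION_KINDS}")
        lo, hi = self.interval
        if not lo < hi:
            raise ValueError("interval must satisfy low < high")
        if self.gap <= 0:
            raise ValueError("termination gap must be positive")

    @property
    def mild(self) -> float:
        """Interval endpoint where the model is least perturbed."""
        return self.interval[0] if self.eads_at_high else self.interval[1]

    @property
    def severe(self) -> float:
        return self.interval[1] if self.eads_at_high else self.interval[0]

    @property
    def neutral(self) -> float:
        """The no-intervention value (scale 1 or shift 0)."""
        return 0.0 if self.kind == "INa_shift" else 1.0

    def apply(self, params: ModelParameters, value: float) -> ModelParameters:
        """Layer the intervention on top of (possibly drug-blocked) params."""
        if self.kind == "ICaL_scale":
            return params.with_updates(scale_ICaL=params.scale_ICaL * value)
        if self.kind == "INa_shift":
            return params.with_updates(shift_INa_inact=params.shift_INa_inact + value)
        return params.with_updates(scale_IKr=params.scale_IKr * value)

    def with_gap(self, gap: float) -> "InterventionSpec":
        return replace(self, gap=gap)


def default_interventions(gap: float = 1e-4) -> dict[str, InterventionSpec]:
    """The three interventions with their standard search intervals."""
    return {
        "ICaL_scale": InterventionSpec("ICaL_scale", (1.0, 80.0), True, gap),
        "INa_shift": InterventionSpec("INa_shift", (0.0, 20.0), True, gap),
        "IKr_scale": InterventionSpec("IKr_scale", (0.0, 1.0), False, gap),
    }


@dataclass
class EadThresholdResult:
    drug: str
    intervention: str
    threshold: float
    status: str  # converged | ead_at_baseline | not_provokable | error
    iterations: int
    #: "ead" when the threshold is a slope-detected EAD onset, or
    #: "repolarisation_failure" when no slope EAD exists at any level and the
    #: threshold is the onset of the sustained depolarised plateau
    mode: str = "ead"
    steady_paces: int = 0
    steady_converged: bool = True
    message: str = ""


def bisect_threshold(
    has_ead: Callable[[float], bool],
    mild: float,
    severe: float,
    gap: float,
) -> tuple[float, int, bool]:
    """Interval bisection from the mild toward the severe endpoint.

    At each iterate the midpoint is tested; an EAD-positive verdict moves
    the severe-side endpoint inward, a negative verdict moves the mild-side
    endpoint, so whenever the search has seen both verdicts the bracket
    straddles the EAD onset.  Stops when the bracket is narrower than
    ``gap``.  Returns ``(final midpoint, iterations, found_positive)`` where
    ``found_positive`` reports whether any tested value showed an EAD — if
    not, the "threshold" is merely the severe endpoint and the caller must
    decide whether EADs occur there at all.
    """
    neg, pos = mild, severe
    iterations = 0
    found_positive = False
    while abs(neg - pos) >= gap:
        mid = 0.5 * (neg + pos)
        if has_ead(mid):
            pos = mid
            found_positive = True
        else:
            neg = mid
        iterations += 1
    return 0.5 * (neg + pos), iterations, found_positive


def find_threshold(
    profile: DrugProfile | None,
    spec: InterventionSpec,
    pacing: PacingProtocol | None = None,
    settings: SolverSettings | None = None,
    steady_state: np.ndarray | None = None,
    test_duration: float = TEST_DURATION,
) -> EadThresholdResult:
    """Minimal EAD-provoking intervention level for one drug (None = control).

    Applies drug block at EFTPC_max, paces to steady state (unless a saved
    ``steady_state`` for this drug/pacing/settings combination is supplied),
    then bisects the intervention between its no-EAD and EAD endpoints.
    """
    pacing = pacing or DEFAULT_PACING
    settings = settings or DEFAULT_SETTINGS
    name = profile.name if profile is not None else "control"
    base = apply_drug(profile) if profile is not None else ModelParameters()

    paces_used = 0
    converged = True
    if steady_state is None:
        ss = run_to_steady_state(base, pacing, settings)
        steady_state = ss.state
        paces_used = ss.paces_used
        converged = ss.converged
        if not converged:
            logger.warning(
                "%s: steady state not reached in %d paces (norm %.3g); using final state",
                name, ss.paces_used, ss.final_norm,
            )

    verdicts: dict[float, tuple[bool, bool]] = {}

    def probe(value: float) -> tuple[bool, bool]:
        """(slope EAD, repolarisation failure) at one intervention level."""
        if value not in verdicts:
            params = spec.apply(base, value)
            trace = simulate(steady_state, params, pacing, test_duration, settings)
            verdicts[value] = (
                detect_eads(trace).has_ead,
                repolarisation_failure(trace),
            )
        return verdicts[value]

    def has_ead(value: float) -> bool:
        return probe(value)[0]

    def pathological(value: float) -> bool:
        # either morphology: discrete supra-threshold upstrokes or the
        # sustained failed-repolarisation plateau (see docs/methods.md)
        return probe(value)[0] or probe(value)[1]

    def baseline_pathological() -> bool:
        return pathological(spec.neutral)

    common = dict(
        drug=name, intervention=spec.kind,
        steady_paces=paces_used, steady_converged=converged,
    )
    try:
        if baseline_pathological():
            return EadThresholdResult(
                threshold=spec.neutral, status="ead_at_baseline", iterations=0, **common
            )
        if spec.mild != spec.neutral and has_ead(spec.mild):
            # mild interval endpoint differs from "no intervention" only if a
            # custom interval was supplied; treat like a baseline EAD
            return EadThresholdResult(
                threshold=spec.mild, status="ead_at_baseline", iterations=0, **common
            )
        def search(predicate):
            """Bisection, then a bracket-recovery sweep for interior windows."""
            threshold, iters, found = bisect_threshold(
                predicate, spec.mild, spec.severe, spec.gap
            )
            if found:
                return threshold, iters, True
            grid = np.linspace(spec.mild, spec.severe, spec.fallback_points + 1)[1:]
            for lo, hi in zip(np.concatenate(([spec.mild], grid[:-1])), grid):
                iters += 1
                if predicate(hi):
                    threshold, extra, _ = bisect_threshold(predicate, lo, hi, spec.gap)
                    return threshold, iters + extra, True
            return math.nan, iters, False

        # discrete slope-detected EADs take precedence; if none exist at any
        # level, the onset of repolarisation failure is the threshold
        mode = "ead"
        threshold, iterations, found = search(has_ead)
        if not found:
            mode = "repolarisation_failure"
            threshold, extra, found = search(pathological)
            iterations += extra
            if not found:
                return EadThresholdResult(
                    threshold=math.nan, status="not_provokable",
                    iterations=iterations, **common,
                )
    except SolverError as exc:
        return EadThresholdResult(
            threshold=math.nan, status="error", iterations=0, message=str(exc), **common
        )
    return EadThresholdResult(
        threshold=threshold, status="converged", iterations=iterations, mode=mode, **common
    )


def threshold_table(
    profiles: Sequence[DrugProfile],
    specs: Sequence[InterventionSpec] | None = None,
    pacing: PacingProtocol | None = None,
    settings: SolverSettings | None = None,
    include_control: bool = True,
    progress: Callable[[str], None] | None = None,
    test_duration: float = TEST_DURATION,
) -> pd.DataFrame:
    """Thresholds for every (drug, intervention) pair, in long format.

    One steady state is computed per drug and reused across interventions.
    Per-cell solver failures are recorded as ``status == "error"`` without
    aborting the scan.  Columns: drug, intervention, threshold, status,
    iterations, steady_paces, steady_converged.
    """
    pacing = pacing or DEFAULT_PACING
    settings = settings or DEFAULT_SETTINGS
    if specs is None:
        specs = list(default_interventions().values())

    entries: list[DrugProfile | None] = list(profiles)
    if include_control:
        entries = [None] + entries

    results = []
    for profile in entries:
        name = profile.name if profile is not None else "control"
        if progress is not None:
            progress(name)
        base = apply_drug(profile) if profile is not None else ModelParameters()
        try:
            ss = run_to_steady_state(base, pacing, settings)
        except SolverError as exc:
            for spec in specs:
                results.append(
                    EadThresholdResult(name, spec.kind, math.nan, "error", 0, message=str(exc))
                )
            continue
        for spec in specs:
            res = find_threshold(
                profile, spec, pacing, settings,
                steady_state=ss.state, test_duration=test_duration,
            )
            res.steady_paces = ss.paces_used
            res.steady_converged = ss.converged
            results.append(res)

    return pd.DataFrame(
        {
            "drug": [r.drug for r in results],
            "intervention": [r.intervention for r in results],
            "threshold": [r.threshold for r in results],
            "status": [r.status for r in results],
            "mode": [r.mode for r in results],
            "iterations": [r.iterations for r in results],
            "steady_paces": [r.steady_paces for r in results],
            "steady_converged": [r.steady_converged for r in results],
        }
    )
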