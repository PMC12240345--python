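"""Rest–activity fragmentation: transition-probability curves and kAR/kRA.

The analysis-scale trace is binarized at a fixed magnitude cut-off
(default 0.0167 g) into rest/active states.  Runs are maximal
same-state stretches; ``N_t`` is the number of runs of duration >= t
(the survival count of run lengths).  The discrete hazard of ending a
run — the probability of switching state at t+1 after t sustained
epochs — is estimated at every *represented* duration t (one actually
observed) with a gap correction for unobserved durations:

    p(t) = (N_t - N_{t+g}) / (N_t * g),

where g is the interval to the next represented duration (g = 1 at the
largest t, with N beyond it zero).  A LOWESS fit to the (t, p) points
locates the *constant region*: the longest contiguous stretch of
represented durations over which the smoothed curve varies by no more
than one standard deviation of the raw curve.  The fragmentation index
(kAR for active->rest, kRA for rest->active) is the sqrt(N_t)-weighted
mean of p(t) over that region.  High values mean fragmented, short-bout
behaviour; low values mean consolidated bouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .trace import ActivityTrace, ValidationError

DEFAULT_THRESHOLD_G = 0.0167  # activity cut-off in g
DEFAULT_LOWESS_FRACTION = 0.5

__all__ = [
    "DEFAULT_THRESHOLD_G",
    "DEFAULT_LOWESS_FRACTION",
    "BinarySequence",
    "RunLengthTable",
    "TransitionCurve",
    "ConstantRegion",
    "FragmentationResult",
    "binarize",
    "run_length_table",
    "transition_probability_curve",
    "find_constant_region",
    "fragmentation_index",
    "fragmentation_analysis",
    "transition_curve_frame",
]


@dataclass
class BinarySequence:
    """Rest/activity coding of a trace (True = active)."""

    states: np.ndarray
    threshold: float
    epoch_seconds: float

    @property
    def n(self) -> int:
        return int(self.states.size)


@dataclass
class RunLengthTable:
    """Run durations per state, with survival counts.

    ``active_durations`` / ``rest_durations`` list every maximal run in
    order of occurrence (boundary runs at the start and end of the
    recording included as complete runs).  ``flags`` marks degenerate
    sequences (a single state present) whose downstream indices are
    undefined.
    """

    active_durations: np.ndarray
    rest_durations: np.ndarray
    epoch_seconds: float
    flags: tuple[str, ...] = ()

    def durations(self, state: str) -> np.ndarray:
        if state == "active":
            return self.active_durations
        if state == "rest":
            return self.rest_durations
        raise ValidationError(f"state must be 'active' or 'rest', got {state!r}")

    def survival(self, state: str) -> np.ndarray:
        """``N_t`` for t = 1..t_max: the number of runs of duration >= t."""
        durs = self.durations(state)
        if durs.size == 0:
            return np.zeros(0, dtype=np.int64)
        t_max = int(durs.max())
        counts = np.bincount(durs, minlength=t_max + 1)[1:]
        return counts[::-1].cumsum()[::-1]


@dataclass
class TransitionCurve:
    """p(t) at represented durations, with run counts and gaps.

    ``direction`` is ``"AR"`` (active->rest hazard, from active runs) or
    ``"RA"`` (rest->active, from rest runs).  ``gap`` is the interval to
    the next represented duration (the gap-correction interval).
    """

    t: np.ndarray
    p: np.ndarray
    n_runs: np.ndarray
    gap: np.ndarray
    direction: str
    epoch_seconds: float


@dataclass
class ConstantRegion:
    """Contiguous stretch of represented durations where the LOWESS fit is flat."""

    start_index: int
    end_index: int            # inclusive
    t_start: int
    t_end: int
    flags: tuple[str, ...] = ()


@dataclass
class FragmentationResult:
    k_ar: float
    k_ra: float
    ar_region: Optional[ConstantRegion]
    ra_region: Optional[ConstantRegion]
    ar_curve: Optional[TransitionCurve]
    ra_curve: Optional[TransitionCurve]
    threshold: float
    lowess_fraction: float
    flags: tuple[str, ...] = ()


def binarize(trace: ActivityTrace, threshold: float = DEFAULT_THRESHOLD_G) -> BinarySequence:
    """Code each epoch active iff its magnitude strictly exceeds ``threshold``.

    A value exactly at the cut-off is rest: with equality unassigned by
    the above-or-below rule, rest is the conservative reading for noisy
    baselines.
    """
    if not threshold > 0:
        raise ValidationError(f"threshold must be positive, got {threshold}")
    return BinarySequence(
        states=trace.values > threshold,
        threshold=float(threshold),
        epoch_seconds=trace.epoch_seconds,
    )


def run_length_table(binary: BinarySequence) -> RunLengthTable:
    """Enumerate maximal same-state runs and their durations.

    The first and last (censored) runs are included as complete runs;
    over multi-day recordings their contribution is negligible.  A
    sequence in a single state yields an empty table for the other state
    and a flag instead of an error.
    """
    s = np.asarray(binary.states, dtype=bool)
    change = np.flatnonzero(np.diff(s))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [s.size]))
    durations = ends - starts
    is_active = s[starts]
    active = durations[is_active].astype(np.int64)
    rest = durations[~is_active].astype(np.int64)
    flags = []
    if active.size == 0:
        flags.append("no_active_runs")
    if rest.size == 0:
        flags.append("no_rest_runs")
    return RunLengthTable(
        active_durations=active,
        rest_durations=rest,
        epoch_seconds=binary.epoch_seconds,
        flags=tuple(flags),
    )


def transition_probability_curve(table: RunLengthTable, direction: str) -> TransitionCurve:
    """Estimate the state-exit hazard p(t) at every represented duration.

    ``direction="AR"`` uses active runs (probability of resting at t+1
    after t active epochs); ``"RA"`` uses rest runs.  Durations are
    *represented* when at least one run of exactly that length occurred,
    i.e. where ``N_t > N_{t+1}``.
    """
    if direction not in ("AR", "RA"):
        raise ValidationError(f"direction must be 'AR' or 'RA', got {direction!r}")
    state = "active" if direction == "AR" else "rest"
    survival = table.survival(state)
    if survival.size == 0:
        raise ValidationError(f"no {state} runs: transition curve undefined")
    t_max = survival.size
    n_beyond = np.concatenate((survival, [0]))  # N_t for t = 1..t_max+1
    represented = np.flatnonzero(n_beyond[:-1] > n_beyond[1:]) + 1  # 1-based t
    gaps = np.diff(np.concatenate((represented, [represented[-1] + 1])))
    n_t = survival[represented - 1]
    n_next = np.where(represented + gaps <= t_max, n_beyond[represented + gaps - 1], 0)
    p = (n_t - n_next) / (n_t * gaps)
    return TransitionCurve(
        t=represented.astype(np.int64),
        p=p.astype(float),
        n_runs=n_t.astype(np.int64),
        gap=gaps.astype(np.int64),
        direction=direction,
        epoch_seconds=table.epoch_seconds,
    )


def find_constant_region(
    curve: TransitionCurve, lowess_fraction: float = DEFAULT_LOWESS_FRACTION
) -> ConstantRegion:
    """Locate the longest flat stretch of the LOWESS-smoothed curve.

    The smoothed curve is fitted to the (t, p) points (one robustifying
    iteration); the region is the longest contiguous index window over
    which it varies by no more than one standard deviation of the raw
    p(t) curve (population SD).  Ties between equally long windows go to
    the earlier start.  If no window of length >= 2 qualifies, the
    single point with the smallest smoothed slope magnitude is returned,
    flagged.
    """
    if not (0 < lowess_fraction <= 1):
        raise ValidationError(f"lowess_fraction must be in (0, 1], got {lowess_fraction}")
    n = curve.t.size
    if n < 3:
        raise ValidationError(f"constant-region search needs >= 3 curve points, got {n}")
    smoothed = _lowess(
        curve.p, curve.t.astype(float), frac=lowess_fraction, it=1, return_sorted=False
    )
    sd = float(np.std(curve.p))  # population denominator over the whole raw curve
    sd += 1e-12  # numerical headroom so an exactly constant curve spans the domain

    best_i, best_j = 0, -1  # empty
    for i in range(n):
        lo = hi = smoothed[i]
        for j in range(i, n):
            v = smoothed[j]
            if v < lo:
                lo = v
            elif v > hi:
                hi = v
            if hi - lo > sd:
                break
            if j - i > best_j - best_i:
                best_i, best_j = i, j
        if n - 1 - i <= best_j - best_i:  # no longer window can start here
            break

    if best_j - best_i + 1 >= 2:
        return ConstantRegion(
            start_index=best_i,
            end_index=best_j,
            t_start=int(curve.t[best_i]),
            t_end=int(curve.t[best_j]),
        )
    # fallback: flattest single point of the smoothed curve
    t = curve.t.astype(float)
    slopes = np.gradient(smoothed, t)
    k = int(np.argmin(np.abs(slopes)))
    return ConstantRegion(
        start_index=k,
        end_index=k,
        t_start=int(curve.t[k]),
        t_end=int(curve.t[k]),
        flags=("single_point_fallback",),
    )


def fragmentation_index(curve: TransitionCurve, region: ConstantRegion) -> float:
    """sqrt(N_t)-weighted mean of p(t) over the constant region."""
    i, j = region.start_index, region.end_index
    if j < i or i < 0 or j >= curve.t.size:
        raise ValidationError(f"region [{i}, {j}] is empty or outside the curve")
    w = np.sqrt(curve.n_runs[i : j + 1].astype(float))
    return float((w * curve.p[i : j + 1]).sum() / w.sum())


def fragmentation_analysis(
    trace: ActivityTrace,
    threshold: float = DEFAULT_THRESHOLD_G,
    lowess_fraction: float = DEFAULT_LOWESS_FRACTION,
) -> FragmentationResult:
    """Binarize, tabulate runs and compute both fragmentation indices.

    Degenerate inputs (single-state sequences, curves too short for the
    region search) yield NaN indices with explanatory flags rather than
    exceptions.  An index estimate of exactly 1 (every run the same,
    immediately-ending duration) is clamped to ``1 - 1/(2 N_1)`` so the
    downstream logit transform stays finite; the clamp is flagged.
    """
    binary = binarize(trace, threshold)
    table = run_length_table(binary)
    flags = list(table.flags)
    results: dict[str, tuple[float, Optional[ConstantRegion], Optional[TransitionCurve]]] = {}
    for direction, absent_flag in (("AR", "no_active_runs"), ("RA", "no_rest_runs")):
        if absent_flag in table.flags or (
            direction == "AR" and table.rest_durations.size == 0
        ) or (direction == "RA" and table.active_durations.size == 0):
            # single-state recording: hazard of leaving the state unobservable
            results[direction] = (float("nan"), None, None)
            if f"k_{direction.lower()}_undefined" not in flags:
                flags.append(f"k_{direction.lower()}_undefined")
            continue
        curve = transition_probability_curve(table, direction)
        if curve.t.size < 3:
            # too few points to locate a plateau: use the whole curve
            region = ConstantRegion(
                start_index=0,
                end_index=curve.t.size - 1,
                t_start=int(curve.t[0]),
                t_end=int(curve.t[-1]),
                flags=("short_curve_full_region",),
            )
        else:
            region = find_constant_region(curve, lowess_fraction)
        flags.extend(f"{direction.lower()}_{f}" for f in region.flags)
        k = fragmentation_index(curve, region)
        if k >= 1.0:
            n1 = int(curve.n_runs[0])
            k = 1.0 - 1.0 / (2.0 * n1)
            flags.append(f"k_{direction.lower()}_clamped")
        results[direction] = (k, region, curve)
    k_ar, ar_region, ar_curve = results["AR"]
    k_ra, ra_region, ra_curve = results["RA"]
    return FragmentationResult(
        k_ar=k_ar,
        k_ra=k_ra,
        ar_region=ar_region,
        ra_region=ra_region,
        ar_curve=ar_curve,
        ra_curve=ra_curve,
        threshold=threshold,
        lowess_fraction=lowess_fraction,
        flags=tuple(flags),
    )


def transition_curve_frame(
    curve: TransitionCurve, region: Optional[ConstantRegion] = None
) -> pd.DataFrame:
    """Serialize a transition curve (and optional region) to a table."""
    in_region = np.zeros(curve.t.size, dtype=bool)
    if region is not None:
        in_region[region.start_index : region.end_index + 1] = True
    return pd.DataFrame(
        {
            "t": curve.t,
            "p": curve.p,
            "n_runs": curve.n_runs,
            "gap": curve.gap,
            "in_region": in_region,
        }
    )
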