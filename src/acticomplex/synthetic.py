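"""Synthetic signals and rest/activity cohorts with known ground truth.

Two kinds of test material are produced here:

* canonical signals (sine, white noise, AR(1) red noise, the Hénon map)
  whose correlation-dimension behaviour is known, and
* two-state semi-Markov rest/activity traces that emulate epoch-level
  ankle-accelerometer recordings, with healthy-like and patient-like
  parameter templates.

The semi-Markov construction is deliberately simple: per-epoch transition
probabilities (hazards) are constant within a state, which makes the
fragmentation indices kAR/kRA exactly identifiable and turns the whole
fragmentation stage into a parameter-recovery problem with known truth.
Rest consolidation at night is modelled as a sinusoidal suppression of the
rest→active hazard over the 24 h cycle.

Amplitudes are state-conditional: rest epochs draw uniformly from
``[0, rest_amp_max]`` strictly below the binarization threshold, active
epochs draw from a log-normal shifted above the threshold and modulated by
a multiplicative AR(1) red-noise component.  Binarizing a generated trace
at its native epoch length therefore recovers the latent state path
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numba as nb
import numpy as np
import pandas as pd

from .fragmentation import DEFAULT_THRESHOLD_G
from .trace import ActivityTrace, ValidationError, write_trace_csv

EPOCHS_PER_DAY_5S = 17280  # 5-second epochs in 24 h

__all__ = [
    "SemiMarkovParams",
    "CohortSpec",
    "healthy_template",
    "patient_template",
    "generate_canonical_signal",
    "generate_semi_markov_activity",
    "generate_cohort",
    "write_cohort",
]


@dataclass
class SemiMarkovParams:
    """Parameters of the two-state rest/activity generator.

    Probabilities are per epoch; amplitude parameters are on the scale
    noted.  ``diurnal_depth`` multiplicatively suppresses ``p_ra`` around a
    nightly minimum (03:00), so rest consolidates at night; 0 disables the
    cycle.  ``ar1_phi``/``ar1_sd`` parameterize a log-additive AR(1)
    red-noise component of the active-epoch amplitudes.
    """

    p_ar: float = 0.02          # active -> rest hazard per epoch
    p_ra: float = 0.025         # rest -> active hazard per epoch (daytime)
    active_amp_mean: float = math.log(0.08)   # log-scale location of active magnitudes (g)
    active_amp_sd: float = 0.7                # log-scale spread of active magnitudes
    rest_amp_max: float = 0.01  # upper bound of rest-epoch magnitudes (g)
    diurnal_depth: float = 0.85  # in [0, 1): 0 = no 24 h cycle
    ar1_phi: float = 0.5        # AR(1) coefficient of the red-noise component
    ar1_sd: float = 0.3         # stationary SD (log scale) of the red-noise component
    n_epochs: int = 14 * EPOCHS_PER_DAY_5S
    epoch_seconds: float = 5.0
    threshold_g: float = DEFAULT_THRESHOLD_G  # downstream binarization cut-off
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("p_ar", "p_ra"):
            p = getattr(self, name)
            # 0 is allowed (absorbing state) even though typical use keeps
            # hazards strictly positive
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        if self.p_ar == 0.0 and self.p_ra == 0.0:
            raise ValidationError("p_ar and p_ra cannot both be 0")
        if not (0.0 <= self.diurnal_depth < 1.0):
            raise ValidationError(f"diurnal_depth must be in [0, 1), got {self.diurnal_depth}")
        if not (0.0 <= self.ar1_phi < 1.0):
            raise ValidationError(f"ar1_phi must be in [0, 1), got {self.ar1_phi}")
        if self.ar1_sd < 0:
            raise ValidationError(f"ar1_sd must be nonnegative, got {self.ar1_sd}")
        if not (0.0 < self.rest_amp_max < self.threshold_g):
            raise ValidationError(
                f"rest_amp_max must be in (0, threshold_g={self.threshold_g}), "
                f"got {self.rest_amp_max}"
            )
        if self.active_amp_sd < 0:
            raise ValidationError(f"active_amp_sd must be nonnegative, got {self.active_amp_sd}")
        if int(self.n_epochs) != self.n_epochs or self.n_epochs < 2:
            raise ValidationError(f"n_epochs must be an integer >= 2, got {self.n_epochs}")
        if self.epoch_seconds <= 0:
            raise ValidationError(f"epoch_seconds must be positive, got {self.epoch_seconds}")


def healthy_template(**overrides) -> SemiMarkovParams:
    """Healthy-like defaults: long activity bouts (~4 min), short daytime
    rest bouts (~3 min), strongly consolidated night rest, weak red noise."""
    return SemiMarkovParams(**overrides)


def patient_template(**overrides) -> SemiMarkovParams:
    """Patient-like defaults: short activity bouts (~2 min), long
    low-activity periods (~20 min) scattered through day and night, lower
    activity amplitudes, and a strong slow red-noise amplitude component."""
    base = dict(
        p_ar=0.04,
        p_ra=0.004,
        active_amp_mean=math.log(0.04),
        diurnal_depth=0.3,
        ar1_phi=0.985,
        ar1_sd=0.8,
    )
    base.update(overrides)
    return SemiMarkovParams(**base)


@dataclass
class CohortSpec:
    """A balanced two-group synthetic cohort.

    ``between_subject_jitter`` is the relative (log-scale) spread applied
    to each subject's hazards, amplitude location and red-noise amplitude;
    jittered hazards are clipped into (0, 1].  Age and sex marginals
    default to the descriptives of the cohorts the generator stands in
    for.
    """

    n_per_group: int = 20
    healthy_params: SemiMarkovParams = field(default_factory=healthy_template)
    patient_params: SemiMarkovParams = field(default_factory=patient_template)
    between_subject_jitter: float = 0.15
    healthy_age: tuple[float, float] = (35.3, 10.3)
    patient_age: tuple[float, float] = (46.5, 12.0)
    healthy_male_fraction: float = 0.42
    patient_male_fraction: float = 0.54
    master_seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_per_group) != self.n_per_group or self.n_per_group < 1:
            raise ValidationError(f"n_per_group must be a positive integer, got {self.n_per_group}")
        if self.between_subject_jitter < 0:
            raise ValidationError("between_subject_jitter must be nonnegative")
        for name in ("healthy_male_fraction", "patient_male_fraction"):
            f = getattr(self, name)
            if not (0.0 <= f <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {f}")


# ---------------------------------------------------------------------------
# canonical signals


def _henon_orbit(n: int, a: float, b: float, x0: float, y0: float, burn_in: int) -> np.ndarray:
    x, y = x0, y0
    out = np.empty(n)
    for i in range(-burn_in, n):
        if i >= 0:
            out[i] = x
        x, y = 1.0 - a * x * x + y, b * x
        if abs(x) > 1e6:
            raise ValidationError(
                f"henon orbit diverged at iterate {i + burn_in}; params a={a}, b={b} unstable"
            )
    return out


def generate_canonical_signal(kind: str, n: int, seed: int = 0, **params) -> ActivityTrace:
    """Generate a canonical test signal as an :class:`ActivityTrace`.

    Supported kinds and their parameters (with defaults):

    ``sine``
        ``amplitude`` (1.0), ``period`` (50*pi epochs), ``phase`` (0.0).
        The default period is irrational so integer sampling fills the
        cycle densely instead of revisiting a finite set of points.
    ``white_noise``
        ``sd`` (1.0): i.i.d. Gaussian.
    ``ar1``
        ``phi`` (0.9), ``sd`` (1.0): stationary Gaussian AR(1) with
        stationary standard deviation ``sd``.
    ``henon``
        ``a`` (1.4), ``b`` (0.3), ``x0``/``y0`` (0.0), ``burn_in`` (1000):
        x-coordinate orbit of the Hénon map in its canonical chaotic
        regime, after the stated burn-in.
    """
    if n < 10:
        raise ValidationError(f"n must be >= 10, got {n}")
    rng = np.random.default_rng(seed)
    if kind == "sine":
        amplitude = params.pop("amplitude", 1.0)
        period = params.pop("period", 50.0 * math.pi)
        phase = params.pop("phase", 0.0)
        _reject_unknown(kind, params)
        if period < 2:
            raise ValidationError(f"period must be >= 2 epochs, got {period}")
        t = np.arange(n)
        values = amplitude * np.sin(2.0 * np.pi * t / period + phase)
    elif kind == "white_noise":
        sd = params.pop("sd", 1.0)
        _reject_unknown(kind, params)
        if sd <= 0:
            raise ValidationError(f"sd must be positive, got {sd}")
        values = rng.normal(0.0, sd, n)
    elif kind == "ar1":
        phi = params.pop("phi", 0.9)
        sd = params.pop("sd", 1.0)
        _reject_unknown(kind, params)
        if not abs(phi) < 1:
            raise ValidationError(f"phi must satisfy |phi| < 1, got {phi}")
        if sd <= 0:
            raise ValidationError(f"sd must be positive, got {sd}")
        innov = rng.normal(0.0, sd * math.sqrt(1.0 - phi * phi), n)
        values = np.empty(n)
        values[0] = rng.normal(0.0, sd)
        for i in range(1, n):
            values[i] = phi * values[i - 1] + innov[i]
    elif kind == "henon":
        a = params.pop("a", 1.4)
        b = params.pop("b", 0.3)
        x0 = params.pop("x0", 0.0)
        y0 = params.pop("y0", 0.0)
        burn_in = params.pop("burn_in", 1000)
        _reject_unknown(kind, params)
        if burn_in < 0:
            raise ValidationError(f"burn_in must be nonnegative, got {burn_in}")
        values = _henon_orbit(n, a, b, x0, y0, burn_in)
    else:
        raise ValidationError(
            f"unknown kind {kind!r}; expected sine, white_noise, ar1 or henon"
        )
    return ActivityTrace(values=values, epoch_seconds=1.0, subject_id=f"{kind}")


def _reject_unknown(kind: str, leftover: dict) -> None:
    if leftover:
        raise ValidationError(f"unknown parameter(s) for kind={kind!r}: {sorted(leftover)}")


# ---------------------------------------------------------------------------
# semi-Markov rest/activity traces


@nb.njit(cache=True)
def _latent_path(u: np.ndarray, p_ar: float, p_ra_t: np.ndarray, s0: int) -> np.ndarray:
    n = u.shape[0]
    states = np.empty(n, dtype=np.int8)
    s = s0
    for i in range(n):
        states[i] = s
        if s == 1:
            if u[i] < p_ar:
                s = 0
        else:
            if u[i] < p_ra_t[i]:
                s = 1
    return states


def _diurnal_p_ra(params: SemiMarkovParams, n: int) -> np.ndarray:
    if params.diurnal_depth == 0.0:
        return np.full(n, params.p_ra)
    hours = (np.arange(n) * params.epoch_seconds / 3600.0) % 24.0
    # weight 1 at the nightly minimum (03:00), 0 twelve hours away
    w = 0.5 * (1.0 + np.cos(2.0 * np.pi * (hours - 3.0) / 24.0))
    return params.p_ra * (1.0 - params.diurnal_depth * w)


def generate_semi_markov_activity(
    params: SemiMarkovParams,
    with_states: bool = False,
    initial_state: Optional[str] = None,
) -> ActivityTrace | tuple[ActivityTrace, np.ndarray]:
    """Simulate one epoch-level rest/activity trace.

    With ``with_states=True`` the latent state path (1 = active, 0 = rest)
    is returned alongside the trace; the trace itself is identical either
    way for a given ``params.seed``.  ``initial_state`` forces the first
    epoch to ``"rest"`` or ``"active"``; by default it is drawn from the
    stationary distribution of the unmodulated chain.
    """
    params.validate()
    n = int(params.n_epochs)
    rng = np.random.default_rng(params.seed)

    stationary_active = params.p_ra / (params.p_ar + params.p_ra)
    u0 = rng.random()  # always consumed, so initial_state does not shift the stream
    if initial_state is None:
        s0 = 1 if u0 < stationary_active else 0
    elif initial_state in ("rest", "active"):
        s0 = 1 if initial_state == "active" else 0
    else:
        raise ValidationError(f"initial_state must be 'rest' or 'active', got {initial_state!r}")
    u = rng.random(n)
    p_ra_t = _diurnal_p_ra(params, n)
    states = _latent_path(u, params.p_ar, p_ra_t, s0)
    active = states == 1

    # red-noise component: stationary AR(1) on the log-amplitude scale
    z = np.zeros(n)
    if params.ar1_sd > 0:
        innov = rng.normal(0.0, params.ar1_sd * math.sqrt(1.0 - params.ar1_phi**2), n)
        z[0] = rng.normal(0.0, params.ar1_sd)
        z[1:] = innov[1:]
        _ar1_accumulate(z, params.ar1_phi)

    eps = rng.normal(0.0, 1.0, n)
    rest_mag = rng.uniform(0.0, params.rest_amp_max, n)
    active_mag = params.threshold_g + np.exp(
        params.active_amp_mean + params.active_amp_sd * eps + z
    )
    values = np.where(active, active_mag, rest_mag)
    trace = ActivityTrace(
        values=values, epoch_seconds=params.epoch_seconds, subject_id="synthetic"
    )
    if with_states:
        return trace, states
    return trace


@nb.njit(cache=True)
def _ar1_accumulate(z: np.ndarray, phi: float) -> None:
    for i in range(1, z.shape[0]):
        z[i] += phi * z[i - 1]


# ---------------------------------------------------------------------------
# cohorts


def _jitter_params(
    template: SemiMarkovParams, jitter: float, rng: np.random.Generator, seed: int
) -> SemiMarkovParams:
    if jitter == 0.0:
        return replace(template, seed=seed)
    g = rng.normal(0.0, jitter, 4)
    p_ar = min(1.0, template.p_ar * math.exp(g[0]))
    p_ra = min(1.0, template.p_ra * math.exp(g[1]))
    return replace(
        template,
        p_ar=p_ar,
        p_ra=p_ra,
        active_amp_mean=template.active_amp_mean + g[2],
        ar1_sd=template.ar1_sd * math.exp(g[3]),
        seed=seed,
    )


def generate_cohort(spec: CohortSpec) -> list[ActivityTrace]:
    """Generate a balanced healthy/patient cohort.

    Returns ``2 * n_per_group`` traces (healthy first) with subject
    metadata attached.  Per-subject simulation seeds and jitter draws are
    derived deterministically from ``master_seed``.
    """
    ss = np.random.SeedSequence(spec.master_seed)
    meta_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * spec.n_per_group)]

    traces: list[ActivityTrace] = []
    idx = 0
    for group, template, (age_mean, age_sd), male_frac, prefix in (
        ("healthy", spec.healthy_params, spec.healthy_age, spec.healthy_male_fraction, "H"),
        ("patient", spec.patient_params, spec.patient_age, spec.patient_male_fraction, "P"),
    ):
        for k in range(spec.n_per_group):
            params = _jitter_params(
                template, spec.between_subject_jitter, meta_rng, child_seeds[idx]
            )
            age = float(np.clip(meta_rng.normal(age_mean, age_sd), 18.0, 90.0))
            sex = "male" if meta_rng.random() < male_frac else "female"
            trace = generate_semi_markov_activity(params)
            trace.subject_id = f"{prefix}{k + 1:02d}"
            trace.group = group
            trace.age = round(age, 1)
            trace.sex = sex
            traces.append(trace)
            idx += 1
    return traces


def write_cohort(traces: list[ActivityTrace], outdir) -> str:
    """Write per-subject trace CSVs plus a cohort manifest.

    The manifest (``manifest.csv``: subject_id, group, age, sex, path) is
    the input the cohort pipeline consumes; the path returned is the
    manifest's.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for trace in traces:
        fname = f"{trace.subject_id}.csv"
        write_trace_csv(trace, os.path.join(outdir, fname))
        rows.append(
            {
                "subject_id": trace.subject_id,
                "group": trace.group,
                "age": trace.age,
                "sex": trace.sex,
                "path": fname,
            }
        )
    manifest = os.path.join(outdir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
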