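"""Synthetic dyadic-session generator.

Emulates the structure of a lab study of dyadic "difficult conversations":
per-second behavior codes (1 = proself, 2 = neutral, 3 = prosocial) whose
dwell times follow either a memoryless (Markov) or a stretched-exponential
family, and per-second emotional-valence traces recorded as mouse-position
pixels on a 0..1123 screen axis, modeled as a bounded random walk (optionally
with fractional-Gaussian-noise increments for a prescribed Hurst index).

Nothing here couples a person's behavior stream to their emotion stream, nor
the two persons of a dyad to each other: the downstream analyses treat every
stream marginally, so the generator does too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc, gammaincinv

from .errors import ParameterError
from .io import SessionRecord, StudyTable

PIXEL_MAX = 1123
STATES = (1, 2, 3)


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ParameterError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class BehaviorGenParams:
    """Parameters of the semi-Markov behavior-state generator.

    dwell_form "markov" draws dwell times from a (discretized) single
    exponential -- constant switching probability per second; "stretched"
    draws them from a density proportional to exp(-(t/tau)^b), whose hazard
    falls with time already spent in the state when b < 1.

    The default (b = 0.3, tau = 0.1 s) gives integer dwells with median ~8 s
    and mean ~19 s, i.e. roughly sixty behavioral runs in a twenty-minute
    session -- the order of switching seen in per-second-coded conversation.
    Note that for b < 1 the effective dwell scale is much larger than tau
    itself (the mean of exp(-(t/tau)^b) is tau * Gamma(2/b) / Gamma(1/b)).
    """

    dwell_form: str = "stretched"
    exponent_b: float = 0.3
    timescale_tau: float = 0.1
    # state -> weights over the other two states, in ascending state order
    transition_weights: dict[int, tuple[float, float]] | None = None
    session_length: int = 1200
    min_dwell: int = 1

    def __post_init__(self):
        if self.dwell_form not in ("markov", "stretched"):
            raise ParameterError(f"unknown dwell_form {self.dwell_form!r}")
        _check_finite("exponent_b", self.exponent_b)
        _check_finite("timescale_tau", self.timescale_tau)
        if not 0 < self.exponent_b <= 1:
            raise ParameterError(f"exponent_b must be in (0, 1], got {self.exponent_b}")
        if self.timescale_tau <= 0:
            raise ParameterError(f"timescale_tau must be > 0, got {self.timescale_tau}")
        if self.session_length < 1:
            raise ParameterError("session_length must be >= 1")
        if self.min_dwell < 1:
            raise ParameterError("min_dwell must be >= 1")
        if self.transition_weights is not None:
            for state, w in self.transition_weights.items():
                if state not in STATES:
                    raise ParameterError(f"unknown state {state} in transition_weights")
                if len(w) != 2 or min(w) < 0 or max(w) <= 0:
                    raise ParameterError(
                        f"weights for state {state} must be two nonnegative "
                        f"values, not all zero: {w!r}"
                    )

    @property
    def effective_b(self) -> float:
        return 1.0 if self.dwell_form == "markov" else self.exponent_b


@dataclass(frozen=True)
class EmotionGenParams:
    """Parameters of the bounded-random-walk emotion generator (pixel units)."""

    increment_sd: float = 5.0
    start_value: float = 561.0
    bounds: tuple[float, float] = (0.0, float(PIXEL_MAX))
    hurst_target: float = 0.5
    session_length: int = 1200

    def __post_init__(self):
        _check_finite("increment_sd", self.increment_sd)
        _check_finite("start_value", self.start_value)
        _check_finite("hurst_target", self.hurst_target)
        lo, hi = self.bounds
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ParameterError(f"invalid bounds {self.bounds!r}")
        if not lo <= self.start_value <= hi:
            raise ParameterError(
                f"start_value {self.start_value} outside bounds {self.bounds}"
            )
        if not 0 < self.hurst_target < 1:
            raise ParameterError(f"hurst_target must be in (0, 1), got {self.hurst_target}")
        if self.increment_sd <= 0:
            raise ParameterError("increment_sd must be > 0")
        if self.session_length < 1:
            raise ParameterError("session_length must be >= 1")


@dataclass(frozen=True)
class StudyGenConfig:
    """Shape of a full synthetic study: 11 intractable + 12 tractable dyads of
    two persons each, with occasional missing person-records (the real study
    lost two persons "due to a technical reason")."""

    n_intractable_dyads: int = 11
    n_tractable_dyads: int = 12
    intractable_behavior: BehaviorGenParams = field(default_factory=BehaviorGenParams)
    tractable_behavior: BehaviorGenParams = field(default_factory=BehaviorGenParams)
    intractable_emotion: EmotionGenParams = field(default_factory=EmotionGenParams)
    tractable_emotion: EmotionGenParams = field(default_factory=EmotionGenParams)
    missing_person_rate: float = 2.0 / 46.0
    master_seed: int = 0

    def __post_init__(self):
        if self.n_intractable_dyads < 0 or self.n_tractable_dyads < 0:
            raise ParameterError("dyad counts must be >= 0")
        if not 0 <= self.missing_person_rate <= 1:
            raise ParameterError("missing_person_rate must be in [0, 1]")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_stretched_exp_durations(
    b: float,
    tau: float,
    n: int,
    min_dwell: int = 1,
    seed=None,
) -> np.ndarray:
    """Draw ``n`` integer dwell times from density ∝ exp(-(t/tau)^b), t >= min_dwell.

    Inverse-transform sampling: with u = (t/tau)^b the CDF reduces to the
    regularized lower incomplete gamma function P(1/b, u), which scipy inverts
    exactly; continuous draws are rounded up to whole seconds (the coding
    resolution of the data this emulates is 1 s).
    """
    for name, v in (("b", b), ("tau", tau)):
        _check_finite(name, v)
    if not 0 < b <= 1:
        raise ParameterError(f"b must be in (0, 1], got {b}")
    if tau <= 0:
        raise ParameterError(f"tau must be > 0, got {tau}")
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if min_dwell < 1:
        raise ParameterError(f"min_dwell must be >= 1, got {min_dwell}")
    rng = _as_rng(seed)
    k = 1.0 / b
    u0 = gammainc(k, (min_dwell / tau) ** b)
    u = u0 + rng.random(n) * (1.0 - u0)
    t = tau * gammaincinv(k, u) ** k
    return np.ceil(t).astype(np.int64)


def _sample_dwells(params: BehaviorGenParams, n: int, rng: np.random.Generator) -> np.ndarray:
    return sample_stretched_exp_durations(
        params.effective_b, params.timescale_tau, n, params.min_dwell, rng
    )


def generate_behavior_series(params: BehaviorGenParams, seed=None) -> np.ndarray:
    """Generate one person's per-second behavior codes for a session.

    Semi-Markov construction: an initial state drawn uniformly, dwell times
    drawn from the configured family, next state drawn among the other two
    states by ``transition_weights`` (uniform by default); the final run is
    truncated at the session boundary.
    """
    rng = _as_rng(seed)
    length = params.session_length
    out = np.empty(length, dtype=np.int64)
    weights = {}
    for s in STATES:
        others = tuple(o for o in STATES if o != s)
        w = (
            np.asarray(params.transition_weights[s], dtype=float)
            if params.transition_weights is not None
            else np.ones(2)
        )
        weights[s] = (others, w / w.sum())

    state = int(rng.choice(STATES))
    pos = 0
    # draw dwell times in batches to amortize the inverse-gamma evaluation
    batch = max(8, int(2 * length / _expected_dwell(params)))
    while pos < length:
        dwells = _sample_dwells(params, batch, rng)
        for d in dwells:
            end = min(pos + int(d), length)
            out[pos:end] = state
            pos = end
            if pos >= length:
                break
            others, p = weights[state]
            state = int(others[rng.choice(2, p=p)])
    return out


def _expected_dwell(params: BehaviorGenParams) -> float:
    # crude mean of the continuous density, enough to size sampling batches
    from scipy.special import gamma as gamma_fn

    b, tau = params.effective_b, params.timescale_tau
    return max(1.0, tau * gamma_fn(2.0 / b) / gamma_fn(1.0 / b))


def fractional_gaussian_noise(
    hurst: float, n: int, seed=None, sd: float = 1.0
) -> np.ndarray:
    """Exact-covariance fractional Gaussian noise via circulant embedding.

    Davies-Harte synthesis: the circular embedding of the fGn autocovariance
    is diagonalized by the FFT; nonnegative eigenvalues (which hold for fGn)
    give an exact stationary Gaussian sample. Falls back to a Cholesky factor
    of the covariance matrix if an eigenvalue is numerically negative.
    """
    if not 0 < hurst < 1:
        raise ParameterError(f"hurst must be in (0, 1), got {hurst}")
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = _as_rng(seed)
    if hurst == 0.5:
        return sd * rng.standard_normal(n)
    k = np.arange(n)
    acov = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    if n == 1:
        return sd * rng.standard_normal(1)
    row = np.concatenate([acov, acov[-2:0:-1]])
    m = len(row)
    lam = np.fft.fft(row).real
    if lam.min() < -1e-10 * lam.max():
        cov = acov[np.abs(k[:, None] - k[None, :])]
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
        return sd * chol @ rng.standard_normal(n)
    lam = np.clip(lam, 0.0, None)
    half = m // 2
    w = np.empty(m, dtype=complex)
    w[0] = rng.standard_normal()
    w[half] = rng.standard_normal()
    re = rng.standard_normal(half - 1)
    im = rng.standard_normal(half - 1)
    w[1:half] = (re + 1j * im) / np.sqrt(2.0)
    w[half + 1:] = np.conj(w[1:half][::-1])
    x = np.fft.fft(np.sqrt(lam) * w) / np.sqrt(m)
    return sd * x.real[:n]


def generate_emotion_series(params: EmotionGenParams, seed=None) -> np.ndarray:
    """Generate one person's per-second emotion pixels.

    A bounded random walk: Gaussian (or fGn, for hurst_target != 0.5)
    increments accumulated from ``start_value`` with saturating clipping at
    the screen edges (the mouse cannot move past the edge), rounded to the
    integer pixel grid at the end.
    """
    rng = _as_rng(seed)
    n = params.session_length
    if params.hurst_target == 0.5:
        inc = params.increment_sd * rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    else:
        inc = fractional_gaussian_noise(
            params.hurst_target, max(n - 1, 1), rng, sd=params.increment_sd
        )[: n - 1]
    lo, hi = params.bounds
    x = np.empty(n, dtype=float)
    x[0] = params.start_value
    cur = params.start_value
    for i, step in enumerate(inc, start=1):
        cur = min(hi, max(lo, cur + step))
        x[i] = cur
    return np.clip(np.rint(x), np.ceil(lo), np.floor(hi)).astype(np.int64)


def person_seed(master_seed: int, dyad_index: int, person: int, stream: int) -> np.random.Generator:
    """Deterministic per-person, per-stream generator.

    Keyed by (master_seed, dyad_index, person, stream) so adding dyads to a
    config never perturbs the streams of existing ones. Stream ids:
    0 = missingness, 1 = behavior, 2 = emotion.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(dyad_index), int(person), int(stream)])
    )


def generate_study(config: StudyGenConfig, seed: int | None = None) -> StudyTable:
    """Assemble a full synthetic study: one SessionRecord per present person.

    ``seed`` overrides ``config.master_seed`` when given. Persons are dropped
    independently with ``missing_person_rate``.
    """
    master = config.master_seed if seed is None else int(seed)
    records: list[SessionRecord] = []
    groups = [
        ("intractable", "i", config.n_intractable_dyads,
         config.intractable_behavior, config.intractable_emotion, 0),
        ("tractable", "t", config.n_tractable_dyads,
         config.tractable_behavior, config.tractable_emotion, 1000),
    ]
    for group, prefix, n_dyads, bparams, eparams, offset in groups:
        for d in range(n_dyads):
            dyad_id = f"{prefix}{d + 1:02d}"
            for person in (1, 2):
                miss_rng = person_seed(master, offset + d, person, 0)
                if miss_rng.random() < config.missing_person_rate:
                    continue
                behavior = generate_behavior_series(
                    bparams, person_seed(master, offset + d, person, 1)
                )
                emotion = generate_emotion_series(
                    eparams, person_seed(master, offset + d, person, 2)
                )
                records.append(
                    SessionRecord(
                        dyad_id=dyad_id,
                        person=person,
                        group=group,
                        behavior=behavior,
                        emotion=emotion,
                    )
                )
    return StudyTable(
        records=records,
        provenance=f"conflictdyn synthetic study, master_seed={master}",
    )

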