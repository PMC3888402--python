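"""Dwell-time analysis of behavior-state series.

The pipeline here is: run-length extraction of the seconds spent in each
behavior state, pooling across persons (per state and across all three
states), multi-bin-size probability-density estimation, least-squares fitting
of three candidate densities on log-log axes, and the effective kinetic rate
constant k(t) = PDF(t)/S(t) implied by the fitted form.

The three candidate forms:

    single exponential     f(t) = A exp(-a t)        constant hazard (Markov)
    power law              f(t) = A t^(-alpha)       scale-free
    stretched exponential  f(t) = A exp(-(a t)^b)    hazard falls with time in
                                                     state when b < 1 ("memory")

Fits minimize weighted squared error in log density with weights sqrt(count):
the variance of the log of a histogram count is approximately 1/count, so
this is the standard weighting for least squares on logged Poisson counts.
R^2 is the weighted coefficient of determination about the weighted mean log
density. Because the single exponential is the b = 1 slice of the stretched
form and the stretched optimizer is seeded with the single-exponential
solution, the stretched R^2 can never fall below the single-exponential R^2
by more than solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import least_squares

from .errors import (
    DegenerateInputError,
    FitFailureError,
    InsufficientDataError,
    ParameterError,
)

BEHAVIOR_STATES = ("1", "2", "3")
POOLED_LABEL = "123"

FORMS = ("single_exponential", "power_law", "stretched_exponential")
_N_PARAMS = {"single_exponential": 2, "power_law": 2, "stretched_exponential": 3}


@dataclass
class DurationSet:
    """Dwell durations (whole seconds, >= 1) for one state label."""

    state_label: str
    durations: np.ndarray

    def __post_init__(self):
        self.durations = np.asarray(self.durations, dtype=np.int64)
        if len(self.durations) and self.durations.min() < 1:
            raise ParameterError("durations must be >= 1 second")

    @property
    def n_total(self) -> int:
        return len(self.durations)


@dataclass
class PdfEstimate:
    """Multi-bin-size density points: (t = bin left edge, density, width, count)."""

    t: np.ndarray
    density: np.ndarray
    bin_width: np.ndarray
    count: np.ndarray
    n_total: int
    cumulative: np.ndarray | None = None  # rows (t, P(value > t))

    def restrict(self, t_min: float = -np.inf, t_max: float = np.inf) -> "PdfEstimate":
        m = (self.t >= t_min) & (self.t <= t_max)
        return PdfEstimate(self.t[m], self.density[m], self.bin_width[m],
                           self.count[m], self.n_total, self.cumulative)


@dataclass
class ModelFit:
    """A fitted density form; only the parameters of its form are set."""

    form: str
    r_squared: float
    amplitude_A: float
    rate_a: float | None = None        # exponential forms
    exponent_b: float | None = None    # stretched exponential
    exponent_alpha: float | None = None  # power law

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        if self.form == "single_exponential":
            return self.amplitude_A * np.exp(-self.rate_a * t)
        if self.form == "power_law":
            return self.amplitude_A * t ** (-self.exponent_alpha)
        if self.form == "stretched_exponential":
            return self.amplitude_A * np.exp(-((self.rate_a * t) ** self.exponent_b))
        raise ParameterError(f"unknown form {self.form!r}")


@dataclass
class RateCurve:
    """Effective kinetic rate constant k(t) on a time grid."""

    grid: np.ndarray
    rate_k: np.ndarray


def extract_durations(behavior) -> dict[str, DurationSet]:
    """Run-length encode a behavior series into per-state duration sets.

    Every second belongs to exactly one run; first and last (boundary) runs
    are included as complete durations.
    """
    codes = np.asarray(behavior, dtype=np.int64)
    if codes.size == 0:
        raise ParameterError("behavior series is empty")
    if not np.isin(codes, (1, 2, 3)).all():
        bad = codes[~np.isin(codes, (1, 2, 3))][0]
        raise ParameterError(f"invalid behavior code {bad}")
    change = np.nonzero(np.diff(codes))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(codes)]])
    lengths = ends - starts
    states = codes[starts]
    return {
        label: DurationSet(label, lengths[states == int(label)])
        for label in BEHAVIOR_STATES
    }


def pool_durations(sets: list[DurationSet], states: set | None = None) -> DurationSet:
    """Concatenate duration sets; label '123' when all three states are pooled."""
    if not sets:
        raise ParameterError("no duration sets to pool")
    states = {str(s) for s in (states or {s.state_label for s in sets})}
    picked = [s for s in sets if s.state_label in states]
    if not picked:
        raise ParameterError(f"no duration sets match states {sorted(states)}")
    if states == set(BEHAVIOR_STATES):
        label = POOLED_LABEL
    elif len(states) == 1:
        label = next(iter(states))
    else:
        raise ParameterError(
            f"pooling must target one state or all three, got {sorted(states)}"
        )
    durs = (np.concatenate([s.durations for s in picked])
            if picked else np.empty(0, dtype=np.int64))
    return DurationSet(label, durs)


def default_bin_widths(max_duration: int) -> list[int]:
    """Powers of two 1, 2, 4, ... up to the maximum duration."""
    widths = [1]
    while widths[-1] < max_duration:
        widths.append(widths[-1] * 2)
    return widths


def estimate_pdf_multibin(
    durations: DurationSet,
    bin_widths: list[int] | None = None,
    min_count: int = 5,
) -> PdfEstimate:
    """Multi-bin-size PDF estimate.

    For each bin width dt, histogram bins [t, t+dt) are anchored at the
    minimum observed duration and each retained bin (count >= min_count)
    contributes the point (t, count / (n_total * dt)) at its left edge. Where
    two widths produce a point at the same t the smaller width wins, so fine
    resolution survives at small t while wide bins resolve the sparse tail.
    """
    d = durations.durations
    n = durations.n_total
    if n < max(min_count, 1):
        raise InsufficientDataError(
            f"need at least {min_count} durations, have {n}"
        )
    t0 = int(d.min())
    tmax = int(d.max())
    if bin_widths is None:
        bin_widths = default_bin_widths(tmax)
    bin_widths = sorted(int(w) for w in bin_widths)
    if bin_widths[0] < 1 or len(set(bin_widths)) != len(bin_widths):
        raise ParameterError("bin widths must be distinct integers >= 1")

    points: dict[int, tuple[float, int, int]] = {}
    for w in reversed(bin_widths):  # smaller widths processed last: they win
        edges = np.arange(t0, tmax + w + 1, w)
        counts, _ = np.histogram(d, bins=edges)
        for i, c in enumerate(counts):
            if c >= min_count:
                points[int(edges[i])] = (c / (n * w), w, int(c))
    ts = np.array(sorted(points), dtype=np.int64)
    dens = np.array([points[t][0] for t in ts])
    widths = np.array([points[t][1] for t in ts], dtype=np.int64)
    counts = np.array([points[t][2] for t in ts], dtype=np.int64)

    uniq = np.unique(d)
    survival = 1.0 - np.searchsorted(np.sort(d), uniq, side="right") / n
    cumulative = np.column_stack([uniq, survival])
    return PdfEstimate(ts, dens, widths, counts, n, cumulative)


def _weighted_r2(log_y: np.ndarray, pred: np.ndarray, w: np.ndarray) -> float:
    ybar = np.sum(w * log_y) / np.sum(w)
    sse = np.sum(w * (log_y - pred) ** 2)
    sst = np.sum(w * (log_y - ybar) ** 2)
    if sst == 0:
        raise DegenerateInputError("log densities are constant; R^2 undefined")
    return 1.0 - sse / sst


def _linear_fit(x, log_y, w):
    # weighted least squares for log_y = c0 + c1 * x
    W = np.sqrt(w)
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(W[:, None] * A, W * log_y, rcond=None)
    return coef  # (intercept, slope)


def fit_pdf_model(pdf: PdfEstimate, form: str) -> ModelFit:
    """Fit one density form by weighted least squares on log density."""
    if form not in FORMS:
        raise ParameterError(f"unknown form {form!r}; expected one of {FORMS}")
    min_pts = 2 if form == "power_law" else 4
    if len(pdf.t) < min_pts:
        raise InsufficientDataError(
            f"{form} fit needs >= {min_pts} PDF points, have {len(pdf.t)}"
        )
    t = pdf.t.astype(float)
    log_y = np.log(pdf.density)
    w = np.sqrt(pdf.count.astype(float))

    if form == "single_exponential":
        c0, c1 = _linear_fit(t, log_y, w)
        a = max(-c1, 1e-12)
        pred = c0 + c1 * t
        return ModelFit(form, _weighted_r2(log_y, pred, w),
                        amplitude_A=float(np.exp(c0)), rate_a=float(a))

    if form == "power_law":
        if t.min() <= 0:
            raise ParameterError("power-law fit requires t > 0")
        c0, c1 = _linear_fit(np.log(t), log_y, w)
        pred = c0 + c1 * np.log(t)
        return ModelFit(form, _weighted_r2(log_y, pred, w),
                        amplitude_A=float(np.exp(c0)), exponent_alpha=float(-c1))

    # stretched exponential: multi-start nonlinear weighted least squares
    sw = np.sqrt(w)

    def resid(p):
        log_a, b, log_A = p
        return sw * (log_A - (np.exp(log_a) * t) ** b - log_y)

    def jac(p):
        log_a, b, log_A = p
        at = np.exp(log_a) * t
        atb = at ** b
        return np.column_stack([-sw * b * atb, -sw * atb * np.log(at), sw])

    starts = []
    # the single-exponential solution seeds b = 1 so nesting is preserved
    c0, c1 = _linear_fit(t, log_y, w)
    a1 = max(-c1, 1e-9)
    starts.append((np.log(a1), 1.0, c0))
    for b0 in (0.15, 0.3, 0.5, 0.8):
        for a0 in (a1, 0.2):
            starts.append((np.log(max(a0, 1e-9)), b0, log_y.max()))

    best = None
    failures = []
    for p0 in starts:
        try:
            res = least_squares(
                resid, p0, jac=jac,
                bounds=([-30.0, 0.02, -50.0], [5.0, 1.5, 50.0]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailureError("stretched-exponential fit failed from all starts",
                              {"failures": failures})
    log_a, b, log_A = best.x
    pred = log_A - (np.exp(log_a) * t) ** b
    return ModelFit("stretched_exponential", _weighted_r2(log_y, pred, w),
                    amplitude_A=float(np.exp(log_A)), rate_a=float(np.exp(log_a)),
                    exponent_b=float(b))


def compare_fits(pdf: PdfEstimate) -> list[ModelFit]:
    """Fit all three forms and rank by descending R^2, ties to fewer parameters."""
    fits = []
    errors = {}
    for form in FORMS:
        try:
            fits.append(fit_pdf_model(pdf, form))
        except (InsufficientDataError, FitFailureError, ParameterError) as exc:
            errors[form] = exc
    if len(fits) < 2:
        raise FitFailureError("fewer than two forms could be fitted",
                              {k: str(v) for k, v in errors.items()})
    fits.sort(key=lambda f: (-f.r_squared, _N_PARAMS[f.form], f.form))
    return fits


def effective_rate_constant(fit: ModelFit, grid) -> RateCurve:
    """Effective kinetic rate k(t) = PDF(t) / S(t), S(t) = integral_t^inf PDF.

    The survival integral of the fitted form is evaluated by adaptive
    quadrature. For the single exponential k(t) is the constant rate a; for a
    stretched exponential with b < 1 it decreases with the time already spent
    in the state.
    """
    if fit.form not in ("single_exponential", "stretched_exponential"):
        raise ParameterError(f"rate curve undefined for form {fit.form!r}")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or grid.min() <= 0:
        raise ParameterError("grid must be positive times")
    if np.any(np.diff(grid) <= 0):
        raise ParameterError("grid must be strictly increasing")
    rates = np.empty_like(grid)
    for i, t in enumerate(grid):
        surv, _ = quad(fit.pdf, t, np.inf, limit=200)
        if surv <= 0:
            raise ParameterError(f"survival vanished at t={t}; grid outside support")
        rates[i] = fit.pdf(t) / surv
    return RateCurve(grid, rates)
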