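"""Models of where foragers pick their first target.

First selections in this paradigm are bimodal across people: most start in
the top-left corner of the display, a smaller group starts near the centre.
Two models capture this:

* a per-participant model — independent beta distributions for the x and y
  coordinates of each participant's first selections (4 parameters per
  participant);
* a shared two-component beta mixture — one corner component and one
  diffuse central component common to everyone, with a single per-participant
  mixing weight ``lambda`` on the corner component (8 + P parameters).

Both are fitted by maximum likelihood (the mixture by EM).  Responsibilities
are computed per trial with one shared component indicator for x and y
jointly; a joint indicator is what makes ``lambda`` identifiable from
bivariate first-selection locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import betaln, digamma, logsumexp

from .core import Display
from .exceptions import (
    DegenerateComponentError,
    InsufficientDataError,
    InvalidArgumentError,
    NotFittedError,
)

__all__ = [
    "BetaShape",
    "ParticipantBetaModel",
    "MixtureModel",
    "beta_log_density",
    "clamp_unit",
    "fit_participant_betas",
    "fit_mixture_em",
    "count_free_parameters",
    "initial_item_weights",
]

#: coordinates are clamped into [EPS, 1-EPS] before beta fitting/evaluation
EPS = 1e-6


@dataclass(frozen=True)
class BetaShape:
    """Shape parameters (alpha, beta) of a beta distribution."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (
            np.isfinite(self.alpha)
            and np.isfinite(self.beta)
            and self.alpha > 0
            and self.beta > 0
        ):
            raise InvalidArgumentError("beta shapes must be finite and positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def to_dict(self) -> dict[str, float]:
        return {"alpha": float(self.alpha), "beta": float(self.beta)}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "BetaShape":
        return cls(float(d["alpha"]), float(d["beta"]))


def clamp_unit(values: np.ndarray, eps: float = EPS) -> np.ndarray:
    """Clamp coordinates into the open unit interval [eps, 1-eps]."""
    return np.clip(np.asarray(values, dtype=float), eps, 1.0 - eps)


def beta_log_density(value: float, shape: BetaShape) -> float:
    """Log density of Beta(alpha, beta) at ``value`` in (0, 1)."""
    value = np.asarray(value, dtype=float)
    if np.any(value <= 0.0) or np.any(value >= 1.0):
        raise InvalidArgumentError("value must lie strictly inside (0, 1)")
    out = stats.beta.logpdf(value, shape.alpha, shape.beta)
    return float(out) if np.isscalar(value) or value.ndim == 0 else out


@dataclass
class ParticipantBetaModel:
    """Independent beta shapes for x and y per participant."""

    x_shapes: dict[str, BetaShape]
    y_shapes: dict[str, BetaShape]
    log_likelihood: float = float("nan")

    @property
    def participants(self) -> tuple[str, ...]:
        return tuple(self.x_shapes)

    def to_dict(self) -> dict:
        return {
            "model": "participant_betas",
            "participants": {
                p: {"x": self.x_shapes[p].to_dict(), "y": self.y_shapes[p].to_dict()}
                for p in self.x_shapes
            },
            "log_likelihood": float(self.log_likelihood),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParticipantBetaModel":
        parts = d["participants"]
        return cls(
            x_shapes={p: BetaShape.from_dict(v["x"]) for p, v in parts.items()},
            y_shapes={p: BetaShape.from_dict(v["y"]) for p, v in parts.items()},
            log_likelihood=float(d.get("log_likelihood", float("nan"))),
        )


@dataclass
class MixtureModel:
    """Two shared beta components with a per-participant corner weight.

    ``component_1`` is the corner component (smaller mean x by convention),
    ``component_2`` the diffuse central one.  ``lam[p]`` is participant
    ``p``'s mixing weight on the corner component.
    """

    comp1_x: BetaShape
    comp1_y: BetaShape
    comp2_x: BetaShape
    comp2_y: BetaShape
    lam: dict[str, float]
    log_likelihood: float = float("nan")
    n_iterations: int = 0
    converged: bool = True
    #: indices (1 and/or 2) of components holding < 0.5% of responsibility mass
    degenerate_components: tuple[int, ...] = ()
    #: observed-data log-likelihood trace of the winning EM run
    ll_trace: list[float] = field(default_factory=list)
    #: traces of every restart, for monotonicity diagnostics
    all_traces: list[list[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for p, v in self.lam.items():
            if not (0.0 <= v <= 1.0):
                raise InvalidArgumentError(f"lambda[{p}]={v} outside [0, 1]")

    @property
    def participants(self) -> tuple[str, ...]:
        return tuple(self.lam)

    def to_dict(self) -> dict:
        return {
            "model": "mixture",
            "components": {
                "corner": {"x": self.comp1_x.to_dict(), "y": self.comp1_y.to_dict()},
                "centre": {"x": self.comp2_x.to_dict(), "y": self.comp2_y.to_dict()},
            },
            "lambda": {p: float(v) for p, v in self.lam.items()},
            "log_likelihood": float(self.log_likelihood),
            "n_iterations": int(self.n_iterations),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MixtureModel":
        comps = d["components"]
        return cls(
            comp1_x=BetaShape.from_dict(comps["corner"]["x"]),
            comp1_y=BetaShape.from_dict(comps["corner"]["y"]),
            comp2_x=BetaShape.from_dict(comps["centre"]["x"]),
            comp2_y=BetaShape.from_dict(comps["centre"]["y"]),
            lam={p: float(v) for p, v in d["lambda"].items()},
            log_likelihood=float(d.get("log_likelihood", float("nan"))),
            n_iterations=int(d.get("n_iterations", 0)),
            converged=bool(d.get("converged", True)),
        )


def _as_xy(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidArgumentError("first selections must be an (n, 2) array of (x, y)")
    return arr


def fit_participant_betas(
    first_selections: Mapping[str, Sequence],
) -> ParticipantBetaModel:
    """Fit independent beta shapes to each participant's first-selection x and y.

    Maximum likelihood per participant and axis (via ``scipy.stats.beta.fit``
    with the support fixed to [0, 1]).  Coordinates are clamped into the
    open unit interval first.
    """
    x_shapes: dict[str, BetaShape] = {}
    y_shapes: dict[str, BetaShape] = {}
    total_ll = 0.0
    for participant, values in first_selections.items():
        xy = _as_xy(values)
        if xy.shape[0] < 2:
            raise InsufficientDataError(
                f"participant {participant!r} has {xy.shape[0]} first selections (need >= 2)"
            )
        for axis, store in ((0, x_shapes), (1, y_shapes)):
            v = clamp_unit(xy[:, axis])
            if np.ptp(v) < 1e-12:
                raise InsufficientDataError(
                    f"participant {participant!r}: axis {'xy'[axis]} is degenerate "
                    "(all first selections identical after clamping)"
                )
            a, b, _, _ = stats.beta.fit(v, floc=0.0, fscale=1.0)
            store[participant] = BetaShape(float(a), float(b))
            total_ll += float(stats.beta.logpdf(v, a, b).sum())
    return ParticipantBetaModel(x_shapes, y_shapes, log_likelihood=total_ll)


def weighted_beta_mle(
    values: np.ndarray,
    weights: np.ndarray,
    start: BetaShape | None = None,
) -> BetaShape:
    """Weighted maximum-likelihood beta shapes.

    Maximizes sum_i w_i * log Beta(v_i; a, b) over a, b > 0, in log-shape
    coordinates with analytic gradient.  Used by the EM M-step, where
    scipy's unweighted fitter does not apply.
    """
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total < 1e-8:
        raise DegenerateComponentError("component has (almost) no responsibility mass")
    v = clamp_unit(values)
    s1 = float(np.sum(w * np.log(v)) / total)
    s2 = float(np.sum(w * np.log1p(-v)) / total)

    def neg(logab):
        a, b = np.exp(logab)
        val = -((a - 1.0) * s1 + (b - 1.0) * s2 - betaln(a, b))
        dab = digamma(a + b)
        ga = -(s1 - digamma(a) + dab) * a
        gb = -(s2 - digamma(b) + dab) * b
        return val, np.array([ga, gb])

    if start is None:
        # method-of-moments start
        mean = float(np.sum(w * v) / total)
        var = float(np.sum(w * (v - mean) ** 2) / total)
        var = max(var, 1e-6)
        common = max(mean * (1.0 - mean) / var - 1.0, 1e-3)
        x0 = np.log([max(mean * common, 1e-3), max((1.0 - mean) * common, 1e-3)])
    else:
        x0 = np.log([start.alpha, start.beta])
    res = optimize.minimize(neg, x0, jac=True, method="L-BFGS-B")
    a, b = np.exp(res.x)
    return BetaShape(float(a), float(b))


def _mixture_ll_parts(x, y, lam_per_obs, shapes):
    c1x, c1y, c2x, c2y = shapes
    l1 = (
        np.log(lam_per_obs)
        + stats.beta.logpdf(x, c1x.alpha, c1x.beta)
        + stats.beta.logpdf(y, c1y.alpha, c1y.beta)
    )
    l2 = (
        np.log1p(-lam_per_obs)
        + stats.beta.logpdf(x, c2x.alpha, c2x.beta)
        + stats.beta.logpdf(y, c2y.alpha, c2y.beta)
    )
    return l1, l2


def mixture_log_likelihood(
    first_selections: Mapping[str, Sequence], model: MixtureModel
) -> float:
    """Observed-data log-likelihood of first selections under a mixture model."""
    total = 0.0
    shapes = (model.comp1_x, model.comp1_y, model.comp2_x, model.comp2_y)
    for participant, values in first_selections.items():
        xy = _as_xy(values)
        x = clamp_unit(xy[:, 0])
        y = clamp_unit(xy[:, 1])
        lam = np.clip(model.lam[participant], 1e-12, 1.0 - 1e-12)
        l1, l2 = _mixture_ll_parts(x, y, np.full(x.size, lam), shapes)
        total += float(np.logaddexp(l1, l2).sum())
    return total


def fit_mixture_em(
    first_selections: Mapping[str, Sequence],
    n_starts: int = 3,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureModel:
    """Fit the shared two-component beta mixture with per-participant lambda by EM.

    E-step: per-trial responsibility of the corner component under the joint
    (x, y) product density.  M-step: lambda[p] is the mean responsibility of
    participant p's trials; the four shared shape pairs are updated by
    weighted beta MLE warm-started at the current shapes (a generalized EM,
    so the observed-data log-likelihood never decreases).  The best of
    ``n_starts`` seeded restarts is returned, with components ordered so
    component 1 has the smaller mean x (the corner mode).
    """
    participants = list(first_selections)
    if len(participants) < 2:
        raise InsufficientDataError("mixture fitting needs >= 2 participants")
    rng = np.random.default_rng(seed)

    xs, ys, pidx = [], [], []
    for k, p in enumerate(participants):
        xy = _as_xy(first_selections[p])
        if xy.shape[0] < 1:
            raise InsufficientDataError(f"participant {p!r} has no first selections")
        xs.append(clamp_unit(xy[:, 0]))
        ys.append(clamp_unit(xy[:, 1]))
        pidx.append(np.full(xy.shape[0], k))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    pidx = np.concatenate(pidx)
    n_p = len(participants)
    counts = np.bincount(pidx, minlength=n_p).astype(float)

    best: MixtureModel | None = None
    all_traces: list[list[float]] = []
    for _ in range(max(1, n_starts)):
        # corner-fraction heuristic for lambda, jittered across restarts
        corner = (x + y < 1.0).astype(float)
        lam = np.bincount(pidx, corner, minlength=n_p) / counts
        lam = np.clip(lam + rng.uniform(-0.2, 0.2, size=n_p), 0.05, 0.95)
        split = x + y < np.median(x + y)
        shapes = [
            weighted_beta_mle(x, split.astype(float)),
            weighted_beta_mle(y, split.astype(float)),
            weighted_beta_mle(x, (~split).astype(float)),
            weighted_beta_mle(y, (~split).astype(float)),
        ]

        trace: list[float] = []
        converged = False
        r = np.full(x.size, 0.5)
        for _it in range(max_iter):
            lam_obs = np.clip(lam[pidx], 1e-12, 1.0 - 1e-12)
            l1, l2 = _mixture_ll_parts(x, y, lam_obs, shapes)
            ll = float(np.logaddexp(l1, l2).sum())
            trace.append(ll)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
                converged = True
                break
            r = np.exp(l1 - np.logaddexp(l1, l2))
            lam = np.bincount(pidx, r, minlength=n_p) / counts
            new_shapes = [
                weighted_beta_mle(x, r, start=shapes[0]),
                weighted_beta_mle(y, r, start=shapes[1]),
                weighted_beta_mle(x, 1.0 - r, start=shapes[2]),
                weighted_beta_mle(y, 1.0 - r, start=shapes[3]),
            ]
            shapes = new_shapes
        all_traces.append(trace)

        total_r = float(r.sum())
        shares = (total_r / x.size, 1.0 - total_r / x.size)
        degenerate = tuple(k + 1 for k, s in enumerate(shares) if s < 0.005)
        if not degenerate:
            # if a single shared component explains the data as well (by BIC),
            # the minority component is redundant: flag it degenerate
            ones = np.ones(x.size)
            sx, sy = weighted_beta_mle(x, ones), weighted_beta_mle(y, ones)
            single_ll = float(
                stats.beta.logpdf(x, sx.alpha, sx.beta).sum()
                + stats.beta.logpdf(y, sy.alpha, sy.beta).sum()
            )
            extra_params = (8 + n_p) - 4
            if 2.0 * (trace[-1] - single_ll) < extra_params * np.log(x.size):
                degenerate = (1 if shares[0] < shares[1] else 2,)

        lam_dict = {p: float(np.clip(v, 0.0, 1.0)) for p, v in zip(participants, lam)}
        model = MixtureModel(
            comp1_x=shapes[0],
            comp1_y=shapes[1],
            comp2_x=shapes[2],
            comp2_y=shapes[3],
            lam=lam_dict,
            log_likelihood=trace[-1],
            n_iterations=len(trace),
            converged=converged,
            degenerate_components=degenerate,
            ll_trace=trace,
        )
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model

    assert best is not None
    # ordering convention: component 1 is the corner mode (smaller mean x)
    if best.comp1_x.mean > best.comp2_x.mean:
        best = MixtureModel(
            comp1_x=best.comp2_x,
            comp1_y=best.comp2_y,
            comp2_x=best.comp1_x,
            comp2_y=best.comp1_y,
            lam={p: 1.0 - v for p, v in best.lam.items()},
            log_likelihood=best.log_likelihood,
            n_iterations=best.n_iterations,
            converged=best.converged,
            degenerate_components=tuple(3 - k for k in best.degenerate_components),
            ll_trace=best.ll_trace,
        )
    best.all_traces = all_traces
    if not best.converged:
        import warnings

        warnings.warn(
            f"EM did not converge within {max_iter} iterations "
            f"(last change {best.ll_trace[-1] - best.ll_trace[-2]:.3g}); "
            "returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return best


def count_free_parameters(
    model: ParticipantBetaModel | MixtureModel, n_participants: int
) -> int:
    """Number of free parameters of an initial-selection model.

    The mixture needs 8 shared shape parameters plus one lambda per
    participant; the per-participant model needs 4 shapes per participant.
    """
    if n_participants < 1:
        raise InvalidArgumentError("n_participants must be >= 1")
    if isinstance(model, MixtureModel):
        return 8 + n_participants
    if isinstance(model, ParticipantBetaModel):
        return 4 * n_participants
    raise InvalidArgumentError(f"unknown model type {type(model).__name__}")


def initial_item_weights(
    display: Display,
    model: ParticipantBetaModel | MixtureModel,
    participant: str,
) -> dict[int, float]:
    """Probability of each display item being selected first, for one participant.

    Each item's weight is the fitted density of its (x, y) position —
    the product of the x and y densities, lambda-mixed across components
    for the mixture model — normalized over the display.
    """
    ids = np.array(sorted(display.item_ids))
    idx = np.array([display.index(i) for i in ids])
    x = clamp_unit(display.positions[idx, 0])
    y = clamp_unit(display.positions[idx, 1])
    if isinstance(model, ParticipantBetaModel):
        if participant not in model.x_shapes:
            raise NotFittedError(f"no fitted shapes for participant {participant!r}")
        sx, sy = model.x_shapes[participant], model.y_shapes[participant]
        logd = stats.beta.logpdf(x, sx.alpha, sx.beta) + stats.beta.logpdf(
            y, sy.alpha, sy.beta
        )
    elif isinstance(model, MixtureModel):
        if participant not in model.lam:
            raise NotFittedError(f"no fitted lambda for participant {participant!r}")
        lam = np.clip(model.lam[participant], 1e-12, 1.0 - 1e-12)
        l1 = (
            np.log(lam)
            + stats.beta.logpdf(x, model.comp1_x.alpha, model.comp1_x.beta)
            + stats.beta.logpdf(y, model.comp1_y.alpha, model.comp1_y.beta)
        )
        l2 = (
            np.log1p(-lam)
            + stats.beta.logpdf(x, model.comp2_x.alpha, model.comp2_x.beta)
            + stats.beta.logpdf(y, model.comp2_y.alpha, model.comp2_y.beta)
        )
        logd = np.logaddexp(l1, l2)
    else:
        raise NotFittedError(f"unsupported model type {type(model).__name__}")
    logd = logd - logsumexp(logd)
    p = np.exp(logd)
    p /= p.sum()
    return {int(i): float(v) for i, v in zip(ids, p)}
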