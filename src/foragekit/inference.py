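"""Likelihood-based estimation of the foraging biases.

Each participant's four biases are estimated by maximizing the summed
sequence log-likelihood over their trials with a multi-start quasi-Newton
optimizer (analytic gradient).  Standard errors come from the observed
information (finite-difference Hessian of the negative log-likelihood at
the optimum).  ``fit_population`` optionally applies two-stage
empirical-Bayes shrinkage of the per-participant estimates toward the
population mean, weighting by estimate precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .core import (
    PARAM_NAMES,
    Display,
    ForagingParams,
    SelectionSequence,
    SequenceCache,
)
from .exceptions import InsufficientDataError, InvalidArgumentError, NonConvergenceError
from .io import ForagingDataset, Trial

__all__ = [
    "FitResult",
    "fit_foraging_params",
    "fit_population",
    "train_test_split",
]


@dataclass
class FitResult:
    """A fitted set of foraging biases with uncertainty."""

    params: ForagingParams
    standard_errors: dict[str, float]
    log_likelihood: float
    converged: bool
    n_selections: int

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "standard_errors": {k: float(v) for k, v in self.standard_errors.items()},
            "log_likelihood": float(self.log_likelihood),
            "converged": bool(self.converged),
            "n_selections": int(self.n_selections),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitResult":
        return cls(
            params=ForagingParams.from_dict(d["params"]),
            standard_errors=dict(d["standard_errors"]),
            log_likelihood=float(d["log_likelihood"]),
            converged=bool(d["converged"]),
            n_selections=int(d["n_selections"]),
        )


def _hessian(grad_fn, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    n = x.size
    H = np.zeros((n, n))
    for i in range(n):
        step = h * (1.0 + abs(x[i]))
        e = np.zeros(n)
        e[i] = step
        H[:, i] = (grad_fn(x + e) - grad_fn(x - e)) / (2.0 * step)
    return 0.5 * (H + H.T)


def fit_foraging_params(
    trials: Sequence[tuple[Display, SelectionSequence]],
    include_first: bool = False,
    seed: int | np.random.Generator = 0,
    n_starts: int = 5,
    gtol: float = 1e-8,
) -> FitResult:
    """Maximum-likelihood foraging biases for one set of trials.

    By default the first selection of each trial is not scored (the core
    model says little about it); pass ``include_first=True`` to score it
    with the class-salience factor.
    """
    caches = [
        SequenceCache.build(d, s, include_first=include_first) for d, s in trials
    ]
    cache = SequenceCache.concat(caches)
    if cache.n_segments == 0:
        raise InsufficientDataError(
            "no scorable selections (every trial has < 2 selections)"
        )

    def objective(x):
        ll, grad = cache.log_likelihood_grad(x)
        return -ll, -grad

    rng = np.random.default_rng(seed)
    starts = [np.zeros(4)] + [rng.normal(0.0, 1.0, 4) for _ in range(n_starts - 1)]
    best = None
    for x0 in starts:
        try:
            res = optimize.minimize(
                objective,
                x0,
                jac=True,
                method="BFGS",
                options={"gtol": gtol, "maxiter": 1000},
            )
        except (ValueError, FloatingPointError):  # pragma: no cover - defensive
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise NonConvergenceError("optimizer failed on every start")

    grad_fn = lambda x: objective(x)[1]
    H = _hessian(grad_fn, best.x)
    se = np.full(4, np.nan)
    converged = bool(best.success) or float(np.linalg.norm(best.jac)) < 1e-4
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.all(diag > 0):
            se = np.sqrt(diag)
        else:
            converged = False
    except np.linalg.LinAlgError:
        converged = False

    return FitResult(
        params=ForagingParams.from_array(best.x),
        standard_errors=dict(zip(PARAM_NAMES, (float(v) for v in se))),
        log_likelihood=float(-best.fun),
        converged=converged,
        n_selections=int(cache.n_segments),
    )


def shrink_estimates(
    estimates: np.ndarray, standard_errors: np.ndarray
) -> np.ndarray:
    """Empirical-Bayes shrinkage of noisy per-unit estimates toward their mean.

    For each column: the between-unit variance tau^2 is estimated by the
    method of moments (sample variance of the estimates minus the mean
    squared SE, floored at 0); each estimate is then pulled toward the
    population mean with reliability weight tau^2 / (tau^2 + SE^2).
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(standard_errors, dtype=float)
    out = est.copy()
    for j in range(est.shape[1]):
        mu = est[:, j].mean()
        tau2 = max(np.var(est[:, j], ddof=1) - np.mean(se[:, j] ** 2), 0.0)
        w = tau2 / (tau2 + se[:, j] ** 2)
        out[:, j] = w * est[:, j] + (1.0 - w) * mu
    return out


def fit_population(
    dataset: ForagingDataset | Mapping[str, Sequence[tuple[Display, SelectionSequence]]],
    pooling: str = "none",
    include_first: bool = False,
    seed: int = 0,
    n_starts: int = 5,
) -> dict[str, FitResult]:
    """Fit every participant, optionally shrinking estimates toward the mean.

    ``pooling="none"`` gives independent per-participant fits;
    ``pooling="shrinkage"`` applies :func:`shrink_estimates` to the four
    biases (standard errors are left at their per-participant values).
    """
    if pooling not in ("none", "shrinkage"):
        raise InvalidArgumentError(f"unknown pooling {pooling!r}")
    if isinstance(dataset, ForagingDataset):
        grouped = dataset.pairs_by_participant()
    else:
        grouped = dict(dataset)
    if not grouped:
        raise InsufficientDataError("no participants in dataset")

    seeds = np.random.SeedSequence(seed).spawn(len(grouped))
    results: dict[str, FitResult] = {}
    for ss, (participant, trials) in zip(seeds, grouped.items()):
        try:
            results[participant] = fit_foraging_params(
                trials,
                include_first=include_first,
                seed=np.random.default_rng(ss),
                n_starts=n_starts,
            )
        except (InsufficientDataError, NonConvergenceError) as err:
            raise type(err)(f"participant {participant!r}: {err}") from err

    if pooling == "shrinkage" and len(results) > 1:
        participants = list(results)
        est = np.array([results[p].params.as_array() for p in participants])
        se = np.array(
            [
                [results[p].standard_errors[n] for n in PARAM_NAMES]
                for p in participants
            ]
        )
        shrunk = shrink_estimates(est, se)
        for k, p in enumerate(participants):
            r = results[p]
            results[p] = FitResult(
                params=ForagingParams.from_array(shrunk[k]),
                standard_errors=r.standard_errors,
                log_likelihood=r.log_likelihood,
                converged=r.converged,
                n_selections=r.n_selections,
            )
    return results


def train_test_split(
    dataset: ForagingDataset,
    fraction: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[ForagingDataset, ForagingDataset]:
    """Randomly split whole trials into train/test per participant and condition.

    The split is stratified by (participant, condition) so each group
    contributes ``round(fraction * n)`` training trials; it is disjoint,
    exhaustive and reproducible under the seed.
    """
    if not (0.0 < fraction < 1.0):
        raise InvalidArgumentError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, str], list[Trial]] = {}
    for t in dataset.trials:
        groups.setdefault((t.participant, t.condition), []).append(t)
    train: list[Trial] = []
    test: list[Trial] = []
    for (participant, condition), trials in groups.items():
        n = len(trials)
        if n < 2:
            raise InsufficientDataError(
                f"participant {participant!r} condition {condition!r} has {n} trial(s); "
                "need >= 2 to split"
            )
        n_train = min(max(int(round(fraction * n)), 1), n - 1)
        perm = rng.permutation(n)
        chosen = set(perm[:n_train].tolist())
        for k, trial in enumerate(trials):
            (train if k in chosen else test).append(trial)
    return ForagingDataset(train), ForagingDataset(test)
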