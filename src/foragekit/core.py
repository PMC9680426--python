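"""Core domain types and the sampling-without-replacement selection model.

Foraging is treated as sequential sampling without replacement from the set
of remaining targets.  Each remaining item ``i`` receives a weight

    w_i = g(b_class * t_i + b_stick * m_i) * exp(-sigma_d * d_i)
                                           * exp(-sigma_theta * theta_i)

where ``t_i`` indicates class A, ``m_i`` indicates the same class as the
previously selected item, ``d_i`` is the Euclidean distance from the last
selection, ``theta_i`` is the normalized angular deviation from the previous
direction of travel, and ``g`` is the logistic function.  Selection
probabilities are the weights renormalized over the remaining items.

The first selection carries no selection history, so it is scored with the
class-salience factor g(b_class * t_i) alone; on the second selection no
direction of travel exists yet, so the direction factor is fixed to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from scipy.special import expit, log_expit

from .exceptions import (
    DegenerateGeometryError,
    EmptyChoiceSetError,
    InvalidArgumentError,
    SequenceMismatchError,
)

__all__ = [
    "CLASS_A",
    "CLASS_B",
    "Item",
    "Display",
    "SelectionSequence",
    "ForagingParams",
    "TrialState",
    "SequenceCache",
    "angular_difference",
    "direction_cost",
    "proximity_kernel",
    "direction_kernel",
    "class_stick_weight",
    "selection_weights",
    "selection_log_weights",
    "selection_probabilities",
    "sequence_log_likelihood",
]

CLASS_A = "A"
CLASS_B = "B"

#: minimum pairwise spacing between items; keeps direction_cost defined
MIN_ITEM_SPACING = 1e-6

PARAM_NAMES = ("b_class", "b_stick", "sigma_d", "sigma_theta")

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class Item:
    """A selectable target with a normalized position and a binary class."""

    item_id: int
    x: float
    y: float
    item_class: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise InvalidArgumentError("item position must be finite")
        if not (0.0 <= self.x <= 1.0 and 0.0 <= self.y <= 1.0):
            raise InvalidArgumentError(
                f"item {self.item_id} position ({self.x}, {self.y}) outside unit square"
            )
        if self.item_class not in (CLASS_A, CLASS_B):
            raise InvalidArgumentError(
                f"item_class must be {CLASS_A!r} or {CLASS_B!r}, got {self.item_class!r}"
            )

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


class Display:
    """An immutable choice set of items inside the unit square.

    Coordinates follow screen convention: origin at the top-left, ``y``
    increasing downward, so the corner bias of first selections sits near
    (0, 0).
    """

    def __init__(self, items: Iterable[Item]):
        items = tuple(items)
        if len(items) < 2:
            raise InvalidArgumentError("a display needs at least 2 items")
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            raise InvalidArgumentError("item ids must be distinct")
        self.items: tuple[Item, ...] = items
        self._index: dict[int, int] = {it.item_id: k for k, it in enumerate(items)}
        self.positions: np.ndarray = np.array([[it.x, it.y] for it in items])
        self.is_class_a: np.ndarray = np.array(
            [it.item_class == CLASS_A for it in items]
        )
        if len(items) > 1 and pdist(self.positions).min() < MIN_ITEM_SPACING:
            raise DegenerateGeometryError(
                f"items closer than the minimum spacing {MIN_ITEM_SPACING}"
            )

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> tuple[int, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def n_per_class(self) -> dict[str, int]:
        n_a = int(self.is_class_a.sum())
        return {CLASS_A: n_a, CLASS_B: self.n_items - n_a}

    def index(self, item_id: int) -> int:
        try:
            return self._index[item_id]
        except KeyError:
            raise SequenceMismatchError(f"item {item_id} not in display") from None

    def item(self, item_id: int) -> Item:
        return self.items[self.index(item_id)]

    def __contains__(self, item_id: int) -> bool:
        return item_id in self._index

    def __len__(self) -> int:
        return self.n_items

    def __repr__(self) -> str:
        n = self.n_per_class
        return f"Display(n_items={self.n_items}, A={n[CLASS_A]}, B={n[CLASS_B]})"


@dataclass(frozen=True)
class SelectionSequence:
    """The ordered item ids selected in one trial (no repeats)."""

    item_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        if len(set(self.item_ids)) != len(self.item_ids):
            raise SequenceMismatchError("selection sequence repeats an item")

    def validate_against(self, display: Display) -> None:
        if len(self.item_ids) > display.n_items:
            raise SequenceMismatchError("sequence longer than display")
        for item_id in self.item_ids:
            if item_id not in display:
                raise SequenceMismatchError(f"item {item_id} not in display")

    def __len__(self) -> int:
        return len(self.item_ids)

    def __iter__(self):
        return iter(self.item_ids)

    def __getitem__(self, k):
        return self.item_ids[k]


@dataclass(frozen=True)
class ForagingParams:
    """The four foraging biases.

    b_class
        Salience of class A relative to class B (logit scale).
    b_stick
        Preference for repeating the previous item's class (logit scale).
    sigma_d
        Proximity bias: exponential decay rate of weight with distance from
        the last selection, in units of inverse normalized distance.
    sigma_theta
        Direction (momentum) bias: exponential decay rate with the
        normalized angular deviation from the previous movement direction.

    All four are unconstrained reals; a negative decay rate encodes the
    opposite bias (preferring far / reversing candidates).
    """

    b_class: float = 0.0
    b_stick: float = 0.0
    sigma_d: float = 0.0
    sigma_theta: float = 0.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if not np.isfinite(getattr(self, name)):
                raise InvalidArgumentError(f"{name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "ForagingParams":
        return cls(**dict(zip(PARAM_NAMES, (float(v) for v in x))))

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ForagingParams":
        return cls(**{n: float(d[n]) for n in PARAM_NAMES})


@dataclass(frozen=True)
class TrialState:
    """The evolving context of a trial: remaining items plus the last two picks."""

    display: Display
    remaining: frozenset[int]
    last: int | None = None
    second_last: int | None = None

    def __post_init__(self) -> None:
        if self.last is not None and self.last in self.remaining:
            raise InvalidArgumentError("last selection still in remaining set")
        if self.second_last is not None and self.second_last in self.remaining:
            raise InvalidArgumentError("second_last selection still in remaining set")
        for item_id in self.remaining:
            if item_id not in self.display:
                raise SequenceMismatchError(f"remaining item {item_id} not in display")

    @classmethod
    def initial(cls, display: Display) -> "TrialState":
        return cls(display=display, remaining=frozenset(display.item_ids))

    def advance(self, chosen: int) -> "TrialState":
        if chosen not in self.remaining:
            raise SequenceMismatchError(f"item {chosen} is not available for selection")
        return TrialState(
            display=self.display,
            remaining=self.remaining - {chosen},
            last=chosen,
            second_last=self.last,
        )


def angular_difference(phi1: float, phi2: float) -> float:
    """Smallest angle between two directions, in [0, pi].

    Symmetric in its arguments and invariant to adding multiples of 2*pi
    to either one.
    """
    if not (np.isfinite(phi1) and np.isfinite(phi2)):
        raise InvalidArgumentError("angles must be finite")
    d = (phi1 - phi2) % _TWO_PI
    return float(min(d, _TWO_PI - d))


def _angular_difference_vec(phi: np.ndarray, ref: float) -> np.ndarray:
    d = np.mod(phi - ref, _TWO_PI)
    return np.minimum(d, _TWO_PI - d)


def direction_cost(candidate: Item, current: Item, previous: Item) -> float:
    """Normalized change of heading in [0, 1] implied by selecting ``candidate``.

    0 means continuing straight along the previous direction of travel
    (previous -> current), 1 means a full reversal.
    """
    v_prev = current.position - previous.position
    v_cand = candidate.position - current.position
    if np.allclose(v_prev, 0.0) or np.allclose(v_cand, 0.0):
        raise DegenerateGeometryError("coincident positions: direction undefined")
    phi_prev = math.atan2(v_prev[1], v_prev[0])
    phi_cand = math.atan2(v_cand[1], v_cand[0])
    return angular_difference(phi_cand, phi_prev) / math.pi


def proximity_kernel(distance: float, sigma_d: float) -> float:
    """Exponential proximity weight exp(-sigma_d * distance)."""
    if distance < 0:
        raise InvalidArgumentError("distance must be nonnegative")
    return float(np.exp(-sigma_d * distance))


def direction_kernel(theta: float, sigma_theta: float) -> float:
    """Exponential direction weight exp(-sigma_theta * theta), theta in [0, 1]."""
    if not (0.0 <= theta <= 1.0):
        raise InvalidArgumentError("theta must lie in [0, 1]")
    return float(np.exp(-sigma_theta * theta))


def class_stick_weight(
    item_class: str, prev_class: str | None, params: ForagingParams
) -> float:
    """Logistic class/stick factor g(b_class * t + b_stick * m) in (0, 1)."""
    t = 1.0 if item_class == CLASS_A else 0.0
    m = 1.0 if (prev_class is not None and item_class == prev_class) else 0.0
    return float(expit(params.b_class * t + params.b_stick * m))


def _state_log_weights(
    state: TrialState, params: ForagingParams
) -> tuple[np.ndarray, np.ndarray]:
    """Item ids (sorted) and their log selection weights for ``state``."""
    if not state.remaining:
        raise EmptyChoiceSetError("no items remain to be selected")
    display = state.display
    ids = np.array(sorted(state.remaining))
    idx = np.array([display.index(i) for i in ids])
    t = display.is_class_a[idx].astype(float)
    if state.last is None:
        return ids, np.asarray(log_expit(params.b_class * t))
    last_idx = display.index(state.last)
    m = (display.is_class_a[idx] == display.is_class_a[last_idx]).astype(float)
    diff = display.positions[idx] - display.positions[last_idx]
    dist = np.hypot(diff[:, 0], diff[:, 1])
    logw = (
        np.asarray(log_expit(params.b_class * t + params.b_stick * m))
        - params.sigma_d * dist
    )
    if state.second_last is not None:
        prev_pos = display.positions[display.index(state.second_last)]
        move = display.positions[last_idx] - prev_pos
        phi_prev = math.atan2(move[1], move[0])
        phi = np.arctan2(diff[:, 1], diff[:, 0])
        theta = _angular_difference_vec(phi, phi_prev) / math.pi
        logw = logw - params.sigma_theta * theta
    return ids, logw


def selection_log_weights(
    state: TrialState, params: ForagingParams
) -> dict[int, float]:
    """Log selection weights over the remaining items (numerically safe)."""
    ids, logw = _state_log_weights(state, params)
    return {int(i): float(w) for i, w in zip(ids, logw)}


def selection_weights(state: TrialState, params: ForagingParams) -> dict[int, float]:
    """Unnormalized selection weights over the remaining items.

    All weights are strictly positive in exact arithmetic; with extreme
    decay rates they may underflow — use :func:`selection_log_weights`
    (or the probability helpers, which work in log space) in that regime.
    """
    ids, logw = _state_log_weights(state, params)
    return {int(i): float(w) for i, w in zip(ids, np.exp(logw))}


def selection_probabilities(weights: Mapping[int, float]) -> dict[int, float]:
    """Normalize positive weights into selection probabilities (sum to 1)."""
    if not weights:
        raise InvalidArgumentError("at least one weight required")
    ids = sorted(weights)
    w = np.array([weights[i] for i in ids], dtype=float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise InvalidArgumentError("weights must be finite and strictly positive")
    p = w / w.sum()
    return {int(i): float(v) for i, v in zip(ids, p)}


def state_selection_probabilities(
    state: TrialState, params: ForagingParams
) -> dict[int, float]:
    """Selection probabilities for a trial state, computed in log space."""
    ids, logw = _state_log_weights(state, params)
    logw = logw - logw.max()
    p = np.exp(logw)
    p /= p.sum()
    return {int(i): float(v) for i, v in zip(ids, p)}


class SequenceCache:
    """Flattened per-step arrays for fast likelihood evaluation.

    For every scored selection the cache stores, for each then-remaining
    candidate, the class indicator ``t``, same-class indicator ``m``,
    distance ``d`` to the last selection and normalized heading change
    ``theta`` — everything that does not depend on the parameters.  The
    log-likelihood and its gradient are then vectorized over all steps of
    all trials at once.
    """

    __slots__ = ("t", "m", "d", "theta", "seg_starts", "seg_id", "chosen")

    def __init__(self, t, m, d, theta, seg_starts, chosen):
        self.t = np.asarray(t, dtype=float)
        self.m = np.asarray(m, dtype=float)
        self.d = np.asarray(d, dtype=float)
        self.theta = np.asarray(theta, dtype=float)
        self.seg_starts = np.asarray(seg_starts, dtype=np.intp)
        self.chosen = np.asarray(chosen, dtype=np.intp)
        lengths = np.diff(np.append(self.seg_starts, self.t.size))
        self.seg_id = np.repeat(np.arange(self.seg_starts.size), lengths)

    @property
    def n_segments(self) -> int:
        return self.seg_starts.size

    @classmethod
    def build(
        cls,
        display: Display,
        sequence: SelectionSequence,
        include_first: bool = False,
    ) -> "SequenceCache":
        sequence.validate_against(display)
        order = np.array([display.index(i) for i in sequence], dtype=np.intp)
        pos, isa = display.positions, display.is_class_a
        mask = np.zeros(display.n_items, dtype=bool)
        t_l, m_l, d_l, th_l = [], [], [], []
        seg_starts, chosen = [], []
        offset = 0
        start = 0 if include_first else 1
        for j in range(order.size):
            if j >= start:
                rem = np.flatnonzero(~mask)
                nr = rem.size
                t_l.append(isa[rem].astype(float))
                if j == 0:
                    m_l.append(np.zeros(nr))
                    d_l.append(np.zeros(nr))
                    th_l.append(np.zeros(nr))
                else:
                    li = order[j - 1]
                    m_l.append((isa[rem] == isa[li]).astype(float))
                    diff = pos[rem] - pos[li]
                    d_l.append(np.hypot(diff[:, 0], diff[:, 1]))
                    if j >= 2:
                        move = pos[li] - pos[order[j - 2]]
                        phi_prev = math.atan2(move[1], move[0])
                        phi = np.arctan2(diff[:, 1], diff[:, 0])
                        th_l.append(_angular_difference_vec(phi, phi_prev) / math.pi)
                    else:
                        th_l.append(np.zeros(nr))
                seg_starts.append(offset)
                chosen.append(offset + int(np.flatnonzero(rem == order[j])[0]))
                offset += nr
            mask[order[j]] = True
        if not seg_starts:
            empty = np.empty(0)
            return cls(empty, empty, empty, empty, np.empty(0, np.intp), np.empty(0, np.intp))
        return cls(
            np.concatenate(t_l),
            np.concatenate(m_l),
            np.concatenate(d_l),
            np.concatenate(th_l),
            np.array(seg_starts),
            np.array(chosen),
        )

    @classmethod
    def concat(cls, caches: Sequence["SequenceCache"]) -> "SequenceCache":
        caches = [c for c in caches if c.n_segments > 0]
        if not caches:
            empty = np.empty(0)
            return cls(empty, empty, empty, empty, np.empty(0, np.intp), np.empty(0, np.intp))
        offsets = np.cumsum([0] + [c.t.size for c in caches[:-1]])
        return cls(
            np.concatenate([c.t for c in caches]),
            np.concatenate([c.m for c in caches]),
            np.concatenate([c.d for c in caches]),
            np.concatenate([c.theta for c in caches]),
            np.concatenate([c.seg_starts + o for c, o in zip(caches, offsets)]),
            np.concatenate([c.chosen + o for c, o in zip(caches, offsets)]),
        )

    def _log_weights(self, x: np.ndarray) -> np.ndarray:
        b_class, b_stick, sigma_d, sigma_theta = x
        z = b_class * self.t + b_stick * self.m
        return (
            np.asarray(log_expit(z)) - sigma_d * self.d - sigma_theta * self.theta
        )

    def log_likelihood(self, params: ForagingParams | np.ndarray) -> float:
        """Sum over scored selections of log p(chosen | state)."""
        if self.n_segments == 0:
            return 0.0
        x = params.as_array() if isinstance(params, ForagingParams) else np.asarray(params)
        lw = self._log_weights(x)
        seg_max = np.maximum.reduceat(lw, self.seg_starts)
        ex = np.exp(lw - seg_max[self.seg_id])
        seg_sum = np.add.reduceat(ex, self.seg_starts)
        lse = seg_max + np.log(seg_sum)
        return float(lw[self.chosen].sum() - lse.sum())

    def log_likelihood_grad(
        self, params: ForagingParams | np.ndarray
    ) -> tuple[float, np.ndarray]:
        """Log-likelihood and its analytic gradient in (b_class, b_stick, sigma_d, sigma_theta)."""
        if self.n_segments == 0:
            return 0.0, np.zeros(4)
        x = params.as_array() if isinstance(params, ForagingParams) else np.asarray(params)
        b_class, b_stick, _, _ = x
        z = b_class * self.t + b_stick * self.m
        lw = self._log_weights(x)
        seg_max = np.maximum.reduceat(lw, self.seg_starts)
        ex = np.exp(lw - seg_max[self.seg_id])
        seg_sum = np.add.reduceat(ex, self.seg_starts)
        lse = seg_max + np.log(seg_sum)
        ll = float(lw[self.chosen].sum() - lse.sum())
        p = ex / seg_sum[self.seg_id]
        resid = -p
        resid[self.chosen] += 1.0
        one_minus_s = expit(-z)  # d/dz log g(z)
        grad = np.array(
            [
                np.sum(resid * one_minus_s * self.t),
                np.sum(resid * one_minus_s * self.m),
                np.sum(resid * (-self.d)),
                np.sum(resid * (-self.theta)),
            ]
        )
        return ll, grad


def sequence_log_likelihood(
    display: Display,
    sequence: SelectionSequence,
    params: ForagingParams,
    include_first: bool = False,
) -> float:
    """Log-likelihood of an observed selection order under the model.

    The first selection, when scored (``include_first``), uses the
    class-salience factor only; later selections use the full weights with
    the evolving trial state.
    """
    return SequenceCache.build(display, sequence, include_first).log_likelihood(params)
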