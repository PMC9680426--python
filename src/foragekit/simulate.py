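"""Synthetic-data generation: displays, selection sequences, whole studies.

The default scenario emulates the paradigm the model was built for: 58
participants foraging 40 targets (20 per class) scattered in the unit
square, in a "feature" condition (easy discrimination, frequent class
switching) and a "conjunction" condition (hard discrimination, long
same-class runs — a stronger stick bias).  First selections mix a
top-left-corner strategy and a diffuse central strategy via a two-component
beta mixture with a per-participant corner weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    CLASS_A,
    CLASS_B,
    Display,
    ForagingParams,
    Item,
    SelectionSequence,
    TrialState,
    state_selection_probabilities,
)
from .exceptions import InvalidArgumentError, PackingInfeasibleError
from .initial import BetaShape, MixtureModel, ParticipantBetaModel, initial_item_weights
from .io import ForagingDataset, Trial

__all__ = [
    "ParamPopulation",
    "SimulationScenario",
    "default_scenario",
    "generate_display",
    "simulate_sequence",
    "simulate_dataset",
    "simulate_first_selections",
]


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ParamPopulation:
    """Population mean and SD of each foraging bias (independent normals)."""

    mean: ForagingParams
    sd: ForagingParams

    def draw(self, rng: np.random.Generator) -> ForagingParams:
        mu = self.mean.as_array()
        sigma = self.sd.as_array()
        if np.any(sigma < 0):
            raise InvalidArgumentError("population SDs must be nonnegative")
        return ForagingParams.from_array(rng.normal(mu, sigma))


#: corner-start component: mass piled near (0, 0), the top-left of the screen
CORNER_COMPONENT = BetaShape(1.5, 10.0)
#: diffuse central component
CENTRE_COMPONENT = BetaShape(5.0, 5.0)


@dataclass(frozen=True)
class SimulationScenario:
    """Everything needed to simulate a full study.

    ``populations`` maps condition name to the distribution the
    per-participant biases are drawn from.  ``lambda_beta`` is the beta
    distribution the per-participant corner weight lambda is drawn from;
    the default favours corner starters, which form the majority group in
    this paradigm.
    """

    n_participants: int = 58
    trials_per_participant: int = 20
    n_per_class: int = 20
    populations: Mapping[str, ParamPopulation] = field(
        default_factory=lambda: {
            "feature": ParamPopulation(
                mean=ForagingParams(0.5, 1.0, 5.0, 0.5),
                sd=ForagingParams(0.2, 0.3, 1.0, 0.2),
            ),
            "conjunction": ParamPopulation(
                mean=ForagingParams(0.5, 3.0, 5.0, 0.5),
                sd=ForagingParams(0.2, 0.5, 1.0, 0.2),
            ),
        }
    )
    corner_x: BetaShape = CORNER_COMPONENT
    corner_y: BetaShape = CORNER_COMPONENT
    centre_x: BetaShape = CENTRE_COMPONENT
    centre_y: BetaShape = CENTRE_COMPONENT
    lambda_beta: tuple[float, float] = (2.0, 1.0)
    min_spacing: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.trials_per_participant < 1:
            raise InvalidArgumentError("counts must be >= 1")
        if self.min_spacing <= 0:
            raise InvalidArgumentError("min_spacing must be positive")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.populations)


def default_scenario(**overrides) -> SimulationScenario:
    return replace(SimulationScenario(), **overrides) if overrides else SimulationScenario()


def generate_display(
    n_per_class: int,
    min_spacing: float = 0.04,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 20000,
) -> Display:
    """Uniform random display of 2*n_per_class items with pairwise min spacing.

    Positions are rejection-sampled in the unit square; class labels are a
    random even split.
    """
    if n_per_class < 1:
        raise InvalidArgumentError("n_per_class must be >= 1")
    rng = _as_rng(seed)
    n = 2 * n_per_class
    placed = np.empty((0, 2))
    attempts = 0
    while placed.shape[0] < n:
        if attempts >= max_attempts:
            raise PackingInfeasibleError(
                f"could not place {n} items at spacing {min_spacing} "
                f"within {max_attempts} attempts"
            )
        candidate = rng.uniform(0.0, 1.0, size=2)
        attempts += 1
        if placed.size == 0 or np.min(
            np.hypot(*(placed - candidate).T)
        ) >= min_spacing:
            placed = np.vstack([placed, candidate])
    labels = np.array([CLASS_A] * n_per_class + [CLASS_B] * n_per_class)
    labels = labels[rng.permutation(n)]
    items = [
        Item(item_id=k, x=float(placed[k, 0]), y=float(placed[k, 1]), item_class=labels[k])
        for k in range(n)
    ]
    return Display(items)


def simulate_sequence(
    display: Display,
    params: ForagingParams,
    seed: int | np.random.Generator = 0,
    first_policy: str = "salience",
    initial_model: ParticipantBetaModel | MixtureModel | None = None,
    participant: str | None = None,
) -> SelectionSequence:
    """Sample a complete selection order from the model.

    ``first_policy="salience"`` picks the first item with probability
    proportional to g(b_class * t_i); ``"spatial"`` uses the fitted
    initial-selection density of ``participant`` under ``initial_model``.
    Every later item is drawn from the selection probabilities of the
    evolving trial state until the display is exhausted.
    """
    rng = _as_rng(seed)
    if first_policy == "spatial":
        if initial_model is None or participant is None:
            raise InvalidArgumentError(
                "spatial first policy needs initial_model and participant"
            )
        probs = initial_item_weights(display, initial_model, participant)
    elif first_policy == "salience":
        state0 = TrialState.initial(display)
        probs = state_selection_probabilities(state0, params)
    else:
        raise InvalidArgumentError(f"unknown first_policy {first_policy!r}")
    ids = np.array(sorted(probs))
    p = np.array([probs[i] for i in ids])
    first = int(rng.choice(ids, p=p))
    chosen = [first]
    state = TrialState.initial(display).advance(first)
    while state.remaining:
        probs = state_selection_probabilities(state, params)
        ids = np.array(sorted(probs))
        p = np.array([probs[i] for i in ids])
        nxt = int(rng.choice(ids, p=p))
        chosen.append(nxt)
        state = state.advance(nxt)
    return SelectionSequence(tuple(chosen))


def simulate_first_selections(
    lam: Mapping[str, float],
    trials_per_participant: int,
    seed: int | np.random.Generator = 0,
    corner_x: BetaShape = CORNER_COMPONENT,
    corner_y: BetaShape = CORNER_COMPONENT,
    centre_x: BetaShape = CENTRE_COMPONENT,
    centre_y: BetaShape = CENTRE_COMPONENT,
) -> dict[str, np.ndarray]:
    """Draw first-selection (x, y) locations from the beta mixture.

    For each trial a single component indicator is drawn (corner with
    probability lambda), then x and y are drawn from that component —
    matching the joint-indicator reading of the mixture.
    """
    rng = _as_rng(seed)
    out: dict[str, np.ndarray] = {}
    for participant, weight in lam.items():
        z = rng.random(trials_per_participant) < weight
        x = np.where(
            z,
            rng.beta(corner_x.alpha, corner_x.beta, trials_per_participant),
            rng.beta(centre_x.alpha, centre_x.beta, trials_per_participant),
        )
        y = np.where(
            z,
            rng.beta(corner_y.alpha, corner_y.beta, trials_per_participant),
            rng.beta(centre_y.alpha, centre_y.beta, trials_per_participant),
        )
        out[participant] = np.column_stack([x, y])
    return out


def simulate_dataset(
    scenario: SimulationScenario,
) -> tuple[ForagingDataset, pd.DataFrame, MixtureModel]:
    """Simulate a whole study from a scenario.

    Returns the tidy dataset, a ground-truth table (one row per participant
    per condition: the four biases plus lambda) and the initial-selection
    mixture model actually used (with the drawn per-participant lambdas).
    """
    rng = np.random.default_rng(scenario.seed)
    participants = [f"p{k + 1:03d}" for k in range(scenario.n_participants)]
    a, b = scenario.lambda_beta
    lam = {p: float(rng.beta(a, b)) for p in participants}
    initial_model = MixtureModel(
        comp1_x=scenario.corner_x,
        comp1_y=scenario.corner_y,
        comp2_x=scenario.centre_x,
        comp2_y=scenario.centre_y,
        lam=lam,
    )
    trials: list[Trial] = []
    truth_rows = []
    for participant in participants:
        for condition in scenario.conditions:
            params = scenario.populations[condition].draw(rng)
            truth_rows.append(
                {
                    "participant_id": participant,
                    "condition": condition,
                    **params.to_dict(),
                    "lambda": lam[participant],
                }
            )
            for trial_id in range(1, scenario.trials_per_participant + 1):
                display = generate_display(
                    scenario.n_per_class, scenario.min_spacing, seed=rng
                )
                sequence = simulate_sequence(
                    display,
                    params,
                    seed=rng,
                    first_policy="spatial",
                    initial_model=initial_model,
                    participant=participant,
                )
                trials.append(
                    Trial(participant, condition, trial_id, display, sequence)
                )
    truth = pd.DataFrame(truth_rows)
    return ForagingDataset(trials), truth, initial_model
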