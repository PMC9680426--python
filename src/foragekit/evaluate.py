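"""Target-by-target evaluation of the foraging model.

The evaluation steps through each observed trial, recomputing the model's
selection probabilities over the then-remaining items at every selection.
From the resulting per-selection records it derives: per-participant
accuracy (how often the model's top-weighted item was the one actually
selected), the uniform chance baseline, a calibration table (predicted top
weight vs. empirical top-choice frequency), runner-up rank selection rates,
path-length comparisons against simulated foragers, and the association
between accuracy and the fitted biases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    PARAM_NAMES,
    Display,
    ForagingParams,
    SelectionSequence,
    TrialState,
    state_selection_probabilities,
)
from .exceptions import InvalidArgumentError
from .initial import MixtureModel, ParticipantBetaModel, initial_item_weights
from .io import ForagingDataset
from .simulate import simulate_sequence

__all__ = [
    "PredictionRecord",
    "step_through",
    "step_through_dataset",
    "records_to_frame",
    "participant_accuracy",
    "chance_baseline",
    "calibration_table",
    "rank_selection_rates",
    "path_length",
    "compare_path_lengths",
    "accuracy_parameter_association",
    "PARAMETER_REPORT_LABELS",
]

#: reporting labels for the four biases (field convention: pA, pS, bP, bM)
PARAMETER_REPORT_LABELS = {
    "b_class": "pA",
    "b_stick": "pS",
    "sigma_d": "bP",
    "sigma_theta": "bM",
}


@dataclass(frozen=True)
class PredictionRecord:
    """The model's verdict on one observed selection.

    ``ranked_weights`` holds the full probability vector over the remaining
    items sorted best-first (ties broken by lowest item id) — needed for
    runner-up rank analyses.
    """

    participant: str
    condition: str
    trial: int
    selection_index: int
    n_remaining: int
    weight_on_selected: float
    max_weight: float
    rank_of_selected: int
    top_item_correct: bool
    ranked_weights: tuple[float, ...] | None = None


def _record_from_probs(
    probs: Mapping[int, float],
    chosen: int,
    selection_index: int,
    participant: str,
    condition: str,
    trial: int,
    keep_ranked: bool,
) -> PredictionRecord:
    ids = np.array(sorted(probs))
    p = np.array([probs[i] for i in ids])
    order = np.lexsort((ids, -p))  # descending probability, lowest id first on ties
    ranked_ids = ids[order]
    ranked_p = p[order]
    rank = int(np.flatnonzero(ranked_ids == chosen)[0]) + 1
    return PredictionRecord(
        participant=participant,
        condition=condition,
        trial=trial,
        selection_index=selection_index,
        n_remaining=int(ids.size),
        weight_on_selected=float(probs[chosen]),
        max_weight=float(ranked_p[0]),
        rank_of_selected=rank,
        top_item_correct=rank == 1,
        ranked_weights=tuple(float(v) for v in ranked_p) if keep_ranked else None,
    )


def step_through(
    display: Display,
    sequence: SelectionSequence,
    params: ForagingParams,
    include_first: bool = False,
    initial_model: ParticipantBetaModel | MixtureModel | None = None,
    participant: str = "",
    condition: str = "",
    trial: int = 0,
    keep_ranked: bool = True,
) -> list[PredictionRecord]:
    """One prediction record per scored selection of an observed trial.

    Selection indices are 1-based over the trial; when the first selection
    is excluded (default) records start at index 2.  With ``include_first``
    the first selection is scored by the fitted initial-selection density
    if ``initial_model`` is given, otherwise by class salience alone.
    """
    sequence.validate_against(display)
    records: list[PredictionRecord] = []
    state = TrialState.initial(display)
    for j, chosen in enumerate(sequence):
        if j > 0 or include_first:
            if j == 0 and initial_model is not None:
                probs = initial_item_weights(display, initial_model, participant)
            else:
                probs = state_selection_probabilities(state, params)
            records.append(
                _record_from_probs(
                    probs, chosen, j + 1, participant, condition, trial, keep_ranked
                )
            )
        state = state.advance(chosen)
    return records


def step_through_dataset(
    dataset: ForagingDataset,
    params_by_participant: Mapping[str, ForagingParams] | ForagingParams,
    include_first: bool = False,
    initial_model: ParticipantBetaModel | MixtureModel | None = None,
    keep_ranked: bool = True,
) -> list[PredictionRecord]:
    """Step through every trial of a dataset with per-participant parameters."""
    records: list[PredictionRecord] = []
    for t in dataset:
        params = (
            params_by_participant
            if isinstance(params_by_participant, ForagingParams)
            else params_by_participant[t.participant]
        )
        records.extend(
            step_through(
                t.display,
                t.sequence,
                params,
                include_first=include_first,
                initial_model=initial_model,
                participant=t.participant,
                condition=t.condition,
                trial=t.trial_id,
                keep_ranked=keep_ranked,
            )
        )
    return records


def records_to_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant": [r.participant for r in records],
            "condition": [r.condition for r in records],
            "trial": [r.trial for r in records],
            "selection_index": [r.selection_index for r in records],
            "n_remaining": [r.n_remaining for r in records],
            "weight_on_selected": [r.weight_on_selected for r in records],
            "max_weight": [r.max_weight for r in records],
            "rank_of_selected": [r.rank_of_selected for r in records],
            "top_item_correct": [r.top_item_correct for r in records],
        }
    )


def participant_accuracy(
    records: Sequence[PredictionRecord], by_condition: bool = False
) -> pd.Series:
    """Mean proportion of selections where the model's top item was chosen."""
    if not records:
        raise InvalidArgumentError("no prediction records")
    df = records_to_frame(records)
    keys = ["participant", "condition"] if by_condition else ["participant"]
    return df.groupby(keys)["top_item_correct"].mean()


def chance_baseline(n_items: int, exclude_first: bool = True) -> float:
    """Expected accuracy of uniform guessing over the course of a trial.

    Averaging 1/(remaining items) across the scored selections of a fully
    foraged n-item display: H(n-1)/(n-1) when the first selection is
    excluded, H(n)/n otherwise (H = harmonic number).
    """
    if n_items < 2:
        raise InvalidArgumentError("n_items must be >= 2")
    if exclude_first:
        k = np.arange(1, n_items)
        return float(np.sum(1.0 / k) / (n_items - 1))
    k = np.arange(1, n_items + 1)
    return float(np.sum(1.0 / k) / n_items)


def calibration_table(
    records: Sequence[PredictionRecord], n_bins: int = 10
) -> pd.DataFrame:
    """Bin records by top weight; compare mean predicted with observed frequency.

    Equal-width bins over (0, 1]; empty bins are omitted.  A well-calibrated
    model has observed ~= predicted in every bin.
    """
    if not records:
        raise InvalidArgumentError("no prediction records")
    if n_bins < 2:
        raise InvalidArgumentError("n_bins must be >= 2")
    mw = np.array([r.max_weight for r in records])
    correct = np.array([r.top_item_correct for r in records], dtype=float)
    bins = np.clip(np.ceil(mw * n_bins).astype(int) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = bins == b
        n = int(mask.sum())
        if n == 0:
            continue
        rows.append(
            {
                "bin_low": b / n_bins,
                "bin_high": (b + 1) / n_bins,
                "mean_predicted": float(mw[mask].mean()),
                "observed": float(correct[mask].mean()),
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def rank_selection_rates(
    records: Sequence[PredictionRecord], max_rank: int = 3
) -> pd.DataFrame:
    """Mean assigned weight vs. observed selection frequency at each rank.

    Rank 1 is the model's favourite among the remaining items.  Records
    lacking a rank (n_remaining < rank) are skipped for that rank, with the
    skip count reported.
    """
    if not records:
        raise InvalidArgumentError("no prediction records")
    if any(r.ranked_weights is None for r in records):
        raise InvalidArgumentError(
            "records lack full weight vectors; run step_through with keep_ranked=True"
        )
    rows = []
    for rank in range(1, max_rank + 1):
        usable = [r for r in records if r.n_remaining >= rank]
        skipped = len(records) - len(usable)
        if not usable:
            rows.append(
                {"rank": rank, "mean_weight": np.nan, "observed_rate": np.nan,
                 "n": 0, "skipped": skipped}
            )
            continue
        weights = np.array([r.ranked_weights[rank - 1] for r in usable])
        hits = np.array([r.rank_of_selected == rank for r in usable], dtype=float)
        rows.append(
            {
                "rank": rank,
                "mean_weight": float(weights.mean()),
                "observed_rate": float(hits.mean()),
                "n": len(usable),
                "skipped": skipped,
            }
        )
    return pd.DataFrame(rows)


def path_length(display: Display, sequence: SelectionSequence) -> float:
    """Total Euclidean distance of the selection order's polyline."""
    sequence.validate_against(display)
    if len(sequence) < 2:
        return 0.0
    idx = [display.index(i) for i in sequence]
    pos = display.positions[idx]
    return float(np.sum(np.hypot(*(np.diff(pos, axis=0).T))))


def compare_path_lengths(
    dataset: ForagingDataset,
    params_by_participant: Mapping[str, ForagingParams],
    n_sims: int = 50,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Compare observed path lengths with paths simulated from fitted biases.

    For every trial, ``n_sims`` sequences are simulated on the same display
    from the participant's parameters.  Per participant the table reports
    the median observed length, the median of per-trial median simulated
    lengths, and the proportion of trials whose observed path was shorter
    than the simulated median.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for participant, trials in dataset.by_participant().items():
        params = params_by_participant[participant]
        human_lengths = []
        model_medians = []
        shorter = []
        for t in trials:
            human = path_length(t.display, t.sequence)
            sims = [
                path_length(
                    t.display, simulate_sequence(t.display, params, seed=rng)
                )
                for _ in range(n_sims)
            ]
            med = float(np.median(sims))
            human_lengths.append(human)
            model_medians.append(med)
            shorter.append(human < med)
        rows.append(
            {
                "participant": participant,
                "median_human_length": float(np.median(human_lengths)),
                "median_model_length": float(np.median(model_medians)),
                "prop_human_shorter": float(np.mean(shorter)),
                "n_trials": len(trials),
            }
        )
    return pd.DataFrame(rows)


def accuracy_parameter_association(
    accuracy: Mapping[str, float] | pd.Series,
    params_by_participant: Mapping[str, ForagingParams],
) -> pd.DataFrame:
    """Pearson correlation of per-participant accuracy with each fitted bias.

    Parameters with zero variance across participants (or constant
    accuracy) are flagged undefined rather than reported as spurious
    correlations.
    """
    acc = pd.Series(dict(accuracy))
    participants = [p for p in acc.index if p in params_by_participant]
    if len(participants) < 3:
        raise InvalidArgumentError("need >= 3 participants for correlations")
    a = acc.loc[participants].to_numpy(dtype=float)
    rows = []
    for name in PARAM_NAMES:
        v = np.array(
            [getattr(params_by_participant[p], name) for p in participants]
        )
        if np.ptp(v) < 1e-12 or np.ptp(a) < 1e-12:
            rows.append(
                {"parameter": name, "label": PARAMETER_REPORT_LABELS[name],
                 "r": np.nan, "p_value": np.nan, "defined": False}
            )
            continue
        r, p = stats.pearsonr(a, v)
        rows.append(
            {"parameter": name, "label": PARAMETER_REPORT_LABELS[name],
             "r": float(r), "p_value": float(p), "defined": True}
        )
    return pd.DataFrame(rows)
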