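"""Tidy tabular data format and serialization.

The interchange format is a tidy CSV with one row per item per trial:

    participant_id, condition, trial_id, item_id, x, y, item_class, selection_order

``selection_order`` is 1-based over the selected items of a trial (blank for
unselected items); within a trial the non-blank orders must form a
permutation of 1..n_selected.  Coordinates are normalized to the unit
square (a bounding box can be supplied to auto-normalize raw pixels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import Display, Item, SelectionSequence
from .exceptions import DatasetValidationError
from .initial import MixtureModel, ParticipantBetaModel

__all__ = [
    "COLUMNS",
    "Trial",
    "ForagingDataset",
    "read_dataset",
    "write_dataset",
    "save_json",
    "load_json",
    "save_fit_results",
    "load_fit_results",
    "save_initial_model",
    "load_initial_model",
]

COLUMNS = (
    "participant_id",
    "condition",
    "trial_id",
    "item_id",
    "x",
    "y",
    "item_class",
    "selection_order",
)


@dataclass(frozen=True)
class Trial:
    """One trial: a display plus the observed selection order."""

    participant: str
    condition: str
    trial_id: int
    display: Display
    sequence: SelectionSequence


class ForagingDataset:
    """A collection of trials grouped by participant/condition/trial."""

    def __init__(self, trials: Iterable[Trial]):
        self.trials: list[Trial] = list(trials)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def participants(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.participant, None)
        return tuple(seen)

    def by_participant(self) -> dict[str, list[Trial]]:
        out: dict[str, list[Trial]] = {}
        for t in self.trials:
            out.setdefault(t.participant, []).append(t)
        return out

    def pairs_by_participant(
        self,
    ) -> dict[str, list[tuple[Display, SelectionSequence]]]:
        return {
            p: [(t.display, t.sequence) for t in trials]
            for p, trials in self.by_participant().items()
        }

    def first_selections(self) -> dict[str, np.ndarray]:
        """Per participant, the (x, y) coordinates of first-selected items."""
        out: dict[str, list[tuple[float, float]]] = {}
        for t in self.trials:
            if len(t.sequence) == 0:
                continue
            item = t.display.item(t.sequence[0])
            out.setdefault(t.participant, []).append((item.x, item.y))
        return {p: np.array(v) for p, v in out.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            order = {item_id: k + 1 for k, item_id in enumerate(t.sequence)}
            for it in t.display.items:
                rows.append(
                    (
                        t.participant,
                        t.condition,
                        t.trial_id,
                        it.item_id,
                        it.x,
                        it.y,
                        it.item_class,
                        order.get(it.item_id),
                    )
                )
        df = pd.DataFrame(rows, columns=list(COLUMNS))
        df["selection_order"] = df["selection_order"].astype("Int64")
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ForagingDataset":
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise DatasetValidationError(f"missing columns: {missing}")
        df = df.copy()
        df["selection_order"] = pd.array(
            pd.to_numeric(df["selection_order"], errors="coerce"), dtype="Int64"
        )
        bad_xy = df.index[
            (df["x"] < 0) | (df["x"] > 1) | (df["y"] < 0) | (df["y"] > 1)
        ].tolist()
        if bad_xy:
            raise DatasetValidationError(
                f"coordinates outside the unit square at rows {bad_xy[:10]}"
            )
        dup = df.duplicated(
            subset=["participant_id", "condition", "trial_id", "item_id"], keep=False
        )
        if dup.any():
            raise DatasetValidationError(
                "duplicate (participant, condition, trial, item) at rows "
                f"{df.index[dup].tolist()[:10]}"
            )
        trials = []
        for (participant, condition, trial_id), grp in df.groupby(
            ["participant_id", "condition", "trial_id"], sort=True
        ):
            items = [
                Item(int(r.item_id), float(r.x), float(r.y), str(r.item_class))
                for r in grp.itertuples()
            ]
            selected = grp.dropna(subset=["selection_order"])
            orders = selected["selection_order"].astype(int)
            n_sel = len(orders)
            if n_sel and sorted(orders) != list(range(1, n_sel + 1)):
                raise DatasetValidationError(
                    f"trial ({participant}, {condition}, {trial_id}): selection_order "
                    f"values {sorted(orders)} are not a permutation of 1..{n_sel}"
                )
            seq_ids = tuple(
                int(i)
                for i in selected.sort_values("selection_order")["item_id"]
            )
            trials.append(
                Trial(
                    participant=str(participant),
                    condition=str(condition),
                    trial_id=int(trial_id),
                    display=Display(items),
                    sequence=SelectionSequence(seq_ids),
                )
            )
        return cls(trials)


def read_dataset(
    path: str | Path,
    bounds: tuple[float, float, float, float] | None = None,
) -> ForagingDataset:
    """Read and validate a tidy foraging CSV.

    ``bounds = (xmin, xmax, ymin, ymax)`` rescales raw coordinates into the
    unit square before validation.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if bounds is not None:
        xmin, xmax, ymin, ymax = bounds
        if xmax <= xmin or ymax <= ymin:
            raise DatasetValidationError("degenerate bounding box")
        df["x"] = (df["x"] - xmin) / (xmax - xmin)
        df["y"] = (df["y"] - ymin) / (ymax - ymin)
    return ForagingDataset.from_frame(df)


def write_dataset(dataset: ForagingDataset, path: str | Path) -> None:
    # %.17g keeps the CSV round-trip bit-exact for float64 coordinates
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")


def save_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())


def save_fit_results(results: Mapping[str, "FitResult"], path: str | Path) -> None:
    """Serialize per-participant fit results as JSON."""
    save_json({p: r.to_dict() for p, r in results.items()}, path)


def load_fit_results(path: str | Path) -> dict[str, "FitResult"]:
    from .inference import FitResult

    return {p: FitResult.from_dict(d) for p, d in load_json(path).items()}


def save_initial_model(
    model: ParticipantBetaModel | MixtureModel, path: str | Path
) -> None:
    save_json(model.to_dict(), path)


def load_initial_model(path: str | Path) -> ParticipantBetaModel | MixtureModel:
    d = load_json(path)
    if d.get("model") == "mixture":
        return MixtureModel.from_dict(d)
    return ParticipantBetaModel.from_dict(d)
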