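"""Containers for completed 4AFC match-to-sample trials.

A trial presents a colored cue, then four choice colors of which exactly one
is a direct match to the cue; the subject selects one choice.  Only completed
trials are ever represented (aborted trials never enter any analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colorspace import StimulusSet

__all__ = ["TrialTable", "TrialValidationError"]

CSV_COLUMNS = [
    "session_id",
    "trial",
    "cue",
    "choice1",
    "choice2",
    "choice3",
    "choice4",
    "selected",
    "correct",
]


class TrialValidationError(ValueError):
    """Raised when a trial table violates the paradigm invariants.

    Carries per-row diagnostics in ``errors`` as ``(row_index, message)``.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        preview = "; ".join(f"row {i}: {msg}" for i, msg in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"{len(self.errors)} invalid trial(s): {preview}{more}")


@dataclass
class TrialTable:
    """Completed 4AFC trials against a fixed stimulus set.

    Attributes
    ----------
    cue : (T,) int array of cue color indices
    choices : (T, 4) int array of offered color indices (presentation order)
    selected : (T,) int array of selected positions, 1-based in {1..4}
    stimulus_set : StimulusSet
    session_id : (T,) object array of opaque session labels
    seed : int or None
        Seed of the generator that produced the table, when synthetic.
    """

    cue: np.ndarray
    choices: np.ndarray
    selected: np.ndarray
    stimulus_set: StimulusSet
    session_id: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self):
        self.cue = np.asarray(self.cue, dtype=np.int64)
        self.choices = np.asarray(self.choices, dtype=np.int64)
        self.selected = np.asarray(self.selected, dtype=np.int64)
        if self.session_id is None:
            self.session_id = np.full(self.cue.shape[0], "s0", dtype=object)
        else:
            self.session_id = np.asarray(self.session_id, dtype=object)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        errors = list(self.iter_violations())
        if errors:
            raise TrialValidationError(errors)

    def iter_violations(self):
        n = self.stimulus_set.n_colors
        T = self.cue.shape[0]
        if self.choices.shape != (T, 4):
            yield (-1, f"choices must be (T, 4), got {self.choices.shape}")
            return
        bad_cue = (self.cue < 0) | (self.cue >= n)
        bad_choice = ((self.choices < 0) | (self.choices >= n)).any(axis=1)
        bad_sel = (self.selected < 1) | (self.selected > 4)
        dup = np.array(
            [len(set(row)) != 4 for row in self.choices], dtype=bool
        )
        no_match = (self.choices != self.cue[:, None]).all(axis=1)
        for i in np.flatnonzero(bad_cue):
            yield (int(i), f"cue index {self.cue[i]} out of range [0, {n})")
        for i in np.flatnonzero(bad_choice):
            yield (int(i), f"choice indices {self.choices[i].tolist()} out of range [0, {n})")
        for i in np.flatnonzero(bad_sel):
            yield (int(i), f"selected={self.selected[i]} not in 1..4")
        for i in np.flatnonzero(dup & ~bad_choice):
            yield (int(i), f"duplicate choices {self.choices[i].tolist()}")
        for i in np.flatnonzero(no_match & ~bad_choice & ~bad_cue):
            yield (int(i), "no choice matches the cue (direct match must be offered)")

    # -- derived quantities --------------------------------------------
    @property
    def n_trials(self) -> int:
        return int(self.cue.shape[0])

    @property
    def selected_color(self) -> np.ndarray:
        """Color index of the selected choice, per trial."""
        return self.choices[np.arange(self.n_trials), self.selected - 1]

    @property
    def correct(self) -> np.ndarray:
        """Boolean array: the selected choice was the direct match."""
        return self.selected_color == self.cue

    def accuracy(self) -> float:
        return float(self.correct.mean())

    # -- subsetting ----------------------------------------------------
    def subset(self, index) -> "TrialTable":
        return TrialTable(
            cue=self.cue[index],
            choices=self.choices[index],
            selected=self.selected[index],
            stimulus_set=self.stimulus_set,
            session_id=self.session_id[index],
            seed=self.seed,
        )

    @staticmethod
    def concatenate(tables: list["TrialTable"]) -> "TrialTable":
        if not tables:
            raise ValueError("cannot concatenate an empty list of tables")
        sset = tables[0].stimulus_set
        return TrialTable(
            cue=np.concatenate([t.cue for t in tables]),
            choices=np.concatenate([t.choices for t in tables]),
            selected=np.concatenate([t.selected for t in tables]),
            stimulus_set=sset,
            session_id=np.concatenate([t.session_id for t in tables]),
        )

    # -- I/O -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "session_id": self.session_id,
                "trial": np.arange(self.n_trials),
                "cue": self.cue,
                "choice1": self.choices[:, 0],
                "choice2": self.choices[:, 1],
                "choice3": self.choices[:, 2],
                "choice4": self.choices[:, 3],
                "selected": self.selected,
                "correct": self.correct.astype(int),
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, stimulus_set: StimulusSet, seed: int | None = None
    ) -> "TrialTable":
        missing = [c for c in CSV_COLUMNS if c not in frame.columns and c != "correct"]
        if missing:
            raise TrialValidationError(
                [(-1, f"missing required column(s): {', '.join(missing)}")]
            )
        choices = frame[["choice1", "choice2", "choice3", "choice4"]].to_numpy(np.int64)
        return cls(
            cue=frame["cue"].to_numpy(np.int64),
            choices=choices,
            selected=frame["selected"].to_numpy(np.int64),
            stimulus_set=stimulus_set,
            session_id=frame["session_id"].to_numpy(object),
            seed=seed,
        )

    @classmethod
    def read_csv(cls, path, stimulus_set: StimulusSet) -> "TrialTable":
        return cls.from_frame(pd.read_csv(path), stimulus_set)
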