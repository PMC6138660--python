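"""Labelled bait x prey matrices and their TSV representation.

Every stage of the pipeline passes around a rectangular matrix indexed by
bait ids (rows) and prey ids (columns): integer usable-read counts per
condition, detection frequencies, the marginal-product null, and interaction
scores. All of them share one base container with TSV round-tripping; the
subclasses only add stage-specific metadata and validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "ScreenMatrix",
    "CountMatrix",
    "FrequencyMatrix",
    "NullMatrix",
    "ISMatrix",
]

#: Growth conditions of a pooled screen: recombination-selection (RS, tracks
#: clone representation) and recombination-interaction-selection (RIS, tracks
#: reporter-activating bait-prey pairs).
CONDITIONS = ("RS", "RIS")


@dataclass
class ScreenMatrix:
    """A dense matrix with bait row labels and prey column labels."""

    baits: list[str]
    preys: list[str]
    values: np.ndarray
    condition: str | None = None

    def __post_init__(self) -> None:
        self.baits = list(self.baits)
        self.preys = list(self.preys)
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.baits), len(self.preys)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.baits)} baits x {len(self.preys)} preys"
            )
        if len(set(self.baits)) != len(self.baits):
            raise ValueError("duplicate bait ids")
        if len(set(self.preys)) != len(self.preys):
            raise ValueError("duplicate prey ids")
        if self.condition is not None and self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def bait_index(self, bait: str) -> int:
        return self.baits.index(bait)

    def prey_index(self, prey: str) -> int:
        return self.preys.index(prey)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        bait, prey = pair
        return self.values[self.bait_index(bait), self.prey_index(prey)]

    def same_labels(self, other: "ScreenMatrix") -> bool:
        return self.baits == other.baits and self.preys == other.preys

    def require_same_labels(self, other: "ScreenMatrix") -> None:
        if not self.same_labels(other):
            raise ValueError("bait/prey id ordering differs between matrices")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.baits, columns=self.preys)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="bait")

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, condition: str | None = None
    ) -> "ScreenMatrix":
        return cls(
            baits=[str(b) for b in frame.index],
            preys=[str(p) for p in frame.columns],
            values=frame.to_numpy(),
            condition=condition,
        )

    @classmethod
    def from_tsv(cls, path: str | Path, condition: str | None = None) -> "ScreenMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_dataframe(frame, condition=condition)


@dataclass
class CountMatrix(ScreenMatrix):
    """Usable read-pair counts N(x, y) for one screen condition."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.rint(self.values)
            if not np.allclose(self.values, rounded):
                raise ValueError("count matrix must contain integers")
            self.values = rounded.astype(np.int64)
        if (self.values < 0).any():
            raise ValueError("count matrix must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.values.sum())


@dataclass
class FrequencyMatrix(ScreenMatrix):
    """Detection frequencies F(x, y) = N(x, y) / sum(N); sums to 1 (or 0)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("frequencies must be nonnegative")

    def row_marginals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def col_marginals(self) -> np.ndarray:
        return self.values.sum(axis=0)


@dataclass
class NullMatrix(ScreenMatrix):
    """Independence null F_phi(x, y) = F_RS(x) * F_RS(y) from RS marginals."""

    row_marginal: np.ndarray = field(default=None)  # type: ignore[assignment]
    col_marginal: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = np.asarray(self.values, dtype=float)
        if self.row_marginal is None or self.col_marginal is None:
            raise ValueError("null matrix requires the RS marginals it was built from")
        self.row_marginal = np.asarray(self.row_marginal, dtype=float)
        self.col_marginal = np.asarray(self.col_marginal, dtype=float)


@dataclass
class ISMatrix(ScreenMatrix):
    """Interaction scores; ``flagged`` marks cells scored against the null floor.

    A cell is flagged when its null expectation was exactly zero while signal
    was present, so the score was computed against the smallest positive null
    entry instead of dropped (see :func:`recynh.scoring.interaction_score`).
    """

    flagged: np.ndarray | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = np.asarray(self.values, dtype=float)
        if self.flagged is not None:
            self.flagged = np.asarray(self.flagged, dtype=bool)
            if self.flagged.shape != self.values.shape:
                raise ValueError("flag mask shape must match score matrix")
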