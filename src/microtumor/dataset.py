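"""The ROI x protein expression container and its processing-state machine.

An :class:`ExpressionDataset` holds one count (or count-density) matrix with
one row per profiled region of interest (ROI) plus per-ROI metadata: the
tissue it came from, the UV-illuminated mask area in square microns and the
image-derived fraction of CD45+ (immune) cells. The ``state`` attribute
tracks where the data sit in the processing chain

    raw -> ercc_normalized -> background_subtracted -> density -> log
        -> standardized

and every processing step validates the state it requires, so steps cannot
be reordered or repeated silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

STATES = (
    "raw",
    "ercc_normalized",
    "background_subtracted",
    "density",
    "log",
    "standardized",
)

META_COLUMNS = ("tissue_id", "mask_area", "cd45_fraction")


@dataclass
class ExpressionDataset:
    """ROI x protein matrix with ROI metadata and a processing state.

    Attributes
    ----------
    matrix
        ROI x protein values, indexed by ROI id (string). Includes control
        columns (IgG isotypes, ERCC spike-ins) until they are dropped by an
        analysis step.
    roi_meta
        Per-ROI metadata indexed identically: ``tissue_id``, ``mask_area``
        (squared-length units, e.g. µm² or mm²; the synthetic generators use
        mm²), ``cd45_fraction`` and, once assigned, ``compartment``.
    state
        Position in the processing chain (see module docstring).
    control_columns
        Names of columns that are controls rather than biological targets.
    scaling_params
        Per-protein ``mean``/``sd`` recorded by standardization.
    """

    matrix: pd.DataFrame
    roi_meta: pd.DataFrame
    state: str = "raw"
    control_columns: list[str] = field(default_factory=list)
    scaling_params: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if not self.matrix.index.equals(self.roi_meta.index):
            raise ValueError("matrix and roi_meta must share the same ROI index")
        for col in META_COLUMNS:
            if col not in self.roi_meta.columns:
                raise ValueError(f"roi_meta missing required column {col!r}")
        self.matrix.index = self.matrix.index.astype(str)
        self.roi_meta.index = self.roi_meta.index.astype(str)
        if self.matrix.index.has_duplicates:
            raise ValueError("duplicate ROI ids")
        if self._state_index() < STATES.index("log"):
            if (self.matrix.to_numpy() < 0).any():
                raise ValueError(f"negative values not allowed in state {self.state!r}")
        area = self.roi_meta["mask_area"].to_numpy(dtype=float)
        if (area <= 0).any():
            bad = self.roi_meta.index[area <= 0].tolist()
            raise ValueError(f"mask_area must be positive; offending ROIs: {bad}")
        frac = self.roi_meta["cd45_fraction"].to_numpy(dtype=float)
        if ((frac < 0) | (frac > 1)).any():
            bad = self.roi_meta.index[(frac < 0) | (frac > 1)].tolist()
            raise ValueError(f"cd45_fraction must lie in [0, 1]; offending ROIs: {bad}")

    def _state_index(self) -> int:
        return STATES.index(self.state)

    def require_state(self, state: str) -> None:
        if self.state != state:
            raise ValueError(
                f"operation requires state {state!r}, dataset is in {self.state!r}"
            )

    def advance_state(self, new_state: str) -> None:
        """Move to ``new_state``; only the next state in the chain is legal."""
        new_idx = STATES.index(new_state)
        if new_idx != self._state_index() + 1:
            raise ValueError(
                f"illegal state transition {self.state!r} -> {new_state!r}"
            )
        self.state = new_state

    @property
    def target_columns(self) -> list[str]:
        ctrl = set(self.control_columns)
        return [c for c in self.matrix.columns if c not in ctrl]

    @property
    def n_rois(self) -> int:
        return len(self.matrix)

    def targets(self) -> pd.DataFrame:
        """Matrix restricted to biological target columns."""
        return self.matrix[self.target_columns]

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            matrix=self.matrix.copy(),
            roi_meta=self.roi_meta.copy(),
            state=self.state,
            control_columns=list(self.control_columns),
            scaling_params=None if self.scaling_params is None else self.scaling_params.copy(),
        )

    def subset_rois(self, roi_ids: Sequence[str]) -> "ExpressionDataset":
        roi_ids = list(roi_ids)
        missing = [r for r in roi_ids if r not in self.matrix.index]
        if missing:
            raise KeyError(f"unknown ROI ids: {missing}")
        return ExpressionDataset(
            matrix=self.matrix.loc[roi_ids].copy(),
            roi_meta=self.roi_meta.loc[roi_ids].copy(),
            state=self.state,
            control_columns=list(self.control_columns),
        )

    def with_compartments(self, labels: pd.Series) -> "ExpressionDataset":
        """Return a copy with per-ROI compartment labels attached."""
        out = self.copy()
        out.roi_meta["compartment"] = labels.reindex(out.roi_meta.index)
        return out

    def equals(self, other: "ExpressionDataset") -> bool:
        return (
            self.state == other.state
            and list(self.control_columns) == list(other.control_columns)
            and self.matrix.equals(other.matrix)
            and self.roi_meta[list(META_COLUMNS)].equals(other.roi_meta[list(META_COLUMNS)])
        )


def geometric_mean(values: np.ndarray, axis: int | None = None) -> np.ndarray:
    """Geometric mean of strictly positive values."""
    values = np.asarray(values, dtype=float)
    if (values <= 0).any():
        raise ValueError("geometric mean requires strictly positive values")
    return np.exp(np.mean(np.log(values), axis=axis))
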