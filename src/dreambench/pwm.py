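"""Position weight matrices.

A PWM describes the per-position symbol preferences of a binding domain
(kinase, PDZ, SH3, transcription factor ...). Rows are symbols, columns are
sequence positions, and every column is a probability simplex: entries are
non-negative and sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: tolerance on the per-column probability sum
COLUMN_SUM_TOL = 1e-9


@dataclass
class PWMatrix:
    """A position weight matrix (rows = symbols, columns = positions)."""

    values: np.ndarray
    name: str = field(default="")

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.size == 0:
            raise ValidationError(
                f"PWM {self.name!r}: expected a non-empty 2-D matrix, "
                f"got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError(f"PWM {self.name!r}: non-finite entries")
        if np.any(values < 0):
            raise ValidationError(f"PWM {self.name!r}: negative entries")
        sums = values.sum(axis=0)
        bad = np.flatnonzero(np.abs(sums - 1.0) > COLUMN_SUM_TOL)
        if bad.size:
            raise ValidationError(
                f"PWM {self.name!r}: column(s) {bad.tolist()} sum to "
                f"{sums[bad].tolist()}, expected 1 within {COLUMN_SUM_TOL}"
            )
        object.__setattr__(self, "values", values)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


def normalize_columns(values: np.ndarray) -> np.ndarray:
    """Rescale each column of a non-negative matrix to sum to one."""
    values = np.asarray(values, dtype=float)
    sums = values.sum(axis=0)
    if np.any(sums <= 0):
        raise ValidationError("cannot normalize a column with non-positive sum")
    return values / sums
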