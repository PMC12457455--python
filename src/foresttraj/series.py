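"""Container for one analysis cell's annual categorical land-cover grids."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LCSeries:
    """Annual categorical grids for one cell: (years, rows, cols) class codes."""

    data: np.ndarray
    cell_id: str = "cell"
    years: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LCSeries data must be (years, rows, cols)")
        if self.years is None:
            self.years = np.arange(self.data.shape[0])
        self.years = np.asarray(self.years)
        if len(self.years) != self.data.shape[0]:
            raise ValueError("years length mismatch")

    @property
    def n_years(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape[1:]

    @property
    def cell_size(self) -> int:
        return self.data.shape[1] * self.data.shape[2]

    def mask(self, year_index: int, class_code: int) -> np.ndarray:
        """Boolean mask of one class at one year."""
        return self.data[year_index] == class_code

    def class_counts(self, class_code: int) -> np.ndarray:
        """Pixel count of a class per year (length n_years)."""
        return (self.data == class_code).sum(axis=(1, 2))
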