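"""Item-response data: loading, validation and missingness handling."""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

DEFAULT_MISSING_CODES = ("", "NA")


class DataError(ValueError):
    """Raised for malformed or degenerate item-response input."""


@dataclass
class ItemResponseMatrix:
    """An n x k table of item scores with an observedness mask.

    ``values`` holds NaN wherever ``mask`` is False; complete cells are
    finite floats.  Invariants: at least 2 items, at least 2 respondents,
    every item observed at least twice, unique item names.
    """

    values: np.ndarray
    mask: np.ndarray
    item_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D array")
        if self.mask.shape != self.values.shape:
            raise DataError("mask shape must match values shape")
        n, k = self.values.shape
        if k < 2:
            raise DataError(f"need at least 2 items, got {k}")
        if n < 2:
            raise DataError(f"need at least 2 respondents, got {n}")
        self.item_names = tuple(str(s) for s in self.item_names)
        if len(self.item_names) != k:
            raise DataError("item_names length must equal the number of items")
        if len(set(self.item_names)) != k:
            raise DataError("item_names must be unique")
        per_item = self.mask.sum(axis=0)
        if (per_item < 2).any():
            bad = [self.item_names[i] for i in np.where(per_item < 2)[0]]
            raise DataError(f"items with fewer than 2 observed values: {bad}")
        # enforce the values/mask correspondence
        self.values = np.where(self.mask, self.values, np.nan)
        if not np.isfinite(self.values[self.mask]).all():
            raise DataError("non-finite value in an observed cell")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int((~self.mask).sum())

    @property
    def complete_rows(self) -> np.ndarray:
        """Boolean selector of rows with no missing cell."""
        return self.mask.all(axis=1)

    def complete_cases(self) -> "ItemResponseMatrix":
        """Listwise-deleted view (rows with any missing cell removed)."""
        sel = self.complete_rows
        if sel.sum() < 2:
            raise DataError("fewer than 2 complete rows after listwise deletion")
        return ItemResponseMatrix(
            values=self.values[sel], mask=self.mask[sel], item_names=self.item_names
        )

    def drop_item(self, index: int) -> "ItemResponseMatrix":
        if not 0 <= index < self.k:
            raise DataError(f"item index {index} out of range for k={self.k}")
        keep = [j for j in range(self.k) if j != index]
        return ItemResponseMatrix(
            values=self.values[:, keep],
            mask=self.mask[:, keep],
            item_names=tuple(self.item_names[j] for j in keep),
        )

    @classmethod
    def from_values(cls, values: np.ndarray,
                    item_names: Optional[Sequence[str]] = None) -> "ItemResponseMatrix":
        """Wrap a numeric array; NaN cells are treated as missing."""
        values = np.asarray(values, dtype=float)
        if item_names is None:
            item_names = [f"item_{j + 1}" for j in range(values.shape[1])]
        return cls(values=values, mask=np.isfinite(values), item_names=tuple(item_names))


def read_item_data(
    path: Union[str, Path],
    missing_codes: Iterable[str] = DEFAULT_MISSING_CODES,
) -> ItemResponseMatrix:
    """Read a comma-separated item-response table with a header row.

    Cells equal to one of ``missing_codes`` (after stripping whitespace) or
    empty are marked missing.  Any other non-numeric cell raises a
    :class:`DataError` naming its row and column.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    codes = {str(c).strip() for c in missing_codes} | {""}
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    if raw.shape[1] < 2:
        raise DataError(f"need at least 2 columns, found {raw.shape[1]} in {path}")
    names = [str(c).strip().strip('"') for c in raw.columns]
    n, k = raw.shape
    values = np.full((n, k), np.nan)
    mask = np.zeros((n, k), dtype=bool)
    for j, col in enumerate(raw.columns):
        cells = raw[col].astype(str).str.strip()
        for i, cell in enumerate(cells):
            if cell in codes:
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise DataError(
                    f"non-numeric cell {cell!r} at row {i + 2} (1-based, incl. "
                    f"header), column {names[j]!r} of {path}"
                ) from None
            mask[i, j] = True
    return ItemResponseMatrix(values=values, mask=mask, item_names=tuple(names))


def load_example() -> ItemResponseMatrix:
    """Bundled 78 x 5 mania-scale example dataset (0-4 Likert items)."""
    ref = importlib.resources.files("relicred.datasets").joinpath("asrm.csv")
    with importlib.resources.as_file(ref) as p:
        return read_item_data(p)
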