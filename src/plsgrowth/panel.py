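"""Panel-survey data container and ingestion.

A panel table holds one row per respondent and one column per survey item,
where repeated constructs contribute one set of item columns per wave.
Missing responses are tracked explicitly so that imputation is an auditable,
separate step rather than a side effect of parsing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PanelTable", "load_panel_csv", "impute_mean"]


class PanelDataError(ValueError):
    """Raised for malformed panel data or invalid item references."""


@dataclass
class PanelTable:
    """Respondent x item matrix of numeric survey responses.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric responses, one row per respondent, one column per item.
        Cells flagged in ``missing_mask`` hold NaN until imputation.
    missing_mask : pandas.DataFrame of bool, optional
        True where the original response was missing. Defaults to the NaN
        pattern of ``values``.
    """

    values: pd.DataFrame
    missing_mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.missing_mask is None:
            self.missing_mask = self.values.isna()
        if len(self.values) < 3:
            raise PanelDataError(
                f"panel needs at least 3 respondents, got {len(self.values)}"
            )
        dup = self.values.columns[self.values.columns.duplicated()]
        if len(dup):
            raise PanelDataError(f"duplicate item column(s): {sorted(set(dup))}")

    @property
    def item_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_respondents(self) -> int:
        return len(self.values)

    @property
    def has_missing(self) -> bool:
        """True while any cell still awaits imputation.

        ``missing_mask`` keeps recording which cells were originally
        missing even after imputation fills them in.
        """
        return bool(self.values.isna().to_numpy().any())

    def require_items(self, items: list[str]) -> None:
        """Raise if any requested item is absent from the table."""
        absent = [it for it in items if it not in self.values.columns]
        if absent:
            raise PanelDataError(f"item(s) not found in panel table: {absent}")

    def copy(self) -> "PanelTable":
        return PanelTable(self.values.copy(), self.missing_mask.copy())


def load_panel_csv(path, na_tokens: set[str] | None = None) -> PanelTable:
    """Read a wide-format panel CSV (header row, one row per respondent).

    Parameters
    ----------
    path : str or Path
        CSV file with a header row of item names.
    na_tokens : set of str, optional
        Strings to treat as missing responses (e.g. ``{"NA", ""}``).
        Only these tokens and empty cells are accepted as missing.

    Returns
    -------
    PanelTable
        With ``missing_mask`` true at every declared-NA cell.
    """
    na_tokens = set(na_tokens or {"NA", "NaN", ""})
    with open(path) as fh:
        header = [h.strip() for h in next(csv.reader(fh))]
    dup = sorted({h for h in header if header.count(h) > 1})
    if dup:
        raise PanelDataError(f"duplicate column name(s) in {path}: {dup}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    mask = raw.isin(na_tokens) | (raw == "")
    numeric = raw.mask(mask).apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~mask
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        r, c = rows[0], cols[0]
        raise PanelDataError(
            f"non-numeric cell {raw.iat[r, c]!r} at row {r + 2} "
            f"(1-based incl. header), column {raw.columns[c]!r}"
        )
    return PanelTable(numeric, mask)


def impute_mean(table: PanelTable) -> PanelTable:
    """Replace each missing cell with the observed mean of its item column.

    Mean replacement is applied per item, before any standardization, so
    imputation never shifts an item's observed mean. Observed cells are
    left untouched.

    Raises
    ------
    PanelDataError
        If any column has no observed value at all.
    """
    if not table.has_missing:
        return table
    fully_missing = [
        c for c in table.values.columns if table.missing_mask[c].all()
    ]
    if fully_missing:
        raise PanelDataError(f"column(s) fully missing, cannot impute: {fully_missing}")
    filled = table.values.fillna(table.values.mean())
    return PanelTable(filled, table.missing_mask.copy())
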