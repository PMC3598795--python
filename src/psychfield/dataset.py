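"""Respondent-level response data: validation and CSV I/O.

A :class:`ResponseDataset` holds the raw (untransformed) ordinal responses,
one row per respondent and one column per item, plus optional respondent
metadata: age in years and 5-level self-reported health status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .instrument import RESERVED_COLUMNS, InstrumentSpec

__all__ = ["ResponseDataset", "ResponseDataError", "load_responses", "HEALTH_LEVELS"]

HEALTH_LEVELS = ("excellent", "very good", "good", "fair", "poor")


class ResponseDataError(ValueError):
    """Raised when a response table violates the instrument's constraints."""


@dataclass
class ResponseDataset:
    """Raw responses (respondents x items) with respondent metadata.

    ``raw`` is a float DataFrame indexed by respondent id with one column per
    item id in instrument order; missing cells are NaN.  ``age`` and
    ``health_status`` are Series aligned to the same index (may be empty).
    """

    raw: pd.DataFrame
    age: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    health_status: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        if not self.age.empty:
            self.age = self.age.reindex(self.raw.index)
        if not self.health_status.empty:
            self.health_status = self.health_status.reindex(self.raw.index)

    @property
    def respondent_ids(self) -> list:
        return list(self.raw.index)

    @property
    def n_respondents(self) -> int:
        return len(self.raw)

    def validate(self, spec: InstrumentSpec) -> None:
        """Check column set and admissible values against the instrument."""
        expected = list(spec.item_ids)
        got = list(self.raw.columns)
        if set(got) != set(expected):
            missing = sorted(set(expected) - set(got))
            extra = sorted(set(got) - set(expected))
            raise ResponseDataError(
                f"item columns do not match instrument: missing={missing}, unknown={extra}"
            )
        values = self.raw.to_numpy(dtype=float)
        ok = np.isnan(values) | np.isin(values, np.asarray(spec.scale_points, dtype=float))
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise ResponseDataError(
                f"value {values[r, c]!r} at respondent {self.raw.index[r]!r}, "
                f"item {self.raw.columns[c]!r} not in scale_points {spec.scale_points}"
            )
        bad_hs = [
            v for v in self.health_status.dropna().unique() if v not in HEALTH_LEVELS
        ]
        if bad_hs:
            raise ResponseDataError(
                f"unknown health_status value(s) {bad_hs}; expected one of {HEALTH_LEVELS}"
            )

    def to_csv(self, path: str | Path) -> None:
        """Write the wide CSV (id, age, health_status, then item columns)."""
        out = self.raw.copy()
        if not self.health_status.empty:
            out.insert(0, "health_status", self.health_status)
        if not self.age.empty:
            out.insert(0, "age", self.age)
        out.index.name = "id"
        # raw values are integers; render 3 not 3.0, blank for missing
        out.to_csv(path, float_format="%g")


def load_responses(
    path: str | Path,
    spec: InstrumentSpec,
    missing_sentinels: tuple[str, ...] = ("", "NA"),
) -> ResponseDataset:
    """Read a wide response CSV and validate it against the instrument.

    The CSV needs an ``id`` column (or the items in instrument order with an
    unnamed first index column), one column per item id, and may carry ``age``
    and ``health_status`` metadata columns.  Blank cells and the configured
    sentinels (default empty string and "NA") are treated as missing.
    """
    df = pd.read_csv(
        path,
        dtype=str,
        keep_default_na=False,
        na_values=list(missing_sentinels),
        skipinitialspace=True,
    )
    if "id" in df.columns:
        df = df.set_index("id")
    else:
        df = df.set_index(df.columns[0])

    known = set(spec.item_ids) | set(RESERVED_COLUMNS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ResponseDataError(f"unknown column(s) in response CSV: {unknown}")
    missing_items = [c for c in spec.item_ids if c not in df.columns]
    if missing_items:
        raise ResponseDataError(f"response CSV lacks item column(s): {missing_items}")

    raw = df[list(spec.item_ids)].apply(pd.to_numeric, errors="coerce")
    # cells that were non-missing text but failed numeric conversion
    text_mask = df[list(spec.item_ids)].notna() & raw.isna()
    if text_mask.to_numpy().any():
        r, c = np.argwhere(text_mask.to_numpy())[0]
        raise ResponseDataError(
            f"non-numeric value {df[list(spec.item_ids)].iat[r, c]!r} at "
            f"respondent {df.index[r]!r}, item {spec.item_ids[c]!r}"
        )

    age = (
        pd.to_numeric(df["age"], errors="coerce")
        if "age" in df.columns
        else pd.Series(dtype=float)
    )
    hs = (
        df["health_status"].str.strip().str.lower()
        if "health_status" in df.columns
        else pd.Series(dtype=object)
    )
    ds = ResponseDataset(raw=raw, age=age, health_status=hs)
    ds.validate(spec)
    return ds
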