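"""Scoring engine and feasibility metrics.

Raw ordinal responses are reverse scored and linearly transformed to 0-100
(0 -> 100, 1 -> 75, 2 -> 50, 3 -> 25, 4 -> 0), so higher scores signify
better functioning / fewer problems.  A subscale score is the mean of its
answered transformed items; it is left missing when *more than* half of the
subscale's items are missing (exactly half missing still scores).  The Total
Score is the item-weighted mean over all analyzed items (67 by default) --
not the mean of subscale scores -- under the same more-than-half rule.

Feasibility is the percentage of missing item responses, per subscale and
overall.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ResponseDataset
from .instrument import InstrumentSpec

__all__ = [
    "TOTAL_SCORE",
    "transform_item",
    "score_subscale",
    "score_total",
    "score_dataset",
    "ScoreTable",
    "FeasibilityReport",
    "feasibility_report",
]

TOTAL_SCORE = "Total Score"


def transform_item(raw, scale_points: tuple[int, ...] = (0, 1, 2, 3, 4)):
    """Reverse score and linearly transform raw value(s) to the 0-100 scale.

    For the default 5-point scale: score = 25 * (4 - raw).  Accepts scalars
    or arrays; NaN propagates (missing in, missing out).
    """
    lo, hi = scale_points[0], scale_points[-1]
    arr = np.asarray(raw, dtype=float)
    with np.errstate(invalid="ignore"):
        ok = np.isnan(arr) | np.isin(arr, np.asarray(scale_points, dtype=float))
    if not np.all(ok):
        bad = arr[~ok].flat[0]
        raise ValueError(f"raw value {bad!r} not in scale points {scale_points}")
    out = 100.0 * (hi - arr) / (hi - lo)
    return out if np.ndim(raw) else float(out)


def _mean_with_half_rule(transformed: np.ndarray) -> float:
    """Mean of answered values; NaN when more than 50% are missing."""
    n = transformed.size
    n_missing = int(np.isnan(transformed).sum())
    if n_missing * 2 > n:
        return float("nan")
    return float(np.nanmean(transformed))


def score_subscale(
    responses, spec: InstrumentSpec | None = None
) -> float:
    """Score one respondent on one subscale from raw responses.

    ``responses`` is the sequence of raw values (with NaN/None for missing)
    for every item of the subscale.  Returns the mean transformed score, or
    NaN when more than 50% of the items are missing.
    """
    scale_points = spec.scale_points if spec is not None else (0, 1, 2, 3, 4)
    arr = np.array([np.nan if r is None else r for r in np.ravel(responses)], dtype=float)
    return _mean_with_half_rule(np.asarray(transform_item(arr, scale_points)))


def score_total(responses: pd.Series, spec: InstrumentSpec) -> float:
    """Total Score for one respondent: item-weighted mean over analyzed items."""
    arr = responses.reindex(list(spec.analyzed_item_ids)).to_numpy(dtype=float)
    return _mean_with_half_rule(np.asarray(transform_item(arr, spec.scale_points)))


@dataclass
class ScoreTable:
    """Respondents x (subscale scores + Total Score), 0-100 scale.

    ``items_answered`` counts answered items per respondent per subscale
    (Total Score column counts answered analyzed items).
    """

    scores: pd.DataFrame
    items_answered: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        out = self.scores.copy()
        out.index.name = "id"
        out.to_csv(path, float_format="%.10g")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.scores.to_json(orient="index", indent=2))


def score_dataset(ds: ResponseDataset, spec: InstrumentSpec) -> ScoreTable:
    """Score every respondent on every subscale and the Total Score."""
    ds.validate(spec)
    transformed = pd.DataFrame(
        transform_item(ds.raw.to_numpy(dtype=float), spec.scale_points),
        index=ds.raw.index,
        columns=ds.raw.columns,
    )
    scores: dict[str, pd.Series] = {}
    answered: dict[str, pd.Series] = {}
    for sub in spec.subscales:
        block = transformed[list(sub.item_ids)]
        n_ans = block.notna().sum(axis=1)
        mean = block.mean(axis=1)  # nanmean over answered
        mean[n_ans * 2 < sub.n_items] = np.nan
        scores[sub.name] = mean
        answered[sub.name] = n_ans
    total_block = transformed[list(spec.analyzed_item_ids)]
    n_ans = total_block.notna().sum(axis=1)
    total = total_block.mean(axis=1)
    total[n_ans * 2 < len(spec.analyzed_item_ids)] = np.nan
    scores[TOTAL_SCORE] = total
    answered[TOTAL_SCORE] = n_ans
    return ScoreTable(scores=pd.DataFrame(scores), items_answered=pd.DataFrame(answered))


@dataclass
class FeasibilityReport:
    """Missing-response accounting per subscale and overall.

    ``per_subscale`` columns: items, expected (respondents x items), missing,
    missing_pct.  ``overall_pct`` is over the analyzed subscales;
    ``overall_pct_all`` additionally includes excluded (e.g. sensitive)
    subscales, since either convention is defensible for a headline figure.
    """

    per_subscale: pd.DataFrame
    overall_pct: float
    overall_pct_all: float
    n_respondents: int

    def to_csv(self, path: str | Path) -> None:
        out = self.per_subscale.copy()
        out.index.name = "subscale"
        out.to_csv(path, float_format="%.10g")

    def to_json(self, path: str | Path) -> None:
        d = {
            "n_respondents": self.n_respondents,
            "overall_pct": self.overall_pct,
            "overall_pct_all": self.overall_pct_all,
            "per_subscale": self.per_subscale.to_dict(orient="index"),
        }
        import json

        Path(path).write_text(json.dumps(d, indent=2))


def feasibility_report(
    ds: ResponseDataset, spec: InstrumentSpec, include_excluded: bool = False
) -> FeasibilityReport:
    """Percentage of missing item responses per subscale and overall.

    Denominators count every cell of every respondent in the dataset,
    including respondents who skipped entire pages.  ``include_excluded``
    selects which overall figure (analyzed-only vs all subscales) is surfaced
    as ``overall_pct``; both are always computed.
    """
    if ds.n_respondents == 0:
        raise ValueError("empty dataset: no respondents")
    ds.validate(spec)
    n = ds.n_respondents
    rows = {}
    for sub in spec.subscales:
        expected = n * sub.n_items
        missing = int(ds.raw[list(sub.item_ids)].isna().to_numpy().sum())
        rows[sub.name] = {
            "items": sub.n_items,
            "expected": expected,
            "missing": missing,
            "missing_pct": 100.0 * missing / expected,
        }
    per = pd.DataFrame.from_dict(rows, orient="index")
    analyzed = [s.name for s in spec.analyzed_subscales]
    pct_analyzed = 100.0 * per.loc[analyzed, "missing"].sum() / per.loc[analyzed, "expected"].sum()
    pct_all = 100.0 * per["missing"].sum() / per["expected"].sum()
    overall = pct_all if include_excluded else pct_analyzed
    return FeasibilityReport(
        per_subscale=per,
        overall_pct=float(overall),
        overall_pct_all=float(pct_all),
        n_respondents=n,
    )
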