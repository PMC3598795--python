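"""Multitrait scaling analysis: item convergent/discriminant validity.

Each analyzed item is correlated (Pearson, pairwise deletion) with every
analyzed subscale score.  The correlation with the item's own subscale is
corrected for overlap: the subscale score is recomputed without the item, so
the item never correlates with a sum containing itself.  Two tests follow:

* item discrimination: corrected own-scale r >= 0.40 passes;
* scaling success: for each competitor subscale, the item succeeds when its
  own-scale correlation exceeds the competitor correlation by at least two
  standard errors.  The default operationalisation is the Fisher-z
  difference, z(r_own) - z(r_other) >= 2 * sqrt(2 / (n - 3)), treating the
  two correlations as independent; a raw-difference variant
  (r_own - r_other >= 2 / sqrt(n - 3)) is available.  The method used is
  recorded in every output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ResponseDataset
from .instrument import InstrumentSpec
from .scoring import transform_item

__all__ = [
    "ItemScaleMatrix",
    "ScalingTestResult",
    "item_scale_correlations",
    "discrimination_flags",
    "scaling_test",
    "multitrait_summary",
]


def _pairwise_corr(x: pd.Series, y: pd.Series) -> tuple[float, int]:
    """Pearson r and n on the pairwise-complete subset; NaN r if degenerate."""
    mask = x.notna() & y.notna()
    n = int(mask.sum())
    if n < 4:
        return float("nan"), n
    xv = x[mask].to_numpy(dtype=float)
    yv = y[mask].to_numpy(dtype=float)
    if xv.std(ddof=1) == 0 or yv.std(ddof=1) == 0:
        return float("nan"), n
    return float(np.corrcoef(xv, yv)[0, 1]), n


def _half_rule_mean(block: pd.DataFrame) -> pd.Series:
    """Row mean of answered transformed items; NaN when > 50% missing."""
    n_items = block.shape[1]
    mean = block.mean(axis=1)
    mean[block.notna().sum(axis=1) * 2 < n_items] = np.nan
    return mean


@dataclass
class ItemScaleMatrix:
    """Analyzed items x analyzed subscales correlation matrix.

    ``r``: Pearson correlations; the cell in an item's own column uses the
    subscale score recomputed without that item (correction for overlap).
    ``n``: pairwise-complete case count per cell.  ``own_scale`` maps each
    item to its subscale.  ``undefined_cells`` lists (item, subscale) cells
    where a zero-variance margin left the correlation undefined.
    """

    r: pd.DataFrame
    n: pd.DataFrame
    own_scale: pd.Series
    undefined_cells: list[tuple[str, str]] = field(default_factory=list)

    def own_r(self, item_id: str) -> float:
        return float(self.r.at[item_id, self.own_scale[item_id]])


def item_scale_correlations(ds: ResponseDataset, spec: InstrumentSpec) -> ItemScaleMatrix:
    """Correlate every analyzed item with every analyzed subscale score."""
    ds.validate(spec)
    transformed = pd.DataFrame(
        transform_item(ds.raw.to_numpy(dtype=float), spec.scale_points),
        index=ds.raw.index,
        columns=ds.raw.columns,
    )
    subs = spec.analyzed_subscales
    scale_scores = {
        s.name: _half_rule_mean(transformed[list(s.item_ids)]) for s in subs
    }
    items = list(spec.analyzed_item_ids)
    own = {i: spec.owner_of(i).name for i in items}
    r = pd.DataFrame(index=items, columns=[s.name for s in subs], dtype=float)
    n = pd.DataFrame(0, index=items, columns=[s.name for s in subs], dtype=int)
    undefined: list[tuple[str, str]] = []
    for s in subs:
        for item in items:
            if own[item] == s.name:
                rest = [j for j in s.item_ids if j != item]
                score = _half_rule_mean(transformed[rest])
            else:
                score = scale_scores[s.name]
            rv, nv = _pairwise_corr(transformed[item], score)
            r.at[item, s.name] = rv
            n.at[item, s.name] = nv
            if np.isnan(rv):
                undefined.append((item, s.name))
    if undefined:
        warnings.warn(
            f"{len(undefined)} undefined item-scale correlation cell(s) "
            "(zero variance or < 4 pairwise cases); excluded from scaling tests",
            stacklevel=2,
        )
    return ItemScaleMatrix(
        r=r, n=n, own_scale=pd.Series(own), undefined_cells=undefined
    )


def discrimination_flags(m: ItemScaleMatrix, cutoff: float = 0.40) -> pd.DataFrame:
    """Per-item discrimination test: corrected own-scale r >= cutoff passes."""
    rows = {
        item: {
            "own_scale": m.own_scale[item],
            "r_own": m.own_r(item),
            "passes": bool(m.own_r(item) >= cutoff),
        }
        for item in m.r.index
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def scaling_test(
    r_own: float, r_other: float, n: int, method: str = "fisher_z"
) -> tuple[float, float, bool]:
    """One item scaling test: does r_own beat r_other by >= 2 SE?

    Returns (statistic, threshold, success).  Under ``fisher_z`` the
    statistic is z(r_own) - z(r_other) against 2*sqrt(2/(n-3)); under
    ``raw_diff`` it is r_own - r_other against 2/sqrt(n-3).
    """
    if n < 4:
        raise ValueError(f"scaling test needs n >= 4, got {n}")
    if not (np.isfinite(r_own) and np.isfinite(r_other)) and not (
        abs(r_own) == 1 or abs(r_other) == 1
    ):
        raise ValueError("correlations must be defined")
    if r_own == r_other:
        # zero difference can never reach 2 SE, including the +-1 edge
        method_thr = 2.0 * np.sqrt(2.0 / (n - 3)) if method == "fisher_z" else 2.0 / np.sqrt(n - 3)
        return 0.0, float(method_thr), False
    if method == "fisher_z":
        stat = float(np.arctanh(r_own) - np.arctanh(r_other))  # +-inf at |r|=1
        thr = float(2.0 * np.sqrt(2.0 / (n - 3)))
    elif method == "raw_diff":
        stat = float(r_own - r_other)
        thr = float(2.0 / np.sqrt(n - 3))
    else:
        raise ValueError(f"unknown method {method!r}; use 'fisher_z' or 'raw_diff'")
    return stat, thr, bool(stat >= thr)


@dataclass
class ScalingTestResult:
    """All item scaling tests plus the per-subscale summary table.

    ``tests``: long frame, one row per (item, competitor subscale) with
    columns (item, own_scale, other_scale, r_own, r_other, n, statistic,
    threshold, outcome).  ``summary``: per subscale -- item count, signed
    min/max of corrected own-scale correlations (convergent range), signed
    min/max of competitor correlations (discriminant range), successes,
    total tests and the success rate in percent.  ``mean_success_rate`` /
    ``median_success_rate`` aggregate the subscale rates.
    """

    tests: pd.DataFrame
    summary: pd.DataFrame
    method: str
    mean_success_rate: float
    median_success_rate: float

    def to_csv(self, tests_path: str | Path, summary_path: str | Path | None = None) -> None:
        t = self.tests.copy()
        t.insert(0, "method", self.method)
        t.to_csv(tests_path, index=False, float_format="%.10g")
        if summary_path is not None:
            s = self.summary.copy()
            s.index.name = "subscale"
            s.to_csv(summary_path, float_format="%.10g")


def multitrait_summary(
    ds: ResponseDataset,
    spec: InstrumentSpec,
    method: str = "fisher_z",
    matrix: ItemScaleMatrix | None = None,
) -> ScalingTestResult:
    """Run every item scaling test and summarise per subscale.

    For each item, one test per competitor subscale: items x (analyzed
    subscales - 1) tests per subscale.  The n for a test is the smaller of
    the two cells' pairwise ns (most conservative under pairwise deletion).
    Undefined cells are excluded and shrink the denominator, with a warning.
    """
    m = matrix if matrix is not None else item_scale_correlations(ds, spec)
    sub_names = list(m.r.columns)
    records = []
    for item in m.r.index:
        own_name = m.own_scale[item]
        r_own = m.r.at[item, own_name]
        n_own = m.n.at[item, own_name]
        for other in sub_names:
            if other == own_name:
                continue
            r_other = m.r.at[item, other]
            n_other = m.n.at[item, other]
            if np.isnan(r_own) or np.isnan(r_other):
                records.append(
                    dict(item=item, own_scale=own_name, other_scale=other,
                         r_own=r_own, r_other=r_other, n=0, statistic=np.nan,
                         threshold=np.nan, outcome="undefined"))
                continue
            n_test = int(min(n_own, n_other))
            stat, thr, ok = scaling_test(float(r_own), float(r_other), n_test, method)
            records.append(
                dict(item=item, own_scale=own_name, other_scale=other,
                     r_own=float(r_own), r_other=float(r_other), n=n_test,
                     statistic=stat, threshold=thr,
                     outcome="success" if ok else "failure"))
    tests = pd.DataFrame.from_records(records)
    if (tests["outcome"] == "undefined").any():
        warnings.warn(
            "some scaling tests undefined (zero-variance cells); "
            "denominators shrunk accordingly",
            stacklevel=2,
        )

    rows = {}
    for s in spec.analyzed_subscales:
        item_ids = list(s.item_ids)
        sub_tests = tests[tests["own_scale"] == s.name]
        defined = sub_tests[sub_tests["outcome"] != "undefined"]
        own_r = m.r.loc[item_ids, s.name]
        other_cols = [c for c in sub_names if c != s.name]
        other_r = m.r.loc[item_ids, other_cols].to_numpy().ravel()
        other_r = other_r[~np.isnan(other_r)]
        successes = int((defined["outcome"] == "success").sum())
        total = int(len(defined))
        rows[s.name] = {
            "items": s.n_items,
            "own_r_min": float(np.nanmin(own_r)) if own_r.notna().any() else np.nan,
            "own_r_max": float(np.nanmax(own_r)) if own_r.notna().any() else np.nan,
            "other_r_min": float(other_r.min()) if other_r.size else np.nan,
            "other_r_max": float(other_r.max()) if other_r.size else np.nan,
            "successes": successes,
            "total_tests": total,
            "success_rate_pct": 100.0 * successes / total if total else np.nan,
        }
    summary = pd.DataFrame.from_dict(rows, orient="index")
    rates = summary["success_rate_pct"].dropna()
    return ScalingTestResult(
        tests=tests,
        summary=summary,
        method=method,
        mean_success_rate=float(rates.mean()),
        median_success_rate=float(rates.median()),
    )
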