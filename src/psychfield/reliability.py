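"""Internal-consistency reliability: Cronbach's alpha and item analysis.

Alpha is computed on the transformed 0-100 item scores (the transform is a
joint affine map of all items, so alpha is identical on raw 0-4 scores; the
choice is documented for reproducibility).  Case handling is complete-case
(listwise) within each scale by default, with a pairwise-covariance option.

Reliability benchmarks used in reporting: >= 0.70 supports group
comparisons, >= 0.90 supports individual-patient interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ResponseDataset
from .instrument import InstrumentSpec
from .scoring import TOTAL_SCORE, score_dataset, transform_item

__all__ = [
    "cronbach_alpha",
    "alpha_if_item_deleted",
    "ReliabilityReport",
    "reliability_report",
]


def _as_matrix(items_matrix) -> np.ndarray:
    m = np.asarray(
        items_matrix.to_numpy() if isinstance(items_matrix, pd.DataFrame) else items_matrix,
        dtype=float,
    )
    if m.ndim != 2:
        raise ValueError("items_matrix must be 2-D (respondents x items)")
    return m


def cronbach_alpha(items_matrix, pairwise: bool = False) -> float:
    """Cronbach's coefficient alpha of a respondents x k item-score matrix.

    alpha = k/(k-1) * (1 - sum_i var(item_i) / var(total)), sample variances
    with denominator n-1.  Rows with any missing item are dropped unless
    ``pairwise`` is set, in which case variances and the total variance are
    assembled from the pairwise-complete covariance matrix.

    Raises for k < 2, fewer than 3 usable cases, or a degenerate
    (zero-total-variance) scale.  Negative alpha is returned as computed,
    with a warning.
    """
    m = _as_matrix(items_matrix)
    k = m.shape[1]
    if k < 2:
        raise ValueError(f"need >= 2 items, got {k}")
    if pairwise:
        df = pd.DataFrame(m)
        n_pair = df.notna().astype(int).T.dot(df.notna().astype(int)).to_numpy()
        if n_pair.min() < 3:
            raise ValueError("fewer than 3 pairwise-complete cases for some item pair")
        cov = df.cov(min_periods=3).to_numpy()  # pairwise by construction
        if np.isnan(cov).any():
            raise ValueError("pairwise covariance undefined for some item pair")
        var_total = float(cov.sum())
        var_items = float(np.trace(cov))
    else:
        complete = m[~np.isnan(m).any(axis=1)]
        if complete.shape[0] < 3:
            raise ValueError(
                f"insufficient cases: {complete.shape[0]} complete rows (< 3)"
            )
        var_total = float(complete.sum(axis=1).var(ddof=1))
        var_items = float(complete.var(axis=0, ddof=1).sum())
    if var_total <= 0:
        raise ValueError("degenerate scale: total score has zero variance")
    alpha = (k / (k - 1.0)) * (1.0 - var_items / var_total)
    if alpha < 0:
        warnings.warn(
            f"negative Cronbach's alpha ({alpha:.3f}); items may be scored in "
            "inconsistent directions",
            stacklevel=2,
        )
    return alpha


def alpha_if_item_deleted(items_matrix, pairwise: bool = False) -> pd.DataFrame:
    """Alpha of the scale with each item removed in turn.

    Returns a DataFrame indexed by item with columns ``alpha_if_deleted`` and
    ``improves`` (True where deleting the item raises alpha above the
    full-scale value).  Requires k >= 3: deleting from a 2-item scale leaves
    no scale.
    """
    is_df = isinstance(items_matrix, pd.DataFrame)
    m = _as_matrix(items_matrix)
    k = m.shape[1]
    if k < 3:
        raise ValueError(f"need >= 3 items to delete one, got {k}")
    labels = list(items_matrix.columns) if is_df else list(range(k))
    full = cronbach_alpha(m, pairwise=pairwise)
    vals = [
        cronbach_alpha(np.delete(m, i, axis=1), pairwise=pairwise) for i in range(k)
    ]
    return pd.DataFrame(
        {"alpha_if_deleted": vals, "improves": [v > full for v in vals]}, index=labels
    )


@dataclass
class ReliabilityReport:
    """Descriptive / reliability table plus per-item deletion diagnostics.

    ``table``: one row per analyzed subscale and the Total Score with columns
    (items, n, mean, sd, alpha); n, mean and sd describe respondents holding
    a non-missing scale score, which is why n varies by row under the
    more-than-half missing rule.  ``item_diagnostics``: per item (for scales
    with >= 3 items) the alpha-if-deleted value and an improvement flag.
    """

    table: pd.DataFrame
    item_diagnostics: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "scale"
        out.to_csv(path, float_format="%.10g")

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(
            json.dumps(self.table.to_dict(orient="index"), indent=2)
        )


def reliability_report(
    ds: ResponseDataset, spec: InstrumentSpec, pairwise: bool = False
) -> ReliabilityReport:
    """Reliability and descriptive statistics for every analyzed scale.

    Alpha for each subscale is computed over its items; the Total row's alpha
    treats all analyzed items (67 for the default instrument) as one scale.
    """
    scored = score_dataset(ds, spec)
    transformed = pd.DataFrame(
        transform_item(ds.raw.to_numpy(dtype=float), spec.scale_points),
        index=ds.raw.index,
        columns=ds.raw.columns,
    )
    rows = {}
    diags = []
    for sub in spec.analyzed_subscales:
        block = transformed[list(sub.item_ids)]
        s = scored.scores[sub.name].dropna()
        rows[sub.name] = {
            "items": sub.n_items,
            "n": int(s.size),
            "mean": float(s.mean()),
            "sd": float(s.std(ddof=1)),
            "alpha": cronbach_alpha(block, pairwise=pairwise),
        }
        if sub.n_items >= 3:
            d = alpha_if_item_deleted(block, pairwise=pairwise)
            d.insert(0, "subscale", sub.name)
            diags.append(d)
    total_block = transformed[list(spec.analyzed_item_ids)]
    t = scored.scores[TOTAL_SCORE].dropna()
    rows[TOTAL_SCORE] = {
        "items": len(spec.analyzed_item_ids),
        "n": int(t.size),
        "mean": float(t.mean()),
        "sd": float(t.std(ddof=1)),
        "alpha": cronbach_alpha(total_block, pairwise=pairwise),
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    item_diag = pd.concat(diags) if diags else pd.DataFrame(
        columns=["subscale", "alpha_if_deleted", "improves"]
    )
    return ReliabilityReport(table=table, item_diagnostics=item_diag)
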