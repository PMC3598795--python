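"""Known-groups construct validity: one-way ANOVA and the eta effect size.

Respondents are stratified into three health-status groups (excellent/very
good, good, fair/poor).  Scale scores are compared across groups with a
fixed-effects one-way ANOVA, and the magnitude of separation is the
correlation ratio eta = sqrt(SS_between / (SS_between + SS_within)),
interpreted against the conventional anchors small (.20), medium (.50) and
large (.80).  The ANOVA can run from raw scores or be recomposed exactly
from printed group summaries (n, mean, SD), which makes published tables
re-checkable without the raw data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import HEALTH_LEVELS, ResponseDataset
from .instrument import InstrumentSpec
from .scoring import score_dataset

__all__ = [
    "GROUP_LABELS",
    "GroupSummary",
    "AnovaRow",
    "assign_groups",
    "anova_oneway",
    "anova_from_summary",
    "effect_size_label",
    "known_groups_table",
    "load_group_summaries",
    "format_p",
]

GROUP_LABELS = ("excellent-very good", "good", "fair-poor")
_LEVEL_TO_GROUP = {
    "excellent": GROUP_LABELS[0],
    "very good": GROUP_LABELS[0],
    "good": GROUP_LABELS[1],
    "fair": GROUP_LABELS[2],
    "poor": GROUP_LABELS[2],
}


@dataclass(frozen=True)
class GroupSummary:
    """One group's score summary: label, n, mean, SD."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0")


@dataclass(frozen=True)
class AnovaRow:
    """One scale's known-groups decomposition and effect size."""

    groups: tuple[GroupSummary, ...]
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    f: float
    p: float
    eta: float

    @property
    def eta_squared(self) -> float:
        return self.eta**2

    @property
    def cohens_f(self) -> float:
        """Alternative effect size f = sqrt(eta^2 / (1 - eta^2))."""
        e2 = self.eta_squared
        return float(np.sqrt(e2 / (1.0 - e2))) if e2 < 1 else float("inf")

    @property
    def grand_mean(self) -> float:
        tot = sum(g.n for g in self.groups)
        return float(sum(g.n * g.mean for g in self.groups) / tot)


def assign_groups(health_status: Iterable) -> tuple[pd.Series, int]:
    """Map 5-level health status to the 3 known groups.

    Returns (labels aligned to the input, count of missing/excluded values).
    Unknown non-missing levels raise.
    """
    s = pd.Series(list(health_status) if not isinstance(health_status, pd.Series) else health_status)
    if not isinstance(health_status, pd.Series):
        s.index = range(len(s))
    missing = s.isna()
    bad = sorted(set(s[~missing].unique()) - set(HEALTH_LEVELS))
    if bad:
        raise ValueError(f"unknown health status value(s): {bad}; expected {HEALTH_LEVELS}")
    labels = s.map(_LEVEL_TO_GROUP)
    return labels, int(missing.sum())


def _finish_row(groups: tuple[GroupSummary, ...], ssb: float, ssw: float) -> AnovaRow:
    g = len(groups)
    n_total = sum(gr.n for gr in groups)
    dfb, dfw = g - 1, n_total - g
    ssb = max(float(ssb), 0.0)
    ssw = max(float(ssw), 0.0)
    if ssw == 0.0:
        f = float("inf") if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
    else:
        f = (ssb / dfb) / (ssw / dfw)
        p = float(stats.f.sf(f, dfb, dfw))
    sstot = ssb + ssw
    eta = float(np.sqrt(ssb / sstot)) if sstot > 0 else 0.0
    return AnovaRow(
        groups=groups, ss_between=ssb, ss_within=ssw,
        df_between=dfb, df_within=dfw, f=float(f), p=p, eta=eta,
    )


def anova_oneway(values: Sequence[float], groups: Sequence[str]) -> AnovaRow:
    """One-way fixed-effects ANOVA from raw scores.

    Missing scores are dropped listwise; every remaining group needs >= 2
    observations.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": list(groups)}).dropna()
    counts = df.groupby("g", sort=False)["y"].count()
    if len(counts) < 2:
        raise ValueError(f"need >= 2 non-empty groups, got {len(counts)}")
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"group(s) with < 2 non-missing scores: {list(small.index)}")
    grand = df["y"].mean()
    summaries = []
    ssb = ssw = 0.0
    for label, sub in df.groupby("g", sort=False):
        m = sub["y"].mean()
        ssb += len(sub) * (m - grand) ** 2
        ssw += float(((sub["y"] - m) ** 2).sum())
        summaries.append(
            GroupSummary(label=str(label), n=len(sub), mean=float(m),
                         sd=float(sub["y"].std(ddof=1)))
        )
    return _finish_row(tuple(summaries), ssb, ssw)


def anova_from_summary(groups: Sequence[GroupSummary]) -> AnovaRow:
    """One-way ANOVA recomposed from printed group summaries (n, mean, SD).

    grand = sum(n_i m_i) / sum(n_i); SS_between = sum n_i (m_i - grand)^2;
    SS_within = sum (n_i - 1) sd_i^2.  Exactly reproduces the raw-data ANOVA
    when the summaries are exact.
    """
    groups = tuple(groups)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    n_total = sum(g.n for g in groups)
    grand = sum(g.n * g.mean for g in groups) / n_total
    ssb = sum(g.n * (g.mean - grand) ** 2 for g in groups)
    ssw = sum((g.n - 1) * g.sd**2 for g in groups)
    return _finish_row(groups, ssb, ssw)


def effect_size_label(eta: float) -> str:
    """Band an effect size against the anchors .20 / .50 / .80."""
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta must be in [0, 1], got {eta}")
    if eta < 0.20:
        return "sub-small"
    if eta < 0.50:
        return "small"
    if eta < 0.80:
        return "medium"
    return "large"


def format_p(p: float) -> str:
    """Print style for p-values: 3 decimals, '<.0001' below that threshold."""
    return "<.0001" if p < 0.0001 else f"{p:.3f}"


@dataclass
class KnownGroupsTable:
    """Per-scale known-groups comparison (group summaries, ANOVA, eta).

    ``rows`` maps scale name -> AnovaRow; ``skipped`` maps scale name -> the
    reason its row could not be computed (e.g. a group emptied by
    missingness).  ``excluded_respondents`` counts respondents without a
    health-status rating, who are left out of these analyses only.
    """

    rows: dict[str, AnovaRow]
    skipped: dict[str, str]
    excluded_respondents: int

    def to_frame(self) -> pd.DataFrame:
        recs = {}
        for scale, row in self.rows.items():
            rec: dict[str, object] = {}
            for g in row.groups:
                rec[f"n ({g.label})"] = g.n
                rec[f"mean ({g.label})"] = g.mean
                rec[f"sd ({g.label})"] = g.sd
            rec.update(
                ss_between=row.ss_between, ss_within=row.ss_within,
                F=row.f, p=row.p, eta=row.eta,
                effect_size=effect_size_label(row.eta),
            )
            recs[scale] = rec
        return pd.DataFrame.from_dict(recs, orient="index")

    def to_csv(self, path: str | Path) -> None:
        out = self.to_frame()
        out.index.name = "scale"
        out.to_csv(path, float_format="%.10g")


def known_groups_table(ds: ResponseDataset, spec: InstrumentSpec) -> KnownGroupsTable:
    """Known-groups comparison of every analyzed scale plus the Total Score."""
    if ds.health_status.empty:
        raise ValueError("dataset has no health_status metadata")
    scored = score_dataset(ds, spec)
    labels, n_excluded = assign_groups(ds.health_status)
    analyzed = [s.name for s in spec.analyzed_subscales] + ["Total Score"]
    rows: dict[str, AnovaRow] = {}
    skipped: dict[str, str] = {}
    order = pd.Categorical(labels, categories=list(GROUP_LABELS), ordered=True)
    groups_present = {g for g in labels.dropna().unique()}
    for scale in analyzed:
        y = scored.scores[scale]
        mask = labels.notna() & y.notna()
        try:
            sub = pd.DataFrame({"y": y[mask], "g": order[mask.to_numpy()]})
            sub = sub.sort_values("g")
            counts = sub.groupby("g", observed=True)["y"].count()
            emptied = sorted(groups_present - set(counts[counts >= 2].index))
            if emptied:
                raise ValueError(f"group(s) emptied by missing scores: {emptied}")
            rows[scale] = anova_oneway(sub["y"].to_numpy(), sub["g"].astype(str).to_numpy())
        except ValueError as e:
            skipped[scale] = str(e)
    return KnownGroupsTable(rows=rows, skipped=skipped, excluded_respondents=n_excluded)


def load_group_summaries(path: str | Path) -> dict[str, list[GroupSummary]]:
    """Read a summary-statistics CSV with columns (scale, group, n, mean, sd).

    Lets published tables be typed directly and re-analysed with
    :func:`anova_from_summary`.
    """
    df = pd.read_csv(path)
    required = {"scale", "group", "n", "mean", "sd"}
    if not required.issubset(df.columns):
        raise ValueError(f"summary CSV needs columns {sorted(required)}")
    out: dict[str, list[GroupSummary]] = {}
    for scale, sub in df.groupby("scale", sort=False):
        out[str(scale)] = [
            GroupSummary(label=str(r.group), n=int(r.n), mean=float(r.mean), sd=float(r.sd))
            for r in sub.itertuples()
        ]
    return out
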