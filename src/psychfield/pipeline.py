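"""Pipeline orchestration and report rendering.

Runs the full field-test analysis -- feasibility, reliability, multitrait
scaling, EFA and known-groups validity -- over one response table and writes
every table plus a manifest recording the configuration, library versions
and a checksum per output, so a run can be reproduced and verified byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import ResponseDataset, load_responses
from .efa import efa_from_dataset, simple_structure_flags
from .instrument import InstrumentSpec, load_instrument
from .known_groups import KnownGroupsTable, effect_size_label, format_p, known_groups_table
from .multitrait import ScalingTestResult, multitrait_summary
from .reliability import ReliabilityReport, reliability_report
from .scoring import FeasibilityReport, ScoreTable, feasibility_report, score_dataset

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "render_tables"]


@dataclass
class PipelineConfig:
    instrument: str = "pedsql_nf1_adult"
    responses: str | Path | None = None
    extra_exclusions: tuple[str, ...] = ()
    mt_method: str = "fisher_z"
    efa_factors: int | None = None
    efa_rotation: str = "promax"
    out_dir: str | Path = "pipeline_out"
    seed: int | None = None
    pairwise_alpha: bool = False

    def to_dict(self) -> dict:
        return {
            "instrument": str(self.instrument),
            "responses": None if self.responses is None else str(self.responses),
            "extra_exclusions": list(self.extra_exclusions),
            "mt_method": self.mt_method,
            "efa_factors": self.efa_factors,
            "efa_rotation": self.efa_rotation,
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "pairwise_alpha": self.pairwise_alpha,
        }


@dataclass
class ReportBundle:
    """All stage outputs of one pipeline run."""

    spec: InstrumentSpec
    scores: ScoreTable
    feasibility: FeasibilityReport
    reliability: ReliabilityReport
    multitrait: ScalingTestResult
    known_groups: KnownGroupsTable | None
    efa_loadings: pd.DataFrame | None
    efa_factor_corr: pd.DataFrame | None
    simple_structure: pd.DataFrame | None
    warnings: list[str] = field(default_factory=list)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig, ds: ResponseDataset | None = None) -> ReportBundle:
    """Execute every analysis stage and write tables + manifest to out_dir.

    ``ds`` may be passed directly (e.g. fresh from the simulator); otherwise
    ``cfg.responses`` is loaded.  A dataset without health-status metadata
    skips the known-groups stage with a warning; other stage failures
    propagate after partial outputs are written.
    """
    spec = load_instrument(cfg.instrument)
    if cfg.extra_exclusions:
        spec = InstrumentSpec(
            name=spec.name,
            subscales=spec.subscales,
            scale_points=spec.scale_points,
            scale_labels=spec.scale_labels,
            total_score_exclusions=spec.total_score_exclusions | set(cfg.extra_exclusions),
        )
    if ds is None:
        if cfg.responses is None:
            raise ValueError("PipelineConfig needs a responses path or an in-memory dataset")
        ds = load_responses(cfg.responses, spec)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    notes: list[str] = []

    scores = score_dataset(ds, spec)
    scores.to_csv(out / "scores.csv")

    feas = feasibility_report(ds, spec)
    feas.to_csv(out / "feasibility.csv")

    rel = reliability_report(ds, spec, pairwise=cfg.pairwise_alpha)
    rel.to_csv(out / "reliability.csv")

    mt = multitrait_summary(ds, spec, method=cfg.mt_method)
    mt.to_csv(out / "multitrait_tests.csv", out / "multitrait_summary.csv")

    efa_loadings = efa_phi = ss_table = None
    lm = efa_from_dataset(
        ds, spec, n_factors=cfg.efa_factors, rotation=cfg.efa_rotation
    )
    efa_loadings = lm.loadings
    lm.to_csv(out / "efa_loadings.csv")
    if lm.factor_corr is not None:
        efa_phi = lm.factor_corr
        efa_phi.to_csv(out / "efa_factor_corr.csv", float_format="%.10g")
    ss = simple_structure_flags(lm)
    ss_table = ss.table
    ss.to_csv(out / "simple_structure.csv")

    kg = None
    if ds.health_status.empty or ds.health_status.isna().all():
        notes.append("known-groups stage skipped: no health_status metadata")
    else:
        kg = known_groups_table(ds, spec)
        kg.to_csv(out / "known_groups.csv")

    manifest = {
        "package": {"name": "psychfield", "version": __version__},
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": cfg.to_dict(),
        "warnings": notes,
        "files": {p.name: _sha256(p) for p in sorted(out.glob("*.csv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return ReportBundle(
        spec=spec, scores=scores, feasibility=feas, reliability=rel,
        multitrait=mt, known_groups=kg, efa_loadings=efa_loadings,
        efa_factor_corr=efa_phi, simple_structure=ss_table, warnings=notes,
    )


# ---------------------------------------------------------------------------
# table rendering
# ---------------------------------------------------------------------------

def _scaling_table(b: ReportBundle) -> pd.DataFrame:
    s = b.multitrait.summary
    return pd.DataFrame(
        {
            "Subscale": s.index,
            "Items": s["items"].to_numpy(),
            "Item-Internal consistency": [
                f"{lo:.2f}-{hi:.2f}" for lo, hi in zip(s["own_r_min"], s["own_r_max"])
            ],
            "Item-Discriminant validity": [
                f"{lo:.2f}-{hi:.2f}" for lo, hi in zip(s["other_r_min"], s["other_r_max"])
            ],
            "Success/Total": [
                f"{int(a)}/{int(t)}" for a, t in zip(s["successes"], s["total_tests"])
            ],
            "Scaling success rate (%)": [f"{r:.2f}" for r in s["success_rate_pct"]],
        }
    )


def _reliability_table(b: ReportBundle) -> pd.DataFrame:
    t = b.reliability.table
    return pd.DataFrame(
        {
            "Domain": t.index,
            "Items": t["items"].to_numpy(),
            "Sample": t["n"].to_numpy(),
            "Mean ± SD": [f"{m:.2f} ± {s:.2f}" for m, s in zip(t["mean"], t["sd"])],
            "α": [f"{a:.2f}" for a in t["alpha"]],
        }
    )


def _known_groups_table(b: ReportBundle) -> pd.DataFrame:
    if b.known_groups is None:
        return pd.DataFrame()
    recs = []
    for scale, row in b.known_groups.rows.items():
        rec: dict[str, object] = {"Scale": scale}
        for g in row.groups:
            rec[f"{g.label} (n)"] = g.n
            rec[f"{g.label} (Mean ± SD)"] = f"{g.mean:.2f} ± {g.sd:.2f}"
        rec["p-value"] = format_p(row.p)
        rec["Effect size"] = f"{row.eta:.2f} ({effect_size_label(row.eta)})"
        recs.append(rec)
    return pd.DataFrame.from_records(recs)


def _feasibility_table(b: ReportBundle) -> pd.DataFrame:
    t = b.feasibility.per_subscale
    return pd.DataFrame(
        {
            "Subscale": t.index,
            "Items": t["items"].to_numpy(),
            "Expected": t["expected"].to_numpy(),
            "Missing": t["missing"].to_numpy(),
            "Missing (%)": [f"{p:.1f}" for p in t["missing_pct"]],
        }
    )


def render_tables(bundle: ReportBundle, out_dir: str | Path, fmt: str = "markdown") -> list[Path]:
    """Render the field-test tables in csv, json or markdown."""
    if fmt not in {"csv", "json", "markdown"}:
        raise ValueError(f"unknown format {fmt!r}; use csv, json or markdown")
    tables = {
        "feasibility": _feasibility_table(bundle),
        "scaling_tests": _scaling_table(bundle),
        "reliability": _reliability_table(bundle),
        "known_groups": _known_groups_table(bundle),
    }
    tables = {k: v for k, v in tables.items() if not v.empty}
    if not tables:
        raise ValueError("empty report bundle: nothing to render")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        if fmt == "csv":
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
        elif fmt == "json":
            p = out / f"{name}.json"
            p.write_text(json.dumps(df.to_dict(orient="records"), indent=2, default=str))
        else:
            p = out / f"{name}.md"
            p.write_text(df.to_markdown(index=False) + "\n")
        written.append(p)
    return written
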