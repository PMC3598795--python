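"""Seedable generator of synthetic respondent datasets.

The generative model is a one-factor-per-subscale graded model: each
respondent draws a latent problem-burden vector (one trait per subscale)
from a multivariate normal with a configurable inter-factor correlation
matrix; a health-status group adds an ordered mean shift (worse health ->
higher burden); each item's latent value mixes its subscale trait with
unique noise through a loading, and is cut at 4 ordered thresholds into the
raw 0-4 response (higher burden -> higher raw value -> lower transformed
score).  Missingness is applied afterwards: MCAR at the cell level, then
whole-block skips on sensitive subscales.

Defaults mirror a field-test setting of 134 respondents split 47/46/41
across health groups with +-0.8 SD latent shifts, 4.8% cell-level
missingness and a 30% block-skip rate on the sensitive subscale.
Everything is reproducible bit-for-bit from (config, seed): each stage of
the generator draws from its own child stream of the seed, so adding a
stage never perturbs earlier draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import ResponseDataset
from .instrument import InstrumentSpec, pedsql_nf1_adult

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "simulate",
    "calibrate_loadings",
    "export_fixture",
    "load_fixture",
    "uniform_factor_corr",
]

DEFAULT_THRESHOLDS = (-1.5, -0.5, 0.5, 1.5)


def uniform_factor_corr(n: int, rho: float) -> np.ndarray:
    """Equicorrelation matrix: 1 on the diagonal, rho elsewhere."""
    m = np.full((n, n), float(rho))
    np.fill_diagonal(m, 1.0)
    return m


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the reference scenario."""

    n_respondents: int = 134
    instrument: InstrumentSpec = field(default_factory=pedsql_nf1_adult)
    factor_corr: np.ndarray | None = None  # default: equicorrelation 0.5
    loadings: float | dict[str, float] = 0.8
    thresholds: tuple[float, ...] | dict[str, tuple[float, ...]] = DEFAULT_THRESHOLDS
    group_probs: tuple[float, float, float] = (47 / 134, 46 / 134, 41 / 134)
    group_shifts: tuple[float, float, float] | np.ndarray = (-0.8, 0.0, 0.8)
    item_missing_rate: float = 0.048
    sensitive_block_missing_rate: float = 0.30
    seed: int = 0

    def resolved_factor_corr(self) -> np.ndarray:
        n = len(self.instrument.subscales)
        fc = (
            uniform_factor_corr(n, 0.5)
            if self.factor_corr is None
            else np.asarray(self.factor_corr, dtype=float)
        )
        if fc.shape != (n, n):
            raise ValueError(f"factor_corr must be {n}x{n} for this instrument")
        if not np.allclose(fc, fc.T, atol=1e-10) or not np.allclose(np.diag(fc), 1.0):
            raise ValueError("factor_corr must be symmetric with unit diagonal")
        w = np.linalg.eigvalsh(fc)
        if w.min() < -1e-10:
            raise ValueError(
                f"factor_corr is not positive semidefinite (min eigenvalue "
                f"{w.min():.3g}); consider projecting to the nearest PSD matrix "
                "by clipping negative eigenvalues and renormalising the diagonal"
            )
        return fc

    def loading_of(self, item_id: str) -> float:
        lam = (
            self.loadings.get(item_id, 0.8)
            if isinstance(self.loadings, dict)
            else float(self.loadings)
        )
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"loading for {item_id!r} must be in [0, 1], got {lam}")
        return lam

    def thresholds_of(self, item_id: str) -> np.ndarray:
        t = (
            self.thresholds.get(item_id, DEFAULT_THRESHOLDS)
            if isinstance(self.thresholds, dict)
            else self.thresholds
        )
        t = np.asarray(t, dtype=float)
        if t.size != len(self.instrument.scale_points) - 1 or np.any(np.diff(t) <= 0):
            raise ValueError(f"thresholds for {item_id!r} must be strictly increasing cuts")
        return t

    def resolved_group_shifts(self) -> np.ndarray:
        """Per-group, per-factor latent shifts, shape (3, n_subscales)."""
        n_fac = len(self.instrument.subscales)
        gs = np.asarray(self.group_shifts, dtype=float)
        if gs.ndim == 1:
            if gs.size != 3:
                raise ValueError("group_shifts must have one entry per group")
            gs = np.repeat(gs[:, None], n_fac, axis=1)
        elif gs.shape != (3, n_fac):
            raise ValueError(f"per-factor group_shifts must be 3x{n_fac}")
        return gs

    def to_dict(self) -> dict:
        return {
            "n_respondents": self.n_respondents,
            "instrument": self.instrument.name,
            "factor_corr": None
            if self.factor_corr is None
            else np.asarray(self.factor_corr).tolist(),
            "loadings": self.loadings,
            "thresholds": list(self.thresholds)
            if not isinstance(self.thresholds, dict)
            else {k: list(v) for k, v in self.thresholds.items()},
            "group_probs": list(self.group_probs),
            "group_shifts": np.asarray(self.group_shifts).tolist(),
            "item_missing_rate": self.item_missing_rate,
            "sensitive_block_missing_rate": self.sensitive_block_missing_rate,
            "seed": self.seed,
        }


@dataclass
class SimulatedTruth:
    """Generating ground truth: latent traits, groups, loadings, thresholds."""

    traits: pd.DataFrame  # respondents x subscales, shift included
    group: pd.Series  # group index 0/1/2 per respondent
    loadings: pd.Series  # per item
    thresholds: dict[str, list[float]]
    config: SimulationConfig


# health-status levels emitted for each latent group (split at random)
_GROUP_LEVELS = (("excellent", "very good"), ("good",), ("fair", "poor"))


def simulate(config: SimulationConfig) -> tuple[ResponseDataset, SimulatedTruth]:
    """Draw one synthetic dataset; identical (config, seed) -> identical data."""
    spec = config.instrument
    probs = np.asarray(config.group_probs, dtype=float)
    if probs.size != 3 or abs(probs.sum() - 1.0) > 1e-9 or probs.min() < 0:
        raise ValueError("group_probs must be 3 non-negative values summing to 1")
    fc = config.resolved_factor_corr()
    shifts = config.resolved_group_shifts()
    n = int(config.n_respondents)
    if n < 1:
        raise ValueError("n_respondents must be >= 1")

    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_group = np.random.default_rng(streams[0])
    rng_trait = np.random.default_rng(streams[1])
    rng_item = np.random.default_rng(streams[2])
    rng_mcar = np.random.default_rng(streams[3])
    rng_block = np.random.default_rng(streams[4])

    ids = [f"r{i + 1:04d}" for i in range(n)]
    sub_names = [s.name for s in spec.subscales]
    n_fac = len(sub_names)

    group = rng_group.choice(3, size=n, p=probs)
    # 5-level self-report consistent with the latent group
    hs = np.array(
        [rng_group.choice(_GROUP_LEVELS[g]) for g in group], dtype=object
    )
    age = rng_group.integers(20, 72, size=n)

    chol = np.linalg.cholesky(fc + 1e-12 * np.eye(n_fac))
    traits = rng_trait.standard_normal((n, n_fac)) @ chol.T
    traits = traits + shifts[group, :]

    raw = np.empty((n, spec.n_items), dtype=float)
    factor_of = {
        item: sub_names.index(spec.owner_of(item).name) for item in spec.item_ids
    }
    for j, item in enumerate(spec.item_ids):
        lam = config.loading_of(item)
        cuts = config.thresholds_of(item)
        latent = lam * traits[:, factor_of[item]] + np.sqrt(1.0 - lam**2) * (
            rng_item.standard_normal(n)
        )
        raw[:, j] = np.searchsorted(cuts, latent, side="right")

    if not 0.0 <= config.item_missing_rate < 1.0:
        raise ValueError("item_missing_rate must be in [0, 1)")
    mcar = rng_mcar.random((n, spec.n_items)) < config.item_missing_rate
    raw[mcar] = np.nan
    for s in spec.subscales:
        if not s.sensitive:
            continue
        skip = rng_block.random(n) < config.sensitive_block_missing_rate
        cols = [list(spec.item_ids).index(i) for i in s.item_ids]
        for c in cols:
            raw[skip, c] = np.nan

    ds = ResponseDataset(
        raw=pd.DataFrame(raw, index=ids, columns=list(spec.item_ids)),
        age=pd.Series(age.astype(float), index=ids),
        health_status=pd.Series(hs, index=ids),
    )
    ds.validate(spec)
    truth = SimulatedTruth(
        traits=pd.DataFrame(traits, index=ids, columns=sub_names),
        group=pd.Series(group, index=ids),
        loadings=pd.Series({i: config.loading_of(i) for i in spec.item_ids}),
        thresholds={i: list(config.thresholds_of(i)) for i in spec.item_ids},
        config=config,
    )
    return ds, truth


def calibrate_loadings(target_alpha: float, k_items: int) -> float:
    """Equal loading lambda hitting a target alpha on the continuous scale.

    Inverts the standardized-alpha identity alpha = k rbar / (1 + (k-1) rbar)
    with rbar = lambda^2.  Ordinal discretization attenuates the realized
    alpha somewhat below the target.
    """
    if not 0.0 < target_alpha < 1.0:
        raise ValueError("target_alpha must be in (0, 1)")
    if k_items < 2:
        raise ValueError("k_items must be >= 2")
    rbar = target_alpha / (k_items - (k_items - 1) * target_alpha)
    if rbar > 1.0:
        raise ValueError(
            f"target alpha {target_alpha} unreachable with {k_items} items "
            f"(requires mean inter-item correlation {rbar:.3f} > 1)"
        )
    return float(np.sqrt(rbar))


def export_fixture(ds: ResponseDataset, truth: SimulatedTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write responses.csv, truth.json and config.yaml into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "responses": out / "responses.csv",
        "truth": out / "truth.json",
        "config": out / "config.yaml",
    }
    ds.to_csv(paths["responses"])
    paths["truth"].write_text(
        json.dumps(
            {
                "traits": truth.traits.round(10).to_dict(orient="index"),
                "group": truth.group.to_dict(),
                "loadings": truth.loadings.to_dict(),
                "thresholds": truth.thresholds,
            },
            indent=2,
        )
    )
    paths["config"].write_text(yaml.safe_dump(truth.config.to_dict(), sort_keys=False))
    return paths


def load_fixture(fixture_dir: str | Path, spec: InstrumentSpec) -> ResponseDataset:
    """Reload the responses CSV written by :func:`export_fixture`."""
    from .dataset import load_responses

    return load_responses(Path(fixture_dir) / "responses.csv", spec)
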