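"""Exploratory factor analysis and simple-structure item reduction.

Extraction is iterated principal-axis factoring (PAF): communalities start
at the squared multiple correlations, the reduced correlation matrix is
eigen-decomposed, communalities are updated from the loadings, and the loop
repeats to convergence.  Rotation is varimax (orthogonal) optionally powered
into an oblique promax solution (kappa = 4 by default).  Items are then
screened against a salience cutoff of 0.30 on absolute pattern loadings: an
item shows *simple structure* when exactly one loading is salient.
Reduction candidates combine that screen with the item-deletion reliability
diagnostic: an item is proposed for deletion only when it is non-simple AND
deleting it raises its subscale's alpha.  The tool proposes candidates; the
final deletion is an analyst decision.
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
    "LoadingMatrix",
    "SimpleStructureReport",
    "principal_axis_factoring",
    "varimax",
    "varimax_criterion",
    "promax",
    "simple_structure_flags",
    "reduction_candidates",
    "efa_from_dataset",
]


@dataclass
class LoadingMatrix:
    """Factor loadings with communalities and (for oblique) factor correlations.

    ``loadings`` holds pattern loadings (items x factors).  ``factor_corr``
    is None for unrotated/orthogonal solutions.  ``eigenvalues`` are the
    eigenvalues of the input correlation matrix (unit diagonal), for Kaiser
    and scree diagnostics.  ``heywood_items`` lists items whose communality
    hit the [0, 1] boundary from above and was clipped.
    """

    loadings: pd.DataFrame
    communalities: pd.Series
    rotation: str = "none"
    factor_corr: pd.DataFrame | None = None
    converged: bool = True
    n_iter: int = 0
    eigenvalues: np.ndarray | None = None
    heywood_items: list[str] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        out = self.loadings.copy()
        out["communality"] = self.communalities
        out.index.name = "item"
        out.to_csv(path, float_format="%.10g")


def _check_corr(R: np.ndarray, tol: float = 1e-8) -> None:
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValueError("correlation matrix must have unit diagonal")
    w = np.linalg.eigvalsh(R)
    if w.min() < -1e-6:
        raise ValueError(
            f"correlation matrix not positive semidefinite (min eigenvalue {w.min():.3g})"
        )


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations; falls back to max |r| for singular R."""
    try:
        Rinv = np.linalg.inv(R)
        smc = 1.0 - 1.0 / np.diag(Rinv)
        if np.any(~np.isfinite(smc)) or smc.min() < 0:
            raise np.linalg.LinAlgError
        return np.clip(smc, 0.0, 1.0)
    except np.linalg.LinAlgError:
        off = np.abs(R - np.eye(len(R)))
        return off.max(axis=1)


def principal_axis_factoring(
    R,
    n_factors: int,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> LoadingMatrix:
    """Iterated-communalities principal-axis extraction.

    Negative eigenvalues of the reduced matrix are truncated at zero before
    taking root-eigenvalue-scaled eigenvectors.  Non-convergence returns the
    last iterate with ``converged=False`` and a warning; communalities above
    1 (Heywood) are clipped and the items flagged.
    """
    labels = list(R.index) if isinstance(R, pd.DataFrame) else None
    Rm = np.asarray(R, dtype=float)
    _check_corr(Rm)
    p = Rm.shape[0]
    if not (1 <= n_factors < p):
        raise ValueError(f"n_factors must be in [1, {p - 1}], got {n_factors}")
    if labels is None:
        labels = [f"x{i + 1}" for i in range(p)]
    eigenvalues = np.linalg.eigvalsh(Rm)[::-1]

    h2 = _smc(Rm)
    L = np.zeros((p, n_factors))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Rr = Rm.copy()
        np.fill_diagonal(Rr, h2)
        w, V = np.linalg.eigh(Rr)
        idx = np.argsort(w)[::-1][:n_factors]
        w_top = np.clip(w[idx], 0.0, None)
        L = V[:, idx] * np.sqrt(w_top)
        h2_new = np.clip((L**2).sum(axis=1), 0.0, None)
        delta = float(np.max(np.abs(h2_new - h2)))
        h2 = h2_new
        if delta < tol:
            converged = True
            break
    heywood = [labels[i] for i in np.flatnonzero(h2 > 1.0 + 1e-10)]
    if heywood:
        warnings.warn(f"Heywood case(s): communality > 1 for {heywood}; clipped", stacklevel=2)
        h2 = np.clip(h2, 0.0, 1.0)
    if not converged:
        warnings.warn(
            f"PAF did not converge in {max_iter} iterations (last delta above tol)",
            stacklevel=2,
        )
    cols = [f"F{j + 1}" for j in range(n_factors)]
    # orient each factor so its largest-magnitude loading is positive
    for j in range(n_factors):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return LoadingMatrix(
        loadings=pd.DataFrame(L, index=labels, columns=cols),
        communalities=pd.Series(np.clip(h2, 0.0, 1.0), index=labels),
        rotation="none",
        converged=converged,
        n_iter=it,
        eigenvalues=eigenvalues,
    )


def varimax_criterion(L: np.ndarray) -> float:
    """Varimax objective: sum over factors of the variance of squared loadings."""
    L2 = np.asarray(L, dtype=float) ** 2
    return float(np.sum(L2.var(axis=0)))


def varimax(
    lm: LoadingMatrix, tol: float = 1e-10, max_iter: int = 1000, normalize: bool = True
) -> LoadingMatrix:
    """Orthogonal varimax rotation (Kaiser-normalized by default).

    Communalities (row sums of squared loadings) are preserved exactly up to
    floating point.  A single-factor solution is returned unchanged.
    """
    L = lm.loadings.to_numpy(dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return LoadingMatrix(
            loadings=lm.loadings.copy(), communalities=lm.communalities.copy(),
            rotation="varimax", converged=True, n_iter=0, eigenvalues=lm.eigenvalues,
            heywood_items=list(lm.heywood_items),
        )
    h = np.sqrt((L**2).sum(axis=1))
    if normalize:
        safe = np.where(h > 0, h, 1.0)
        L = L / safe[:, None]
    T = np.eye(k)
    d_old = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        Lr = L @ T
        B = L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        U, s, Vt = np.linalg.svd(B)
        T = U @ Vt
        d = s.sum()
        if d_old != 0 and d / d_old < 1 + tol:
            break
        d_old = d
    L = L @ T
    if normalize:
        L = L * np.where(h > 0, h, 1.0)[:, None]
    # column order by explained variance, sign so dominant loading positive
    order = np.argsort(-(L**2).sum(axis=0))
    L = L[:, order]
    for j in range(k):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return LoadingMatrix(
        loadings=pd.DataFrame(L, index=lm.loadings.index, columns=lm.loadings.columns),
        communalities=pd.Series((L**2).sum(axis=1), index=lm.loadings.index),
        rotation="varimax",
        converged=it < max_iter,
        n_iter=it,
        eigenvalues=lm.eigenvalues,
        heywood_items=list(lm.heywood_items),
    )


def promax(lm: LoadingMatrix, kappa: int = 4) -> LoadingMatrix:
    """Oblique promax rotation of a varimax solution.

    The varimax loadings are powered elementwise to |loading|^kappa * sign to
    sharpen simple structure, a least-squares transform to that target is
    computed, and the transform is rescaled so every factor has unit
    variance; pattern loadings and the factor correlation matrix are
    returned.
    """
    L = lm.loadings.to_numpy(dtype=float)
    p, k = L.shape
    if k < 2:
        out = LoadingMatrix(
            loadings=lm.loadings.copy(), communalities=lm.communalities.copy(),
            rotation="promax", factor_corr=pd.DataFrame(
                np.eye(1), index=lm.loadings.columns, columns=lm.loadings.columns),
            eigenvalues=lm.eigenvalues, heywood_items=list(lm.heywood_items),
        )
        return out
    target = np.abs(L) ** kappa * np.sign(L)
    gram = L.T @ L
    cond = np.linalg.cond(gram)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"varimax loading matrix nearly rank-deficient (condition number {cond:.3g})"
        )
    Q = np.linalg.solve(gram, L.T @ target)
    # rescale columns so the implied factors have unit variance
    d = np.sqrt(np.diag(np.linalg.inv(Q.T @ Q)))
    Q = Q * d
    pattern = L @ Q
    phi = np.linalg.inv(Q.T @ Q)
    phi = (phi + phi.T) / 2.0
    np.fill_diagonal(phi, 1.0)
    cols = list(lm.loadings.columns)
    return LoadingMatrix(
        loadings=pd.DataFrame(pattern, index=lm.loadings.index, columns=cols),
        communalities=lm.communalities.copy(),
        rotation="promax",
        factor_corr=pd.DataFrame(phi, index=cols, columns=cols),
        eigenvalues=lm.eigenvalues,
        heywood_items=list(lm.heywood_items),
    )


@dataclass
class SimpleStructureReport:
    """Per-item salience screen against the loading cutoff.

    ``table`` columns: n_salient, dominant_factor, status in
    {simple, cross-loading, no-salient-loading} (exhaustive, exclusive).
    """

    table: pd.DataFrame
    cutoff: float

    def non_simple_items(self) -> list[str]:
        return list(self.table.index[self.table["status"] != "simple"])

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "item"
        out.to_csv(path)


def simple_structure_flags(lm: LoadingMatrix, cutoff: float = 0.30) -> SimpleStructureReport:
    """Classify items by how many absolute pattern loadings reach the cutoff."""
    A = lm.loadings.to_numpy(dtype=float)
    absA = np.abs(A)
    n_salient = (absA >= cutoff).sum(axis=1)
    dominant = lm.loadings.columns[np.argmax(absA, axis=1)]
    status = np.where(
        n_salient == 1, "simple", np.where(n_salient >= 2, "cross-loading", "no-salient-loading")
    )
    table = pd.DataFrame(
        {"n_salient": n_salient, "dominant_factor": dominant, "status": status},
        index=lm.loadings.index,
    )
    return SimpleStructureReport(table=table, cutoff=cutoff)


def reduction_candidates(
    ss: SimpleStructureReport, alpha_gains: pd.Series
) -> pd.DataFrame:
    """Rank deletion candidates: non-simple items whose removal raises alpha.

    ``alpha_gains`` maps item id -> (alpha-if-deleted minus full-scale alpha)
    for its own subscale.  Items failing only one of the two screens appear
    in the output with ``candidate=False`` (flag-only); candidates are
    ranked by alpha gain, largest first.  Nothing is deleted automatically.
    """
    common = [i for i in ss.table.index if i in alpha_gains.index]
    rows = []
    for item in common:
        non_simple = ss.table.at[item, "status"] != "simple"
        gain = float(alpha_gains[item])
        rows.append(
            dict(item=item, status=ss.table.at[item, "status"],
                 alpha_gain=gain, candidate=bool(non_simple and gain > 0))
        )
    out = pd.DataFrame.from_records(rows).set_index("item")
    out = out.sort_values(["candidate", "alpha_gain"], ascending=[False, False])
    return out


def efa_from_dataset(
    ds: ResponseDataset,
    spec: InstrumentSpec,
    n_factors: int | None = None,
    rotation: str = "promax",
    kappa: int = 4,
) -> LoadingMatrix:
    """Full EFA on the analyzed items of a dataset.

    Correlations are computed pairwise on transformed item scores; the
    factor count defaults to the number of analyzed subscales.  Emits a
    warning when the respondent-to-item ratio is below 5:1, where factor
    solutions are imprecise.
    """
    ds.validate(spec)
    items = list(spec.analyzed_item_ids)
    if ds.n_respondents < 5 * len(items):
        warnings.warn(
            f"respondent-to-item ratio {ds.n_respondents}/{len(items)} is below 5:1; "
            "factor solution will be imprecise",
            stacklevel=2,
        )
    transformed = pd.DataFrame(
        transform_item(ds.raw[items].to_numpy(dtype=float), spec.scale_points),
        index=ds.raw.index, columns=items,
    )
    R = transformed.corr(min_periods=4)
    if R.isna().any().any():
        bad = list(R.columns[R.isna().any()])
        raise ValueError(f"undefined correlations involving item(s) {bad}")
    # pairwise correlation matrices may be slightly indefinite; lift tiny
    # negative eigenvalues before extraction
    w, V = np.linalg.eigh(R.to_numpy())
    if w.min() < 0:
        if w.min() < -0.05:
            raise ValueError(
                f"item correlation matrix strongly indefinite (min eigenvalue {w.min():.3g})"
            )
        Rfix = V @ np.diag(np.clip(w, 1e-10, None)) @ V.T
        d = np.sqrt(np.diag(Rfix))
        Rfix = Rfix / np.outer(d, d)
        np.fill_diagonal(Rfix, 1.0)
        R = pd.DataFrame(Rfix, index=R.index, columns=R.columns)
    k = n_factors if n_factors is not None else len(spec.analyzed_subscales)
    lm = principal_axis_factoring(R, n_factors=k)
    if rotation == "none" or k == 1:
        return lm
    vm = varimax(lm)
    if rotation == "varimax":
        return vm
    if rotation == "promax":
        return promax(vm, kappa=kappa)
    raise ValueError(f"unknown rotation {rotation!r}")
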