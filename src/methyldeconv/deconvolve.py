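"""Constrained projection of bulk profiles and the CETYGO error score.

Given a model of per-cell-type mean methylation over M marker sites, the
cellular composition of a bulk sample is estimated by least squares,

    minimise  sum_j ( B_j - sum_k p_k C_{j,k} )^2   subject to  p >= 0,

optionally with the additional constraint sum_k p_k <= 1. Proportions are
deliberately NOT renormalised to sum to one: the raw sum is itself
informative (it drops below 1 when the panel is incomplete or the sample is
noisy).

The CETYGO score of a sample is the root mean square error between its
observed betas and the betas implied by the estimated proportions, over the
marker sites used in the fit. Zero means a perfect fit; larger values flag
compositions the model cannot explain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .model import DeconvolutionModel

__all__ = [
    "NONNEG",
    "NONNEG_SUM_LE_1",
    "DeconvolutionResult",
    "project_proportions",
    "expected_profile",
    "cetygo_score",
    "deconvolve_with_error",
    "results_to_frame",
]

NONNEG = "nonneg"
NONNEG_SUM_LE_1 = "nonneg_sum_le_1"
_MODES = (NONNEG, NONNEG_SUM_LE_1)

# tolerance on the Sum p <= 1 constraint (solver slack)
_SUM_TOL = 1e-8


@dataclass
class DeconvolutionResult:
    """Estimated composition and fit quality for one bulk sample."""

    sample_id: str
    proportions: pd.Series | None
    proportion_sum: float
    cetygo: float
    n_sites_used: int
    constraint_mode: str
    error: str | None = field(default=None)

    @property
    def ok(self) -> bool:
        return self.error is None


def _align(
    model: DeconvolutionModel,
    bulk: pd.Series,
    min_coverage: float,
) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    """Intersect model marker probes with the bulk's probes."""
    shared = model.mean_profiles.index.intersection(bulk.index)
    observed = bulk.loc[shared]
    shared = shared[~observed.isna().to_numpy()]
    if len(shared) == 0:
        raise ValueError(
            "no marker probe of the model is present (non-missing) in the "
            "bulk profile"
        )
    coverage = len(shared) / model.n_sites
    if coverage < min_coverage:
        warnings.warn(
            f"only {len(shared)}/{model.n_sites} marker probes "
            f"({coverage:.1%}) found in bulk profile; estimates may be "
            "unreliable",
            stacklevel=3,
        )
    a = model.mean_profiles.loc[shared].to_numpy(dtype=float)
    b = bulk.loc[shared].to_numpy(dtype=float)
    return a, b, shared


def _solve(a: np.ndarray, b: np.ndarray, constraint_mode: str) -> np.ndarray:
    if constraint_mode not in _MODES:
        raise ValueError(
            f"constraint_mode must be one of {_MODES}, got {constraint_mode!r}"
        )
    if np.linalg.matrix_rank(a) < a.shape[1]:
        warnings.warn(
            "mean-profile matrix is rank deficient over the shared probes; "
            "the returned proportions are not unique",
            stacklevel=3,
        )
    x, _ = optimize.nnls(a, b)
    if constraint_mode == NONNEG_SUM_LE_1 and x.sum() > 1.0 + _SUM_TOL:
        # the sum constraint is active: solve the QP from the NNLS point
        n = a.shape[1]

        def objective(p: np.ndarray) -> float:
            r = a @ p - b
            return float(r @ r)

        def gradient(p: np.ndarray) -> np.ndarray:
            return 2.0 * a.T @ (a @ p - b)

        res = optimize.minimize(
            objective,
            x0=x / x.sum(),
            jac=gradient,
            method="SLSQP",
            bounds=[(0.0, None)] * n,
            constraints=[
                {
                    "type": "ineq",
                    "fun": lambda p: 1.0 - p.sum(),
                    "jac": lambda p: -np.ones_like(p),
                }
            ],
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if not res.success:
            raise RuntimeError(
                f"sum-constrained least squares failed: {res.message}"
            )
        x = np.clip(res.x, 0.0, None)
    return x


def project_proportions(
    model: DeconvolutionModel,
    bulk: pd.Series,
    constraint_mode: str = NONNEG,
    min_coverage: float = 0.8,
) -> pd.Series:
    """Estimate cell-type proportions for one bulk profile.

    The fit runs over the intersection of the model's marker probes and the
    bulk's non-missing probes; a warning is emitted when fewer than
    ``min_coverage`` of the marker probes are available.
    """
    a, b, _ = _align(model, bulk, min_coverage)
    x = _solve(a, b, constraint_mode)
    return pd.Series(x, index=model.cell_types, name=bulk.name)


def expected_profile(
    model: DeconvolutionModel, proportions: pd.Series | np.ndarray
) -> pd.Series:
    """Betas implied by a composition: B_hat_j = sum_k p_k C_{j,k}."""
    p = np.asarray(
        proportions.loc[model.cell_types]
        if isinstance(proportions, pd.Series)
        else proportions,
        dtype=float,
    )
    if p.shape != (len(model.cell_types),):
        raise ValueError(
            f"expected {len(model.cell_types)} proportions, got {p.shape}"
        )
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    return pd.Series(
        model.mean_profiles.to_numpy(dtype=float) @ p,
        index=model.mean_profiles.index,
        name="expected",
    )


def cetygo_score(observed, expected) -> float:
    """Root mean square deviation between observed and model-implied betas.

    Both vectors must be aligned probe-by-probe and of equal length M >= 1.
    Returns 0 exactly when the vectors are identical.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1:
        raise ValueError(
            f"observed and expected must be equal-length vectors, got shapes "
            f"{obs.shape} and {exp.shape}"
        )
    if obs.size == 0:
        raise ValueError("cannot score an empty profile (M = 0)")
    return float(np.sqrt(np.mean((obs - exp) ** 2)))


def deconvolve_with_error(
    model: DeconvolutionModel,
    bulk: pd.DataFrame | pd.Series,
    constraint_mode: str = NONNEG,
    min_coverage: float = 0.8,
) -> list[DeconvolutionResult]:
    """Estimate proportions and CETYGO for every sample in a bulk matrix.

    Per-sample failures (e.g., zero shared probes) are returned as failure
    records rather than aborting the batch.
    """
    if isinstance(bulk, pd.Series):
        bulk = bulk.to_frame(name=bulk.name if bulk.name is not None else "sample")
    results: list[DeconvolutionResult] = []
    for sample_id in bulk.columns:
        column = bulk[sample_id]
        try:
            a, b, shared = _align(model, column, min_coverage)
            x = _solve(a, b, constraint_mode)
            score = cetygo_score(b, a @ x)
        except (ValueError, RuntimeError) as exc:
            results.append(
                DeconvolutionResult(
                    sample_id=str(sample_id),
                    proportions=None,
                    proportion_sum=float("nan"),
                    cetygo=float("nan"),
                    n_sites_used=0,
                    constraint_mode=constraint_mode,
                    error=str(exc),
                )
            )
            continue
        results.append(
            DeconvolutionResult(
                sample_id=str(sample_id),
                proportions=pd.Series(x, index=model.cell_types),
                proportion_sum=float(x.sum()),
                cetygo=score,
                n_sites_used=len(shared),
                constraint_mode=constraint_mode,
            )
        )
    return results


def results_to_frame(results: list[DeconvolutionResult]) -> pd.DataFrame:
    """Tidy table: one row per sample, one column per cell type."""
    rows = []
    for r in results:
        row: dict = {"sample_id": r.sample_id}
        if r.proportions is not None:
            row.update({str(k): v for k, v in r.proportions.items()})
        row.update(
            proportion_sum=r.proportion_sum,
            cetygo=r.cetygo,
            n_sites_used=r.n_sites_used,
            constraint_mode=r.constraint_mode,
            error=r.error if r.error is not None else "",
        )
        rows.append(row)
    return pd.DataFrame(rows)
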