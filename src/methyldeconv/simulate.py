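"""Reconstructed bulk profiles of known composition and validation experiments.

Bulk methylation profiles are rebuilt as weighted sums of per-cell-type test
profiles, optionally corrupted by a controlled proportion of uniform noise,
and then deconvolved so the error of the estimate can be measured against the
known truth. Three experiments probe the error score:

* a noise grid (31 noise proportions from 0 to 0.5),
* leave-one-out: a cell type omitted from training but present in the bulk
  at increasing proportions,
* panel subsets: every 3-, 4- and 5-type model from a 6-type panel applied
  to a grid of full-panel compositions.

Noise model. With noise proportion rho and eps_j ~ Uniform(0, 1) i.i.d., the
default "mixture" form is

    B_j = (1 - rho) * sum_k p_k C_{j,k} + rho * eps_j,

treating rho literally as the fraction of the signal replaced by noise; the
"additive" form B_j = sum_k p_k C_{j,k} + rho * eps_j (which can exceed 1 and
systematically inflates estimated proportion sums) is available as an option.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deconvolve import NONNEG, cetygo_score, deconvolve_with_error
from .model import DeconvolutionModel, train_model
from .panel import ReferencePanel

__all__ = [
    "CompositionSpec",
    "NoiseSpec",
    "noise_grid",
    "panel_subsets",
    "composition_grid",
    "reconstruct_bulk",
    "run_noise_experiment",
    "run_loo_experiment",
    "run_subset_experiment",
]

_SUM_TOL = 1e-12

MIXTURE = "mixture"
ADDITIVE = "additive"


@dataclass(frozen=True)
class CompositionSpec:
    """Ground-truth mixing proportions over a set of cell types."""

    proportions: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        values = np.array([v for _, v in self.proportions], dtype=float)
        if (values < 0).any():
            raise ValueError("proportions must be non-negative")
        if abs(values.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"proportions must sum to 1, got {values.sum()!r}"
            )
        names = [k for k, _ in self.proportions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell types in composition")

    @classmethod
    def from_series(cls, series: pd.Series) -> "CompositionSpec":
        return cls(tuple((str(k), float(v)) for k, v in series.items()))

    @classmethod
    def from_tenths(
        cls, cell_types: list[str], tenths: tuple[int, ...]
    ) -> "CompositionSpec":
        if sum(tenths) != 10:
            raise ValueError("tenths must sum to 10")
        return cls(
            tuple((ct, t / 10.0) for ct, t in zip(cell_types, tenths))
        )

    @property
    def series(self) -> pd.Series:
        return pd.Series(dict(self.proportions), dtype=float)

    @property
    def cell_types(self) -> list[str]:
        return [k for k, _ in self.proportions]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise proportion rho and the RNG seed for the uniform noise draw."""

    rho: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 0.5:
            raise ValueError("rho must be in [0, 0.5]")


def noise_grid() -> np.ndarray:
    """The standard 31-level noise grid: 0 to 0.1 by 0.01, 0.12 to 0.5 by 0.02."""
    fine = np.arange(0, 11)  # 0.00 .. 0.10
    coarse = np.arange(12, 51, 2)  # 0.12 .. 0.50
    return np.concatenate([fine, coarse]) / 100.0


def panel_subsets(
    cell_types: list[str], min_size: int = 3, max_size: int = 5
) -> list[tuple[str, ...]]:
    """All cell-type subsets of the given sizes, in deterministic order."""
    cell_types = list(cell_types)
    if len(set(cell_types)) != len(cell_types):
        raise ValueError("duplicate cell-type names")
    if not 1 <= min_size <= max_size <= len(cell_types):
        raise ValueError("invalid subset size bounds")
    ordered = sorted(cell_types)
    out: list[tuple[str, ...]] = []
    for size in range(min_size, max_size + 1):
        out.extend(itertools.combinations(ordered, size))
    return out


def composition_grid(
    cell_types: list[str],
    unit: float = 0.1,
    min_p: float = 0.1,
    max_p: float = 0.5,
) -> list[CompositionSpec]:
    """All compositions on a unit grid with per-type bounds, summing to 1.

    Enumeration runs in integer grid units (tenths for unit = 0.1) so sums
    are exact; order is lexicographic in the sorted cell types.
    """
    cell_types = sorted(cell_types)
    n = len(cell_types)
    total = int(round(1.0 / unit))
    if abs(total * unit - 1.0) > 1e-9:
        raise ValueError("unit must divide 1 exactly")
    lo = int(round(min_p / unit))
    hi = int(round(max_p / unit))
    if n * lo > total or n * hi < total:
        raise ValueError(
            f"infeasible bounds: {n} types with per-type range "
            f"[{min_p}, {max_p}] cannot sum to 1"
        )

    def rec(remaining: int, slots: int) -> list[tuple[int, ...]]:
        if slots == 1:
            return [(remaining,)] if lo <= remaining <= hi else []
        out = []
        for v in range(lo, hi + 1):
            rest = remaining - v
            if rest < lo * (slots - 1) or rest > hi * (slots - 1):
                continue
            out.extend((v, *tail) for tail in rec(rest, slots - 1))
        return out

    return [
        CompositionSpec(
            tuple((ct, u * unit) for ct, u in zip(cell_types, combo))
        )
        for combo in rec(total, n)
    ]


def reconstruct_bulk(
    test_profiles: pd.DataFrame,
    composition: CompositionSpec,
    noise: NoiseSpec | None = None,
    noise_model: str = MIXTURE,
) -> pd.Series:
    """Build a bulk profile from per-cell-type test profiles.

    ``test_profiles`` holds one column per cell type over a common probe
    index; the composition must cover exactly those cell types. With
    rho = 0 the output is the exact weighted sum, independent of the seed.
    """
    if noise_model not in (MIXTURE, ADDITIVE):
        raise ValueError(f"unknown noise_model {noise_model!r}")
    if set(composition.cell_types) != set(test_profiles.columns):
        raise ValueError(
            "composition cell types "
            f"{sorted(composition.cell_types)} do not match test profiles "
            f"{sorted(test_profiles.columns)}"
        )
    p = composition.series.loc[test_profiles.columns]
    signal = test_profiles.to_numpy(dtype=float) @ p.to_numpy()
    if noise is None or noise.rho == 0.0:
        values = signal
    else:
        rng = np.random.default_rng(noise.seed)
        eps = rng.uniform(0.0, 1.0, size=signal.shape)
        if noise_model == MIXTURE:
            values = (1.0 - noise.rho) * signal + noise.rho * eps
        else:
            values = signal + noise.rho * eps
    bulk = pd.Series(values, index=test_profiles.index, name="bulk")
    bulk.attrs["simulated"] = True
    return bulk


def _condition_seed(seed: int, *indices: int) -> int:
    """Deterministic per-condition child seed."""
    return int(np.random.SeedSequence([int(seed), *map(int, indices)])
               .generate_state(1)[0])


def _replicates(
    test_profiles: pd.DataFrame | list[pd.DataFrame], count: int | None = None
) -> list[pd.DataFrame]:
    if isinstance(test_profiles, pd.DataFrame):
        reps = [test_profiles] * (count if count else 1)
    else:
        reps = list(test_profiles)
        if count is not None and len(reps) != count:
            raise ValueError(
                f"got {len(reps)} test-profile replicates for {count} seeds"
            )
    return reps


def _estimate_row(result, truth: pd.Series | None) -> dict:
    row = {
        "cetygo": result.cetygo,
        "proportion_sum": result.proportion_sum,
        "n_sites_used": result.n_sites_used,
    }
    if result.proportions is not None:
        for ct, v in result.proportions.items():
            row[f"est_{ct}"] = v
        if truth is not None:
            est = result.proportions
            t = truth.loc[est.index]
            row["rmse_truth"] = float(
                np.sqrt(np.mean((est.to_numpy() - t.to_numpy()) ** 2))
            )
    if truth is not None:
        for ct, v in truth.items():
            row[f"true_{ct}"] = v
    return row


def run_noise_experiment(
    model: DeconvolutionModel,
    test_profiles: pd.DataFrame | list[pd.DataFrame],
    base_composition: pd.Series,
    seeds: list[int],
    constraint_mode: str = NONNEG,
    noise_model: str = MIXTURE,
) -> pd.DataFrame:
    """Deconvolution accuracy across the 31-level noise grid.

    For every seed and noise level the bulk is reconstructed from the test
    profiles at the base composition, deconvolved, and scored: the table
    records the error score, the RMSE between estimated and true
    proportions, and the estimated proportion sum.
    """
    composition = CompositionSpec.from_series(base_composition)
    reps = _replicates(test_profiles, len(seeds))
    grid = noise_grid()
    records = []
    for seed, profiles in zip(seeds, reps):
        for i, rho in enumerate(grid):
            noise = NoiseSpec(rho=float(rho), seed=_condition_seed(seed, i))
            bulk = reconstruct_bulk(profiles, composition, noise, noise_model)
            (result,) = deconvolve_with_error(model, bulk, constraint_mode)
            truth = composition.series.reindex(model.cell_types).fillna(0.0)
            records.append(
                {"seed": seed, "rho": float(rho),
                 **_estimate_row(result, truth)}
            )
    return pd.DataFrame(records)


def run_loo_experiment(
    panel: ReferencePanel,
    test_profiles: pd.DataFrame | list[pd.DataFrame],
    omitted_type: str,
    base_composition: pd.Series | None = None,
    omitted_proportions: tuple[float, ...] = (
        0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9,
    ),
    sites_per_type: int = 100,
    p_threshold: float = 1e-8,
    constraint_mode: str = NONNEG,
) -> pd.DataFrame:
    """Error inflation when a cell type is missing from the reference panel.

    A model is trained with ``omitted_type`` removed from the panel; bulks
    containing all cell types are reconstructed noise-free with the omitted
    type at each proportion q (the remaining types scaled to 1 - q in their
    base ratios) and deconvolved with the incomplete model.
    """
    if omitted_type not in panel.cell_type_names:
        raise KeyError(f"cell type {omitted_type!r} not in panel")
    loo_model = train_model(
        panel.drop_cell_type(omitted_type), sites_per_type, p_threshold
    )
    reps = _replicates(test_profiles)
    all_types = sorted(reps[0].columns)
    if base_composition is None:
        from .synthetic import whole_blood_composition

        base_composition = whole_blood_composition(all_types)
    kept = [t for t in all_types if t != omitted_type]
    base_kept = base_composition.loc[kept]
    base_kept = base_kept / base_kept.sum()
    records = []
    for rep_idx, profiles in enumerate(reps):
        for q in omitted_proportions:
            series = pd.Series(0.0, index=all_types)
            series[omitted_type] = q
            series[kept] = (1.0 - q) * base_kept
            composition = CompositionSpec.from_series(series)
            bulk = reconstruct_bulk(profiles, composition)
            (result,) = deconvolve_with_error(loo_model, bulk, constraint_mode)
            truth = series.reindex(loo_model.cell_types)
            records.append(
                {
                    "replicate": rep_idx,
                    "omitted_type": omitted_type,
                    "omitted_proportion": float(q),
                    **_estimate_row(result, truth),
                }
            )
    return pd.DataFrame(records)


def run_subset_experiment(
    panel: ReferencePanel,
    test_profiles: pd.DataFrame | list[pd.DataFrame],
    subsets: list[tuple[str, ...]] | None = None,
    compositions: list[CompositionSpec] | None = None,
    sites_per_type: int = 100,
    p_threshold: float = 1e-8,
    constraint_mode: str = NONNEG,
) -> pd.DataFrame:
    """Incomplete-panel sweep: subset models vs a full composition grid.

    Every model built from a subset of the panel's cell types is applied to
    noise-free bulks spanning all cell types; each record carries the subset
    size and the covered proportion (the share of the bulk composed of cell
    types the model knows about).
    """
    all_types = panel.cell_type_names
    if subsets is None:
        subsets = panel_subsets(all_types)
    if compositions is None:
        compositions = composition_grid(all_types)
    reps = _replicates(test_profiles)
    models: dict[tuple[str, ...], DeconvolutionModel] = {}
    with warnings.catch_warnings():
        # subset models legitimately cover < 80% of full-grid bulk probes
        warnings.simplefilter("ignore")
        for subset in subsets:
            models[subset] = train_model(
                panel.subset_cell_types(list(subset)),
                sites_per_type,
                p_threshold,
            )
    records = []
    for rep_idx, profiles in enumerate(reps):
        bulks = {
            i: reconstruct_bulk(profiles, comp)
            for i, comp in enumerate(compositions)
        }
        for subset in subsets:
            model = models[subset]
            for i, comp in enumerate(compositions):
                series = comp.series
                # compositions are grid multiples; round so equal coverages
                # land in the same bin despite float summation
                covered = round(float(series.loc[list(subset)].sum()), 10)
                (result,) = deconvolve_with_error(
                    model, bulks[i], constraint_mode
                )
                truth = series.reindex(model.cell_types)
                records.append(
                    {
                        "replicate": rep_idx,
                        "subset": "+".join(subset),
                        "subset_size": len(subset),
                        "composition_id": i,
                        "covered_proportion": covered,
                        **_estimate_row(result, truth),
                    }
                )
    return pd.DataFrame(records)
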