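"""Selection of cell-type-discriminative marker CpGs.

Candidate probes are gated by a one-way ANOVA F-test across cell-type groups
(p < 1e-8 by default). For each cell type the gated probes are then ranked by
the one-vs-rest mean difference (target-type mean minus the mean over all
other samples) and the top half hypermethylated / half hypomethylated probes
are retained, 100 sites per cell type by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import ReferencePanel

__all__ = ["MarkerEntry", "MarkerSet", "one_way_f_test", "select_markers"]

HYPER = "hyper"
HYPO = "hypo"


@dataclass(frozen=True)
class MarkerEntry:
    """One selected marker probe for one cell type."""

    probe: str
    cell_type: str
    direction: str  # "hyper" or "hypo" relative to the other cell types
    statistic: float  # one-way ANOVA F statistic
    p_value: float
    mean_difference: float  # target-type mean minus rest mean


@dataclass
class MarkerSet:
    """Ordered collection of selected marker probes with provenance."""

    entries: list[MarkerEntry]
    sites_per_type: int
    p_threshold: float
    cell_types: list[str] = field(default_factory=list)

    @property
    def probes(self) -> list[str]:
        """Deduplicated probe list in first-selected order; defines M."""
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.probe, None)
        return list(seen)

    def counts(self) -> pd.DataFrame:
        """Achieved entry counts per (cell type, direction)."""
        out = pd.DataFrame(
            0, index=self.cell_types, columns=[HYPER, HYPO], dtype=int
        )
        for e in self.entries:
            out.loc[e.cell_type, e.direction] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.probe, e.cell_type, e.direction, e.statistic,
                 e.p_value, e.mean_difference)
                for e in self.entries
            ],
            columns=["probe", "cell_type", "direction", "statistic",
                     "p_value", "mean_difference"],
        )


def one_way_f_test(
    values: np.ndarray, group_columns: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-way fixed-effects ANOVA over the rows of ``values``.

    Parameters
    ----------
    values
        Array of shape (n_probes, n_samples).
    group_columns
        One integer index array per group, partitioning the columns.

    Returns
    -------
    F, p
        Arrays of per-row F statistics and upper-tail p-values. Rows with
        zero within-group variance get F = inf (p = 0) when the group means
        differ, and p = 1 when all values are identical.
    """
    k = len(group_columns)
    n = values.shape[1]
    if k < 2:
        raise ValueError("ANOVA requires at least two groups")
    if any(len(idx) < 2 for idx in group_columns):
        raise ValueError("every group needs >= 2 samples")
    grand = values.mean(axis=1)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    for idx in group_columns:
        g = values[:, idx]
        gm = g.mean(axis=1)
        ssb += len(idx) * (gm - grand) ** 2
        ssw += ((g - gm[:, None]) ** 2).sum(axis=1)
    df_between, df_within = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_between) / (ssw / df_within)
    p = stats.f.sf(f, df_between, df_within)
    # degenerate rows: (near-)zero scatter at float precision
    tiny = 1e-20
    zero_w = ssw <= tiny
    zero_b = ssb <= tiny
    f = np.where(zero_w & ~zero_b, np.inf, f)
    p = np.where(zero_w & ~zero_b, 0.0, p)
    f = np.where(zero_w & zero_b, 0.0, f)
    p = np.where(zero_w & zero_b, 1.0, p)
    return f, p


def select_markers(
    panel: ReferencePanel,
    sites_per_type: int = 100,
    p_threshold: float = 1e-8,
) -> MarkerSet:
    """Pick the top discriminative probes for every cell type in the panel.

    Probes with any missing beta are excluded before testing. Among probes
    passing the ANOVA gate, each cell type contributes its
    ``sites_per_type / 2`` most hypermethylated and most hypomethylated
    probes by one-vs-rest mean difference; ties break on smaller p-value,
    then lexicographic probe ID. If a direction has fewer qualifying probes
    than requested, a warning is emitted and the achieved count recorded.
    """
    if sites_per_type < 2 or sites_per_type % 2:
        raise ValueError("sites_per_type must be a positive even number")
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError("p_threshold must be in (0, 1]")
    cell_types = panel.cell_type_names
    if len(cell_types) < 2:
        raise ValueError("marker selection requires >= 2 cell types")
    for ct in cell_types:
        if len(panel.samples_of(ct)) < 2:
            raise ValueError(
                f"cell type {ct!r} has < 2 replicates; ANOVA needs within-"
                "group replication"
            )

    complete = panel.betas.dropna(axis=0, how="any")
    values = complete.to_numpy(dtype=float)
    col_pos = {s: i for i, s in enumerate(complete.columns)}
    groups = [
        np.array([col_pos[s] for s in panel.samples_of(ct)])
        for ct in cell_types
    ]
    f_stat, p_val = one_way_f_test(values, groups)
    passing = p_val < p_threshold
    if not passing.any():
        warnings.warn(
            "no probes pass the ANOVA significance gate "
            f"(p < {p_threshold:g}); empty marker set",
            stacklevel=2,
        )

    half = sites_per_type // 2
    entries: list[MarkerEntry] = []
    for ct, idx in zip(cell_types, groups):
        rest = np.setdiff1d(np.arange(values.shape[1]), idx)
        diff = values[:, idx].mean(axis=1) - values[:, rest].mean(axis=1)
        cand = pd.DataFrame(
            {
                "probe": complete.index,
                "statistic": f_stat,
                "p_value": p_val,
                "mean_difference": diff,
            }
        )[passing]
        for direction in (HYPER, HYPO):
            if direction == HYPER:
                pool = cand[cand["mean_difference"] > 0]
                pool = pool.sort_values(
                    ["mean_difference", "p_value", "probe"],
                    ascending=[False, True, True],
                )
            else:
                pool = cand[cand["mean_difference"] < 0]
                pool = pool.sort_values(
                    ["mean_difference", "p_value", "probe"],
                    ascending=[True, True, True],
                )
            top = pool.head(half)
            if len(top) < half:
                warnings.warn(
                    f"cell type {ct!r}: only {len(top)} {direction}methylated "
                    f"probes pass the gate (requested {half})",
                    stacklevel=2,
                )
            entries.extend(
                MarkerEntry(
                    probe=str(r.probe),
                    cell_type=ct,
                    direction=direction,
                    statistic=float(r.statistic),
                    p_value=float(r.p_value),
                    mean_difference=float(r.mean_difference),
                )
                for r in top.itertuples()
            )

    return MarkerSet(
        entries=entries,
        sites_per_type=sites_per_type,
        p_threshold=p_threshold,
        cell_types=cell_types,
    )
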