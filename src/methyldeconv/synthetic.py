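"""Synthetic reference panels with planted cell-type marker structure.

The generator emulates a flow-sorted methylation reference panel: each cell
type owns a disjoint block of hypermethylated and hypomethylated marker
probes separated from the other types by a configurable effect size, on top
of a background of non-informative probes whose mean is shared across types.
Replicate samples are drawn with clipped-Gaussian within-type noise. Probe
identities are permuted per seed so panels generated under different seeds
plant their markers at different probes ("wrong tissue" surrogates share the
probe universe but not the marker structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .panel import ReferencePanel

__all__ = [
    "BLOOD_CELL_TYPES",
    "whole_blood_composition",
    "PanelDesign",
    "generate_reference_panel",
    "generate_test_individual",
    "planted_markers",
]

# Conventional six-type leukocyte panel for whole blood.
BLOOD_CELL_TYPES = ["B", "CD4T", "CD8T", "Gran", "Mono", "NK"]

# Granulocyte-dominant whole-blood-like mean composition used as the default
# ground truth in simulations. A plausible stand-in, not a measured panel.
_WHOLE_BLOOD = {
    "Gran": 0.58,
    "CD4T": 0.16,
    "CD8T": 0.09,
    "Mono": 0.08,
    "B": 0.06,
    "NK": 0.03,
}


def whole_blood_composition(cell_types: list[str] | None = None) -> pd.Series:
    """Granulocyte-dominant base composition over the given cell types.

    For the standard six blood types the named defaults are used; for any
    other label set the same ordered weights are assigned to the sorted
    labels (largest first is arbitrary but fixed).
    """
    if cell_types is None:
        cell_types = BLOOD_CELL_TYPES
    cell_types = list(cell_types)
    if set(cell_types) == set(_WHOLE_BLOOD):
        return pd.Series({ct: _WHOLE_BLOOD[ct] for ct in sorted(cell_types)})
    weights = np.sort(np.array(list(_WHOLE_BLOOD.values())))[::-1][: len(cell_types)]
    weights = weights / weights.sum()
    return pd.Series(weights, index=sorted(cell_types))


@dataclass
class PanelDesign:
    """Parameters of a synthetic reference panel.

    effect_size is the beta-unit separation between a marker's target cell
    type and the other types; markers sit at (1 +- effect_size) / 2, so the
    full range (0, 1] is feasible.
    """

    n_cell_types: int = 6
    n_replicates: int = 6
    n_hyper_markers: int = 150  # planted hypermethylated probes per type
    n_hypo_markers: int = 150  # planted hypomethylated probes per type
    n_background: int = 2000
    effect_size: float = 0.8
    within_type_sd: float = 0.02
    sex_chromosome_fraction: float = 0.1
    seed: int = 0
    cell_type_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        if not 0.0 < self.effect_size <= 1.0:
            raise ValueError("effect_size must be in (0, 1]")
        if min(self.n_cell_types, self.n_replicates, self.n_hyper_markers,
               self.n_hypo_markers, self.n_background) < 1:
            raise ValueError("all design counts must be >= 1")
        if self.n_cell_types < 2:
            raise ValueError("need >= 2 cell types")
        if self.within_type_sd <= 0:
            raise ValueError("within_type_sd must be > 0")
        if not 0.0 <= self.sex_chromosome_fraction < 1.0:
            raise ValueError("sex_chromosome_fraction must be in [0, 1)")
        if self.n_sex_probes > self.n_background:
            raise ValueError(
                "sex_chromosome_fraction too large: sex probes are drawn "
                "from the background block "
                f"({self.n_sex_probes} > {self.n_background})"
            )
        if self.cell_type_names is None:
            if self.n_cell_types == len(BLOOD_CELL_TYPES):
                self.cell_type_names = list(BLOOD_CELL_TYPES)
            else:
                self.cell_type_names = [
                    f"CT{i + 1}" for i in range(self.n_cell_types)
                ]
        if len(self.cell_type_names) != self.n_cell_types:
            raise ValueError("cell_type_names length != n_cell_types")
        if len(set(self.cell_type_names)) != self.n_cell_types:
            raise ValueError("cell_type_names must be unique")

    @property
    def n_probes(self) -> int:
        return (
            self.n_cell_types * (self.n_hyper_markers + self.n_hypo_markers)
            + self.n_background
        )

    @property
    def n_sex_probes(self) -> int:
        return int(round(self.sex_chromosome_fraction * self.n_probes))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PanelDesign":
        return cls(**mapping)


def _layout(design: PanelDesign):
    """Deterministic probe means, roles and annotation for a design.

    Returns (means, annotation, truth) where means is a DataFrame
    (probes x cell types), annotation a Series probe -> chromosome and truth
    a DataFrame of the planted markers. Probe order is permuted under the
    design seed so marker positions differ between seeds.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0]))
    types = sorted(design.cell_type_names)
    lo = (1.0 - design.effect_size) / 2.0
    hi = (1.0 + design.effect_size) / 2.0

    n = design.n_probes
    means = np.empty((n, len(types)))
    role_type: list[str] = []
    role_dir: list[str] = []
    row = 0
    for k, ct in enumerate(types):
        for _ in range(design.n_hyper_markers):
            means[row] = lo
            means[row, k] = hi
            role_type.append(ct)
            role_dir.append("hyper")
            row += 1
        for _ in range(design.n_hypo_markers):
            means[row] = hi
            means[row, k] = lo
            role_type.append(ct)
            role_dir.append("hypo")
            row += 1
    background_mean = rng.uniform(0.1, 0.9, size=design.n_background)
    means[row:] = background_mean[:, None]
    role_type.extend([""] * design.n_background)
    role_dir.extend([""] * design.n_background)

    # chromosomes: markers always autosomal; the sex probes are carved out
    # of the background block so filtering never destroys planted structure
    autosomes = [f"chr{i}" for i in range(1, 23)]
    chroms = [autosomes[i % 22] for i in range(n)]
    for i in range(design.n_sex_probes):
        chroms[n - 1 - i] = "chrX" if i % 2 == 0 else "chrY"

    order = rng.permutation(n)
    probe_ids = pd.Index(
        [f"cg{i:08d}" for i in range(n)], name="probe"
    )
    means = pd.DataFrame(means[order], index=probe_ids, columns=types)
    annotation = pd.Series(
        np.array(chroms, dtype=object)[order], index=probe_ids, name="chromosome"
    )
    truth = pd.DataFrame(
        {
            "cell_type": np.array(role_type, dtype=object)[order],
            "direction": np.array(role_dir, dtype=object)[order],
        },
        index=probe_ids,
    )
    truth = truth[truth["cell_type"] != ""]
    return means, annotation, truth


def planted_markers(design: PanelDesign) -> pd.DataFrame:
    """Ground-truth marker table (probe -> cell_type, direction)."""
    _, _, truth = _layout(design)
    return truth


def _draw(means: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Clipped-Gaussian beta draw around per-probe means."""
    return np.clip(rng.normal(means, sd), 0.0, 1.0)


def generate_reference_panel(design: PanelDesign) -> ReferencePanel:
    """Draw a full replicate panel for the design; deterministic in the seed."""
    means, annotation, _ = _layout(design)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    types = sorted(design.cell_type_names)
    columns = {}
    for ct in types:
        base = means[ct].to_numpy()
        for rep in range(design.n_replicates):
            columns[f"{ct}_rep{rep + 1}"] = _draw(
                base, design.within_type_sd, rng
            )
    betas = pd.DataFrame(columns, index=means.index)
    cell_types = pd.Series(
        {s: s.rsplit("_rep", 1)[0] for s in betas.columns}, name="cell_type"
    )
    return ReferencePanel(betas, cell_types, annotation)


def generate_test_individual(
    design: PanelDesign,
    seed: int,
    panel: ReferencePanel | None = None,
) -> pd.DataFrame:
    """One held-out profile per cell type, exchangeable with the panel.

    Test individuals are fresh draws from the same per-type distributions as
    the reference replicates; ``seed`` distinguishes individuals and is
    independent of the replicate noise stream.
    """
    means, _, _ = _layout(design)
    if panel is not None and not means.index.equals(panel.probes):
        raise ValueError("panel probes do not match this design")
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 2, seed]))
    out = {}
    for ct in means.columns:
        out[ct] = _draw(means[ct].to_numpy(), design.within_type_sd, rng)
    return pd.DataFrame(out, index=means.index)
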