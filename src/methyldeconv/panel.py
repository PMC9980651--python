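"""Reference panels of purified cell-type methylation profiles.

A reference panel is a beta-value matrix (probes x samples) together with a
cell-type label per sample and, optionally, a chromosome annotation per probe.
It is the training input for building a deconvolution model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ReferencePanel", "filter_autosomal", "SEX_CHROMOSOMES"]

# Labels treated as non-autosomal, with and without the UCSC "chr" prefix.
# Mitochondrial probes are excluded alongside the sex chromosomes.
SEX_CHROMOSOMES = frozenset(
    {"x", "y", "m", "mt", "chrx", "chry", "chrm", "chrmt"}
)


@dataclass
class ReferencePanel:
    """Beta matrix of purified cell-type samples with cell-type labels.

    Parameters
    ----------
    betas
        DataFrame of beta values in [0, 1] (NaN marks missing), rows indexed
        by probe ID, columns by reference sample ID.
    cell_types
        Series mapping sample ID -> cell-type label. Must cover every column
        of ``betas``.
    annotation
        Optional Series mapping probe ID -> chromosome label; required only
        for autosomal filtering.
    """

    betas: pd.DataFrame
    cell_types: pd.Series
    annotation: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.betas.index.is_unique:
            dups = self.betas.index[self.betas.index.duplicated()].unique()
            raise ValueError(f"duplicate probe IDs in panel: {list(dups[:5])}")
        if not self.betas.columns.is_unique:
            dups = self.betas.columns[self.betas.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample IDs in panel: {list(dups[:5])}")
        missing = self.betas.columns.difference(self.cell_types.index)
        if len(missing):
            raise ValueError(
                f"samples without a cell-type label: {list(missing[:5])}"
            )
        self.cell_types = self.cell_types.loc[self.betas.columns]
        values = self.betas.to_numpy(dtype=float)
        finite = values[~np.isnan(values)]
        if finite.size and (np.isinf(finite).any()
                            or finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("beta values must be finite and in [0, 1] (or NaN)")

    @property
    def probes(self) -> pd.Index:
        return self.betas.index

    @property
    def samples(self) -> pd.Index:
        return self.betas.columns

    @property
    def cell_type_names(self) -> list[str]:
        """Distinct cell-type labels in stable (sorted) order."""
        return sorted(self.cell_types.unique())

    def samples_of(self, cell_type: str) -> list[str]:
        sel = self.cell_types[self.cell_types == cell_type]
        if sel.empty:
            raise KeyError(f"no samples with cell type {cell_type!r}")
        return list(sel.index)

    def subset_cell_types(self, keep: list[str]) -> "ReferencePanel":
        """Panel restricted to the samples of the given cell types."""
        unknown = set(keep) - set(self.cell_type_names)
        if unknown:
            raise KeyError(f"cell types not in panel: {sorted(unknown)}")
        cols = [s for s in self.samples if self.cell_types[s] in set(keep)]
        return ReferencePanel(
            self.betas[cols], self.cell_types.loc[cols], self.annotation
        )

    def drop_cell_type(self, cell_type: str) -> "ReferencePanel":
        """Panel with every sample of ``cell_type`` removed (leave-one-out)."""
        keep = [t for t in self.cell_type_names if t != cell_type]
        if len(keep) == len(self.cell_type_names):
            raise KeyError(f"cell type {cell_type!r} not in panel")
        return self.subset_cell_types(keep)


def filter_autosomal(panel: ReferencePanel) -> ReferencePanel:
    """Drop probes mapped to the sex chromosomes or the mitochondrial genome.

    Deconvolution models are trained on autosomal probes only so that the
    sex of reference donors does not leak into the marker profiles.

    Raises
    ------
    ValueError
        If any probe lacks a chromosome annotation.
    """
    if panel.annotation is None:
        raise ValueError("panel has no chromosome annotation; cannot filter")
    ann = panel.annotation
    unannotated = panel.probes.difference(ann.index)
    if len(unannotated):
        raise ValueError(
            "probes without chromosome annotation: "
            f"{list(unannotated[:10])}"
            + ("..." if len(unannotated) > 10 else "")
        )
    chrom = ann.loc[panel.probes].astype(str).str.strip().str.lower()
    keep = panel.probes[~chrom.isin(SEX_CHROMOSOMES)]
    return ReferencePanel(
        panel.betas.loc[keep], panel.cell_types, panel.annotation.loc[keep]
    )
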