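"""Deconvolution models: per-cell-type mean profiles over marker probes."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .markers import MarkerEntry, MarkerSet, select_markers
from .panel import ReferencePanel, filter_autosomal

__all__ = ["DeconvolutionModel", "build_model", "train_model",
           "save_model", "load_model"]


@dataclass
class DeconvolutionModel:
    """Mean reference profiles (M probes x N cell types) plus provenance.

    ``mean_profiles[j, k]`` is the average beta at marker probe j over the
    reference replicates of cell type k; this is the design matrix of the
    constrained projection.
    """

    mean_profiles: pd.DataFrame  # probes x cell types
    markers: MarkerSet | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mean_profiles.shape[1] < 2:
            raise ValueError("a deconvolution model needs >= 2 cell types")
        if not self.mean_profiles.index.is_unique:
            raise ValueError("duplicate probes in mean_profiles")
        vals = self.mean_profiles.to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any() or pd.isna(vals).any():
            raise ValueError("mean profile values must lie in [0, 1]")
        self.mean_profiles = self.mean_profiles.rename_axis(index="probe")

    @property
    def cell_types(self) -> list[str]:
        return list(self.mean_profiles.columns)

    @property
    def n_sites(self) -> int:
        return self.mean_profiles.shape[0]


def build_model(
    panel: ReferencePanel, markers: MarkerSet, provenance: dict | None = None
) -> DeconvolutionModel:
    """Average the panel's replicates per cell type over the marker probes."""
    probes = pd.Index(markers.probes)
    missing = probes.difference(panel.probes)
    if len(missing):
        raise KeyError(
            f"marker probes absent from panel: {list(missing[:10])}"
            + ("..." if len(missing) > 10 else "")
        )
    cols = {}
    for ct in panel.cell_type_names:
        cols[ct] = panel.betas.loc[probes, panel.samples_of(ct)].mean(axis=1)
    mean_profiles = pd.DataFrame(cols, index=probes)
    prov = {
        "sites_per_type": markers.sites_per_type,
        "p_threshold": markers.p_threshold,
        "version": __version__,
    }
    prov.update(provenance or {})
    return DeconvolutionModel(mean_profiles, markers, prov)


def train_model(
    panel: ReferencePanel,
    sites_per_type: int = 100,
    p_threshold: float = 1e-8,
    autosomal_only: bool = False,
) -> DeconvolutionModel:
    """Convenience pipeline: (optionally filter) -> select markers -> means."""
    if autosomal_only:
        panel = filter_autosomal(panel)
    markers = select_markers(panel, sites_per_type, p_threshold)
    return build_model(
        panel, markers, provenance={"autosomal_only": autosomal_only}
    )


def save_model(model: DeconvolutionModel, directory: str | Path) -> None:
    """Serialise a model to ``directory`` (TSV profiles + JSON sidecar).

    Floats are written at full precision so that load(save(m)) is lossless.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model.mean_profiles.to_csv(
        directory / "mean_profiles.tsv",
        sep="\t",
        index_label="probe",
        float_format="%.17g",
    )
    meta = {
        "cell_types": model.cell_types,
        "provenance": model.provenance,
        "markers": None,
    }
    if model.markers is not None:
        meta["markers"] = {
            "sites_per_type": model.markers.sites_per_type,
            "p_threshold": model.markers.p_threshold,
            "cell_types": model.markers.cell_types,
            "entries": [
                {
                    "probe": e.probe,
                    "cell_type": e.cell_type,
                    "direction": e.direction,
                    "statistic": e.statistic,
                    "p_value": e.p_value,
                    "mean_difference": e.mean_difference,
                }
                for e in model.markers.entries
            ],
        }
    (directory / "model.json").write_text(json.dumps(meta, indent=1))


def load_model(directory: str | Path) -> DeconvolutionModel:
    directory = Path(directory)
    profiles = pd.read_csv(
        directory / "mean_profiles.tsv",
        sep="\t",
        index_col="probe",
        float_precision="round_trip",
    )
    meta = json.loads((directory / "model.json").read_text())
    profiles = profiles[meta["cell_types"]]
    markers = None
    if meta.get("markers"):
        m = meta["markers"]
        markers = MarkerSet(
            entries=[MarkerEntry(**e) for e in m["entries"]],
            sites_per_type=m["sites_per_type"],
            p_threshold=m["p_threshold"],
            cell_types=m["cell_types"],
        )
    return DeconvolutionModel(profiles, markers, meta.get("provenance", {}))
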