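import numpy as np
import pandas as pd
import pytest

import methyldeconv as md


@pytest.fixture(scope="session")
def small_design() -> md.PanelDesign:
    """Compact 6-type blood-like design used across the unit tests."""
    return md.PanelDesign(
        n_hyper_markers=50,
        n_hypo_markers=50,
        n_background=400,
        seed=1,
    )


@pytest.fixture(scope="session")
def raw_panel(small_design) -> md.ReferencePanel:
    return md.generate_reference_panel(small_design)


@pytest.fixture(scope="session")
def panel(raw_panel) -> md.ReferencePanel:
    return md.filter_autosomal(raw_panel)


@pytest.fixture(scope="session")
def marker_set(panel) -> md.MarkerSet:
    return md.select_markers(panel)


@pytest.fixture(scope="session")
def model(panel, marker_set) -> md.DeconvolutionModel:
    return md.build_model(panel, marker_set)


@pytest.fixture(scope="session")
def test_individuals(small_design) -> list[pd.DataFrame]:
    return [md.generate_test_individual(small_design, i) for i in range(3)]


def toy_panel(
    betas: np.ndarray,
    cell_types: list[str],
    probes: list[str] | None = None,
    annotation: dict | None = None,
) -> md.ReferencePanel:
    """Hand-built panel; one column per entry of ``cell_types``."""
    betas = np.asarray(betas, dtype=float)
    if probes is None:
        probes = [f"p{i}" for i in range(betas.shape[0])]
    samples = []
    seen: dict[str, int] = {}
    for ct in cell_types:
        seen[ct] = seen.get(ct, 0) + 1
        samples.append(f"{ct}_s{seen[ct]}")
    frame = pd.DataFrame(betas, index=probes, columns=samples)
    labels = pd.Series(dict(zip(samples, cell_types)))
    ann = pd.Series(annotation) if annotation is not None else None
    return md.ReferencePanel(frame, labels, ann)
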