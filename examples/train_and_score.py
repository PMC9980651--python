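"""Train a deconvolution model and score a reconstructed blood profile.

Builds a synthetic 6-cell-type reference panel, trains a model (ANOVA-gated
marker selection, 100 sites per type), then deconvolves two bulk profiles of
known granulocyte-dominant composition: one noise-free, one with 20% of the
signal replaced by uniform noise.
"""

import methyldeconv as md

design = md.PanelDesign(seed=11)
panel = md.filter_autosomal(md.generate_reference_panel(design))
model = md.train_model(panel)
print(f"model: {model.n_sites} marker probes x {len(model.cell_types)} cell types")

truth = md.whole_blood_composition()
composition = md.CompositionSpec.from_series(truth)
profiles = md.generate_test_individual(design, seed=99)

for label, noise in [("noise-free", None),
                     ("20% noise", md.NoiseSpec(rho=0.2, seed=1))]:
    bulk = md.reconstruct_bulk(profiles, composition, noise)
    (result,) = md.deconvolve_with_error(model, bulk)
    est = ", ".join(
        f"{ct}={result.proportions[ct]:.3f}" for ct in model.cell_types
    )
    print(f"{label:>10}: {est}")
    print(
        f"{'':>10}  sum={result.proportion_sum:.3f}  "
        f"CETYGO={result.cetygo:.4f}  (truth: Gran=0.58, CD4T=0.16, ...)"
    )

print(
    "\nA CETYGO near 0 means the estimated composition explains the observed "
    "betas; the noisy profile scores higher and its proportion sum drifts "
    "below 1."
)
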