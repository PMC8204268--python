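"""Reduced end-to-end registration-uncertainty analysis.

Runs the full pipeline (bootstrap -> reconstruct -> perturb -> register ->
propagate labels -> Dice against the gold-standard registration) on a
small design, then propagates the registration jitter into SUVr precision.
Takes a few minutes on one CPU.
"""

from petregu import desk_design, run_suvr_propagation, run_uncertainty_analysis

design = desk_design()
print(f"design: frames={design.frames}, levels={design.count_levels}, "
      f"{design.n_bootstrap} bootstraps, grid {design.grid_shape}")

matrix, records = run_uncertainty_analysis(design, root_seed=7)
print("\nDice SD per ROI and count level (registration precision):")
print(matrix.per_roi[["roi", "count_level", "n", "n_failed", "sd"]].to_string(index=False))

table = run_suvr_propagation(design, 7, records=records)
print("\nSUVr coefficient of variation under registration jitter:")
print(table[["frame", "count_level", "pvc", "mean_suvr", "cov"]].to_string(index=False))
print("\nLower count levels give larger Dice SD (less precise registration) "
      "and larger SUVr CoV; PVC amplifies the CoV because it sharpens the "
      "image around the jittering ROI boundaries.")
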