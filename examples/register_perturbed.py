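"""Perturb the MR position and recover it by NMI registration.

The T1w image is repositioned by a random rigid transform drawn uniformly
within +/-10 mm and +/-10 deg (only its affine changes, voxel values stay
intact), then registered back to a reconstructed PET image.
"""

import numpy as np

from petregu import (
    FRAME_SPECS,
    PerturbationSpec,
    ReconConfig,
    RigidTransform,
    Sinogram,
    attenuation_factors,
    bin_events,
    default_system,
    draw_perturbation,
    make_activity,
    make_phantom,
    osem,
    perturb_grid,
    register_rigid,
    simulate_prompts,
)

labels, regions, mu_map, t1w = make_phantom(seed=1)
sys = default_system(labels)
activity = make_activity(labels, regions, FRAME_SPECS["late_neg"], sys)
af = attenuation_factors(mu_map, sys)
lm, _, randoms = simulate_prompts(activity, mu_map, sys, seed=1)
pet = osem(bin_events(lm, sys), sys, ReconConfig(mode="AC", iterations=2),
           af=af, randoms_est=randoms)

q = draw_perturbation(PerturbationSpec(seed=3))
print("applied perturbation :", np.round(q.parameters, 2), "(tx ty tz rx ry rz)")
moved = perturb_grid(t1w, q)

result = register_rigid(pet, moved)
residual = RigidTransform.from_matrix(
    result.transform.matrix @ q.recentered(t1w.world_center()).matrix
)
print("recovered residual   :", np.round(residual.parameters, 3))
print(f"final NMI {result.final_similarity:.4f}, converged={result.converged}, "
      f"{result.n_evaluations} evaluations")
print("\nA residual near zero means the registration undid the misposition; "
      "residual spread across noisy bootstrap replicates is the "
      "registration uncertainty this package quantifies.")
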