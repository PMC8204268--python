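"""SUVr with and without iterative-Yang partial volume correction.

On the high-contrast (amyloid-negative-like) late frame PVC moves the
target SUVr down; on the contrast-less (positive-like) frame it moves it
up — the mechanism by which PVC widens the separation between the two
scan types.  The quantitative PET here is reconstructed from the expected
(noise-free) data at the 30% clinical count level so the resolution-driven
mechanism is visible without Poisson noise on top.
"""

from petregu import (
    FRAME_SPECS,
    ReconConfig,
    Sinogram,
    attenuation_factors,
    default_system,
    forward_project,
    make_activity,
    make_phantom,
    osem,
    simulate_prompts,
    suvr,
    yang_pvc,
)

labels, regions, mu_map, _ = make_phantom(seed=1)
sys = default_system(labels)
af = attenuation_factors(mu_map, sys)
tid, rid = regions.target.label_id, regions.reference.label_id

for frame in ("late_neg", "late_pos"):
    activity = make_activity(labels, regions, FRAME_SPECS[frame], sys)
    _, scatter, randoms = simulate_prompts(activity, mu_map, sys, seed=0, frame_id=frame)
    trues = af.values * forward_project(activity, sys).values
    expected = Sinogram(0.30 * (trues + scatter.values + randoms.values))
    qpet = osem(
        expected,
        sys,
        ReconConfig(mode="QNT", iterations=4),
        af=af,
        scatter_est=Sinogram(scatter.values * 0.30, "scatter"),
        randoms_est=Sinogram(randoms.values * 0.30, "randoms"),
    )
    plain = suvr(qpet, labels, tid, rid)
    corrected = suvr(yang_pvc(qpet, labels, psf_fwhm_mm=4.5), labels, tid, rid,
                     pvc_applied=True)
    arrow = "down" if corrected.suvr < plain.suvr else "up"
    print(f"{frame}: SUVr {plain.suvr:.3f} -> PVC {corrected.suvr:.3f} ({arrow})")
print("\nSUVr = mean(precuneus analogue) / mean(cerebellar GM analogue); the "
      "true ratio is 1.0 in both frames.")
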