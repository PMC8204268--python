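"""OSEM reconstruction under the three correction modes.

NAC omits attenuation correction, AC applies it, QNT adds scatter
correction; randoms are corrected in all modes.  Regional means show how
the modes differ quantitatively (only QNT approaches the true activity).
"""

import numpy as np

from petregu import (
    FRAME_SPECS,
    ReconConfig,
    Sinogram,
    attenuation_factors,
    bin_events,
    bootstrap_listmode,
    default_system,
    estimate_scatter,
    make_activity,
    make_phantom,
    osem,
    simulate_prompts,
)

labels, regions, mu_map, _ = make_phantom(seed=1)
sys = default_system(labels)
activity = make_activity(labels, regions, FRAME_SPECS["late_neg"], sys)
af = attenuation_factors(mu_map, sys)
lm, scatter, randoms = simulate_prompts(activity, mu_map, sys, seed=1)

b = bootstrap_listmode(lm, 0.30, seed=7)  # typical clinical count level
prompts = bin_events(b, sys)
randoms_est = Sinogram(randoms.values * 0.30, "randoms")
scatter_est = estimate_scatter(prompts, af, randoms_est=randoms_est)

gm = labels.values == regions.id_of("CTX")
wm = labels.values == regions.id_of("WM")
print(f"{'mode':4s} {'iters':5s} {'GM/WM ratio':12s} (true ratio "
      f"{activity.values[gm].mean() / activity.values[wm].mean():.2f})")
for mode in ("NAC", "AC", "QNT"):
    for iters in (1, 2, 3):
        img = osem(
            prompts,
            sys,
            ReconConfig(mode=mode, iterations=iters),
            af=af if mode != "NAC" else None,
            scatter_est=scatter_est if mode == "QNT" else None,
            randoms_est=randoms_est,
        )
        ratio = img.values[gm].mean() / img.values[wm].mean()
        print(f"{mode:4s} {iters:5d} {ratio:12.3f}")
print("\nMore iterations sharpen contrast (and raise noise); NAC distorts "
      "the spatial distribution, which is why it registers differently.")
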