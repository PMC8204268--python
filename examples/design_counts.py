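"""Enumerate the experiment-design bookkeeping.

The full design yields 600 bootstrap datasets / 1800 uncertainty images /
1200 mu-map-alignment reconstructions (3000 images total) for the
reconstruction-parameter analysis, and 800 datasets / 2400 images for the
count-level analysis — counted by explicit enumeration, not multiplication.
"""

from petregu import (
    enumerate_count_level_design,
    enumerate_recon_param_design,
    paper_design,
)

d = paper_design()
n_ds, n_img, n_mu, n_tot = enumerate_recon_param_design(d)
print("reconstruction-parameter analysis")
print(f"  bootstrap datasets      : {n_ds}")
print(f"  uncertainty images      : {n_img}")
print(f"  mu-map-alignment recons : {n_mu}")
print(f"  total images            : {n_tot}")

cl_ds, cl_tot = enumerate_count_level_design(d)
print("count-level analysis")
print(f"  bootstrap datasets      : {cl_ds}")
print(f"  total images            : {cl_tot}")
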