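"""Measure ONH depression between a baseline and a high-IOP acquisition.

Segments the ILM in both volumes, corrects per-B-scan axial motion, registers
the follow-up to the baseline using the periphery, and averages the posterior
displacement in the 300/700 um annulus.
"""

import psoct_iop as P

cfg = P.PhantomConfig()
vol_base, _ = P.generate_volume(cfg, iop=14, seed=0)
vol_high, truth_high = P.generate_volume(cfg, iop=105, seed=1)

res_base = P.process_volume(vol_base, None, None)
res_high = P.process_volume(
    vol_high,
    res_base["depression_annulus"],
    res_base["metric_annulus"],
    baseline_ilm=res_base["ilm_aligned"],
)

dep = res_high["depression"]
print(f"ONH depression (14 -> 105 mmHg): {dep.mean:5.1f} +- {dep.sd:4.1f} um "
      f"over {dep.n_valid} annulus pixels")
print(f"ground-truth displacement      : {truth_high.depression_um:5.1f} um")

# The annulus mean should recover the phantom's posterior displacement to
# within the segmentation noise (well under the +-11 um spread the depression
# shows across animals in vivo).
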