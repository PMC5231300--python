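"""Quantify scleral birefringence on a single volume at elevated IOP.

Runs the full per-volume chain (reconstruction, segmentation, corneal
compensation, depth-resolved linear fit in the scleral slab) and averages the
en face birefringence map over the 550/870 um peripapillary annulus.
"""

import numpy as np

import psoct_iop as P
from psoct_iop.stats import birefringence_to_dimensionless

vol, truth = P.generate_volume(P.PhantomConfig(), iop=95, seed=0)
res = P.process_volume(vol, None, None)

bir = res["scleral_birefringence"]
print(f"scleral birefringence  : {bir.mean:.3f} +- {bir.sd:.3f} deg/um "
      f"over {bir.n_valid} annulus A-scans")
print(f"ground truth           : {truth.scleral_birefringence:.3f} deg/um")
print(f"dimensionless dn       : {birefringence_to_dimensionless(bir.mean):.3e}")

sup, inf = res["hemifield_means"]
print(f"superior / inferior    : {sup:.3f} / {inf:.3f} deg/um")

emap = res["scleral_birefringence_map"]
print(f"en face map valid      : {np.mean(emap.valid_mask):.1%} of A-scans")

# At 95 mmHg the phantom sits on the birefringence plateau (1.16 deg/um);
# the pipeline estimate should land within a few percent of it, and the two
# hemifields should agree since the phantom has no superior/inferior asymmetry.
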