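"""Recover injected gait asymmetry through the full pipeline.

Sweeps the injected stride-frequency asymmetry amplitude and compares the
recovered mean per-stride Maxdiff with the dense-grid oracle evaluated on
the closed-form trunk trajectory.
"""

import numpy as np

import hoofline as hl
from hoofline.session import AnalysisOptions, analyze_recording

opts = AnalysisOptions()
cam = hl.default_cameras()[2]

print("asym_amp  recovered Maxdiff  oracle Maxdiff  strides")
for asym in (0.0, 1.0, 2.5, 5.0):
    params = hl.GaitParams(duration=42.0, asym_amp=asym, asym_phase=0.0,
                           noise_sigma=1.0)
    world = hl.simulate_gait(params)
    traj = hl.corrupt(hl.project(world, cam), 1.0, 0.0, seed=0)
    res = analyze_recording(traj, params.withers_height, opts)
    recs = res.valid_strides("dynamic", "withers")
    recovered = np.mean([r.maxdiff for r in recs])
    _, oracle, _ = hl.symmetry_oracle(params, "withers")
    print(f"{asym:7.1f}  {recovered:16.2f}  {oracle.mean():14.2f}  {len(recs):7d}")

print("\n(Maxdiff ~ twice the injected amplitude: the 1f component raises "
      "one diagonal's peak and lowers the other's; recovery should match "
      "the oracle within a few tenths of a millimetre)")
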