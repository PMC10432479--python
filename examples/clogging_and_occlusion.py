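"""Robustness to clogging: array-scale occlusion and single-pore clogs.

Two failure modes of a parallel-pore membrane:

* array scale — fully blocked pores force their flux onto the open ones;
  with the pores acting as parallel resistors at fixed total flow, the
  per-open-pore flux (and hence the maximal drag on an entering EV)
  rises by n/(n−k);
* single pore — a spherical debris particle lodged on a pore's rim
  constricts the lumen and perturbs trajectories near the trap.
"""

import warnings

from tenposim import ClogSpec, DeviceGeometry, ExperimentEngine, FlowCondition

ML_PER_H = 1e-6 / 3600.0

engine = ExperimentEngine()

print("array occlusion (9-pore periodic cell, fixed total flow):")
for k in range(5):
    pct = engine.occlusion_array_experiment(k)
    print(f"  {k}/9 pores blocked -> max drag at open pores +{pct:.1f}%")

geometry = DeviceGeometry(pore_diameter=3e-6)
flow = FlowCondition(2.5 * ML_PER_H)
print("\nsingle-pore clogs on a d = 3 um pore (takes ~1 min):")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for radius in (400e-9, 800e-9):
        out = engine.clog_impact_experiment(ClogSpec(radius), geometry, flow)
        print(f"  {radius*1e9:.0f} nm clog: "
              f"Rs {100*out['Rs_clean']:.0f}% -> {100*out['Rs_clogged']:.0f}%, "
              f"Rw {100*out['Rw_clean']:.0f}% -> {100*out['Rw_clogged']:.0f}%")
print("-> modest occlusion barely perturbs the array; a 400 nm clog leaves")
print("   capture unchanged, an 800 nm clog adds background capture (higher")
print("   Rw) while the strong-tag yield is unaffected.")
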