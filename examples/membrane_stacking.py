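"""Membrane stacking: recovering yield with membranes in series.

A d = 3 µm device discards all weakly-tagged background (Rw = 0) but
captures only part of the strongly-tagged target population.  Stacking n
membranes gives each EV repeated capture chances: uncaptured particles
re-enter the next membrane at a random lateral position (pore positions
of separate membranes are independent).  Prints the cumulative capture
R(n) for n = 1..5.
"""

import warnings

from tenposim import DeviceGeometry, ExperimentEngine, FlowCondition

ML_PER_H = 1e-6 / 3600.0

engine = ExperimentEngine()
geometry = DeviceGeometry(pore_diameter=3e-6)
flow = FlowCondition(2.5 * ML_PER_H)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    strong = engine.multi_membrane_capture(geometry, flow, "strong", 5, seed=0)
    weak = engine.multi_membrane_capture(geometry, flow, "weak", 5, seed=0)

print("n membranes :  1    2    3    4    5")
print("Rs cumulative: " + "  ".join(f"{100*v:3.0f}" for v in strong.cumulative))
print("Rw cumulative: " + "  ".join(f"{100*v:3.0f}" for v in weak.cumulative))
print("-> target yield climbs steeply up to n ≈ 3 and then plateaus, while")
print("   the weak-tag background stays rejected; 2-3 membranes buy most of")
print("   the recoverable yield at no purity cost.")
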