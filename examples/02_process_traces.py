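"""Process raw 6-DOF sensor traces into head-CoG event metrics.

Builds one synthetic impact (a 30 g half-sine at the head centre of
gravity with a matched angular-velocity ramp), maps it to the sensor
frame, then runs the full processing chain: 8 g per-axis trigger with a
10/40 ms window, four-pole zero-phase 200 Hz Butterworth filter, the
rigid-body CoG transform, and PLA/PAA/RVCI extraction.
"""

import numpy as np

from haekit import KinematicsConfig, SimulationConfig, apply_trigger, process_event
from haekit.synthetic import build_pulse_trace

kin = KinematicsConfig()
sim = SimulationConfig(noise_sd_a=(0.0, 0.0, 0.0), noise_sd_w=(0.0, 0.0, 0.0))
rng = np.random.default_rng(7)

pla, paa, rvci = 30.0, 2400.0, 16.5  # drawn ground truth at the head CoG
raw = build_pulse_trace(pla, paa, rvci, noise_class=0, sim=sim, kin=kin, rng=rng,
                        trace_id="demo")

windows = apply_trigger(raw, kin)
print(f"trigger windows: {len(windows)} "
      f"(160 samples each, trigger at sample {kin.trigger_index})")

record = process_event(windows[0], kin)
print(f"PLA  = {record.pla:7.2f} g        (ground truth {pla:.1f}; "
      f"error {abs(record.pla - pla) / pla:.2%})")
print(f"PAA  = {record.paa:7.1f} rad/s^2  (ground truth {paa:.0f})")
print(f"RVCI = {record.rvci:7.2f} rad/s    (ground truth {rvci:.1f})")
print(f"applied cutoff: {record.applied_cutoff:.0f} Hz (noise class "
      f"{record.noise_class})")
print()
print("The sensor-frame trace is the exact inversion of the CoG transform,")
print("so the recovered PLA matches the drawn peak to within the filter's")
print("passband attenuation (<2% for minimal-noise events).")
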