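"""Per-attempt patch-clamp stage rules on synthetic measurements.

Runs the neuron-hunting detector over a synthetic resistance-vs-depth
trace, then walks a seal through gigaseal, break-in, and recording QC.
"""

from patchwalk import (
    RecordingQC,
    SealState,
    break_in_success,
    detect_neuron,
    generate_hunt_trace,
    gigaseal_reached,
    qc_evaluate,
)

trace = generate_hunt_trace(has_cell=True, contact_depth_um=50.0, noise_sd_mohm=0.02, seed=3)
idx = detect_neuron(trace)
print(
    f"hunt: cell contact at {50.0} um depth detected at step {idx} "
    f"(position {trace.positions[idx]:.1f} um, R = {trace.resistances[idx]:.2f} MOhm)"
)

seal = SealState(resistance=1150.0, holding_current=-60.0)
print(f"seal 1150 MOhm: gigaseal reached = {gigaseal_reached(seal)} (wait 5 s, then suction)")

after = SealState(resistance=320.0, holding_current=-95.0)
print(f"after suction 320 MOhm, -95 pA: break-in success = {break_in_success(after)}")

for series in ([14.0, 16.0, 21.0], [25.0, 44.0], [30.0, 52.0]):
    print(f"access resistance {series} MOhm -> {qc_evaluate(RecordingQC(series))}")
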