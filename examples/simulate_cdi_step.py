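"""Simulate fast Ca2+-dependent inactivation during hyperpolarizing steps.

Runs the three-state CDI scheme coupled to the single-channel microdomain
for the wild-type-like and sensitized variants, and quantifies each trace
the way a patch-clamp analysis would: extent of inactivation and
bi-exponential decay constants.
"""

from cracdi import (
    BufferSpec,
    MicrodomainModel,
    VoltageProtocol,
    VoltageSegment,
    fit_double_exponential,
    sensitized,
    simulate_whole_cell,
    wt_like,
)

step = VoltageProtocol.single_sweep(
    [VoltageSegment.step(0.300, -0.100)], sweep_interval=0.35
)

for model in (wt_like(), sensitized()):
    print(f"{model.variant_label} (K_d = {model.kd * 1e6:.3g} uM)")
    for buffer in (BufferSpec.egta(10), BufferSpec.bapta(8)):
        micro = MicrodomainModel(buffer=buffer)
        trace = simulate_whole_cell(model, step, micro)
        fit = fit_double_exponential(trace, (0.0, 0.300))
        print(
            f"  {buffer.label:<12} peak {fit.i_peak * 1e12:7.1f} pA, "
            f"extent {fit.extent:5.2f}, "
            f"tau {fit.tau_fast * 1e3:5.1f} / {fit.tau_slow * 1e3:6.1f} ms"
        )

print()
print("Wild-type-like CDI is stronger in EGTA than BAPTA (the nanodomain "
      "drives it); the sensitized variant inverts the ordering because in "
      "EGTA it is already inactivated at the +30 mV holding potential.")
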