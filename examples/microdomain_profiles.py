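"""Local Ca2+ around an open CRAC channel under different chelators.

Evaluates the buffered point-source model at the inactivation-sensor
distance (3 nm) and prints the concentration profiles that explain why
BAPTA, but not EGTA, suppresses the nanodomain.
"""

from cracdi import BufferSpec, MicrodomainModel, ca_profile, local_ca, space_constant
from cracdi.units import fA, nm, uM

for buffer in (BufferSpec.egta(10), BufferSpec.bapta(8)):
    model = MicrodomainModel(buffer=buffer)
    lam = space_constant(model)
    print(f"{buffer.label}: space constant = {lam / nm:.1f} nm")
    for d_nm in (1, 3, 10, 30):
        ca = local_ca(model, 5 * fA, d_nm * nm)
        print(f"  [Ca2+] at {d_nm:>2d} nm (5 fA source): {ca / uM:6.2f} uM")

print()
print("At the 3 nm sensor with the measured voltage-scaled unitary currents:")
bapta8 = MicrodomainModel(buffer=BufferSpec.bapta(8))
egta10 = MicrodomainModel(buffer=BufferSpec.egta(10))
print(f"  -60 mV (2.2 fA), 8 mM BAPTA : "
      f"{local_ca(bapta8, 2.2 * fA, 3 * nm) / uM:.2f} uM")
print(f"  -120 mV (6.2 fA), 10 mM EGTA: "
      f"{local_ca(egta10, 6.2 * fA, 3 * nm) / uM:.2f} uM")
print("Similar inactivation at these two points implies the sensitized "
      "mutant responds to ~4x less Ca2+ than wild type.")
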