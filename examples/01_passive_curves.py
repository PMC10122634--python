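"""Build the default passive fibre and tendon force-length curves.

Prints the curve anchor points and the dependent stiffnesses that follow
from the strain parameters.
"""

from mtufit import FibreCurveParams, TendonCurveParams, derived_stiffnesses
from mtufit.curves import make_fibre_curve, make_tendon_curve

fibre = FibreCurveParams()  # engages at optimal length, F_max at 70% strain
tendon = TendonCurveParams()  # F_max at 4.9% strain, toe ends at 0.67 F_max

fc, tc = make_fibre_curve(fibre), make_tendon_curve(tendon)
k_low_f, k_one_f, k_one_t = derived_stiffnesses(fibre, tendon)

print("fibre curve (normalised length -> force/F_max)")
print(f"  engagement:      f({1 + fibre.eps_zero_f:.3f}) = {fc.value(1 + fibre.eps_zero_f):.3f}")
print(f"  mid-range:       f(1.350) = {fc.value(1.35):.3f}")
print(f"  one norm force:  f({1 + fibre.eps_one_f:.3f}) = {fc.value(1 + fibre.eps_one_f):.3f}")
print(f"  stiffness at one norm force K_one_f = {k_one_f:.3f} (= 2/(eps_one - eps_zero))")
print(f"  stiffness factor at low force = {fibre.k_low_scale}; K_low_f = {k_low_f:.3f}")
print()
print("tendon curve (normalised length -> force/F_max)")
print(f"  slack:           f(1.000) = {tc.value(1.0):.3f}")
print(f"  toe end:         f({1 + tendon.eps_toe_t:.4f}) = {tc.value(1 + tendon.eps_toe_t):.3f}")
print(f"  one norm force:  f({1 + tendon.eps_one_t:.3f}) = {tc.value(1 + tendon.eps_one_t):.3f}")
print(f"  stiffness at one norm force K_one_t = {k_one_t:.2f} (= 1.375/eps_one_t)")
print()
print("A fibre stretched 35% beyond optimal length transmits "
      f"{100 * fc.value(1.35):.1f}% of F_max passively; the tendon reaches "
      "F_max at 4.9% strain, so it is far stiffer than the fibre.")
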