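"""Infer the cell-autonomous stress ratio from circular-ablation recoils.

Each circular laser cut recoils into an ellipse; the normal recoil
velocities over the half-axes define a velocity-gradient tensor whose
traceless part is proportional to the anisotropic tissue stress.
Regressing its PD projection against cell elongation Q_xx tests the
constitutive law sigma = 2 K Q + zeta: the ratio 2*intercept/slope
estimates zeta_xx / K.
"""

import numpy as np

from epishear import fit_zeta_over_K, recoil_tensor

# nine wing regions with increasing cell elongation, recoil rates on the
# wild-type regression line (slope 0.018/h, intercept 0.003/h)
q_xx = np.linspace(-0.05, 0.35, 9)
shear_rates = 0.018 * q_xx + 0.003

# recoil_tensor turns raw ellipse measurements into those shear rates,
# e.g. an axis-aligned ellipse with the wanted anisotropy:
demo = recoil_tensor(v_par=0.10, v_perp=0.02, r_par=1.0, r_perp=1.0, theta=0.0)
print(f"example ellipse: isotropic rate C = {demo.c:0.3f}/h, "
      f"shear rate s_xx = {demo.s_xx:0.3f}/h")

fit = fit_zeta_over_K(q_xx, shear_rates)
print(f"slope     = {fit.slope:0.4f}/h  (> 0: positive shear modulus K)")
print(f"intercept = {fit.intercept:0.4f}/h")
print(f"zeta_xx/K = {fit.zeta_xx_over_K:0.3f}")
print("A positive ratio means blade cells would spontaneously elongate "
      "along the AP axis if all external stress were removed.")
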