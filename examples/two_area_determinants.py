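"""Two-area linear stability blocks and the shared-coupling implication.

Builds the 8x8 two-area coefficient matrix for a feedforward engram pair
and verifies the determinant factorization det(M) = det(A) det(E - L J^-1 G)
det(J): if the coupled system supports modes (det M != 0) and ephaptic
coupling holds in area 2 (det J != 0), it must hold in area 1 (det A != 0).
"""

import numpy as np

from engramfield.field_model import FarFieldParams, multipole_coefficient
from engramfield.mode_dynamics import build_two_area_blocks, engram_condition

Z = multipole_coefficient(FarFieldParams(gamma=1.0, r_mm=2.0, L_mm=0.5))
K1 = np.array([[0.3, 0.05], [0.05, 0.2]])
K2 = np.array([[0.25, 0.05], [0.05, 0.15]])
sys = build_two_area_blocks(
    K_hat_1=K1, K_hat_2=K2, tau_EP=50.0, tau_NA=1.0, gain=0.5,
    Z1=Z, Z2=Z, W_ff=0.2, beta=0.0,
)
rep = engram_condition(sys)
print(f"det(M) = {rep['det_M']:.6g}   det(A) = {rep['det_A']:.6g}   "
      f"det(J) = {rep['det_J']:.6g}")
print(f"factorization residual: {rep['factorization_residual']:.2e}")
print(f"premise (det M != 0 and det J != 0): {rep['premise_holds']}")
print(f"implication det(A) != 0 holds: {rep['implication_holds']}")
# The residual is at numerical precision: the three-factor identity is
# exact for one-directional inter-area coupling.
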