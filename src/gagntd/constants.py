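"""Physical constants (CGS) and unit conversions.

All internal computation uses CGS units (cm, g, s, erg); the Svedberg
(1 S = 1e-13 s) appears only at input/output boundaries.
"""

# CODATA values, in CGS.  Boltzmann's constant is derived as R / N_A rather
# than quoted independently so that the Svedberg relation closes exactly
# (the separately rounded printed values differ at the 1e-6 level, which
# would leak into M -> (s, D) -> M round trips).
GAS_CONSTANT = 8.31446e7  # erg / (mol K)
AVOGADRO = 6.02214e23  # 1 / mol
BOLTZMANN = GAS_CONSTANT / AVOGADRO  # erg / K (= 1.380649e-16 to 7 digits)

SVEDBERG = 1e-13  # s

CAL_TO_ERG = 4.184e7  # erg / cal


def rpm_to_rad_s(rpm: float) -> float:
    """Rotor speed in revolutions per minute to angular velocity in rad/s."""
    import math

    return rpm * 2.0 * math.pi / 60.0
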