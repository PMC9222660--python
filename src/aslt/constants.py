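"""Physical constants, fixed to the precision used throughout the analysis.

R is deliberately the four-decimal value 8.3144 J/(mol·K) rather than the CODATA
figure: every activation parameter downstream is reported against this value, and
mixing precisions would shift fitted Ea/ΔH* in the fourth digit.
"""

#: Gas constant, J/(mol·K)
R_GAS: float = 8.3144

#: Boltzmann constant, J/K
K_BOLTZMANN: float = 1.381e-23

#: Planck constant, J·s
H_PLANCK: float = 6.626e-34

#: Offset between °C and K
CELSIUS_OFFSET: float = 273.15

#: Seconds per day — converts between d⁻¹ and s⁻¹ rate conventions
SECONDS_PER_DAY: float = 86400.0


def celsius_to_kelvin(temp_c: float) -> float:
    return temp_c + CELSIUS_OFFSET


def kelvin_to_celsius(temp_k: float) -> float:
    return temp_k - CELSIUS_OFFSET
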