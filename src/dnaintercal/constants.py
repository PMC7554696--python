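"""Physical constants and unit conversion factors.

The gas constant / temperature pairing (R = 1.986e-3 kcal/(mol*K),
T = 298 K) is the conventional one for solution-thermodynamics work at
25 degC; both are overridable in every function that uses them.
"""

#: Gas constant in kcal/(mol*K).
R_KCAL_PER_MOL_K: float = 1.986e-3

#: Default absolute temperature (K) for binding free energies.
T_STANDARD: float = 298.0

#: Thermal energy kT in kcal/mol at 298.15 K, the default for PMF work.
KT_KCAL_PER_MOL: float = 0.5925

#: Nanoseconds to seconds.
NS_TO_S: float = 1e-9

#: kcal to microcalories.
KCAL_TO_UCAL: float = 1e9
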