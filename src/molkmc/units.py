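"""Project-wide unit conventions and physical constants.

Units are fixed throughout the package: length in Å, energy in kcal/mol,
temperature in K, force in pN, reaction rates in s⁻¹, sampler time in ps.
"""

#: Boltzmann constant, kcal mol⁻¹ K⁻¹.
KB = 0.0019872

#: Planck constant in kcal mol⁻¹ s, consistent with :data:`KB` for Eyring rates.
PLANCK = 9.5306e-14

#: Default thermodynamic temperature, K.
DEFAULT_TEMPERATURE = 300.0

#: Conversion factor: 1 kcal/mol expressed in pN·Å.
KCALMOL_TO_PN_ANGSTROM = 69.48
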