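"""Physical constants and label/adduct masses.

Energies are kcal/mol, lengths Å, temperatures K, masses Da throughout the
package unless a function says otherwise.
"""

#: Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL_MOL_K = 0.0019872041

#: 1 kcal mol^-1 Å^-1 expressed in pN (force-unit conversion for SMD springs)
KCAL_PER_MOL_ANGSTROM_IN_PN = 69.4786

#: monoisotopic masses, Da
MASS_H_MONO = 1.00782503
MASS_ZN_MONO = 63.9291422
#: carbamidomethylation (iodoacetamide adduct, +C2H3NO)
MASS_IAM_MONO = 57.02146
#: N-ethylmaleimide adduct (+C6H7NO2)
MASS_NEM_MONO = 125.04767

#: average masses, Da (MALDI linear-mode comparisons)
MASS_H_AVG = 1.00794
MASS_ZN_AVG = 65.38
MASS_IAM_AVG = 57.0513
MASS_NEM_AVG = 125.1253

#: Zn(II) bound to two thiolates displaces two protons: net mass change of the
#: neutral species when one Zn(II) is taken up.
DELTA_ZN_MONO = MASS_ZN_MONO - 2.0 * MASS_H_MONO
DELTA_ZN_AVG = MASS_ZN_AVG - 2.0 * MASS_H_AVG
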