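"""Physical constants (CODATA 2022, via the same values scipy.constants ships).

Internal unit conventions:

* electronic-structure modules: hartree / bohr
* potential-energy-surface, ML and free-energy modules: kJ/mol, angstrom, elementary charge
"""

#: Coulomb constant e^2/(4 pi eps0) * N_A, in kJ mol^-1 angstrom e^-2.
COULOMB_KJ_MOL_ANGSTROM = 1389.3545755023301

#: Molar gas constant, kJ mol^-1 K^-1 (k_B expressed per mole).
KB_KJ_MOL_K = 0.00831446261815324

#: 1 hartree in kJ mol^-1.
HARTREE_KJ_MOL = 2625.499639479163

#: 1 bohr in angstrom.
BOHR_ANGSTROM = 0.529177210544
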