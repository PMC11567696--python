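"""Physical constants (CODATA 2018, SI units).

All internal computation in :mod:`diffrate` is done in SI base units
(m, s, kg, K, mol, number density in 1/m^3); bench units such as nM and
nm appear only at I/O boundaries.
"""

#: Avogadro constant, 1/mol (exact).
AVOGADRO = 6.02214076e23

#: Boltzmann constant, J/K (exact).
BOLTZMANN = 1.380649e-23

#: Molar gas constant, J/(mol K) (exact, = AVOGADRO * BOLTZMANN).
GAS_CONSTANT = 8.31446261815324

#: Standard/reference concentration, mol/m^3 (1 mol/L).
STANDARD_CONCENTRATION = 1000.0
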