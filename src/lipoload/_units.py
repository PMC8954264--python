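"""Exact unit-conversion constants used throughout the package.

All geometric quantities are carried in nanometres, concentrations in
millimolar (mmol per litre of suspension), and volumes of bulk liquid in
microlitres.  Every conversion between those scales funnels through the
constants below so that no module carries its own powers of ten.
"""

#: Avogadro constant, CODATA 2018 exact value (molecules per mole).
AVOGADRO = 6.02214076e23

#: Litres per cubic nanometre: 1 nm^3 = 1e-27 m^3 = 1e-24 L.
LITRES_PER_NM3 = 1e-24

#: Moles per litre represented by 1 mM.
MOLAR_PER_MM = 1e-3
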