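"""Physical constants and unit conventions.

All quantities in the package are expressed in pN, nm, s and K unless a
function explicitly documents otherwise (flexural rigidity enters in SI
N·m² and is converted at the boundary).
"""

#: Boltzmann constant in pN·nm per kelvin.
KB = 0.0138065

#: Default assay temperature (K). Room temperature; the tweezers stage is
#: typically not actively temperature controlled, so reports must state T.
DEFAULT_TEMPERATURE = 298.0
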