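"""Element property tables used by the Modified Distance descriptors.

Van der Waals radii follow Bondi's compilation (Å); Sanderson
electronegativities are the published scale values. Both tables cover the
organic-subset elements admitted by the curation rules; the version string is
recorded in descriptor provenance sidecars so matrices remain comparable.
"""

ELEMENT_TABLE_VERSION = "bondi1964-sanderson1983/1"

#: Bondi van der Waals radii, Å (B and Se from later extensions of the set).
VDW_RADIUS = {
    "H": 1.20,
    "B": 1.92,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Se": 1.90,
    "Br": 1.85,
    "I": 1.98,
}

#: Sanderson electronegativities (dimensionless).
SANDERSON_EN = {
    "H": 2.592,
    "B": 2.275,
    "C": 2.746,
    "N": 3.194,
    "O": 3.654,
    "F": 4.000,
    "Si": 2.138,
    "P": 2.515,
    "S": 2.957,
    "Cl": 3.475,
    "Se": 3.014,
    "Br": 3.219,
    "I": 2.778,
}
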