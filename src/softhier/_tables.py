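"""Bundled reference tables for solvent accessibility.

Van der Waals radii are per element; the theoretical maximum accessible
surface areas per amino-acid type follow the Tien et al. (2013)
Gly-X-Gly convention and convert absolute areas (Å²) into relative
accessibility (RASA, percent).  Residue types without a tabulated maximum
(nucleotides, synthetic traces) fall back to the area of their own atoms
computed in isolation, which upper-bounds the context area so RASA stays
in [0, 100].
"""

VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
DEFAULT_RADIUS = 1.70

# Theoretical maximum ASA per residue (Tien et al. 2013), Å².
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
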