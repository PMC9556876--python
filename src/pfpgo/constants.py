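"""Pinned physico-chemical constant tables.

Every numeric table the sequence-property calculations depend on lives here,
so that the provenance of each value is auditable in one place:

* average (isotopic-mixture) residue masses — Expasy convention, Da;
* Kyte-Doolittle hydropathy values;
* Gill-von Hippel molar extinction coefficients at 280 nm (oxidized-cystine
  convention: only paired cysteines absorb);
* Ikai aliphatic-index coefficients;
* a standard biochemistry pKa set (Lehninger free-amino-acid terminal pKas,
  2.34 / 9.60, with the usual seven ionizable side chains) used by the
  isoelectric-point bisection.
"""

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Average residue masses in daltons (monomer minus water).
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524  # one water added per chain

# Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Gill-von Hippel molar extinction coefficients at 280 nm (M^-1 cm^-1).
# Cysteines contribute only as cystine bridges (oxidized convention).
EXTINCTION_TRP = 5500
EXTINCTION_TYR = 1490
EXTINCTION_CYSTINE = 125

# Ikai aliphatic-index coefficients (relative side-chain volumes).
ALIPHATIC_VAL_COEF = 2.9
ALIPHATIC_ILE_LEU_COEF = 3.9

# Charged-residue sets, ProtParam convention (histidine excluded from positives).
NEGATIVE_RESIDUES = frozenset("DE")
POSITIVE_RESIDUES = frozenset("RK")

# pKa set for net-charge / isoelectric-point computation.
PKA_NTERM = 9.60
PKA_CTERM = 2.34
PKA_SIDECHAIN_ACIDIC = {"D": 3.65, "E": 4.25, "C": 8.18, "Y": 10.07}
PKA_SIDECHAIN_BASIC = {"H": 6.00, "K": 10.53, "R": 12.48}
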