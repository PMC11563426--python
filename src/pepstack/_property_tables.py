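"""Physicochemical property tables bundled for the sequence-order encoders.

Values are the widely used descriptor-toolkit constants:

* ``HYDROPHOBICITY`` — normalized hydrophobicity values per residue.
* ``HYDROPHILICITY`` — Hopp–Woods hydrophilicity values.
* ``SIDE_CHAIN_MASS`` — side-chain mass in Daltons.

These three drive the pseudo-amino-acid composition (PAAC) and its
amphiphilic variant (APAAC); the hydrophobicity table also serves as the
default property for the Moran autocorrelation descriptor. Keeping the tables
in-package (rather than fetching AAindex) makes golden-value tests stable.
"""

from __future__ import annotations

import numpy as np

from pepstack.peptide_io import ALPHABET

HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}

HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}

SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}


def standardized(table: dict[str, float]) -> dict[str, float]:
    """Zero-mean, unit-variance rescaling over the 20 residues.

    The divisor is the population standard deviation (n = 20), the convention
    used by the classical pseudo-amino-acid composition formulation.
    """
    vals = np.array([table[a] for a in ALPHABET])
    mu = vals.mean()
    sd = np.sqrt(((vals - mu) ** 2).mean())
    return {a: (table[a] - mu) / sd for a in ALPHABET}


# --- CTD composition: 13 properties, each a 3-group partition of the alphabet.
# Group order within each property is fixed (group1, group2, group3); the
# feature for (property, group) is the fraction of residues falling in that
# group. Groupings follow the standard composition/transition/distribution
# descriptor definitions.
CTD_PROPERTIES: dict[str, tuple[str, str, str]] = {
    "hydrophobicity_PRAM900101": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "hydrophobicity_ARGP820101": ("QSTNGDE", "RAHCKMV", "LYPFIW"),
    "hydrophobicity_ZIMJ680101": ("QNGSWTDERA", "HMCKV", "LPFYI"),
    "hydrophobicity_PONP930101": ("KPDESNQT", "GRHA", "YMFWLCVI"),
    "hydrophobicity_CASG920101": ("KDEQPSRNTG", "AHYMLV", "FIWC"),
    "hydrophobicity_ENGD860101": ("RDKENQHYP", "SGTAW", "CVLIMF"),
    "hydrophobicity_FASG890101": ("KERSQD", "NTPG", "AYHWVMFLIC"),
    "normwaalsvolume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondarystruct": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solventaccess": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

# --- Conjoint-triad classes: 7 residue clusters by dipole and side-chain
# volume. Class index order is fixed 1..7.
CONJOINT_TRIAD_CLASSES: tuple[str, ...] = (
    "AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C",
)

# --- Reduced amino-acid clusters: a fixed 4-cluster reduction used by the
# reduced-alphabet composition encoder. Chosen partition: charged / polar /
# aromatic & large hydrophobic / small hydrophobic.
RAAC_SCHEMES: dict[str, tuple[str, ...]] = {
    "standard4": ("DEHKR", "CNQST", "FILMWY", "AGPV"),
}
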