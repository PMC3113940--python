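"""Reference data and fixed conventions shared by all modules.

Units: solvent-accessible surface areas in Å², residue volumes in Å³,
energies in kcal/mol, angles in degrees, distances in Å.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Amino-acid alphabet
# ---------------------------------------------------------------------------

#: One-letter codes in canonical alphabetical order; index into this list is
#: the internal integer state of the sequence descriptor ``s``.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

N_AA = len(AMINO_ACIDS)

# ---------------------------------------------------------------------------
# Reference solvent accessibilities (Gly-X-Gly extended tripeptide)
# ---------------------------------------------------------------------------

#: Maximum accessible surface area of residue X in an extended Gly-X-Gly
#: tripeptide (theoretical values of Tien et al., PLoS ONE 2013).  Relative
#: accessibility is the observed SASA divided by this reference, in percent.
GXG_REFERENCE_SASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Probe radius used for all SASA computations (water, Å).
SASA_PROBE_RADIUS = 1.4
#: Number of sphere sample points per atom (Shrake-Rupley quadrature).
SASA_N_POINTS = 960

# ---------------------------------------------------------------------------
# Mean residue volumes
# ---------------------------------------------------------------------------

#: Mean residue volumes in Å³ (Zamyatnin, Prog. Biophys. Mol. Biol. 1972;
#: Chothia-style crystallographic averages).  Used for the ΔV± cavity /
#: packing terms of the prediction model.
RESIDUE_VOLUME: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# ---------------------------------------------------------------------------
# Backbone torsion domains
# ---------------------------------------------------------------------------

#: The discrete backbone-conformation alphabet: a fixed seven-domain
#: partition of the Ramachandran plane.  Residues whose φ or ψ cannot be
#: computed (chain termini, chain breaks, missing atoms) receive
#: :data:`TORSION_UNDEFINED` instead, which is *not* part of the alphabet
#: used by the statistical potentials.
TORSION_DOMAINS: tuple[str, ...] = (
    "helical", "extended", "polyproline", "left_helical",
    "gamma", "epsilon", "other",
)
TORSION_INDEX: dict[str, int] = {t: i for i, t in enumerate(TORSION_DOMAINS)}
TORSION_UNDEFINED = "undefined"
N_TORSION = len(TORSION_DOMAINS)


def torsion_domain(phi: float | None, psi: float | None) -> str:
    """Map backbone dihedrals (degrees) to a torsion-domain label.

    The partition is total: every (φ, ψ) in [-180, 180)² maps to exactly
    one of the seven domains.  Boundaries (half-open, lower edge included):

    * φ ∈ [-180, -20):
        - ψ ∈ [-120, 45)                → ``helical``  (right-handed α region)
        - otherwise, φ ∈ [-110, -20)    → ``polyproline`` (PPII: φ≈-75, ψ≈145)
        - otherwise                     → ``extended``  (β: φ≈-120, ψ≈130)
    * φ ∈ [-20, 20)                     → ``other``
    * φ ∈ [20, 180):
        - ψ ∈ [-90, 90)                 → ``left_helical`` (αL)
        - ψ ∈ [90, 180)                 → ``epsilon``
        - ψ ∈ [-180, -90)               → ``gamma``

    ``None`` for either angle yields :data:`TORSION_UNDEFINED`.
    """
    if phi is None or psi is None:
        return TORSION_UNDEFINED
    phi = _wrap_angle(phi)
    psi = _wrap_angle(psi)
    if -180.0 <= phi < -20.0:
        if -120.0 <= psi < 45.0:
            return "helical"
        if phi >= -110.0:
            return "polyproline"
        return "extended"
    if -20.0 <= phi < 20.0:
        return "other"
    if -90.0 <= psi < 90.0:
        return "left_helical"
    if 90.0 <= psi < 180.0:
        return "epsilon"
    return "gamma"


def _wrap_angle(x: float) -> float:
    """Wrap an angle in degrees into [-180, 180)."""
    return float((np.asarray(x) + 180.0) % 360.0 - 180.0)


# ---------------------------------------------------------------------------
# Energy scale and geometry conventions
# ---------------------------------------------------------------------------

#: kT at 298 K in kcal/mol; the inverse-Boltzmann energy scale of the
#: statistical potentials.  Any constant here is absorbed linearly by the
#: trained sigmoid weights.
KT_KCAL_MOL = 0.593

#: Residue pairs closer than this many positions along the same chain are
#: excluded from the distance potentials (nearest sequence neighbours carry
#: covalent rather than tertiary information).
MIN_SEQUENCE_SEPARATION = 2

#: Default centroid-centroid distance cutoff for recording residue pairs (Å).
DEFAULT_DISTANCE_CUTOFF = 8.0

#: Relative-accessibility threshold (percent) separating buried (core) from
#: exposed (surface) residues.  Residues with a == threshold are surface.
CORE_SURFACE_THRESHOLD = 10.0
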