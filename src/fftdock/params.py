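"""Bundled parameter tables: interface propensities, residue contact
preferences, Lennard-Jones classes and the PDB fallback radius/charge maps.

The interface-propensity scale spans -0.38 (ASP) to 0.83 (TRP); higher
values mark residue types that occur more often in protein-protein
interfaces.  The residue-residue contact-preference matrix ``e_ij`` is a
symmetric log-preference score: positive entries mark residue pairs that
like to face each other across an interface.  Both tables anchor the public
extreme values exactly and fill the rest with a documented synthetic
interpolation (see ``data/propensity_synthetic.txt``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

AMINO3 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: polar (X) and non-polar (Y) one-letter classes used by the glycine
#: active-site motif rules G-X-Y / Y-X-G.
POLAR_RESIDUES = set("STCNQYHKRDE")
NONPOLAR_RESIDUES = set("AVLIPFMWG")


def _data_text(name: str) -> str:
    return (importlib.resources.files("fftdock") / "data" / name).read_text()


def _parse_kv(name: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for line in _data_text(name).splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, *vals = line.split()
        out[key] = float(vals[0])
    return out


@dataclass
class ParamTable:
    """Knowledge-based parameter bundle used across scoring and filtering.

    Attributes
    ----------
    propensity : dict
        residue 3-letter code -> natural-log interface propensity l_p.
    contact_pref : ndarray, shape (20, 20)
        symmetric log contact-preference matrix e_ij indexed by ``AMINO3``
        order.
    lj : dict
        element -> (well depth epsilon kcal/mol, contact distance r* A).
    vdw_radius, default_charge : dict
        per-element fallback maps for plain PDB input.
    solvation : dict
        per-element sigma_i plus 'pressure' and 'gamma' constants.
    """

    propensity: dict[str, float]
    contact_pref: np.ndarray
    lj: dict[str, tuple[float, float]]
    vdw_radius: dict[str, float]
    default_charge: dict[str, float] = field(default_factory=dict)
    solvation: dict[str, float] = field(default_factory=dict)

    def propensity_of(self, res3: str) -> float:
        return self.propensity.get(res3.upper(), 0.0)

    def contact_pref_of(self, res3_a: str, res3_b: str) -> float:
        try:
            i = AMINO3.index(res3_a.upper())
            j = AMINO3.index(res3_b.upper())
        except ValueError:
            return 0.0
        return float(self.contact_pref[i, j])

    def lj_of(self, element: str) -> tuple[float, float]:
        # unknown classes fall back to carbon-like defaults
        return self.lj.get(element.upper(), self.lj["C"])


def load_params() -> ParamTable:
    """Load the bundled parameter tables."""
    propensity = {k.upper(): v for k, v in _parse_kv("propensity_synthetic.txt").items()}
    lp = np.array([propensity[r] for r in AMINO3])
    # synthetic contact preferences: pairwise mean of the per-residue
    # propensities -- symmetric by construction, positive for pairs of
    # interface-prone residues, negative for charged/charged pairs.
    contact = 0.5 * (lp[:, None] + lp[None, :])
    lj_raw = _parse_kv("lj_params.txt")
    lj: dict[str, tuple[float, float]] = {}
    for line in _data_text("lj_params.txt").splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        el, eps, rstar = line.split()
        lj[el.upper()] = (float(eps), float(rstar))
    del lj_raw
    solv = _parse_kv("solvation.txt")
    return ParamTable(
        propensity=propensity,
        contact_pref=contact,
        lj=lj,
        vdw_radius={k.upper(): v for k, v in _parse_kv("vdw_radii.txt").items()},
        default_charge={},
        solvation=solv,
    )


def element_of(atom_name: str) -> str:
    """Infer the element class from an atom name (PDB convention)."""
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            # names like '1HG1' start with a digit; first letter wins,
            # two-letter heavy elements in proteins are rare enough that
            # the single-letter class is the documented behavior
            return ch.upper()
    return "C"
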