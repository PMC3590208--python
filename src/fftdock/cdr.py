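"""Sequence-based identification of antibody CDR loops and complex typing.

The six complementarity-determining regions (L1-L3 on the light chain,
H1-H3 on the heavy chain) are located from conserved sequence anchors in
the classic numbering style: cysteine anchors before L1/L3/H1/H3, a
tryptophan immediately after L1/H1, ``FGxG`` after L3 and ``WGxG`` after
H3, with the fixed framework offsets between neighboring loops.  A
molecule is typed as an antibody only if one chain yields all three light
loops and another all three heavy loops - heavy-chain-only (camelid)
antibodies are therefore not recognized, mirroring the known failure mode
of this detection scheme.

Complex typing falls back to the enzyme rule: a molecule with at least
200 residues of which at least 8% of the surface residues are glycines
selects the enzyme parameter set; otherwise the general set is used.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .molio import Molecule

LOOPS = ("L1", "L2", "L3", "H1", "H2", "H3")


@dataclass
class CdrRegions:
    """Residue index ranges (0-based, half-open) of the six CDR loops."""

    loops: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    # loop name -> (chain id, start, end)

    def __post_init__(self):
        by_chain: dict[str, list[tuple[int, int]]] = {}
        for chain, s, e in self.loops.values():
            for s2, e2 in by_chain.get(chain, []):
                if s < e2 and s2 < e:
                    raise ValueError("CDR ranges overlap within a chain")
            by_chain.setdefault(chain, []).append((s, e))

    def residues_of(self, *names: str) -> list[tuple[str, int]]:
        out = []
        for name in names:
            if name in self.loops:
                chain, s, e = self.loops[name]
                out.extend((chain, i) for i in range(s, e))
        return out


def _find_light_loops(seq: str) -> dict[str, tuple[int, int]] | None:
    # L1: starts right after a Cys near position ~23, ends before a Trp
    c1 = seq.find("C", 16, 30)
    if c1 < 0:
        return None
    start1 = c1 + 1
    end1 = None
    for ln in range(10, 18):
        if start1 + ln < len(seq) and seq[start1 + ln] == "W":
            end1 = start1 + ln
            break
    if end1 is None:
        return None
    # L2: fixed framework offset of 16 from the end of L1, length 7
    start2 = end1 + 16
    end2 = start2 + 7
    if end2 >= len(seq):
        return None
    # L3: 2 after the next Cys, ends before an FGxG motif
    c3 = seq.find("C", end2 + 20)
    if c3 < 0:
        return None
    start3 = c3 + 2
    end3 = None
    for ln in range(7, 12):
        tail = seq[start3 + ln:start3 + ln + 4]
        if len(tail) == 4 and re.fullmatch(r"FG.G", tail):
            end3 = start3 + ln
            break
    if end3 is None:
        return None
    return {"L1": (start1, end1), "L2": (start2, end2), "L3": (start3, end3)}


def _find_heavy_loops(seq: str) -> dict[str, tuple[int, int]] | None:
    # H1: starts 4 after a Cys near ~22, ends before a Trp
    c1 = seq.find("C", 16, 28)
    if c1 < 0:
        return None
    start1 = c1 + 4
    end1 = None
    for ln in range(10, 13):
        if start1 + ln < len(seq) and seq[start1 + ln] == "W":
            end1 = start1 + ln
            break
    if end1 is None:
        return None
    # H2: 15 after the end of H1, ends before a K/R framework triplet
    start2 = end1 + 15
    end2 = None
    for ln in range(16, 20):
        tail = seq[start2 + ln:start2 + ln + 3]
        if (len(tail) == 3 and tail[0] in "KR" and tail[1] in "LIVFTA"
                and tail[2] in "TSIA"):
            end2 = start2 + ln
            break
    if end2 is None:
        return None
    # H3: 3 after the next Cys (typically C-A-R), ends before WGxG
    c3 = seq.find("C", end2 + 25)
    if c3 < 0:
        return None
    start3 = c3 + 3
    end3 = None
    for ln in range(3, 26):
        tail = seq[start3 + ln:start3 + ln + 4]
        if len(tail) == 4 and re.fullmatch(r"WG.G", tail):
            end3 = start3 + ln
            break
    if end3 is None:
        return None
    return {"H1": (start1, end1), "H2": (start2, end2), "H3": (start3, end3)}


def identify_cdrs(chains: dict[str, str]) -> CdrRegions | None:
    """Locate all six CDR loops in a chain set, or return None.

    Needs one chain matching the light-loop anchors and a *different*
    chain matching the heavy-loop anchors.
    """
    light = heavy = None
    light_chain = heavy_chain = None
    for cid, seq in chains.items():
        if light is None:
            found = _find_light_loops(seq)
            if found:
                light, light_chain = found, cid
                continue
        if heavy is None:
            found = _find_heavy_loops(seq)
            if found:
                heavy, heavy_chain = found, cid
    if light is None or heavy is None or light_chain == heavy_chain:
        return None
    loops = {k: (light_chain, s, e) for k, (s, e) in light.items()}
    loops.update({k: (heavy_chain, s, e) for k, (s, e) in heavy.items()})
    return CdrRegions(loops)


def surface_glycine_fraction(mol: Molecule) -> float:
    """Fraction of surface residues (>= 1 surface atom) that are glycine."""
    surf = mol.surface_mask
    n_surf = n_gly = 0
    for (chain, seq, icode), atom_idx in mol.residues():
        if not any(surf[i] for i in atom_idx):
            continue
        n_surf += 1
        if mol.atoms[atom_idx[0]].residue_name.upper() == "GLY":
            n_gly += 1
    return n_gly / n_surf if n_surf else 0.0


def detect_complex_type(receptor: Molecule, ligand: Molecule,
                        min_residues: int = 200,
                        min_gly_fraction: float = 0.08) -> str:
    """Classify the pair as 'antibody', 'enzyme' or 'other'.

    Antibody detection (CDR loops on either molecule) takes precedence;
    otherwise a molecule with >= ``min_residues`` residues and >=
    ``min_gly_fraction`` surface glycines selects the enzyme set.
    """
    for mol in (receptor, ligand):
        if identify_cdrs(mol.chains) is not None:
            return "antibody"
    for mol in (receptor, ligand):
        if not mol.surface_mask.any():
            from .molio import detect_surface_atoms
            mol = detect_surface_atoms(mol)
        if len(mol.residues()) >= min_residues and \
                surface_glycine_fraction(mol) >= min_gly_fraction:
            return "enzyme"
    return "other"
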