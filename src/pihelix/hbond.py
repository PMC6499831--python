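"""Backbone hydrogen bonds via the Kabsch-Sander electrostatic model.

Amide hydrogens are placed by the DSSP convention (1.0 A from N, along the
preceding carbonyl C->O direction reversed), and donor/acceptor pairs are
scored with the Kabsch-Sander energy

    E = 0.084 * 332 * (1/r(O,N) + 1/r(C,H) - 1/r(O,H) - 1/r(C,N))  kcal/mol.

Bond bookkeeping follows DSSP: a bond is stored when E < -0.5 kcal/mol, at
most the two lowest-energy acceptors are kept per donor, and energies are
clamped at -9.9 kcal/mol.  This lets the annotation layer run without an
external DSSP binary; when a real ``.dssp`` file is available its bond
lists can be consumed instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import BackboneResidue, Chain

__all__ = [
    "HBond",
    "ENERGY_DETECT_CUTOFF",
    "ENERGY_CLAMP",
    "place_amide_hydrogen",
    "place_hydrogens",
    "ks_energy",
    "find_hbonds",
    "resolve_alternative",
]

#: DSSP conventions
ENERGY_DETECT_CUTOFF = -0.5  # kcal/mol; weaker contacts are not bonds
ENERGY_CLAMP = -9.9  # kcal/mol; lower bound on reported energies
CA_PREFILTER = 9.0  # A; CA-CA distance beyond which no bond is evaluated
MIN_SEQ_SEP = 2  # |donor - acceptor| below this is excluded


@dataclass(frozen=True)
class HBond:
    """A backbone N-H(donor) -> O=C(acceptor) hydrogen bond."""

    donor_idx: int
    acceptor_idx: int
    energy: float

    @property
    def offset(self) -> int:
        """Acceptor-to-donor sequence separation (5 for a pi-type bond)."""
        return self.donor_idx - self.acceptor_idx


def place_amide_hydrogen(prev_C: np.ndarray, prev_O: np.ndarray, N: np.ndarray) -> np.ndarray:
    """DSSP amide-H placement: 1.0 A from N along the reversed C=O direction."""
    d = np.asarray(prev_C, float) - np.asarray(prev_O, float)
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise ValueError("degenerate carbonyl: C and O coincide")
    return np.asarray(N, float) + d / norm


def place_hydrogens(chain: Chain) -> None:
    """Place amide hydrogens in place for all eligible residues.

    Chain-start residues (including restarts after a break) and prolines
    carry no amide hydrogen and therefore cannot donate.
    """
    for i, res in enumerate(chain.residues):
        res.H = None
        if res.aa == "P":
            continue
        if i == 0 or not chain.is_bonded(i - 1):
            continue
        prev = chain.residues[i - 1]
        res.H = place_amide_hydrogen(prev.C, prev.O, res.N)


def ks_energy(donor: BackboneResidue, acceptor: BackboneResidue) -> float:
    """Kabsch-Sander energy (kcal/mol) of donor N-H ... acceptor C=O."""
    if donor.H is None:
        raise ValueError("donor has no amide hydrogen placed")
    r_on = np.linalg.norm(acceptor.O - donor.N)
    r_ch = np.linalg.norm(acceptor.C - donor.H)
    r_oh = np.linalg.norm(acceptor.O - donor.H)
    r_cn = np.linalg.norm(acceptor.C - donor.N)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        raise ValueError("atomic clash: interatomic distance < 0.5 A")
    e = 0.084 * 332.0 * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return max(e, ENERGY_CLAMP)


def find_hbonds(chain: Chain, prefilter: bool = True) -> list[HBond]:
    """All stored backbone hydrogen bonds of a chain.

    For every donor, all acceptors with sequence separation >= 2 (within a
    9 A CA-CA prefilter) are evaluated and the two lowest-energy bonds with
    E < -0.5 kcal/mol are kept.  Hydrogens are placed if absent.
    """
    n = len(chain.residues)
    if n < MIN_SEQ_SEP + 1:
        return []
    if all(r.H is None for r in chain.residues):
        place_hydrogens(chain)
    ca = chain.ca_coords()
    bonds: list[HBond] = []
    for i, donor in enumerate(chain.residues):
        if donor.H is None:
            continue
        candidates = []
        for j, acceptor in enumerate(chain.residues):
            if abs(i - j) < MIN_SEQ_SEP:
                continue
            if prefilter and np.linalg.norm(ca[i] - ca[j]) > CA_PREFILTER:
                continue
            e = ks_energy(donor, acceptor)
            if e < ENERGY_DETECT_CUTOFF:
                candidates.append(HBond(donor_idx=i, acceptor_idx=j, energy=e))
        candidates.sort(key=lambda b: (b.energy, b.acceptor_idx))
        bonds.extend(candidates[:2])
    return bonds


def resolve_alternative(donor_bonds: list[HBond]) -> HBond:
    """Pick the preferred bond among a donor's alternatives.

    The lower-energy bond wins; on an exact tie the bond with the larger
    sequence offset (the pi-type bond) is preferred, since the alternative
    resolution exists precisely to recover pi-helices masked by the
    competing i->i+4 bond.
    """
    if not donor_bonds:
        raise ValueError("no bonds to resolve")
    return min(donor_bonds, key=lambda b: (b.energy, -abs(b.offset)))


def bonds_by_donor(bonds: list[HBond]) -> dict[int, list[HBond]]:
    """Group a bond list by donor index."""
    out: dict[int, list[HBond]] = {}
    for b in bonds:
        out.setdefault(b.donor_idx, []).append(b)
    return out
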