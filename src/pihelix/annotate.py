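"""Structure-based re-annotation of pi-helices and alpha/pi-bulges.

DSSP systematically under-reports pi-helices because its assignment grammar
prefers the competing i->i+4 (alpha) hydrogen bond.  This module re-marks
pi-helical residue ranges from the hydrogen-bond lists directly:

1. every DSSP 'I' label is first erased to 'C';
2. a residue range is re-marked 'I' when it carries at least two
   *consecutive* pi-type (i -> i+5) hydrogen bonds (where a donor offers
   both an i->i+4 and an i->i+5 alternative, the lower-energy bond wins),
   at least one of those bonds has energy <= -2.0 kcal/mol, and every
   residue spanned by the bonds has backbone dihedrals in the broad helical
   region (-180 < phi < 0, -120 < psi < 45);
3. the 8-state labels are reduced to 4 states (H: {G,H}; E: {E,B};
   C: {S,T,C}; I kept).

An isolated single qualifying pi-type bond marks a 6-residue
alpha/pi-bulge instead (never part of a canonical pi-helix, which spans
(#bonds + 5) >= 7 residues).

Bond notation: "i -> i+5" means the C=O of residue i accepts from the N-H
of residue i+5; the spanned range is i .. i+5 inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .hbond import HBond, bonds_by_donor, find_hbonds, resolve_alternative
from .structure_io import Chain, DsspRecord, read_dssp, read_structure

__all__ = [
    "AnnotationParams",
    "SSAnnotation",
    "pi_bond_runs",
    "assign_pi_helices",
    "assign_bulges",
    "reduce_8_to_4",
    "segments_from_labels",
    "annotate_structure",
    "annotate_chain",
]

PI_OFFSET = 5  # donor - acceptor separation of a pi-type bond

_REDUCE = {"G": "H", "H": "H", "E": "E", "B": "E", "S": "C", "T": "C", "C": "C", "I": "I"}


@dataclass(frozen=True)
class AnnotationParams:
    """Thresholds of the pi-helix criteria.

    ``energy_gate`` is the Kabsch-Sander energy (kcal/mol) at least one
    pi-type bond in a run must reach; the dihedral windows are open
    intervals in degrees; ``min_pi_bonds`` is the minimal number of
    consecutive pi-type bonds for a canonical pi-helix.
    """

    energy_gate: float = -2.0
    phi_window: tuple[float, float] = (-180.0, 0.0)
    psi_window: tuple[float, float] = (-120.0, 45.0)
    min_pi_bonds: int = 2

    def __post_init__(self):
        if self.energy_gate >= 0:
            raise ValueError("energy_gate must be negative")
        if self.phi_window[0] >= self.phi_window[1] or self.psi_window[0] >= self.psi_window[1]:
            raise ValueError("empty dihedral window")
        if self.min_pi_bonds < 1:
            raise ValueError("min_pi_bonds must be >= 1")


@dataclass
class SSAnnotation:
    """Per-residue labels plus typed segments for one chain."""

    labels8: str
    labels4: str
    segments: list[tuple[str, int, int]] = field(default_factory=list)
    bulges: list[tuple[int, int]] = field(default_factory=list)


def pi_bond_runs(bonds: Sequence[HBond], chain: Optional[Chain] = None) -> list[list[HBond]]:
    """Maximal runs of pi-type bonds at consecutive acceptor positions.

    A pi-type bond at acceptor ``i`` is the bond (acceptor i, donor i+5)
    that survives the alternative-bond resolution for its donor.
    """
    pi_bonds: dict[int, HBond] = {}
    for donor, donor_bonds in bonds_by_donor(list(bonds)).items():
        best = resolve_alternative(donor_bonds)
        if best.offset == PI_OFFSET:
            pi_bonds[best.acceptor_idx] = best
    runs: list[list[HBond]] = []
    for acc in sorted(pi_bonds):
        if runs and acc == runs[-1][-1].acceptor_idx + 1:
            runs[-1].append(pi_bonds[acc])
        else:
            runs.append([pi_bonds[acc]])
    return runs


def _dihedrals_helical(chain: Chain, start: int, end: int, params: AnnotationParams) -> bool:
    """All residues in [start, end] inside the helical windows (None passes)."""
    for r in chain.residues[start : end + 1]:
        if r.phi is not None and not (params.phi_window[0] < r.phi < params.phi_window[1]):
            return False
        if r.psi is not None and not (params.psi_window[0] < r.psi < params.psi_window[1]):
            return False
    return True


def assign_pi_helices(
    chain: Chain,
    bonds: Sequence[HBond],
    labels8: str,
    params: AnnotationParams = AnnotationParams(),
) -> SSAnnotation:
    """Erase DSSP's 'I' labels and re-mark canonical pi-helical ranges."""
    if len(labels8) != len(chain.residues):
        raise ValueError(
            f"labels8 length {len(labels8)} != chain length {len(chain.residues)}"
        )
    labels = ["C" if lab == "I" else lab for lab in labels8]
    for run in pi_bond_runs(bonds, chain):
        if len(run) < params.min_pi_bonds:
            continue
        if min(b.energy for b in run) > params.energy_gate:
            continue
        start = run[0].acceptor_idx
        end = run[-1].donor_idx
        if not _dihedrals_helical(chain, start, end, params):
            continue
        labels[start : end + 1] = "I" * (end - start + 1)
    labels8_out = "".join(labels)
    labels4 = reduce_8_to_4(labels8_out)
    return SSAnnotation(
        labels8=labels8_out, labels4=labels4, segments=segments_from_labels(labels4)
    )


def assign_bulges(
    chain: Chain,
    bonds: Sequence[HBond],
    params: AnnotationParams = AnnotationParams(),
) -> list[tuple[int, int]]:
    """6-residue alpha/pi-bulge segments (isolated single qualifying pi bond).

    Runs of two or more consecutive pi-type bonds are pi-helix candidates
    and never bulges, keeping the two sets disjoint.
    """
    out = []
    for run in pi_bond_runs(bonds, chain):
        if len(run) != 1:
            continue
        bond = run[0]
        if bond.energy > params.energy_gate:
            continue
        start, end = bond.acceptor_idx, bond.donor_idx
        if _dihedrals_helical(chain, start, end, params):
            out.append((start, end))
    return out


def reduce_8_to_4(labels8: str) -> str:
    """Fixed 8-state -> 4-state reduction; 'I' survives only if re-marked."""
    try:
        return "".join(_REDUCE[lab] for lab in labels8)
    except KeyError as exc:
        raise ValueError(f"unknown 8-state label {exc.args[0]!r}") from exc


def segments_from_labels(labels: str) -> list[tuple[str, int, int]]:
    """Maximal runs of equal labels as (type, start, end-inclusive)."""
    segs = []
    for i, lab in enumerate(labels):
        if segs and segs[-1][0] == lab and segs[-1][2] == i - 1:
            segs[-1] = (lab, segs[-1][1], i)
        else:
            segs.append((lab, i, i))
    return segs


# --------------------------------------------------------------------------
# end-to-end composition


def annotate_chain(
    chain: Chain,
    labels8: Optional[str] = None,
    bonds: Optional[Sequence[HBond]] = None,
    params: AnnotationParams = AnnotationParams(),
    with_bulges: bool = False,
) -> SSAnnotation:
    """Annotate one chain; bonds computed internally when not supplied."""
    if bonds is None:
        bonds = find_hbonds(chain)
    if labels8 is None:
        # without a DSSP file only the pi-annotation layer is available;
        # everything that is not a re-marked pi-helix is reported as coil
        labels8 = "C" * len(chain.residues)
    ann = assign_pi_helices(chain, bonds, labels8, params)
    if with_bulges:
        ann.bulges = assign_bulges(chain, bonds, params)
    return ann


def _dssp_chain_bonds(records: list[DsspRecord]) -> dict[str, tuple[Chain, str, list[HBond]]]:
    """Split DSSP records per chain and localize bond indices."""
    by_chain: dict[str, list[int]] = {}
    for idx, rec in enumerate(records):
        by_chain.setdefault(rec.chain_id, []).append(idx)
    out = {}
    for cid, idxs in by_chain.items():
        glob_to_loc = {g: i for i, g in enumerate(idxs)}
        import numpy as np

        chain = Chain(chain_id=cid)
        labels8 = []
        for g in idxs:
            rec = records[g]
            zero = np.zeros(3)
            from .structure_io import BackboneResidue

            chain.residues.append(
                BackboneResidue(
                    chain_id=cid, res_seq=rec.res_seq, aa=rec.aa,
                    N=zero, CA=zero, C=zero, O=zero,
                    phi=rec.phi, psi=rec.psi,
                )
            )
            labels8.append(rec.label8)
        bonds = []
        for g in idxs:
            rec = records[g]
            for partner, energy in rec.nh_o:
                if partner is None or partner not in glob_to_loc:
                    continue
                if energy < -0.5:
                    bonds.append(
                        HBond(
                            donor_idx=glob_to_loc[g],
                            acceptor_idx=glob_to_loc[partner],
                            energy=energy,
                        )
                    )
        out[cid] = (chain, "".join(labels8), bonds)
    return out


def annotate_structure(
    source,
    params: AnnotationParams = AnnotationParams(),
    mode: str = "internal",
    dssp_path=None,
    with_bulges: bool = False,
) -> dict[str, SSAnnotation]:
    """Annotate a structure end to end; returns per-chain annotations.

    ``source`` is a structure file path or a list of :class:`Chain`.  In
    ``internal`` mode hydrogen bonds are computed with the built-in
    Kabsch-Sander machinery and non-pi residues are labelled coil; in
    ``dssp_file`` mode the 8-state labels, dihedrals and bond lists are
    taken from a classic ``.dssp`` file (``dssp_path``).
    """
    if mode == "dssp_file":
        if dssp_path is None:
            raise ValueError("dssp_file mode requires dssp_path")
        per_chain = _dssp_chain_bonds(read_dssp(dssp_path))
        return {
            cid: annotate_chain(chain, labels8, bonds, params, with_bulges)
            for cid, (chain, labels8, bonds) in per_chain.items()
        }
    if mode != "internal":
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(source, (str,)) or hasattr(source, "__fspath__"):
        _, chains = read_structure(source)
    else:
        chains = list(source)
    return {
        chain.chain_id: annotate_chain(chain, None, None, params, with_bulges)
        for chain in chains
    }
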