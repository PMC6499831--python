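"""Read protein structures and DSSP files into a lightweight backbone model.

The internal representation keeps only what downstream hydrogen-bond
analysis, secondary-structure annotation, and differential geometry need:
per-residue backbone atom coordinates (N, CA, C, O, optionally the amide H),
the backbone dihedrals phi/psi, and chain-break bookkeeping.  Coordinates are
in Angstroms; residues are indexed 0-based and contiguously within a chain,
with the author residue numbering preserved for output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "BackboneResidue",
    "Chain",
    "StructureMeta",
    "DsspRecord",
    "StructureParseError",
    "dihedral",
    "read_structure",
    "read_dssp",
    "write_dssp",
    "write_pdb",
]

#: canonical one-letter codes; anything else with a full backbone becomes 'X'
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: C(i)-N(i+1) peptide-bond distance beyond which a chain break is declared
PEPTIDE_BREAK_DISTANCE = 2.5


class StructureParseError(ValueError):
    """Raised for unreadable or empty structure/DSSP input."""


@dataclass
class BackboneResidue:
    """One residue's identity plus backbone geometry.

    ``phi``/``psi`` are in degrees and ``None`` when undefined (chain
    terminus or flanking a chain break).  ``H`` is the amide hydrogen,
    present only after explicit placement (see :mod:`pihelix.hbond`).
    """

    chain_id: str
    res_seq: int
    aa: str
    N: np.ndarray
    CA: np.ndarray
    C: np.ndarray
    O: np.ndarray
    H: Optional[np.ndarray] = None
    phi: Optional[float] = None
    psi: Optional[float] = None


@dataclass
class Chain:
    """Ordered backbone residues of one polymer chain.

    ``breaks`` holds indices ``i`` such that the peptide bond between
    residue ``i`` and ``i + 1`` is broken (missing residue or C-N distance
    above :data:`PEPTIDE_BREAK_DISTANCE`).
    """

    chain_id: str
    residues: list[BackboneResidue] = field(default_factory=list)
    breaks: set[int] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def __getitem__(self, i):
        return self.residues[i]

    def ca_coords(self) -> np.ndarray:
        return np.array([r.CA for r in self.residues], dtype=float)

    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def is_bonded(self, i: int) -> bool:
        """True if residues ``i`` and ``i + 1`` are peptide-bonded."""
        return 0 <= i < len(self.residues) - 1 and i not in self.breaks


@dataclass
class StructureMeta:
    pdb_id: str = ""
    method: str = ""
    resolution: Optional[float] = None


@dataclass
class DsspRecord:
    """One residue row of a classic-format DSSP file.

    Hydrogen-bond partners are stored as absolute 0-based indices into the
    sequence of emitted records (DSSP's own sequential numbering minus one,
    with offsets resolved); ``None`` marks "no partner" (DSSP offset 0).
    """

    chain_id: str
    res_seq: int
    aa: str
    label8: str
    nh_o: tuple[tuple[Optional[int], float], tuple[Optional[int], float]]
    o_nh: tuple[tuple[Optional[int], float], tuple[Optional[int], float]]
    phi: Optional[float]
    psi: Optional[float]


# --------------------------------------------------------------------------
# geometry helpers


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    return math.degrees(math.atan2(-y, x))


def compute_dihedrals(chain: Chain) -> None:
    """Fill ``phi``/``psi`` in place; undefined at termini and across breaks."""
    res = chain.residues
    for i, r in enumerate(res):
        r.phi = None
        r.psi = None
        if i > 0 and chain.is_bonded(i - 1):
            r.phi = dihedral(res[i - 1].C, r.N, r.CA, r.C)
        if i < len(res) - 1 and chain.is_bonded(i):
            r.psi = dihedral(r.N, r.CA, r.C, res[i + 1].N)


def _detect_breaks(chain: Chain) -> None:
    chain.breaks = {
        i
        for i in range(len(chain.residues) - 1)
        if np.linalg.norm(chain.residues[i + 1].N - chain.residues[i].C)
        > PEPTIDE_BREAK_DISTANCE
    }


def finalize_chain(chain: Chain) -> Chain:
    """Detect breaks from coordinates and (re)compute dihedrals."""
    _detect_breaks(chain)
    compute_dihedrals(chain)
    return chain


# --------------------------------------------------------------------------
# structure reading (gemmi-backed)

_BACKBONE = ("N", "CA", "C", "O")


def read_structure(path, fmt: Optional[str] = None) -> tuple[StructureMeta, list[Chain]]:
    """Read a PDB or mmCIF file into backbone chains.

    Only the first model is used.  Alternate locations are resolved by
    keeping the highest-occupancy atom (ties: first encountered).  Residues
    missing any of N/CA/C/O are dropped and induce a chain break.  Dihedrals
    are computed from the standard four-atom backbone definitions.
    """
    import gemmi

    path = str(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(path)
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(path)[0])
        else:
            st = gemmi.read_structure(path)
    except (RuntimeError, ValueError, IndexError) as exc:
        raise StructureParseError(f"cannot parse structure file {path!r}: {exc}") from exc

    st.setup_entities()
    meta = StructureMeta(
        pdb_id=st.name or "",
        method=str(st.info["_exptl.method"] if "_exptl.method" in st.info else ""),
        resolution=st.resolution if st.resolution and st.resolution > 0 else None,
    )

    chains: list[Chain] = []
    model = st[0] if len(st) else None
    if model is None:
        raise StructureParseError(f"{path!r}: structure contains no model")
    for gchain in model:
        chain = Chain(chain_id=gchain.name)
        dropped = False
        for gres in gchain:
            info = gemmi.find_tabulated_residue(gres.name)
            if info is not None and not info.is_amino_acid():
                continue
            coords = _pick_backbone(gres)
            if coords is None:
                dropped = True  # missing backbone atom: drop, break handled by distance
                continue
            chain.residues.append(
                BackboneResidue(
                    chain_id=gchain.name,
                    res_seq=gres.seqid.num,
                    aa=THREE_TO_ONE.get(gres.name, "X"),
                    **coords,
                )
            )
        if chain.residues:
            finalize_chain(chain)
            chains.append(chain)
        del dropped
    if not chains:
        raise StructureParseError(f"{path!r}: no polymer residues with complete backbones")
    return meta, chains


def _pick_backbone(gres) -> Optional[dict]:
    """Highest-occupancy N/CA/C/O coordinates, or None if any is missing."""
    best: dict[str, tuple[float, np.ndarray]] = {}
    for atom in gres:
        if atom.name not in _BACKBONE:
            continue
        occ = atom.occ
        if atom.name not in best or occ > best[atom.name][0]:
            best[atom.name] = (occ, np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
    if len(best) < 4:
        return None
    return {name: best[name][1] for name in _BACKBONE}


# --------------------------------------------------------------------------
# classic DSSP text format

_DSSP_HEADER_MARK = "  #  RESIDUE"


def read_dssp(path) -> list[DsspRecord]:
    """Parse a classic column-formatted ``.dssp`` file.

    Hydrogen-bond offsets are converted to absolute indices into the list of
    returned records; '!' chain-break rows are skipped (they occupy a DSSP
    sequential number but emit no residue).
    """
    lines = Path(path).read_text().splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.startswith(_DSSP_HEADER_MARK):
            start = i + 1
            break
    if start is None:
        raise StructureParseError(f"{path!r}: malformed DSSP header (no '#  RESIDUE' line)")

    records: list[DsspRecord] = []
    seqno_to_idx: dict[int, int] = {}
    raw: list[tuple[int, list[tuple[int, float]], list[tuple[int, float]]]] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if len(line) < 115 or line[13] == "!":
            continue
        try:
            seqno = int(line[0:5])
            res_seq = int(line[5:10])
            chain_id = line[11].strip() or "A"
            aa = line[13]
            label8 = line[16].strip() or "C"
            hb = [_parse_hb(line, col) for col in (39, 50, 61, 72)]
            phi = float(line[103:109])
            psi = float(line[109:115])
        except ValueError as exc:
            raise StructureParseError(f"{path!r} line {lineno}: cannot parse row: {exc}") from exc
        if aa.islower():
            aa = "C"  # DSSP lowercases SS-bonded cysteines
        if label8 not in "HGIEBSTC":
            raise StructureParseError(
                f"{path!r} line {lineno}: unknown secondary-structure label {label8!r}"
            )
        seqno_to_idx[seqno] = len(records)
        raw.append((seqno, [hb[0], hb[2]], [hb[1], hb[3]]))
        records.append(
            DsspRecord(
                chain_id=chain_id,
                res_seq=res_seq,
                aa=aa,
                label8=label8,
                nh_o=((None, 0.0), (None, 0.0)),
                o_nh=((None, 0.0), (None, 0.0)),
                phi=phi if phi != 360.0 else None,
                psi=psi if psi != 360.0 else None,
            )
        )

    for idx, (seqno, nh_o, o_nh) in enumerate(raw):
        records[idx].nh_o = tuple(_resolve(seqno, off, en, seqno_to_idx) for off, en in nh_o)
        records[idx].o_nh = tuple(_resolve(seqno, off, en, seqno_to_idx) for off, en in o_nh)
    return records


def _parse_hb(line: str, col: int) -> tuple[int, float]:
    fieldstr = line[col : col + 11]
    off_s, en_s = fieldstr.split(",")
    return int(off_s), float(en_s)


def _resolve(seqno: int, offset: int, energy: float, seqno_to_idx: dict[int, int]):
    if offset == 0:
        return (None, energy)
    partner = seqno_to_idx.get(seqno + offset)
    return (partner, energy)


def write_dssp(records: Sequence[DsspRecord], path) -> None:
    """Write records in the classic DSSP column layout (fixture round-trips)."""
    out = ["==== Secondary Structure Definition, pihelix dialect ====", "REFERENCE", "HEADER", "COMPND", "SOURCE", "AUTHOR"]
    out.append(
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA"
    )
    for i, rec in enumerate(records):
        seqno = i + 1
        hb = []
        for (p1, e1), (p2, e2) in ((rec.nh_o[0], rec.o_nh[0]), (rec.nh_o[1], rec.o_nh[1])):
            for p, e in ((p1, e1), (p2, e2)):
                off = 0 if p is None else (p + 1) - seqno
                hb.append(f"{off:6d},{e:4.1f}")
        phi = 360.0 if rec.phi is None else rec.phi
        psi = 360.0 if rec.psi is None else rec.psi
        out.append(
            f"{seqno:5d}{rec.res_seq:5d} {rec.chain_id:1s} {rec.aa:1s}  {rec.label8:1s} "
            f"          0   0    0 "
            f"{hb[0]}{hb[1]}{hb[2]}{hb[3]}"
            f"   0.000 360.0 360.0{phi:6.1f}{psi:6.1f}    0.0    0.0    0.0"
        )
    Path(path).write_text("\n".join(out) + "\n")


# --------------------------------------------------------------------------
# PDB writing


def write_pdb(chains: Iterable[Chain], path, meta: Optional[StructureMeta] = None) -> None:
    """Write backbone chains as standard fixed-width ATOM records.

    Coordinates are rounded to 3 decimals, so ``read_structure(write_pdb(x))``
    reproduces them to 0.001 A.  A TER record separates chains.
    """
    chains = list(chains)
    if not chains or not any(len(c) for c in chains):
        raise ValueError("write_pdb: no residues to write")
    lines = []
    if meta is not None and meta.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {meta.resolution:7.2f} ANGSTROMS.")
    serial = 1
    for chain in chains:
        for res in chain.residues:
            resname = ONE_TO_THREE.get(res.aa, "UNK")
            for name, xyz in (("N", res.N), ("CA", res.CA), ("C", res.C), ("O", res.O)):
                x, y, z = (float(v) for v in xyz)
                if max(abs(x), abs(y), abs(z)) >= 10000:
                    raise ValueError(
                        f"write_pdb: coordinate magnitude >= 10000 A at residue {res.res_seq}"
                    )
                element = name[0]
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s} {resname:>3s} {chain.chain_id:1s}"
                    f"{res.res_seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {element:>2s}"
                )
                serial += 1
        last = chain.residues[-1]
        lines.append(
            f"TER   {serial:5d}      {ONE_TO_THREE.get(last.aa, 'UNK'):>3s} "
            f"{chain.chain_id:1s}{last.res_seq:4d}"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
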