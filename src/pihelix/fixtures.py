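"""Synthetic test data: ideal helical backbones, analytic curves, PSSMs.

Everything the test suite needs is generated here from first principles —
ideal alpha-, pi- and 3-10-helical poly-alanine backbones built from
standard peptide bond geometry, parametric helices with closed-form
curvature/torsion, and labelled synthetic sequence/PSSM datasets with
planted pi-helical segments.  No external downloads are ever required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .structure_io import BackboneResidue, Chain, dihedral, finalize_chain

__all__ = [
    "HelixSpec",
    "HELIX_PRESETS",
    "build_helix",
    "parametric_helix",
    "synth_pssm",
    "synth_dataset",
    "write_fasta",
    "write_pssm",
    "write_labels",
]

# standard peptide backbone geometry (Engh & Huber values)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7


@dataclass(frozen=True)
class HelixSpec:
    """Internal-coordinate recipe for an ideal helical backbone."""

    n_residues: int
    phi: float
    psi: float
    omega: float = 180.0

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("helix needs at least 2 residues")
        for name in ("phi", "psi", "omega"):
            v = getattr(self, name)
            if not (-180.0 <= v <= 180.0):
                raise ValueError(f"{name}={v} outside [-180, 180]")


#: ideal dihedral presets.  alpha and threeten are the conventional textbook
#: values.  With rigid ideal bond lengths/angles the textbook pi dihedrals
#: (-76, -41) do not close the i->i+5 hydrogen-bond loop (real pi-helices
#: relax their bond angles); the pi preset was therefore calibrated once so
#: that the built backbone shows consecutive i->i+5 bonds at <= -2.0
#: kcal/mol dominating the i->i+4 alternatives, and then frozen.
HELIX_PRESETS = {
    "alpha": (-57.0, -47.0),
    "pi": (-62.0, -62.0),
    "threeten": (-49.0, -26.0),
}


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D from A-B-C with bond |C-D|, angle B-C-D, torsion A-B-C-D (deg)."""
    theta = math.radians(angle)
    chi = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(chi),
            bond * math.sin(theta) * math.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_helix(spec_or_preset, n_residues: Optional[int] = None, chain_id: str = "A") -> Chain:
    """Build an ideal helical poly-alanine backbone by sequential NeRF placement.

    Accepts either a :class:`HelixSpec` or a preset name from
    :data:`HELIX_PRESETS` plus ``n_residues``.  The first N sits at the
    origin, the first CA on +x, the first C in the xy-plane; phi/psi of the
    built chain match the spec inputs (recoverable from coordinates to
    better than 0.5 degrees).
    """
    if isinstance(spec_or_preset, str):
        if spec_or_preset not in HELIX_PRESETS:
            raise ValueError(f"unknown preset {spec_or_preset!r}")
        if n_residues is None:
            raise ValueError("n_residues required with a preset name")
        phi, psi = HELIX_PRESETS[spec_or_preset]
        spec = HelixSpec(n_residues=n_residues, phi=phi, psi=psi)
    else:
        spec = spec_or_preset

    n = spec.n_residues
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = math.radians(ANGLE_N_CA_C)
    C = [CA[0] + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])]
    for i in range(1, n):
        N.append(_nerf(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, spec.psi))
        CA.append(_nerf(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, spec.omega))
        C.append(_nerf(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, spec.phi))

    O = []
    for i in range(n):
        if i < n - 1:
            next_n = N[i + 1]
        else:  # virtual next N continues the helix so the last C=O is placed consistently
            next_n = _nerf(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, spec.psi)
        u = CA[i] - C[i]
        u /= np.linalg.norm(u)
        v = next_n - C[i]
        v /= np.linalg.norm(v)
        bisector = u + v
        bisector /= np.linalg.norm(bisector)
        O.append(C[i] - BOND_C_O * bisector)

    chain = Chain(chain_id=chain_id)
    for i in range(n):
        chain.residues.append(
            BackboneResidue(
                chain_id=chain_id, res_seq=i + 1, aa="A",
                N=N[i], CA=CA[i], C=C[i], O=O[i],
            )
        )
    return finalize_chain(chain)


def parametric_helix(R: float, omega_deg: float, c: float, n_points: int):
    """Points of the circular helix (R cos wt, R sin wt, ct) at integer t.

    Returns ``(points, kappa, tau, rpt)`` with the closed-form curvature
    ``R w^2 / (R^2 w^2 + c^2)``, torsion ``c w / (R^2 w^2 + c^2)`` (w in
    radians per point) and residues-per-turn ``360 / omega_deg``.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    w = math.radians(omega_deg)
    t = np.arange(n_points, dtype=float)
    pts = np.column_stack([R * np.cos(w * t), R * np.sin(w * t), c * t])
    denom = R * R * w * w + c * c
    kappa = R * w * w / denom
    tau = c * w / denom
    rpt = 360.0 / omega_deg if omega_deg != 0 else math.inf
    return pts, kappa, tau, rpt


# --------------------------------------------------------------------------
# synthetic sequence / PSSM datasets

#: PSI-BLAST amino-acid column order (canonical, documented contract)
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

_CLASS_ORDER = "EHIC"

# class-conditional score signatures: each class boosts a disjoint column set,
# loosely mimicking real preferences (Asn/aromatics in pi-helices, small
# residues in coil, branched aliphatics in strands)
_CLASS_COLUMNS = {
    "I": [PSSM_ALPHABET.index(a) for a in "NFWM"],
    "H": [PSSM_ALPHABET.index(a) for a in "ALEK"],
    "E": [PSSM_ALPHABET.index(a) for a in "VIYT"],
    "C": [PSSM_ALPHABET.index(a) for a in "GPSD"],
}
_SIGNAL = 4.0
_NOISE_SD = 1.5

# segment-length ranges used by the generator (residues)
_SEG_LEN = {"I": (7, 10), "H": (5, 15), "E": (3, 8), "C": (2, 10)}


def synth_pssm(labels: str, rng: np.random.Generator) -> np.ndarray:
    """Integer log-odds PSSM (L x 20) carrying a class-conditional signal."""
    L = len(labels)
    scores = rng.normal(0.0, _NOISE_SD, size=(L, 20))
    for i, lab in enumerate(labels):
        scores[i, _CLASS_COLUMNS[lab]] += _SIGNAL
    return np.clip(np.rint(scores), -10, 13).astype(int)


def _plant_labels(length: int, pi_rate: float, rng: np.random.Generator) -> str:
    """Segment-structured 4-state label string with planted 'I' runs (>= 7)."""
    mean_len = {c: (lo + hi) / 2 for c, (lo, hi) in _SEG_LEN.items()}
    # choose I-start probability so the expected I fraction matches pi_rate
    other = (mean_len["H"] + mean_len["E"] + mean_len["C"]) / 3
    if pi_rate > 0:
        q = pi_rate * other / (mean_len["I"] * (1 - pi_rate) + pi_rate * other)
    else:
        q = 0.0
    out: list[str] = []
    prev = None
    while len(out) < length:
        if pi_rate > 0 and prev != "I" and rng.random() < q:
            lab = "I"
        else:
            lab = "HEC"[rng.integers(3)]
            while lab == prev == "I":  # pragma: no cover - defensive
                lab = "HEC"[rng.integers(3)]
        lo, hi = _SEG_LEN[lab]
        seg = int(rng.integers(lo, hi + 1))
        if lab == "I" and length - len(out) < lo:
            lab = "C"
            seg = length - len(out)
        out.extend(lab * min(seg, length - len(out)))
        prev = lab
    s = "".join(out[:length])
    # a truncated trailing I run shorter than 7 is not a pi-helix: coil it
    return _trim_short_pi(s)


def _trim_short_pi(labels: str) -> str:
    out = list(labels)
    i = 0
    while i < len(out):
        if out[i] == "I":
            j = i
            while j < len(out) and out[j] == "I":
                j += 1
            if j - i < 7:
                out[i:j] = ["C"] * (j - i)
            i = j
        else:
            i += 1
    return "".join(out)


def _sample_sequence(labels: str, rng: np.random.Generator) -> str:
    """Residues drawn with a mild class-conditional compositional bias."""
    seq = []
    for lab in labels:
        if rng.random() < 0.4:
            cols = _CLASS_COLUMNS[lab]
            seq.append(PSSM_ALPHABET[cols[rng.integers(len(cols))]])
        else:
            seq.append(PSSM_ALPHABET[rng.integers(20)])
    return "".join(seq)


def synth_dataset(
    n_seqs: int,
    pi_rate: float = 0.05,
    length_range: tuple[int, int] = (60, 120),
    seed: int = 0,
) -> list[dict]:
    """Generate labelled sequences with planted pi-helices and synthetic PSSMs.

    Each record is ``{"id", "sequence", "labels", "pssm"}`` with 4-state
    labels over {E, H, I, C}; every 'I' run has length >= 7.  Deterministic
    at fixed seed.
    """
    if not (0.0 <= pi_rate <= 0.2):
        raise ValueError("pi_rate must be in [0, 0.2]")
    lo, hi = length_range
    if lo < 7 or hi < lo:
        raise ValueError(f"infeasible length_range {length_range}")
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n_seqs):
        L = int(rng.integers(lo, hi + 1))
        labels = _plant_labels(L, pi_rate, rng)
        records.append(
            {
                "id": f"synth{k:04d}",
                "sequence": _sample_sequence(labels, rng),
                "labels": labels,
                "pssm": synth_pssm(labels, rng),
            }
        )
    return records


# --------------------------------------------------------------------------
# plain-text writers (fixture files)


def write_fasta(records: dict[str, str] | list[tuple[str, str]], path) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_pssm(sequence: str, scores: np.ndarray, path) -> None:
    """Write integer log-odds in the PSI-BLAST ASCII layout."""
    scores = np.asarray(scores)
    if scores.shape != (len(sequence), 20):
        raise ValueError("scores must be L x 20")
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts\n")
        fh.write("           " + "  ".join(PSSM_ALPHABET) + "   " + "   ".join(PSSM_ALPHABET) + "\n")
        for i, (aa, row) in enumerate(zip(sequence, scores), start=1):
            ints = " ".join(f"{int(v):3d}" for v in row)
            pct = " ".join(f"{0:3d}" for _ in row)
            fh.write(f"{i:5d} {aa} {ints}  {pct}  0.00 0.00\n")
        fh.write("\n")


def write_labels(records: list[dict], path) -> None:
    """TSV: id, sequence, 4-state label string."""
    with open(path, "w") as fh:
        fh.write("id\tsequence\tlabels\n")
        for rec in records:
            fh.write(f"{rec['id']}\t{rec['sequence']}\t{rec['labels']}\n")


def make_all(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write the standard fixture set (PDBs, FASTA, PSSMs, labels) to a directory."""
    from .structure_io import write_pdb

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for preset, n in (("alpha", 12), ("pi", 12), ("threeten", 12)):
        p = out / f"ideal_{preset}_{n}.pdb"
        write_pdb([build_helix(preset, n)], p)
        paths[f"pdb_{preset}"] = p
    ds = synth_dataset(10, seed=seed)
    write_fasta([(r["id"], r["sequence"]) for r in ds], out / "synth.fasta")
    write_labels(ds, out / "synth_labels.tsv")
    for rec in ds[:3]:
        write_pssm(rec["sequence"], rec["pssm"], out / f"{rec['id']}.pssm")
        paths[f"pssm_{rec['id']}"] = out / f"{rec['id']}.pssm"
    paths["fasta"] = out / "synth.fasta"
    paths["labels"] = out / "synth_labels.tsv"
    return paths
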