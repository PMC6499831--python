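"""Sequence + PSSM encoding into the fixed 700 x 40 input representation.

Each residue contributes 40 features: a 20-column one-hot of the amino
acid (all-zero for 'X') and the 20 PSI-BLAST log-odds scores squashed
through the logistic sigmoid into (0, 1).  Sequences shorter than the
700-row frame are zero-padded, with the padding placed entirely at the N-
or C-terminal end, the end drawn uniformly at random from the seed; a mask
records which rows are real.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fixtures import PSSM_ALPHABET

__all__ = ["MAX_LEN", "Pssm", "EncodedSample", "read_pssm", "encode"]

MAX_LEN = 700
N_FEATURES = 40

_AA_INDEX = {aa: i for i, aa in enumerate(PSSM_ALPHABET)}


@dataclass
class Pssm:
    """Per-residue PSI-BLAST log-odds, columns in the canonical order
    ``A R N D C Q E G H I L K M F P S T W Y V``."""

    scores: np.ndarray  # (L, 20) integer-valued
    sequence: str

    def __post_init__(self):
        self.scores = np.asarray(self.scores)
        if self.scores.shape != (len(self.sequence), 20):
            raise ValueError("PSSM shape must be (len(sequence), 20)")


@dataclass
class EncodedSample:
    """700 x 40 network input plus padding bookkeeping."""

    matrix: np.ndarray  # (700, 40)
    mask: np.ndarray  # (700,) bool, True on real rows
    pad_offset: int  # rows of padding before the sequence

    def depad(self) -> np.ndarray:
        """The L x 40 block of real rows (independent of the padding end)."""
        return self.matrix[self.mask]


def read_pssm(path, sequence: str | None = None) -> Pssm:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file (first 20 score columns).

    If ``sequence`` is given it is cross-checked against the PSSM's own
    residue column.
    """
    rows = []
    seq_chars = []
    expecting = 1
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        tokens = line.split()
        if not tokens or not tokens[0].isdigit():
            continue
        idx = int(tokens[0])
        if idx != expecting:
            continue  # not a matrix row (e.g. stray numeric line)
        if len(tokens) < 22:
            raise ValueError(
                f"{path} line {lineno}: matrix row {idx} has {len(tokens) - 2} score columns, expected 20"
            )
        if not re.fullmatch(r"[A-Za-z*]", tokens[1]):
            raise ValueError(f"{path} line {lineno}: unexpected residue column {tokens[1]!r}")
        try:
            scores = [int(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: bad score field: {exc}") from exc
        rows.append(scores)
        seq_chars.append(tokens[1].upper())
        expecting += 1
    if not rows:
        raise ValueError(f"{path}: no PSSM rows found")
    pssm_seq = "".join(seq_chars)
    if sequence is not None and sequence != pssm_seq:
        raise ValueError(
            f"{path}: PSSM sequence does not match the supplied sequence "
            f"({pssm_seq[:20]!r}... vs {sequence[:20]!r}...)"
        )
    return Pssm(scores=np.array(rows, dtype=float), sequence=pssm_seq)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def encode(sequence: str, pssm: Pssm, seed: int = 0) -> EncodedSample:
    """Encode one sequence/PSSM pair into the padded 700 x 40 matrix."""
    L = len(sequence)
    if L == 0:
        raise ValueError("empty sequence")
    if L > MAX_LEN:
        raise ValueError(f"sequence length {L} exceeds the {MAX_LEN}-residue frame")
    if len(pssm.sequence) != L:
        raise ValueError("PSSM not aligned to sequence")

    block = np.zeros((L, N_FEATURES))
    for i, aa in enumerate(sequence):
        j = _AA_INDEX.get(aa)
        if j is not None:
            block[i, j] = 1.0
    block[:, 20:] = _sigmoid(pssm.scores)

    rng = np.random.default_rng(seed)
    pad_at_start = bool(rng.integers(2))  # N-terminal padding if True
    pad_offset = MAX_LEN - L if pad_at_start else 0

    matrix = np.zeros((MAX_LEN, N_FEATURES))
    mask = np.zeros(MAX_LEN, dtype=bool)
    matrix[pad_offset : pad_offset + L] = block
    mask[pad_offset : pad_offset + L] = True
    return EncodedSample(matrix=matrix, mask=mask, pad_offset=pad_offset)
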