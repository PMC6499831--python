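"""Dataset construction rules: structure filters, cluster representatives,
pi-balanced train/test splits, and label correction for sequence datasets.

The rules mirror how a non-redundant pi-helix dataset is carved out of the
PDB: discard structures outside 30-700 residues, worse than 2.5 A
resolution, or not solved by X-ray crystallography; pick one
representative per sequence cluster (best resolution; among pi-containing
clusters also the longest pi segment, with bulge-carrying candidates
excluded so canonical pi-helices and bulges never mix); and split into
train/test sets holding the pi-residue percentage equal on both sides.

Sequence-identity clustering and sequence-to-structure matching are
consumed as precomputed inputs — they come from external search tools and
are outside this package's scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .annotate import AnnotationParams, annotate_chain
from .structure_io import Chain

__all__ = [
    "StructureRecord",
    "structure_filter",
    "select_representative",
    "balanced_split",
    "relabel_dataset",
]

MIN_LENGTH = 30
MAX_LENGTH = 700
MAX_RESOLUTION = 2.5


@dataclass(frozen=True)
class StructureRecord:
    """Summary of one candidate structure for dataset assembly."""

    id: str
    length: int
    resolution: Optional[float] = None
    method: str = "X-ray"
    has_pi: bool = False
    longest_pi: int = 0
    has_bulge: bool = False
    pi_residues: int = 0
    total_residues: Optional[int] = None

    def __post_init__(self):
        if self.pi_residues < 0 or self.longest_pi < 0:
            raise ValueError("counts must be non-negative")
        if self.has_pi and self.longest_pi < 7:
            raise ValueError("a canonical pi-helix spans at least 7 residues")


def structure_filter(record: StructureRecord) -> tuple[bool, str]:
    """Keep/discard decision with a reason.  Boundaries are inclusive:
    length 30 and 700 and resolution 2.5 A pass."""
    if record.length > MAX_LENGTH:
        return False, "too long"
    if record.length < MIN_LENGTH:
        return False, "too short"
    if record.resolution is not None and record.resolution > MAX_RESOLUTION:
        return False, "resolution worse than 2.5 A"
    if record.method != "X-ray":
        return False, "not X-ray"
    return True, "ok"


def select_representative(cluster: Sequence[StructureRecord]) -> Optional[StructureRecord]:
    """One representative per cluster, or None.

    Clusters without any pi-helix or bulge: the member with the best
    (numerically lowest) resolution.  Clusters with pi-helices: among the
    bulge-free pi-containing members, best resolution then longest pi
    segment.  Clusters whose pi candidates all carry bulges: discarded.
    Ties break lexicographically on id.
    """
    if not cluster:
        raise ValueError("empty cluster")

    def res_key(r: StructureRecord):
        return (r.resolution if r.resolution is not None else np.inf, r.id)

    if not any(r.has_pi or r.has_bulge for r in cluster):
        return min(cluster, key=res_key)
    candidates = [r for r in cluster if r.has_pi and not r.has_bulge]
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda r: (
            r.resolution if r.resolution is not None else np.inf,
            -r.longest_pi,
            r.id,
        ),
    )


def _pi_fraction(records: Sequence[StructureRecord], ids) -> float:
    pi = sum(r.pi_residues for r in records if r.id in ids)
    tot = sum((r.total_residues or r.length) for r in records if r.id in ids)
    return pi / tot if tot else 0.0


def balanced_split(
    records: Sequence[StructureRecord],
    test_fraction: float = 0.1,
    seed: int = 0,
    tolerance_pp: float = 0.02,
    max_rounds: int = 10000,
) -> tuple[list[str], list[str]]:
    """Random train/test split with matched pi-residue percentages.

    After an initial random split at ``test_fraction``, pairs of records
    are greedily swapped across the boundary until the train and test
    pi-residue percentages agree within ``tolerance_pp`` percentage
    points.  Deterministic at fixed seed; if the tolerance is infeasible
    the best achieved split is returned with a warning.
    """
    if not records:
        raise ValueError("no records")
    rng = np.random.default_rng(seed)
    ids = [r.id for r in records]
    perm = rng.permutation(len(records))
    n_test = max(1, int(round(test_fraction * len(records))))
    test = {ids[i] for i in perm[:n_test]}
    train = {ids[i] for i in perm[n_test:]}

    pi = np.array([r.pi_residues for r in records], float)
    tot = np.array([float(r.total_residues or r.length) for r in records])
    in_test = np.array([r.id in test for r in records])

    def delta(in_test_mask):
        te_pi, te_tot = pi[in_test_mask].sum(), tot[in_test_mask].sum()
        tr_pi, tr_tot = pi[~in_test_mask].sum(), tot[~in_test_mask].sum()
        fr_te = te_pi / te_tot if te_tot else 0.0
        fr_tr = tr_pi / tr_tot if tr_tot else 0.0
        return 100.0 * (fr_tr - fr_te)

    best = abs(delta(in_test))
    for _ in range(max_rounds):
        if best <= tolerance_pp:
            break
        improved = False
        # try a random batch of candidate swaps, accept the first improvement
        tr_idx = np.nonzero(~in_test)[0]
        te_idx = np.nonzero(in_test)[0]
        for i, j in zip(rng.choice(tr_idx, size=min(64, len(tr_idx)), replace=False),
                        rng.choice(te_idx, size=min(64, len(te_idx)), replace=False)):
            trial = in_test.copy()
            trial[i], trial[j] = True, False
            d = abs(delta(trial))
            if d < best:
                in_test = trial
                best = d
                improved = True
                break
        if not improved:
            break
    if best > tolerance_pp:
        import warnings

        warnings.warn(
            f"balanced_split: achieved |delta|={best:.4f} pp above tolerance {tolerance_pp} pp"
        )
    train_ids = [ids[i] for i in np.nonzero(~in_test)[0]]
    test_ids = [ids[i] for i in np.nonzero(in_test)[0]]
    return train_ids, test_ids


def relabel_dataset(
    entries: Sequence[dict],
    params: AnnotationParams = AnnotationParams(),
) -> tuple[list[dict], list[dict]]:
    """Correct pi-helix annotation of dataset entries with matched structures.

    Each entry is ``{"id", "sequence", "labels8", "chain"}`` where
    ``chain`` is the matched :class:`Chain` whose sequence must equal the
    entry sequence.  The re-annotation first erases prior 'I' labels to
    'C', then re-marks qualifying pi-helical ranges, so only I and C
    labels can change.  Returns (corrected entries, skipped entries with
    reasons).
    """
    corrected = []
    skipped = []
    for entry in entries:
        chain: Chain = entry["chain"]
        if chain.sequence() != entry["sequence"]:
            skipped.append({"id": entry.get("id"), "reason": "sequence mismatch with structure"})
            continue
        if len(entry["labels8"]) != len(entry["sequence"]):
            skipped.append({"id": entry.get("id"), "reason": "labels8 length mismatch"})
            continue
        ann = annotate_chain(chain, labels8=entry["labels8"], params=params)
        corrected.append(
            {
                "id": entry.get("id"),
                "sequence": entry["sequence"],
                "labels8": ann.labels8,
                "labels4": ann.labels4,
            }
        )
    return corrected, skipped
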