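"""Independent brute-force reference implementations used only by tests.

These deliberately re-derive every quantity from first principles (explicit
formulas, exhaustive enumeration) without calling the package's own code
paths, so agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np


# -- hydrogen bonds ---------------------------------------------------------


def ks_energy_raw(N, H, C, O) -> float:
    """Kabsch-Sander energy from the four distances, written out explicitly."""
    q1q2f = 0.084 * 332.0
    r_on = math.dist(O, N)
    r_ch = math.dist(C, H)
    r_oh = math.dist(O, H)
    r_cn = math.dist(C, N)
    e = q1q2f * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return max(e, -9.9)


def brute_force_hbonds(chain) -> list[tuple[int, int, float]]:
    """All-pairs donor/acceptor evaluation with no distance prefilter.

    Returns (donor, acceptor, energy) tuples: per donor the two lowest
    energies below -0.5 kcal/mol, ties broken by acceptor index.
    """
    res = chain.residues
    out = []
    for i, donor in enumerate(res):
        if donor.H is None:
            continue
        cands = []
        for j, acc in enumerate(res):
            if abs(i - j) < 2:
                continue
            e = ks_energy_raw(donor.N, donor.H, acc.C, acc.O)
            if e < -0.5:
                cands.append((e, j))
        cands.sort()
        out.extend((i, j, e) for e, j in cands[:2])
    return out


# -- annotation -------------------------------------------------------------


def literal_pi_annotation(n_res, bonds, phi, psi, labels8, energy_gate=-2.0,
                          min_bonds=2, phi_win=(-180.0, 0.0), psi_win=(-120.0, 45.0)):
    """Exhaustive, literal re-implementation of the pi re-marking criteria.

    ``bonds`` is a list of (donor, acceptor, energy).  Returns the
    corrected 8-state label string and a list of bulge segments.
    """
    # alternative-bond resolution per donor: lowest energy, tie -> larger offset
    preferred = {}
    by_donor: dict[int, list[tuple[int, int, float]]] = {}
    for d, a, e in bonds:
        by_donor.setdefault(d, []).append((d, a, e))
    for d, lst in by_donor.items():
        best = min(lst, key=lambda t: (t[2], -(t[0] - t[1])))
        preferred[d] = best
    pi_at = {}
    for d, (dd, a, e) in preferred.items():
        if dd - a == 5:
            pi_at[a] = e
    # maximal runs of consecutive acceptor positions
    runs = []
    for a in sorted(pi_at):
        if runs and a == runs[-1][-1] + 1:
            runs[-1].append(a)
        else:
            runs.append([a])

    def window_ok(lo, hi):
        for i in range(lo, hi + 1):
            if phi[i] is not None and not (phi_win[0] < phi[i] < phi_win[1]):
                return False
            if psi[i] is not None and not (psi_win[0] < psi[i] < psi_win[1]):
                return False
        return True

    labels = ["C" if l == "I" else l for l in labels8]
    bulges = []
    for run in runs:
        lo, hi = run[0], run[-1] + 5
        energies = [pi_at[a] for a in run]
        if len(run) >= min_bonds:
            if min(energies) <= energy_gate and window_ok(lo, hi):
                for i in range(lo, hi + 1):
                    labels[i] = "I"
        elif len(run) == 1:
            if energies[0] <= energy_gate and window_ok(lo, hi):
                bulges.append((lo, hi))
    return "".join(labels), bulges


def reduce_map(labels8: str) -> str:
    m = {"G": "H", "H": "H", "E": "E", "B": "E", "S": "C", "T": "C", "C": "C", "I": "I"}
    return "".join(m[c] for c in labels8)


# -- evaluation -------------------------------------------------------------


def brute_confusion(true4: str, pred4: str, classes: str = "EHIC"):
    counts = np.zeros((4, 4), dtype=int)
    for t, p in zip(true4, pred4):
        counts[classes.index(t), classes.index(p)] += 1
    return counts


def brute_segment_eval(true_segs, pred_segs):
    def overlaps(a, b):
        return max(a[0], b[0]) <= min(a[1], b[1])

    matched_t = [any(overlaps(t, p) for p in pred_segs) for t in true_segs]
    matched_p = [any(overlaps(p, t) for t in true_segs) for p in pred_segs]
    tp = sum(matched_t)
    fn = len(true_segs) - tp
    fp = len(matched_p) - sum(matched_p)
    return tp, fn, fp


def brute_auprc(y, s):
    """Trapezoid PR area computed by an explicit per-threshold loop."""
    y = np.asarray(y, bool)
    s = np.asarray(s, float)
    n_pos = int(y.sum())
    pts = []
    for thr in sorted(set(s), reverse=True):
        sel = s >= thr
        tp = int((y & sel).sum())
        prec = tp / int(sel.sum())
        rec = tp / n_pos
        pts.append((rec, prec))
    pts = [(0.0, pts[0][1])] + pts
    area = 0.0
    for (r0, p0), (r1, p1) in zip(pts, pts[1:]):
        area += (r1 - r0) * (p0 + p1) / 2.0
    return area


def brute_paired_ttest(a, b):
    """Textbook paired t statistic and two-sided p from the t distribution."""
    from scipy.stats import t as tdist

    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    sd = d.std(ddof=1)
    t_stat = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * tdist.sf(abs(t_stat), n - 1)
    return t_stat, p


# -- geometry ---------------------------------------------------------------


def torsion_four_point(p0, p1, p2, p3) -> float:
    """Four-atom torsion angle in degrees via the atan2 formulation."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    # IUPAC sign convention (clockwise positive looking b1->b2->b3)
    return math.degrees(math.atan2(-(m @ n2), n1 @ n2))
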