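"""Pairwise alignment measurement contract shared by every audit stage.

``align_stats`` computes identity, query coverage and the matched interval on
the target, using an affine-gap Gotoh dynamic program.  Two modes:

* ``glocal`` — the query is aligned end-to-end inside the target (end gaps on
  the target free, everything else penalized).  This is the admission geometry
  of length-sorted greedy clustering: the query must match the representative
  over its own full length, while the representative may extend past it.
* ``global`` — both sequences aligned end-to-end.

Scoring is fixed: match +1, mismatch -1, gap open -2 (first gapped column),
gap extension -1 per further column.  Identity is ``matches / alignment
columns`` within the aligned span (BLAST-like).  The CD-HIT-style alternative
(matches over the shorter sequence length) is exposed as
``AlignmentStats.identity_shorter``; callers choose via the
``identity_definition`` switch where relevant.

Determinism: ties prefer diagonal over target-gap over query-gap moves, and
the leftmost optimal end position on the target.  Coordinates are 0-based,
half-open.

``oracle_align_stats`` is a deliberately simple full-matrix pure-Python
implementation of the same contract with explicit traceback, used in tests as
the independent cross-check; it carries an input-size guard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .synth import LabeledSequence

MATCH = 1
MISMATCH = -1
GAP_OPEN = -2
GAP_EXT = -1

_NEG = -(10**9)


@dataclass(frozen=True)
class AlignmentStats:
    identity: float
    query_coverage: float
    target_coverage: float
    target_interval: tuple[int, int]
    matches: int
    alignment_columns: int
    score: int
    query_length: int
    target_length: int

    @property
    def identity_shorter(self) -> float:
        """Matches over the shorter sequence length (CD-HIT convention)."""
        return self.matches / min(self.query_length, self.target_length)

    def identity_by(self, definition: str) -> float:
        if definition == "alignment_columns":
            return self.identity
        if definition == "shorter_sequence":
            return self.identity_shorter
        raise ValueError(f"unknown identity definition {definition!r}")


@njit(cache=True)
def _gotoh(q, t, glocal):  # pragma: no cover - exercised via align_stats
    n = q.shape[0]
    m = t.shape[0]
    # per-state rows: score, matches, columns, target-start
    sH = np.full(m + 1, _NEG, np.int64)
    sE = np.full(m + 1, _NEG, np.int64)
    sF = np.full(m + 1, _NEG, np.int64)
    mH = np.zeros(m + 1, np.int64); cH = np.zeros(m + 1, np.int64); bH = np.zeros(m + 1, np.int64)
    mE = np.zeros(m + 1, np.int64); cE = np.zeros(m + 1, np.int64); bE = np.zeros(m + 1, np.int64)
    mF = np.zeros(m + 1, np.int64); cF = np.zeros(m + 1, np.int64); bF = np.zeros(m + 1, np.int64)

    if glocal:
        for j in range(m + 1):
            sH[j] = 0
            bH[j] = j
    else:
        sH[0] = 0
        for j in range(1, m + 1):
            sE[j] = GAP_OPEN + GAP_EXT * (j - 1)
            cE[j] = j
    nH = np.empty_like(sH); nE = np.empty_like(sE); nF = np.empty_like(sF)
    nmH = np.empty_like(mH); ncH = np.empty_like(cH); nbH = np.empty_like(bH)
    nmE = np.empty_like(mE); ncE = np.empty_like(cE); nbE = np.empty_like(bE)
    nmF = np.empty_like(mF); ncF = np.empty_like(cF); nbF = np.empty_like(bF)

    for i in range(1, n + 1):
        nH[0] = _NEG; nE[0] = _NEG
        # F at column 0: query base against a gap before the target
        fa = sH[0] + GAP_OPEN
        fb = sF[0] + GAP_EXT
        if fa >= fb:
            nF[0] = fa; nmF[0] = mH[0]; ncF[0] = cH[0] + 1; nbF[0] = bH[0]
        else:
            nF[0] = fb; nmF[0] = mF[0]; ncF[0] = cF[0] + 1; nbF[0] = bF[0]
        qc = q[i - 1]
        for j in range(1, m + 1):
            # H: diagonal from best previous-row state at j-1 (prefer H > E > F)
            ps = sH[j - 1]; pm = mH[j - 1]; pc = cH[j - 1]; pb = bH[j - 1]
            if sE[j - 1] > ps:
                ps = sE[j - 1]; pm = mE[j - 1]; pc = cE[j - 1]; pb = bE[j - 1]
            if sF[j - 1] > ps:
                ps = sF[j - 1]; pm = mF[j - 1]; pc = cF[j - 1]; pb = bF[j - 1]
            if qc == t[j - 1]:
                nH[j] = ps + MATCH; nmH[j] = pm + 1
            else:
                nH[j] = ps + MISMATCH; nmH[j] = pm
            ncH[j] = pc + 1; nbH[j] = pb
            # E: target base against a gap in the query (same row)
            ea = nH[j - 1] + GAP_OPEN
            eb = nE[j - 1] + GAP_EXT
            if ea >= eb:
                nE[j] = ea; nmE[j] = nmH[j - 1]; ncE[j] = ncH[j - 1] + 1; nbE[j] = nbH[j - 1]
            else:
                nE[j] = eb; nmE[j] = nmE[j - 1]; ncE[j] = ncE[j - 1] + 1; nbE[j] = nbE[j - 1]
            # F: query base against a gap in the target (previous row)
            fa = sH[j] + GAP_OPEN
            fb = sF[j] + GAP_EXT
            if fa >= fb:
                nF[j] = fa; nmF[j] = mH[j]; ncF[j] = cH[j] + 1; nbF[j] = bH[j]
            else:
                nF[j] = fb; nmF[j] = mF[j]; ncF[j] = cF[j] + 1; nbF[j] = bF[j]
        sH, nH = nH, sH; sE, nE = nE, sE; sF, nF = nF, sF
        mH, nmH = nmH, mH; cH, ncH = ncH, cH; bH, nbH = nbH, bH
        mE, nmE = nmE, mE; cE, ncE = ncE, cE; bE, nbE = nbE, bE
        mF, nmF = nmF, mF; cF, ncF = ncF, cF; bF, nbF = nbF, bF

    if glocal:
        # free trailing target gap: best end over all j; alignments never end
        # in a target-consuming gap state (ending earlier always scores better)
        best = _NEG; bj = 0; bmat = 0; bcol = 0; bstart = 0
        for j in range(m + 1):
            if sH[j] > best:
                best = sH[j]; bj = j; bmat = mH[j]; bcol = cH[j]; bstart = bH[j]
            if sF[j] > best:
                best = sF[j]; bj = j; bmat = mF[j]; bcol = cF[j]; bstart = bF[j]
        return best, bmat, bcol, bstart, bj
    best = sH[m]; bmat = mH[m]; bcol = cH[m]; bstart = bH[m]
    if sE[m] > best:
        best = sE[m]; bmat = mE[m]; bcol = cE[m]; bstart = bE[m]
    if sF[m] > best:
        best = sF[m]; bmat = mF[m]; bcol = cF[m]; bstart = bF[m]
    return best, bmat, bcol, bstart, m


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(bases: str) -> np.ndarray:
    return np.frombuffer(bases.encode("ascii"), dtype=np.uint8)


def align_stats(query: LabeledSequence | str, target: LabeledSequence | str,
                mode: str = "glocal") -> AlignmentStats:
    """Align *query* against *target* and report the measurement contract.

    In glocal mode an exact-substring fast path short-circuits the DP: a
    perfect placement attains the maximum possible score, and the leftmost
    occurrence matches the DP's leftmost-end tie-break.
    """
    q = query.bases if isinstance(query, LabeledSequence) else query
    t = target.bases if isinstance(target, LabeledSequence) else target
    if not q or not t:
        raise ValueError("align_stats requires non-empty sequences")
    if mode not in ("glocal", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    n, m = len(q), len(t)
    if mode == "glocal":
        idx = t.find(q)
        if idx >= 0:
            return AlignmentStats(
                identity=1.0, query_coverage=1.0, target_coverage=n / m,
                target_interval=(idx, idx + n), matches=n,
                alignment_columns=n, score=n * MATCH,
                query_length=n, target_length=m)
    score, matches, columns, t_start, t_end = _gotoh(
        _encode(q), _encode(t), mode == "glocal")
    return AlignmentStats(
        identity=matches / columns if columns else 1.0,
        query_coverage=1.0,
        target_coverage=(t_end - t_start) / m,
        target_interval=(int(t_start), int(t_end)),
        matches=int(matches), alignment_columns=int(columns),
        score=int(score), query_length=n, target_length=m)


def site_divergence(a: LabeledSequence | str, b: LabeledSequence | str) -> float:
    """Exact per-site divergence of two equal-length sequences.

    For substitution-only constructions this is the ground-truth divergence
    the worst-case merge geometry speaks about: mismatched sites over length.
    Score-based aligners can report slightly *higher* identity on highly
    divergent pairs by realigning around chance local matches with gaps; this
    brute-force count is immune to that and is the measurement of record for
    bound-attainment checks.
    """
    x = a.bases if isinstance(a, LabeledSequence) else a
    y = b.bases if isinstance(b, LabeledSequence) else b
    if len(x) != len(y):
        raise ValueError("site_divergence requires equal-length sequences")
    if not x:
        raise ValueError("site_divergence requires non-empty sequences")
    return sum(1 for p, q in zip(x, y) if p != q) / len(x)


# ---------------------------------------------------------------------------
# Independent oracle: full-matrix Gotoh with explicit traceback, pure Python.

ORACLE_SIZE_LIMIT = 10**6


def oracle_align_stats(query: LabeledSequence | str,
                       target: LabeledSequence | str,
                       mode: str = "glocal") -> AlignmentStats:
    """Reference implementation of the alignment contract (tests only).

    O(n*m) time and memory with explicit per-state traceback pointers;
    guarded to n*m <= 10^6.
    """
    q = query.bases if isinstance(query, LabeledSequence) else query
    t = target.bases if isinstance(target, LabeledSequence) else target
    if not q or not t:
        raise ValueError("oracle requires non-empty sequences")
    n, m = len(q), len(t)
    if n * m > ORACLE_SIZE_LIMIT:
        raise ValueError(f"oracle size guard exceeded: {n}*{m} > {ORACLE_SIZE_LIMIT}")
    glocal = mode == "glocal"
    if not glocal and mode != "global":
        raise ValueError(f"unknown mode {mode!r}")

    H = [[_NEG] * (m + 1) for _ in range(n + 1)]
    E = [[_NEG] * (m + 1) for _ in range(n + 1)]
    F = [[_NEG] * (m + 1) for _ in range(n + 1)]
    # pointers: for H, previous state at (i-1, j-1); for E, state at (i, j-1);
    # for F, state at (i-1, j). "o" marks an origin cell (alignment start).
    PH = [[""] * (m + 1) for _ in range(n + 1)]
    PE = [[""] * (m + 1) for _ in range(n + 1)]
    PF = [[""] * (m + 1) for _ in range(n + 1)]

    for j in range(m + 1):
        if glocal:
            H[0][j] = 0
            PH[0][j] = "o"
        elif j == 0:
            H[0][0] = 0
            PH[0][0] = "o"
        else:
            E[0][j] = GAP_OPEN + GAP_EXT * (j - 1)
            PE[0][j] = "H" if j == 1 else "E"

    for i in range(1, n + 1):
        fa = H[i - 1][0] + GAP_OPEN
        fb = F[i - 1][0] + GAP_EXT
        F[i][0], PF[i][0] = (fa, "H") if fa >= fb else (fb, "F")
        for j in range(1, m + 1):
            s = MATCH if q[i - 1] == t[j - 1] else MISMATCH
            prev = [(H[i - 1][j - 1], "H"), (E[i - 1][j - 1], "E"),
                    (F[i - 1][j - 1], "F")]
            ps, pstate = max(prev, key=lambda x: x[0])
            for val, st in prev:  # prefer H > E > F on ties
                if val == ps:
                    ps, pstate = val, st
                    break
            H[i][j] = ps + s
            PH[i][j] = pstate
            ea, eb = H[i][j - 1] + GAP_OPEN, E[i][j - 1] + GAP_EXT
            E[i][j], PE[i][j] = (ea, "H") if ea >= eb else (eb, "E")
            fa, fb = H[i - 1][j] + GAP_OPEN, F[i - 1][j] + GAP_EXT
            F[i][j], PF[i][j] = (fa, "H") if fa >= fb else (fb, "F")

    if glocal:
        best, state, end_j = _NEG, "H", 0
        for j in range(m + 1):
            if H[n][j] > best:
                best, state, end_j = H[n][j], "H", j
            if F[n][j] > best:
                best, state, end_j = F[n][j], "F", j
    else:
        end_j = m
        cand = [(H[n][m], "H"), (E[n][m], "E"), (F[n][m], "F")]
        best, state = max(cand, key=lambda x: x[0])
        for val, st in cand:
            if val == best:
                best, state = val, st
                break

    # traceback
    i, j = n, end_j
    matches = columns = 0
    while True:
        if state == "H":
            ptr = PH[i][j]
            if ptr == "o":
                break
            columns += 1
            if q[i - 1] == t[j - 1]:
                matches += 1
            i, j, state = i - 1, j - 1, ptr
        elif state == "E":
            columns += 1
            state = PE[i][j]
            j -= 1
            if i == 0 and j == 0:
                break
        else:
            columns += 1
            state = PF[i][j]
            i -= 1
            if i == 0 and state == "H" and not glocal and j == 0:
                break
            if i == 0 and glocal:
                break
    t_start = j
    return AlignmentStats(
        identity=matches / columns if columns else 1.0,
        query_coverage=1.0,
        target_coverage=(end_j - t_start) / m,
        target_interval=(t_start, end_j),
        matches=matches, alignment_columns=columns,
        score=int(best), query_length=n, target_length=m)
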