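"""Independent brute-force oracles used by the test suite.

These re-derive expected results from first principles with different
algorithms than the package: the alignment oracle enumerates every
bounded-error local alignment from every (fragment offset, subject
offset) root recursively (no seeding), and the window oracle rescoring is
a plain double loop.  They are deliberately slow and simple.
"""

from __future__ import annotations

import sys

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _viable_roots(q: str, s: str, max_q0: int, w: int, g: int, e: int) -> np.ndarray:
    """Conservative root prefilter.

    Any acceptable alignment starting at root (q0, s0) consumes at least
    ``w`` query bases with at most ``e`` non-match columns, its diagonal
    drifting by at most ``g``; so among the first ``w`` diagonal steps at
    least ``w - e`` must admit a match within subject shift +-g.  Cells
    past the subject end count as admitting a match (alignments may end
    short of w subject bases when gaps are in the subject).
    """
    if e >= w:
        return np.ones((max_q0 + 1, len(s)), dtype=bool)
    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    sa = np.frombuffer(s.encode(), dtype=np.uint8)
    M = (qa[:, None] == sa[None, :]) & (qa[:, None] != ord("N"))
    k, L = M.shape
    A = np.zeros((k, L), dtype=bool)
    for shift in range(-g, g + 1):
        if shift >= 0:
            A[:, : L - shift] |= M[:, shift:]
        else:
            A[:, -shift:] |= M[:, :shift]
    pad = np.ones((k, w + g), dtype=bool)
    A = np.concatenate([A, pad], axis=1)
    D = np.zeros((max_q0 + 1, L), dtype=np.int32)
    for t in range(w):
        D += A[t : t + max_q0 + 1, t : t + L]
    return D >= (w - e)


def _enumerate_from_root(q, s, s_len, q0, s0, min_cols, min_id, g_allow, e_budget, found):
    """Recursively enumerate alignments rooted at (q0, s0)."""
    k = len(q)

    def rec(qi, sj, m, x, gq, gs, last_gap):
        if not last_gap and (m + x) > 0:
            cols = m + x + gq + gs
            if cols >= min_cols and 100.0 * m > min_id * cols:
                found.add((s0, sj, cols, m, gq + gs))
        errors = x + gq + gs
        if qi < k and sj < s_len:
            if q[qi] == s[sj] and q[qi] != "N":
                rec(qi + 1, sj + 1, m + 1, x, gq, gs, False)
            elif errors < e_budget:
                rec(qi + 1, sj + 1, m, x + 1, gq, gs, False)
        if (m + x + gq + gs) > 0 and (gq + gs) < g_allow and errors < e_budget:
            if sj < s_len:
                rec(qi, sj + 1, m, x, gq + 1, gs, True)
            if qi < k:
                rec(qi + 1, sj, m, x, gq, gs + 1, True)

    rec(q0, s0, 0, 0, 0, 0, True)


def oracle_collapse(cands):
    """Cluster overlapping subject spans and keep the best candidate of each
    cluster (identity desc, columns desc, leftmost, shortest, fewest gaps)."""
    clusters = []
    for cand in sorted(cands):
        if clusters and cand[0] < clusters[-1]["end"]:
            clusters[-1]["members"].append(cand)
            clusters[-1]["end"] = max(clusters[-1]["end"], cand[1])
        else:
            clusters.append({"members": [cand], "end": cand[1]})
    best = []
    for cl in clusters:
        best.append(
            min(
                cl["members"],
                key=lambda c: (-c[3] / c[2], -c[2], c[0], c[1], c[4]),
            )
        )
    return best


def oracle_scan(fragments, transcriptome, params, prefilter=True):
    """Accepted-hit set by brute force.

    Returns a set of tuples
    (fragment_start, subject_id, strand, subject_start, subject_end,
    aligned_len, matches, gap_count) after per-(fragment, subject, strand)
    collapse, comparable with ``hits_to_tuples`` of the package output.
    """
    min_cols = params.min_match_len + 1
    min_id = params.min_identity_pct
    g_allow = params.max_gaps - 1
    e_budget = int((params.k + g_allow) * (100.0 - min_id) // 100.0)
    w = max(1, min_cols - g_allow)

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10000))
    out = set()
    strands = ("+", "-") if params.both_strands else ("+",)
    try:
        for seq in transcriptome.non_target_entries():
            for strand in strands:
                s = seq.residues if strand == "+" else rc(seq.residues)
                s_len = len(s)
                for frag in fragments:
                    q = frag.kmer
                    max_q0 = len(q) - w
                    if max_q0 < 0:
                        continue
                    found = set()
                    if prefilter:
                        viable = _viable_roots(q, s, max_q0, w, g_allow, e_budget)
                        roots = zip(*np.nonzero(viable))
                    else:
                        roots = (
                            (q0, s0)
                            for q0 in range(max_q0 + 1)
                            for s0 in range(s_len)
                        )
                    for q0, s0 in roots:
                        _enumerate_from_root(
                            q, s, s_len, int(q0), int(s0),
                            min_cols, min_id, g_allow, e_budget, found,
                        )
                    if not found:
                        continue
                    if strand == "-":
                        found = {
                            (s_len - e, s_len - b, cols, m, g)
                            for (b, e, cols, m, g) in found
                        }
                    for b, e, cols, m, g in oracle_collapse(found):
                        out.add(
                            (frag.start, seq.id, strand, b, e, cols, m, g)
                        )
    finally:
        sys.setrecursionlimit(old_limit)
    return out


def hits_to_tuples(hits):
    return {
        (
            h.fragment_start,
            h.subject_id,
            h.strand,
            h.subject_start,
            h.subject_end,
            h.aligned_len,
            h.matches,
            h.gap_count,
        )
        for h in hits
    }


def naive_best_window(flagged, k, L, amp_len, containment="full"):
    """Double-loop rescore of every window; returns (start, count, subjects).

    ``flagged``: mapping fragment start -> set of subject ids (flagged
    fragments only).  Tie-break: fewest distinct subjects, then leftmost.
    """
    best = None
    for w in range(L - amp_len + 1):
        subs = set()
        count = 0
        for s, subjects in flagged.items():
            if containment == "full":
                inside = w <= s and s + k <= w + amp_len
            else:
                inside = s < w + amp_len and s + k > w
            if inside:
                count += 1
                subs |= set(subjects)
        key = (count, len(subs), w)
        if best is None or key < best[0]:
            best = (key, w, count, subs)
    _, w, count, subs = best
    return w, count, subs
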