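"""Fragment tiling and approximate-match off-target screening.

The screen tiles the target cDNA into k-mers (default k=19) and reports,
per fragment, every approximate match against non-target transcripts that
satisfies the acceptance rule: aligned length strictly greater than
``min_match_len`` nucleotides (default 17, i.e. >= 18), identity strictly
above ``min_identity_pct`` (default 90), and fewer than ``max_gaps`` gap
columns (default 3, i.e. <= 2).

Matching is seed-and-extend: exact seed words anchor candidate diagonals,
and each anchor window is searched exhaustively for acceptable local
alignments with a bounded-error branch-and-bound aligner.  With the
automatically derived seed length the search is complete: by pigeonhole,
any alignment within the error budget contains an exact word of at least
the seed length, so every acceptable alignment intersects some anchor
window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence as TSequence

from .seq_io import HomologyHit, Sequence, Transcriptome, revcomp

__all__ = [
    "Fragment",
    "ScanParams",
    "OffTargetHit",
    "tile_target",
    "evaluate_hit",
    "scan_offtargets",
    "filter_candidate_hits",
    "fragment_queries",
]


@dataclass(frozen=True)
class Fragment:
    """One k-mer tile of the target, at 0-based offset ``start``."""

    index: int
    start: int
    kmer: str


@dataclass(frozen=True)
class ScanParams:
    """Thresholds and tiling parameters of the off-target screen.

    The three acceptance bounds are exclusive, mirroring the rule
    "larger than ``min_match_len``, identity above ``min_identity_pct``,
    fewer than ``max_gaps`` gaps".
    """

    k: int = 19
    min_match_len: int = 17
    min_identity_pct: float = 90.0
    max_gaps: int = 3
    stride: int = 1
    both_strands: bool = True
    seed_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 1 <= self.min_match_len <= self.k:
            raise ValueError("require 1 <= min_match_len <= k")
        if not 0.0 <= self.min_identity_pct <= 100.0:
            raise ValueError("min_identity_pct must be in [0, 100]")
        if self.max_gaps < 1:
            raise ValueError("max_gaps must be >= 1 (exclusive bound)")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.seed_len is not None and not (
            1 <= self.seed_len <= self.min_match_len
        ):
            raise ValueError("require 1 <= seed_len <= min_match_len")

    @property
    def min_aligned_len(self) -> int:
        """Smallest accepted alignment column count (exclusive bound + 1)."""
        return self.min_match_len + 1

    @property
    def allowed_gaps(self) -> int:
        """Largest accepted total gap-column count (exclusive bound - 1)."""
        return self.max_gaps - 1

    @property
    def error_budget(self) -> int:
        """Upper bound on mismatch + gap columns in any accepted alignment.

        From identity strictly above the threshold over at most
        ``k + allowed_gaps`` columns.
        """
        return int(
            (self.k + self.allowed_gaps) * (100.0 - self.min_identity_pct) // 100.0
        )

    @property
    def min_query_span(self) -> int:
        """Fewest target bases any accepted alignment can consume."""
        return max(1, self.min_aligned_len - self.allowed_gaps)

    @property
    def effective_seed_len(self) -> int:
        """Seed word length guaranteeing completeness by pigeonhole.

        Any accepted alignment has at least
        ``floor(min_identity_pct * min_aligned_len / 100) + 1`` match
        columns, split by at most ``error_budget`` non-match columns into
        at most ``error_budget + 1`` exact runs; the longest run is at
        least their ratio, rounded up.
        """
        if self.seed_len is not None:
            return self.seed_len
        e = self.error_budget
        m_min = int(self.min_identity_pct * self.min_aligned_len // 100) + 1
        m_min = min(m_min, self.min_aligned_len)
        seed = -(-m_min // (e + 1))  # ceil
        return max(1, min(seed, self.min_match_len))


@dataclass(frozen=True)
class OffTargetHit:
    """An accepted approximate match of one fragment to a non-target transcript.

    ``subject_start``/``subject_end`` are 0-based half-open on the forward
    strand of the subject regardless of ``strand``.
    """

    fragment_start: int
    subject_id: str
    subject_start: int
    subject_end: int
    aligned_len: int
    identity_pct: float
    gap_count: int
    strand: str
    matches: int

    def sort_key(self):
        return (
            self.fragment_start,
            self.subject_id,
            self.strand,
            self.subject_start,
            self.subject_end,
        )


def tile_target(target: Sequence, params: ScanParams) -> list[Fragment]:
    """Tile the target into k-mers at the configured stride.

    Stride 1 yields all ``L - k + 1`` fragments.  With a larger stride a
    final fragment ending at the target's end is appended when the regular
    grid does not already reach it.
    """
    L = len(target)
    k = params.k
    if L < k:
        raise ValueError(
            f"target {target.id!r} is shorter ({L} nt) than fragment size k={k}"
        )
    starts = list(range(0, L - k + 1, params.stride))
    if starts[-1] != L - k:
        starts.append(L - k)
    return [
        Fragment(index=i, start=s, kmer=target.residues[s : s + k])
        for i, s in enumerate(starts)
    ]


def evaluate_hit(hit, params: ScanParams, target_ids: Iterable[str]):
    """Apply the acceptance rule to one hit.

    Returns ``(True, None)`` on acceptance or ``(False, reason)`` where
    reason is the first failed criterion among ``self``, ``length``,
    ``identity``, ``gaps``.
    """
    if hit.subject_id in set(target_ids):
        return False, "self"
    if hit.aligned_len <= params.min_match_len:
        return False, "length"
    if hit.identity_pct <= params.min_identity_pct:
        return False, "identity"
    if hit.gap_count >= params.max_gaps:
        return False, "gaps"
    return True, None


def fragment_queries(target_id: str, fragments: TSequence[Fragment]) -> list[Sequence]:
    """Fragments as named query sequences (``<target_id>_<start>``) for
    export to an external search tool."""
    return [Sequence(f"{target_id}_{f.start}", f.kmer) for f in fragments]


# ---------------------------------------------------------------------------
# built-in matcher


def _window_alignments(q, s, ws, we, params):
    """All acceptable local alignments of fragment ``q`` against ``s[ws:we)``.

    Returns a set of (s_start, s_end, cols, matches, gaps) tuples with
    subject coordinates on ``s``.  Alignments begin and end on a
    match/mismatch column (terminal gaps never help acceptance and only
    inflate the span).  Exhaustive within the window via iterative
    depth-first search bounded by the error budget; cheap because accepted
    alignments tolerate very few non-match columns.
    """
    out = set()
    k = len(q)
    g_allow = params.allowed_gaps
    e_budget = params.error_budget
    min_cols = params.min_aligned_len
    min_id = params.min_identity_pct
    max_q0 = k - params.min_query_span
    for q0 in range(0, max_q0 + 1):
        for s0 in range(ws, we):
            # stack holds (qi, sj, matches, mismatches, gq, gs, last_col_mx)
            stack = [(q0, s0, 0, 0, 0, 0, False)]
            while stack:
                qi, sj, m, x, gq, gs, last_mx = stack.pop()
                if last_mx:
                    cols = m + x + gq + gs
                    if cols >= min_cols and m * 100.0 > min_id * cols:
                        out.add((s0, sj, cols, m, gq + gs))
                errors = x + gq + gs
                # match / mismatch column
                if qi < k and sj < we:
                    a, b = q[qi], s[sj]
                    if a == b and a != "N":
                        stack.append((qi + 1, sj + 1, m + 1, x, gq, gs, True))
                    elif errors + 1 <= e_budget:
                        stack.append((qi + 1, sj + 1, m, x + 1, gq, gs, True))
                # interior gap columns
                if m + x + gq + gs > 0 and gq + gs < g_allow and errors + 1 <= e_budget:
                    if sj < we:
                        stack.append((qi, sj + 1, m, x, gq + 1, gs, False))
                    if qi < k:
                        stack.append((qi + 1, sj, m, x, gq, gs + 1, False))
    return out


def _collapse(cands):
    """Collapse overlapping candidate alignments for one
    (fragment, subject, strand) group.

    ``cands``: iterable of (s_start, s_end, cols, matches, gaps).  Spans
    sharing at least one subject position form clusters (transitively);
    each cluster keeps its best candidate by identity, then aligned
    length, then leftmost, shortest, fewest gaps.
    """

    def best_key(c):
        s_start, s_end, cols, matches, gaps = c
        return (-matches / cols, -cols, s_start, s_end, gaps)

    ordered = sorted(cands)
    kept = []
    cluster: list = []
    cluster_end = -1
    for cand in ordered:
        if cluster and cand[0] < cluster_end:
            cluster.append(cand)
            cluster_end = max(cluster_end, cand[1])
        else:
            if cluster:
                kept.append(min(cluster, key=best_key))
            cluster = [cand]
            cluster_end = cand[1]
    if cluster:
        kept.append(min(cluster, key=best_key))
    return kept


def scan_offtargets(
    fragments: TSequence[Fragment],
    transcriptome: Transcriptome,
    params: ScanParams,
) -> list[OffTargetHit]:
    """Find all accepted off-target matches of the fragments in the
    transcriptome's non-target entries.

    Both strands are searched unless disabled.  Overlapping alignments for
    the same (fragment, subject, strand) collapse to a single canonical
    hit; results are sorted by fragment start, subject, strand, span.
    """
    if not fragments:
        return []
    sl = params.effective_seed_len
    k = params.k
    g = params.allowed_gaps

    strands = ("+", "-") if params.both_strands else ("+",)
    oriented: dict[tuple[str, str], str] = {}
    index: dict[str, list[tuple[str, str, int]]] = {}
    for seq in transcriptome.non_target_entries():
        for strand in strands:
            s = seq.residues if strand == "+" else revcomp(seq.residues)
            oriented[(seq.id, strand)] = s
            for pos in range(len(s) - sl + 1):
                word = s[pos : pos + sl]
                if "N" in word:
                    continue
                index.setdefault(word, []).append((seq.id, strand, pos))

    grouped: dict[tuple[int, str, str], set] = {}
    for frag in fragments:
        anchors: set[tuple[str, str, int]] = set()
        kmer = frag.kmer
        for qp in range(k - sl + 1):
            for sid, strand, pos in index.get(kmer[qp : qp + sl], ()):
                anchors.add((sid, strand, pos - qp))
        windows: dict[tuple[str, str], set[tuple[int, int]]] = {}
        for sid, strand, diag in anchors:
            s = oriented[(sid, strand)]
            ws = max(0, diag - g)
            we = min(len(s), diag + k + g)
            if we - ws >= params.min_query_span:
                windows.setdefault((sid, strand), set()).add((ws, we))
        for (sid, strand), spans in windows.items():
            s = oriented[(sid, strand)]
            found = grouped.setdefault((frag.start, sid, strand), set())
            for ws, we in _merge_windows(spans):
                found.update(_window_alignments(kmer, s, ws, we, params))

    hits: list[OffTargetHit] = []
    target_ids = set(transcriptome.target_ids)
    for (fstart, sid, strand), cands in grouped.items():
        if not cands:
            continue
        n = len(oriented[(sid, strand)])
        # report spans on the forward strand of the subject
        if strand == "-":
            cands = {
                (n - s_end, n - s_start, cols, m, gaps)
                for (s_start, s_end, cols, m, gaps) in cands
            }
        for s_start, s_end, cols, m, gaps in _collapse(cands):
            hit = OffTargetHit(
                fragment_start=fstart,
                subject_id=sid,
                subject_start=s_start,
                subject_end=s_end,
                aligned_len=cols,
                identity_pct=m * 100.0 / cols,
                gap_count=gaps,
                strand=strand,
                matches=m,
            )
            ok, _ = evaluate_hit(hit, params, target_ids)
            if ok:
                hits.append(hit)
    hits.sort(key=OffTargetHit.sort_key)
    return hits


def _merge_windows(spans):
    """Merge overlapping/adjacent (start, end) windows to avoid re-searching."""
    merged = []
    for ws, we in sorted(spans):
        if merged and ws <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], we))
        else:
            merged.append((ws, we))
    return merged


def filter_candidate_hits(hits: Iterable[HomologyHit], query_len: int) -> list[HomologyHit]:
    """Keep homology-search hits passing the candidate thresholds: e-value
    below 1e-5, identity above 20%, and query coverage above 50% (all
    strict).

    Coverage is the aligned query span as a percentage of ``query_len``.
    A hit without an e-value is an error.
    """
    if query_len <= 0:
        raise ValueError("query_len must be positive")
    kept = []
    for hit in hits:
        if hit.e_value is None:
            raise ValueError(
                f"hit {hit.query_id!r} vs {hit.subject_id!r} has no e-value"
            )
        coverage = (hit.query_end - hit.query_start) * 100.0 / query_len
        if hit.e_value < 1e-5 and hit.identity_pct > 20.0 and coverage > 50.0:
            kept.append(hit)
    return kept
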