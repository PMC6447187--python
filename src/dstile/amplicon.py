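"""Risk-profile construction, amplicon window selection, and T7 templates.

Accepted off-target hits are mapped back onto the target as per-fragment
counts; every candidate window of the requested amplicon length is scored
by the number of flagged fragments it fully contains, and the window with
the least off-target load is selected (ties: fewest distinct subjects,
then leftmost).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence as TSequence

from .seq_io import Sequence
from .offtarget import Fragment, OffTargetHit

__all__ = [
    "RiskProfile",
    "AmpliconWindow",
    "T7Template",
    "DesignResult",
    "T7_PROMOTER",
    "build_risk_profile",
    "select_window",
    "make_t7_templates",
    "extract_amplicon",
]

#: Canonical T7 RNA polymerase binding site, with the GGG transcription
#: start commonly appended for efficient in vitro transcription.
T7_PROMOTER = "TAATACGACTCACTATAGGG"

_PRIMER_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class RiskProfile:
    """Per-fragment off-target load along the target."""

    target_id: str
    k: int
    target_len: int
    fragment_starts: tuple[int, ...]
    counts: tuple[int, ...]
    subjects: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if not (
            len(self.fragment_starts) == len(self.counts) == len(self.subjects)
        ):
            raise ValueError("profile arrays must have equal length")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be >= 0")

    @property
    def flagged(self) -> tuple[bool, ...]:
        return tuple(c > 0 for c in self.counts)

    @property
    def total_flagged(self) -> int:
        return sum(1 for c in self.counts if c > 0)


@dataclass(frozen=True)
class AmpliconWindow:
    """The selected design region, 0-based half-open on the target."""

    start: int
    end: int
    offtarget_fragment_count: int
    distinct_subjects: frozenset
    rank_context: tuple[int, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class T7Template:
    """Primer pair tagged with a 5' T7 polymerase binding site."""

    promoter: str
    forward_primer: str
    reverse_primer: str

    def __post_init__(self) -> None:
        for name, primer in (
            ("forward", self.forward_primer),
            ("reverse", self.reverse_primer),
        ):
            if not primer:
                raise ValueError(f"{name} primer must be non-empty")
            bad = set(primer.upper()) - _PRIMER_ALPHABET
            if bad:
                raise ValueError(
                    f"{name} primer contains non-nucleotide characters: "
                    f"{sorted(bad)}"
                )
        bad = set(self.promoter.upper()) - _PRIMER_ALPHABET
        if bad:
            raise ValueError(f"promoter contains non-nucleotide characters: {sorted(bad)}")

    @property
    def tagged_forward(self) -> str:
        return self.promoter + self.forward_primer

    @property
    def tagged_reverse(self) -> str:
        return self.promoter + self.reverse_primer


def build_risk_profile(
    fragments: TSequence[Fragment],
    hits: Iterable[OffTargetHit],
    target_id: str = "",
    target_len: Optional[int] = None,
) -> RiskProfile:
    """Tally accepted hits per fragment start.

    A hit whose ``fragment_start`` does not correspond to any fragment is
    an error.
    """
    if not fragments:
        raise ValueError("no fragments")
    k = len(fragments[0].kmer)
    starts = tuple(f.start for f in fragments)
    pos = {s: i for i, s in enumerate(starts)}
    counts = [0] * len(starts)
    subjects: list[set] = [set() for _ in starts]
    for hit in hits:
        i = pos.get(hit.fragment_start)
        if i is None:
            raise ValueError(
                f"hit references unknown fragment start {hit.fragment_start}"
            )
        counts[i] += 1
        subjects[i].add(hit.subject_id)
    if target_len is None:
        target_len = starts[-1] + k
    return RiskProfile(
        target_id=target_id,
        k=k,
        target_len=target_len,
        fragment_starts=starts,
        counts=tuple(counts),
        subjects=tuple(frozenset(s) for s in subjects),
    )


def select_window(
    profile: RiskProfile,
    amplicon_len: int,
    containment: str = "full",
) -> AmpliconWindow:
    """Exhaustively score every candidate window and return the one with
    the fewest flagged fragments.

    A fragment counts toward a window when it is fully contained
    (``containment="full"``, the default, matching the fact that a dsRNA
    amplicon only yields siRNAs wholly within itself) or when it merely
    overlaps (``containment="partial"``).  Ties break by fewest distinct
    contributing subjects, then leftmost start.
    """
    L = profile.target_len
    k = profile.k
    if amplicon_len < k:
        raise ValueError(f"amplicon_len {amplicon_len} is smaller than k={k}")
    if amplicon_len > L:
        raise ValueError(
            f"amplicon_len {amplicon_len} exceeds target length {L}"
        )
    if containment not in ("full", "partial"):
        raise ValueError("containment must be 'full' or 'partial'")

    flagged = [
        (s, subj)
        for s, c, subj in zip(profile.fragment_starts, profile.counts, profile.subjects)
        if c > 0
    ]
    n_windows = L - amplicon_len + 1
    counts = []
    members: list[list[int]] = []
    for w in range(n_windows):
        if containment == "full":
            inside = [
                i
                for i, (s, _) in enumerate(flagged)
                if w <= s and s + k <= w + amplicon_len
            ]
        else:
            inside = [
                i
                for i, (s, _) in enumerate(flagged)
                if s < w + amplicon_len and s + k > w
            ]
        counts.append(len(inside))
        members.append(inside)

    best = min(counts)
    best_w = None
    best_subjects: frozenset = frozenset()
    best_nsubj = None
    for w in range(n_windows):
        if counts[w] != best:
            continue
        subj = frozenset().union(*(flagged[i][1] for i in members[w])) if members[w] else frozenset()
        if best_nsubj is None or len(subj) < best_nsubj:
            best_w, best_subjects, best_nsubj = w, subj, len(subj)
    return AmpliconWindow(
        start=best_w,
        end=best_w + amplicon_len,
        offtarget_fragment_count=best,
        distinct_subjects=best_subjects,
        rank_context=tuple(counts),
    )


def extract_amplicon(target: Sequence, window: AmpliconWindow) -> str:
    """Target residues covered by the window (0-based half-open)."""
    if window.start < 0 or window.end > len(target):
        raise ValueError("window exceeds target bounds")
    return target.residues[window.start : window.end]


def make_t7_templates(
    forward_primer: str,
    reverse_primer: str,
    promoter: str = T7_PROMOTER,
) -> T7Template:
    """Prepend the T7 promoter to both primers of the amplicon PCR."""
    return T7Template(
        promoter=promoter.upper(),
        forward_primer=forward_primer.upper(),
        reverse_primer=reverse_primer.upper(),
    )


@dataclass(frozen=True)
class DesignResult:
    """Complete outcome of one design run, serializable to JSON."""

    target_id: str
    params: dict
    window: AmpliconWindow
    risk_profile: RiskProfile
    amplicon_seq: str
    promoter: str = T7_PROMOTER
    template: Optional[T7Template] = None

    def to_dict(self) -> dict:
        d = {
            "coordinate_convention": "0-based half-open",
            "target_id": self.target_id,
            "params": dict(self.params),
            "window": {
                "start": self.window.start,
                "end": self.window.end,
                "length": self.window.length,
                "offtarget_fragment_count": self.window.offtarget_fragment_count,
                "distinct_subjects": sorted(self.window.distinct_subjects),
            },
            "amplicon_seq": self.amplicon_seq,
            "promoter": self.promoter,
            "n_fragments": len(self.risk_profile.fragment_starts),
            "n_flagged_fragments": self.risk_profile.total_flagged,
            "risk": {
                "k": self.risk_profile.k,
                "target_len": self.risk_profile.target_len,
                "fragment_starts": list(self.risk_profile.fragment_starts),
                "counts": list(self.risk_profile.counts),
                "subjects": [sorted(s) for s in self.risk_profile.subjects],
            },
        }
        if self.template is not None:
            d["template"] = {
                "promoter": self.template.promoter,
                "forward_primer": self.template.forward_primer,
                "reverse_primer": self.template.reverse_primer,
                "tagged_forward": self.template.tagged_forward,
                "tagged_reverse": self.template.tagged_reverse,
            }
        return d
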