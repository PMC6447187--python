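import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dstile import (
    HomologyHit,
    ScanParams,
    Sequence,
    Transcriptome,
    filter_candidate_hits,
    evaluate_hit,
    scan_offtargets,
    tile_target,
)
from dstile.offtarget import fragment_queries
from dstile.seq_io import revcomp

from oracle import hits_to_tuples, oracle_scan


def make_tx(seqs, target_ids=()):
    tx = Transcriptome(target_ids=set(target_ids))
    for sid, res in seqs.items():
        tx.add(Sequence(sid, res))
    return tx


class TestTiling:
    @pytest.mark.parametrize("L,expected", [(19, 1), (25, 7), (564, 546)])
    def test_stride_one_count(self, L, expected, random_target):
        frags = tile_target(random_target(L), ScanParams())
        assert len(frags) == expected
        # independent: enumerate starts directly
        assert [f.start for f in frags] == list(range(L - 19 + 1))
        assert all(len(f.kmer) == 19 for f in frags)

    def test_single_tile(self, random_target):
        t = random_target(19)
        (frag,) = tile_target(t, ScanParams())
        assert frag.start == 0 and frag.kmer == t.residues

    def test_target_shorter_than_k_errors(self, random_target):
        with pytest.raises(ValueError, match="shorter"):
            tile_target(random_target(18), ScanParams())

    def test_stride_appends_final_fragment(self, random_target):
        t = random_target(50)
        frags = tile_target(t, ScanParams(stride=10))
        starts = [f.start for f in frags]
        assert starts == [0, 10, 20, 30, 31]
        assert starts[-1] + 19 == 50

    @settings(max_examples=50, deadline=None)
    @given(L=st.integers(19, 400), stride=st.integers(1, 40))
    def test_tiling_covers_target(self, L, stride):
        rng = np.random.default_rng(L * 1000 + stride)
        t = Sequence("t", "".join(rng.choice(list("ACGT"), size=L)))
        frags = tile_target(t, ScanParams(stride=stride))
        starts = [f.start for f in frags]
        assert starts == sorted(set(starts))
        assert starts[0] == 0 and starts[-1] == L - 19
        if stride == 1:
            assert len(frags) == L - 19 + 1


def hit(**kw):
    base = dict(
        query_id="q",
        subject_id="tx7",
        identity_pct=100.0,
        aligned_len=19,
        gap_count=0,
        query_start=0,
        query_end=19,
        subject_start=100,
        subject_end=119,
        e_value=1e-6,
    )
    base.update(kw)
    return HomologyHit(**base)


class TestEvaluateHit:
    def test_accept(self, default_params):
        assert evaluate_hit(hit(), default_params, {"rel"}) == (True, None)

    def test_length_strictly_larger_than_17(self, default_params):
        ok, reason = evaluate_hit(hit(aligned_len=17), default_params, set())
        assert (ok, reason) == (False, "length")
        ok, _ = evaluate_hit(hit(aligned_len=18, query_end=18), default_params, set())
        assert ok

    def test_identity_exactly_90_rejected(self, default_params):
        ok, reason = evaluate_hit(hit(identity_pct=90.0), default_params, set())
        assert (ok, reason) == (False, "identity")

    def test_three_gaps_rejected_two_accepted(self, default_params):
        ok, reason = evaluate_hit(hit(gap_count=3), default_params, set())
        assert (ok, reason) == (False, "gaps")
        ok, _ = evaluate_hit(hit(gap_count=2), default_params, set())
        assert ok

    def test_self_hit_rejected(self, default_params):
        ok, reason = evaluate_hit(hit(subject_id="rel"), default_params, {"rel"})
        assert (ok, reason) == (False, "self")


class TestScanPlanted:
    def test_exact_19mer_copy_flags_exactly_overlapping_fragments(self, random_target):
        target = random_target(80, seed=5)
        # copy fragment at start 30 into an unrelated transcript
        rng = np.random.default_rng(99)
        host = "".join(rng.choice(list("ACGT"), size=200))
        kmer = target.residues[30:49]
        planted = host[:90] + kmer + host[109:]
        tx = make_tx({"tx1": planted})
        params = ScanParams()
        hits = scan_offtargets(tile_target(target, params), tx, params)
        got = {(h.fragment_start, h.strand) for h in hits if h.identity_pct == 100.0 and h.aligned_len == 19}
        assert (30, "+") in got
        # brute force agrees on the full accepted set
        assert hits_to_tuples(hits) == oracle_scan(tile_target(target, params), tx, params)

    def test_planted_block_one_substitution_identities(self, random_target):
        # 30-nt block with one substitution near the middle: every 19-mer
        # window overlapping the changed column still has 18/19 matches.
        target = random_target(90, seed=11)
        block = target.residues[20:50]
        mid = 15
        sub = {"A": "C", "C": "G", "G": "T", "T": "A"}[block[mid]]
        mutated = block[:mid] + sub + block[mid + 1 :]
        rng = np.random.default_rng(7)
        host = "".join(rng.choice(list("ACGT"), size=160))
        tx = make_tx({"tx1": host[:60] + mutated + host[90:]})
        params = ScanParams()
        frags = tile_target(target, params)
        hits = scan_offtargets(frags, tx, params)
        by_frag = {}
        for h in hits:
            by_frag.setdefault(h.fragment_start, []).append(h)
        # fragments whose 19-mers lie fully inside the block: starts 20..31
        for start in range(20, 32):
            assert start in by_frag, f"fragment {start} not flagged"
            best = max(h.identity_pct for h in by_frag[start])
            assert best * 19 >= 18 * 100 - 1e-6  # at least 18/19
        assert hits_to_tuples(hits) == oracle_scan(frags, tx, params)

    def test_random_unrelated_transcriptome_no_hits(self, random_target):
        target = random_target(120, seed=3)
        from dstile import make_transcriptome

        tx = make_transcriptome(6, (300, 500), seed=42)
        params = ScanParams()
        frags = tile_target(target, params)
        hits = scan_offtargets(frags, tx, params)
        assert hits == []
        assert oracle_scan(frags, tx, params) == set()

    def test_empty_fragment_list(self):
        tx = make_tx({"tx1": "ACGT" * 30})
        assert scan_offtargets([], tx, ScanParams()) == []

    def test_transcriptome_of_only_target_entries_empty(self, random_target):
        target = random_target(60, seed=8)
        tx = make_tx({"target": target.residues}, target_ids={"target"})
        params = ScanParams()
        hits = scan_offtargets(tile_target(target, params), tx, params)
        assert hits == []


class TestScanProperties:
    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_planted(self, seed, planted_instance, default_params):
        target, tx, _ = planted_instance(
            seed=seed,
            sub_rate=[0.0, 0.03, 0.08][seed % 3],
            indel_rate=[0.0, 0.02][seed % 2],
        )
        frags = tile_target(target, default_params)
        assert hits_to_tuples(
            scan_offtargets(frags, tx, default_params)
        ) == oracle_scan(frags, tx, default_params)

    def test_oracle_prefilter_consistency(self, planted_instance, default_params):
        # the vectorized root prefilter must not change the oracle's answer
        target, tx, _ = planted_instance(
            seed=123, target_len=60, n_tx=1, tx_len=(120, 160), block_len=25,
            source_start=10, sub_rate=0.05,
        )
        frags = tile_target(target, default_params)
        assert oracle_scan(frags, tx, default_params, prefilter=True) == oracle_scan(
            frags, tx, default_params, prefilter=False
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_monotonicity_relaxing_thresholds(self, seed, planted_instance):
        target, tx, _ = planted_instance(
            seed=seed, target_len=70, n_tx=2, tx_len=(180, 240),
            block_len=30, source_start=20, sub_rate=0.05, indel_rate=0.02,
        )
        strict = ScanParams()
        frags = tile_target(target, strict)
        base = {
            (h.fragment_start, h.subject_id, h.strand)
            for h in scan_offtargets(frags, tx, strict)
        }
        # seed_len=5 keeps each relaxed scan complete for every hit accepted
        # at the default thresholds (<= 2 errors leave an exact run >= 6).
        for relaxed in (
            ScanParams(min_match_len=15, seed_len=5),
            ScanParams(min_identity_pct=85.0, seed_len=5),
            ScanParams(max_gaps=4, seed_len=5),
        ):
            got = {
                (h.fragment_start, h.subject_id, h.strand)
                for h in scan_offtargets(frags, tx, relaxed)
            }
            assert base <= got, f"relaxation {relaxed} lost hits"

    @pytest.mark.parametrize("seed", range(4))
    def test_strand_symmetry(self, seed, planted_instance, default_params):
        target, tx, _ = planted_instance(seed=seed, sub_rate=0.03)
        frags = tile_target(target, default_params)
        fwd = scan_offtargets(frags, tx, default_params)
        flipped = Transcriptome(
            entries={
                sid: s.reverse_complement() for sid, s in tx.entries.items()
            },
            target_ids=set(tx.target_ids),
        )
        rev = scan_offtargets(frags, flipped, default_params)
        flip = {"+": "-", "-": "+"}
        assert {
            (h.fragment_start, h.subject_id, h.strand) for h in fwd
        } == {
            (h.fragment_start, h.subject_id, flip[h.strand]) for h in rev
        }

    def test_self_exclusion(self, random_target, default_params):
        target = random_target(100, seed=77)
        tx = make_tx({target.id: target.residues}, target_ids={target.id})
        assert scan_offtargets(tile_target(target, default_params), tx, default_params) == []

    def test_dedup_no_duplicate_keys(self, planted_instance, default_params):
        target, tx, _ = planted_instance(seed=2)
        hits = scan_offtargets(tile_target(target, default_params), tx, default_params)
        keys = [
            (h.fragment_start, h.subject_id, h.subject_start, h.subject_end, h.strand)
            for h in hits
        ]
        assert len(keys) == len(set(keys))

    def test_n_never_matches(self, default_params):
        target = Sequence("t", "ACGTA" * 4)  # 20 nt
        # subject equals the first 19-mer but with an N: 18/19 matches
        frags = tile_target(target, default_params)
        subj = "N" + target.residues[1:19]
        tx = make_tx({"tx1": "TTTTT" + subj + "TTTTT"})
        hits = scan_offtargets(frags, tx, default_params)
        hit0 = [h for h in hits if h.fragment_start == 0]
        # the N column never counts as a match: no alignment reaches 19
        # matches (the canonical hit is the 18-mer skipping the N entirely)
        assert hit0 and all(h.matches <= 18 for h in hit0)


class TestFilterCandidateHits:
    def test_kept(self):
        h = hit(e_value=1e-6, identity_pct=25.0, query_end=12, aligned_len=12, query_start=0)
        assert filter_candidate_hits([h], query_len=20) == [h]

    def test_evalue_strict(self):
        h = hit(e_value=1e-4, identity_pct=80.0, query_end=18)
        assert filter_candidate_hits([h], query_len=20) == []

    def test_identity_exactly_20_dropped(self):
        h = hit(e_value=1e-6, identity_pct=20.0, query_end=18)
        assert filter_candidate_hits([h], query_len=20) == []

    def test_coverage_exactly_50_dropped(self):
        h = hit(e_value=1e-6, identity_pct=25.0, query_end=10, aligned_len=10)
        assert filter_candidate_hits([h], query_len=20) == []

    def test_missing_evalue_errors(self):
        with pytest.raises(ValueError, match="e-value"):
            filter_candidate_hits([hit(e_value=None)], query_len=20)


class TestFragmentQueries:
    def test_ids_encode_start(self, random_target):
        frags = tile_target(random_target(25), ScanParams())
        queries = fragment_queries("tgt", frags)
        assert [q.id for q in queries] == [f"tgt_{i}" for i in range(7)]
        assert all(len(q) == 19 for q in queries)
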