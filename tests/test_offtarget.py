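import numpy as np
import pytest

from amirkit import (
    NucSeq,
    Plant,
    ScreenConfig,
    TranscriptomePlan,
    longest_match,
    make_scramble,
    make_transcriptome,
    offtarget_filter,
    revcomp,
)
from amirkit.offtarget import ScreenError
from amirkit.seq import max_homopolymer_run

from conftest import lcs_bruteforce

GUIDE = NucSeq("guide", "TAATGAGCCACACTTGGAGGT", "DNA")


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestLongestMatch:
    def test_verbatim_plant_gives_full_length(self, rng):
        subject = NucSeq("tx", random_seq(rng, 500) + GUIDE.seq + random_seq(rng, 500), "DNA")
        max_len, hits = longest_match(GUIDE, [subject])
        assert max_len == 21
        assert hits[0].orientation == "sense_match"

    def test_planted_18mer_measured_exactly(self):
        plan = TranscriptomePlan(
            seed=4, lengths=(2000,), plants=(Plant(revcomp(GUIDE), 18, 0, 700),)
        )
        records, _ = make_transcriptome(plan)
        max_len, hits = longest_match(GUIDE, records)
        assert max_len == 18
        assert hits[0].orientation == "guide_match"
        assert hits[0].subject_start == 700

    def test_matches_bruteforce_on_random_instances(self, rng):
        cfg_one = ScreenConfig(check_both_orientations=False)
        for _ in range(30):
            q = NucSeq("q", random_seq(rng, 21), "DNA")
            subj = NucSeq("s", random_seq(rng, int(rng.integers(50, 2000))), "DNA")
            got, _ = longest_match(q, [subj], cfg_one)
            assert got == lcs_bruteforce(q.seq, subj.seq)

    def test_both_orientations_is_max_of_each(self, rng):
        for _ in range(10):
            q = NucSeq("q", random_seq(rng, 21), "DNA")
            subj = NucSeq("s", random_seq(rng, 1000), "DNA")
            both, _ = longest_match(q, [subj])
            one = ScreenConfig(check_both_orientations=False)
            sense, _ = longest_match(q, [subj], one)
            guide, _ = longest_match(revcomp(q), [subj], one)
            assert both == max(sense, guide)

    def test_exclusion_semantics(self, rng):
        target_tx = NucSeq("mapt", random_seq(rng, 100) + revcomp(GUIDE).seq + random_seq(rng, 100), "DNA")
        other = NucSeq("other", random_seq(rng, 500), "DNA")
        cfg = ScreenConfig(excluded_subject_ids=frozenset({"mapt"}))
        max_len, hits = longest_match(GUIDE, [target_tx, other], cfg)
        assert max_len < 21
        assert all(h.subject_id == "other" for h in hits)

    def test_all_excluded_is_an_error(self):
        cfg = ScreenConfig(excluded_subject_ids=frozenset({"a"}))
        with pytest.raises(ScreenError, match="nothing to screen"):
            longest_match(GUIDE, [NucSeq("a", "ACGTACGT", "DNA")], cfg)

    def test_short_query_warns(self, rng):
        with pytest.warns(UserWarning, match="21"):
            longest_match(NucSeq("q", "ACGTACGTAC", "DNA"), [NucSeq("s", random_seq(rng, 100), "DNA")])


class TestOfftargetFilter:
    def test_threshold_is_strictly_greater_than(self):
        plants = []
        guides = []
        for i, L in enumerate([15, 16, 17, 18, 19, 20]):
            g = NucSeq(f"g{i}", "".join(np.random.default_rng(100 + i).choice(list("ACGT"), size=21)), "DNA")
            guides.append(g)
            plants.append(Plant(revcomp(g), L, i, 900))
        plan = TranscriptomePlan(seed=6, lengths=(2000,) * 6, plants=tuple(plants))
        records, _ = make_transcriptome(plan)
        results = offtarget_filter(guides, records)
        kept = {g.id: kept for g, ml, _, kept in results}
        lens = {g.id: ml for g, ml, _, kept in results}
        for i, L in enumerate([15, 16, 17, 18, 19, 20]):
            assert lens[f"g{i}"] == L
            assert kept[f"g{i}"] is (L <= 17)

    def test_excluded_target_match_kept(self, rng):
        tx = NucSeq("target", random_seq(rng, 100) + revcomp(GUIDE).seq + random_seq(rng, 100), "DNA")
        cfg = ScreenConfig(excluded_subject_ids=frozenset({"target"}))
        filler = NucSeq("bg", random_seq(rng, 500), "DNA")
        ((_, max_len, _, kept),) = offtarget_filter([GUIDE], [tx, filler], cfg)
        assert kept and max_len <= 17


class TestScramble:
    def _transcriptome(self, rng):
        site = revcomp(GUIDE).seq
        return [NucSeq("tx", random_seq(rng, 2000) + site + random_seq(rng, 2000), "DNA")]

    def test_permutation_and_match_bound(self, rng):
        tx = self._transcriptome(rng)
        scr = make_scramble(GUIDE, tx, seed=42)
        assert sorted(scr.seq) == sorted(GUIDE.seq)
        assert max_homopolymer_run(scr) <= 3
        measured, _ = longest_match(scr, tx)
        assert measured < 15
        # confirm against the independent oracle, both orientations
        assert max(
            lcs_bruteforce(scr.seq, tx[0].seq), lcs_bruteforce(revcomp(scr).seq, tx[0].seq)
        ) == measured

    def test_deterministic_for_fixed_seed(self, rng):
        tx = self._transcriptome(rng)
        assert make_scramble(GUIDE, tx, seed=7).seq == make_scramble(GUIDE, tx, seed=7).seq

    def test_exhaustion_reports_best_attempt(self, rng):
        tx = self._transcriptome(rng)
        cfg = ScreenConfig(scr_max_match=2)  # unattainable for a 21-mer
        with pytest.raises(RuntimeError, match="best attempt"):
            make_scramble(GUIDE, tx, cfg, seed=0, max_attempts=5)
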