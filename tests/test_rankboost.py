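"""Feature counting, empirical-quantile scores, and the boosting loop."""
from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import OracleCandidate, algo1_oracle
from neopept.binding import EpitopeCall
from neopept.errors import ConfigurationError
from neopept.rankboost import (
    Candidate,
    BoostWeights,
    IARFeatures,
    boost_ranks,
    compute_features,
    feature_scores,
    initial_order,
)


def call(peptide="AAAAAAAAA", allele="HLA-A*02:01", mut_rank=2.0,
         wt_rank=None, iar_id="i"):
    return EpitopeCall(iar_id, peptide, allele, mut_rank,
                       wt_peptide="W" * len(peptide) if wt_rank is not None else None,
                       wt_rank=wt_rank)


class FakeIAR:
    def __init__(self, tpm=1.0):
        self.tpm = tpm


class TestComputeFeatures:
    def test_direct_counts(self):
        calls = [
            call(mut_rank=0.5, allele="HLA-A*02:01"),
            call(mut_rank=0.9, allele="HLA-A*02:01"),
            call(mut_rank=2.0, allele="HLA-B*07:02"),
            call(mut_rank=3.0, allele="HLA-B*07:02"),
            call(mut_rank=4.0, allele="HLA-C*07:01"),
            call(mut_rank=4.5, allele="HLA-C*07:01"),
        ]
        f = compute_features(FakeIAR(tpm=12.5), calls, "I")
        assert (f.npa, f.nph, f.nmhc, f.tpm) == (6, 2, 3, 12.5)

    def test_nwt_counts_better_than_wildtype(self):
        calls = [call(mut_rank=0.5, wt_rank=30.0), call(mut_rank=3.0, wt_rank=1.0),
                 call(mut_rank=2.0)]
        assert compute_features(FakeIAR(), calls, "I").nwt == 1

    def test_ovlp_nested_ninemer_same_allele(self):
        calls = [
            call(peptide="AAAAAAAAA", allele="HLA-A*02:01"),
            call(peptide="AAAAAAAAAC", allele="HLA-A*02:01"),
            call(peptide="CCCCCCCCC", allele="HLA-A*02:01"),     # not nested
            call(peptide="AAAAAAAAA", allele="HLA-B*07:02"),     # other allele
        ]
        f = compute_features(FakeIAR(), calls, "I")
        # brute force over all (9-mer, 10-mer) pairs
        nines = [c for c in calls if len(c.peptide) == 9]
        tens = [c for c in calls if len(c.peptide) == 10]
        expected = sum(
            1 for a in nines for b in tens
            if a.allele == b.allele and a.peptide in b.peptide
        )
        assert f.ovlp == expected == 1

    def test_ovlp_zero_for_class_ii(self):
        calls = [call(peptide="AAAAAAAAA"), call(peptide="AAAAAAAAAC")]
        assert compute_features(FakeIAR(), calls, "II").ovlp == 0

    def test_count_invariants(self):
        rng = random.Random(1)
        calls = [call(mut_rank=rng.uniform(0, 5),
                      allele=rng.choice(["HLA-A*02:01", "HLA-B*07:02"]),
                      wt_rank=rng.choice([None, rng.uniform(0, 100)]))
                 for _ in range(30)]
        f = compute_features(FakeIAR(), calls, "I")
        assert f.nph <= f.npa and f.nmhc <= f.npa and f.nwt <= f.npa


def cand(iar_id, best_rank, **feats):
    defaults = dict(npa=1, nph=0, nmhc=1, tpm=1.0, nwt=0, ovlp=0)
    defaults.update(feats)
    return Candidate(iar_id=iar_id, features=IARFeatures(**defaults),
                     best_rank=best_rank)


class TestInitialOrder:
    def test_best_percentile_first(self):
        order = initial_order([cand("b", 2.0), cand("c", 4.4), cand("a", 0.3)])
        assert [c.iar_id for c in order] == ["a", "b", "c"]

    def test_tie_broken_by_npa_then_id(self):
        order = initial_order([cand("x", 1.0, npa=2), cand("y", 1.0, npa=5),
                               cand("z", 1.0, npa=2)])
        assert [c.iar_id for c in order] == ["y", "x", "z"]

    def test_single_candidate(self):
        assert [c.iar_id for c in initial_order([cand("solo", 3.0)])] == ["solo"]


class TestFeatureScores:
    def test_quantile_formula(self):
        cands = [cand(f"c{i}", 1.0, nmhc=v) for i, v in enumerate([1, 2, 3])]
        scores = [s["nmhc"] for s in feature_scores(cands)]
        assert scores == [0.0, 0.5, 1.0]

    def test_all_equal_gives_half(self):
        cands = [cand(f"c{i}", 1.0, nmhc=7) for i in range(4)]
        assert all(s["nmhc"] == 0.5 for s in feature_scores(cands))

    def test_single_candidate_scores_zero(self):
        assert feature_scores([cand("solo", 1.0)])[0]["nmhc"] == 0.0

    def test_monotone_transform_invariance(self):
        values = [0.5, 3.0, 12.0, 1.5]
        a = [cand(f"c{i}", 1.0, tpm=v) for i, v in enumerate(values)]
        b = [cand(f"c{i}", 1.0, tpm=v**3) for i, v in enumerate(values)]
        assert [s["tpm"] for s in feature_scores(a)] == [s["tpm"] for s in feature_scores(b)]


class TestBoostWeights:
    def test_defaults(self):
        wi = BoostWeights.mhc_i_defaults()
        assert (wi.w_ovlp, wi.w_nmhc) == (0.68, 0.32)
        wii = BoostWeights.mhc_ii_defaults()
        assert [wii.w_npa, wii.w_nph, wii.w_nmhc, wii.w_tpm, wii.w_nwt] == [0.2] * 5
        assert wii.w_ovlp == 0.0

    def test_sum_above_one_rejected(self):
        with pytest.raises(ConfigurationError):
            BoostWeights(w_ovlp=0.8, w_nmhc=0.4)

    def test_negative_weight_rejected(self):
        with pytest.raises(ConfigurationError):
            BoostWeights(w_npa=-0.1)


def random_candidates(rng, m):
    return [
        cand(f"iar_{i:02d}", round(rng.uniform(0, 5), 3),
             npa=rng.randint(1, 12), nph=rng.randint(0, 4),
             nmhc=rng.randint(1, 6), tpm=round(rng.uniform(0, 200), 2),
             nwt=rng.randint(0, 6), ovlp=rng.randint(0, 8))
        for i in range(m)
    ]


def as_oracle(cands):
    return [OracleCandidate(c.iar_id, c.best_rank, {
        "npa": c.features.npa, "nph": c.features.nph, "nmhc": c.features.nmhc,
        "tpm": c.features.tpm, "nwt": c.features.nwt, "ovlp": c.features.ovlp,
    }) for c in cands]


WEIGHTS_I = {"npa": 0, "nph": 0, "nmhc": 0.32, "tpm": 0, "nwt": 0, "ovlp": 0.68}


class TestBoostRanks:
    def test_zero_weights_preserve_initial_order(self):
        rng = random.Random(2)
        cands = random_candidates(rng, 10)
        ranked = boost_ranks(cands, BoostWeights())
        assert [r.iar_id for r in ranked] == [c.iar_id for c in initial_order(cands)]
        assert all(r.initial_position == r.final_position for r in ranked)

    def test_new_rank_arithmetic(self):
        # old_rank 10 with boost 0.4 must re-sort as 6.0, overtaking rank 7+
        assert 10 * (1 - 0.4) == 6.0  # the rule itself
        cands = [cand(f"c{i:02d}", float(i)) for i in range(1, 11)]
        cands[-1] = cand("c10", 10.0, nmhc=100)  # top quantile on nmhc
        ranked = boost_ranks(cands, BoostWeights(w_nmhc=0.4))
        moved = next(r for r in ranked if r.iar_id == "c10")
        assert moved.initial_position == 10
        assert moved.final_position < 10

    def test_positions_are_permutation(self):
        rng = random.Random(3)
        ranked = boost_ranks(random_candidates(rng, 15), BoostWeights.mhc_i_defaults())
        assert sorted(r.final_position for r in ranked) == list(range(1, 16))
        assert sorted(r.initial_position for r in ranked) == list(range(1, 16))

    def test_boost_bounded(self):
        rng = random.Random(4)
        for weights in (BoostWeights.mhc_i_defaults(), BoostWeights.mhc_ii_defaults()):
            for r in boost_ranks(random_candidates(rng, 12), weights):
                assert 0.0 <= r.boost <= 1.0

    @pytest.mark.parametrize("m", [1, 2, 4, 20])
    def test_matches_literal_pseudocode_simulation(self, m):
        rng = random.Random(100 + m)
        for _ in range(10):
            cands = random_candidates(rng, m)
            ranked = boost_ranks(cands, BoostWeights.mhc_i_defaults())
            got = [r.iar_id for r in sorted(ranked, key=lambda r: r.final_position)]
            assert got == algo1_oracle(as_oracle(cands), WEIGHTS_I)

    @pytest.mark.parametrize("feature", ["nmhc", "ovlp"])
    def test_monotone_in_each_weighted_feature(self, feature):
        rng = random.Random(7)
        for _ in range(25):
            cands = random_candidates(rng, rng.randint(2, 12))
            target = rng.randrange(len(cands))
            before = boost_ranks(cands, BoostWeights.mhc_i_defaults())
            pos_before = next(r.final_position for r in before
                              if r.iar_id == cands[target].iar_id)
            import dataclasses

            bumped = list(cands)
            best = max(getattr(c.features, feature) for c in cands)
            bumped[target] = Candidate(
                iar_id=cands[target].iar_id,
                features=dataclasses.replace(cands[target].features, **{feature: best + 1}),
                best_rank=cands[target].best_rank,
            )
            after = boost_ranks(bumped, BoostWeights.mhc_i_defaults())
            pos_after = next(r.final_position for r in after
                             if r.iar_id == cands[target].iar_id)
            assert pos_after <= pos_before

    @given(st.integers(1, 12), st.integers(0, 5))
    @settings(deadline=None, max_examples=40)
    def test_permutation_validity_property(self, m, seed):
        rng = random.Random(seed)
        ranked = boost_ranks(random_candidates(rng, m), BoostWeights.mhc_ii_defaults())
        assert sorted(r.final_position for r in ranked) == list(range(1, m + 1))
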