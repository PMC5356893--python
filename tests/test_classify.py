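import numpy as np
import pytest

from crgpred.classify import (
    ScorePair,
    TrainingReference,
    predict,
    score_centroid,
    score_distance,
    score_nearest_neighbor,
    score_with,
)
from crgpred.data_model import NONRECURRENT, RECURRENT

REF_2D = TrainingReference(
    ["g1", "g2"],
    recurrent_vectors=[(0.0, 0.0), (2.0, 0.0)],
    nonrecurrent_vectors=[(4.0, 0.0), (6.0, 0.0)],
)


class TestScorers:
    def test_distance_hand_case(self):
        pair = score_distance(REF_2D, (2.0, 0.0))
        assert pair.recurrence_score == pytest.approx(1.0)   # mean(2, 0)
        assert pair.nonrecurrence_score == pytest.approx(3.0)  # mean(2, 4)
        assert pair.predicted == RECURRENT

    def test_distance_raw_sum(self):
        pair = score_distance(REF_2D, (2.0, 0.0), normalization="raw_sum")
        assert (pair.recurrence_score, pair.nonrecurrence_score) == (2.0, 6.0)

    def test_centroid_hand_case(self):
        pair = score_centroid(REF_2D, (2.0, 0.0))
        assert pair.recurrence_score == pytest.approx(1.0)   # centroid (1,0)
        assert pair.nonrecurrence_score == pytest.approx(3.0)  # centroid (5,0)
        assert pair.predicted == RECURRENT

    def test_centroid_zero_at_centroid(self):
        pair = score_centroid(REF_2D, (1.0, 0.0))
        assert pair.recurrence_score == 0.0 and pair.predicted == RECURRENT

    def test_nearest_neighbor_hand_case(self):
        pair = score_nearest_neighbor(REF_2D, (2.0, 0.0))
        assert (pair.recurrence_score, pair.nonrecurrence_score) == (0.0, 2.0)
        assert pair.predicted == RECURRENT

    def test_training_member_has_zero_score(self):
        pair = score_nearest_neighbor(REF_2D, (0.0, 0.0))
        assert pair.recurrence_score == 0.0

    def test_singleton_groups_all_agree(self):
        ref = TrainingReference(["g"], [(1.0,)], [(5.0,)])
        x = (2.0,)
        pairs = [f(ref, x) for f in (score_distance, score_centroid, score_nearest_neighbor)]
        for p in pairs:
            assert p.recurrence_score == pytest.approx(1.0)
            assert p.nonrecurrence_score == pytest.approx(3.0)

    def test_symmetric_singleton_tie_goes_recurrent(self):
        ref = TrainingReference(["g"], [(3.0,)], [(3.0,)])
        for f in (score_distance, score_centroid, score_nearest_neighbor):
            assert f(ref, (0.0,)).predicted == RECURRENT

    def test_scaling_homogeneity(self):
        c = 3.7
        scaled = TrainingReference(
            ["g1", "g2"],
            REF_2D.recurrent_vectors * c,
            REF_2D.nonrecurrent_vectors * c,
        )
        for f in (score_distance, score_centroid, score_nearest_neighbor):
            base = f(REF_2D, (2.0, 0.0))
            big = f(scaled, (2.0 * c, 0.0))
            assert big.recurrence_score == pytest.approx(c * base.recurrence_score)
            assert big.nonrecurrence_score == pytest.approx(c * base.nonrecurrence_score)
            assert big.predicted == base.predicted

    def test_within_group_permutation_invariance(self):
        rng = np.random.default_rng(9)
        rec = rng.normal(size=(5, 3))
        non = rng.normal(size=(6, 3))
        x = rng.normal(size=3)
        ref = TrainingReference(["a", "b", "c"], rec, non)
        shuffled = TrainingReference(
            ["a", "b", "c"], rec[rng.permutation(5)], non[rng.permutation(6)]
        )
        for f in (score_distance, score_centroid, score_nearest_neighbor):
            p1, p2 = f(ref, x), f(shuffled, x)
            assert p1.recurrence_score == pytest.approx(p2.recurrence_score)
            assert p1.nonrecurrence_score == pytest.approx(p2.nonrecurrence_score)

    def test_dimension_mismatch(self):
        for f in (score_distance, score_centroid, score_nearest_neighbor):
            with pytest.raises(ValueError):
                f(REF_2D, (1.0, 2.0, 3.0))


def _naive_scores(rec, non, x, algorithm):
    """Independent double-loop oracle for all three scorers."""
    def dist(u, v):
        return sum((a - b) ** 2 for a, b in zip(u, v)) ** 0.5

    d_rec = [dist(v, x) for v in rec]
    d_non = [dist(v, x) for v in non]
    if algorithm == "distance":
        return sum(d_rec) / len(d_rec), sum(d_non) / len(d_non)
    if algorithm == "centroid":
        c_rec = [sum(col) / len(rec) for col in zip(*rec)]
        c_non = [sum(col) / len(non) for col in zip(*non)]
        return dist(c_rec, x), dist(c_non, x)
    return min(d_rec), min(d_non)


class TestOracleEquivalence:
    @pytest.mark.parametrize("algorithm", ["centroid", "distance", "nearest_neighbor"])
    def test_matches_naive_double_loop(self, algorithm):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            i = rng.integers(1, 6)
            n_r = rng.integers(1, 7)
            n_n = rng.integers(1, 7)
            rec = rng.normal(size=(n_r, i))
            non = rng.normal(size=(n_n, i))
            x = rng.normal(size=i)
            ref = TrainingReference([f"g{k}" for k in range(i)], rec, non)
            pair = score_with(algorithm, ref, x)
            exp_r, exp_n = _naive_scores(rec.tolist(), non.tolist(), x.tolist(), algorithm)
            assert pair.recurrence_score == pytest.approx(exp_r, abs=1e-12)
            assert pair.nonrecurrence_score == pytest.approx(exp_n, abs=1e-12)


class TestPredict:
    def test_base_rule(self):
        assert predict(ScorePair("s", 1.0, 3.0)) == RECURRENT
        assert predict(ScorePair("s", 3.0, 1.0)) == NONRECURRENT

    def test_modifier_endpoints(self):
        for pair in (ScorePair("s", 1.0, 3.0), ScorePair("s", 9.0, 0.5)):
            assert abs(pair.margin) < 10
            assert predict(pair, modifier=10.0) == RECURRENT
            assert predict(pair, modifier=-10.0) == NONRECURRENT

    def test_monotone_in_modifier(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            pair = ScorePair("s", rng.uniform(0, 5), rng.uniform(0, 5))
            labels = [predict(pair, m) for m in np.linspace(-6, 6, 25)]
            flips = [
                (a, b) for a, b in zip(labels, labels[1:])
                if a == RECURRENT and b == NONRECURRENT
            ]
            assert not flips  # raising the modifier never un-calls recurrence

    def test_scores_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            ScorePair("s", -0.1, 1.0)
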