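import math

import numpy as np
import pytest

from topoconsensus import (
    ConsensusConfig,
    GrammarConfig,
    SimConfig,
    TopologyString,
    build_profile,
    decode_consensus,
    score_path,
    validate_topology,
)
from topoconsensus.consensus import TopologyProfile, consensus
from topoconsensus.simulate import simulate_dataset

from _oracles import direct_score

SMALL = GrammarConfig(min_helix_len=3, min_sp_len=2, max_sp_len=6)


def _t(labels, pid="p"):
    return TopologyString(pid, labels)


def _random_profile(rng, L, n_methods):
    counts = np.zeros((L, 4))
    for _ in range(n_methods):
        idx = rng.integers(0, 4, size=L)
        counts[np.arange(L), idx] += 1
    return TopologyProfile(counts / n_methods, n_methods=n_methods)


class TestBuildProfile:
    def test_counting(self):
        preds = [_t("M" * 4)] * 3 + [_t("i" * 4)] * 2
        prof = build_profile(preds)
        assert np.allclose(prof.fractions[0], [0.0, 0.6, 0.4, 0.0])  # S,M,i,o
        assert prof.n_methods == 5

    def test_identical_methods_one_hot(self):
        prof = build_profile([_t("iiMMoo".replace("MM", "M" * 2))] * 5)
        assert np.allclose(prof.fractions.max(axis=1), 1.0)

    def test_errors(self):
        with pytest.raises(ValueError, match="no predictions"):
            build_profile([])
        with pytest.raises(ValueError, match="length"):
            build_profile([_t("i" * 10), _t("i" * 11)])

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        preds = [
            _t("".join(rng.choice(list("SMio"), size=30))) for _ in range(7)
        ]
        prof = build_profile(preds)
        assert np.allclose(prof.fractions.sum(axis=1), 1.0)


class TestScorePath:
    def test_one_hot_zero_pseudocount(self):
        topo = _t("iiooii".replace("oo", "o" * 2))
        prof = build_profile([topo] * 4)
        assert score_path(prof, topo, pseudocount=0.0) == 0.0

    def test_uniform_profile_constant(self):
        L = 12
        prof = TopologyProfile(np.full((L, 4), 0.25), n_methods=4)
        expected = math.log((0.25 + 1e-6) / (1 + 4e-6))
        for labels in ("i" * L, "o" * L, "M" * L):
            assert score_path(prof, _t(labels)) == pytest.approx(expected, abs=1e-12)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(42)
        prof = _random_profile(rng, 25, 5)
        labels = "".join(rng.choice(list("SMio"), size=25))
        assert score_path(prof, _t(labels)) == pytest.approx(
            direct_score(prof.fractions, labels, 1e-6), abs=1e-12
        )

    def test_length_mismatch(self):
        prof = build_profile([_t("i" * 10)])
        with pytest.raises(ValueError, match="length"):
            score_path(prof, _t("i" * 9))


class TestDecode:
    def test_identity_on_unanimous_valid_input(self):
        t = _t("SSSSSS" + "o" * 6 + "M" * 16 + "i" * 4)
        res = consensus([t] * 5)
        assert res.topology.labels == t.labels
        assert np.allclose(res.per_residue_agreement, 1.0)

    def test_majority_side_wins_when_no_helix_possible(self):
        preds = [_t("i" * 20)] * 2 + [_t("o" * 20)]
        res = consensus(preds)
        assert res.topology.labels == "i" * 20

    def test_reported_score_equals_score_path(self):
        rng = np.random.default_rng(3)
        prof = _random_profile(rng, 40, 5)
        res = decode_consensus(prof, ConsensusConfig(grammar=SMALL))
        assert res.log_geometric_mean_score == score_path(prof, res.topology)

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(5)
        prof = _random_profile(rng, 60, 5)
        cfg = ConsensusConfig(grammar=SMALL)
        a = decode_consensus(prof, cfg)
        b = decode_consensus(prof, cfg)
        assert a.topology.labels == b.topology.labels
        assert a.log_geometric_mean_score == b.log_geometric_mean_score

    def test_tie_break_prefers_inside_loop(self):
        # A fully uniform profile scores every grammar-valid string equally;
        # the documented tie-break (i < o < helix chains < SP chain, fewer
        # segments) must pick the all-inside path.
        prof = TopologyProfile(np.full((20, 4), 0.25), n_methods=4)
        res = decode_consensus(prof)
        assert res.topology.labels == "i" * 20

    def test_output_always_grammar_valid(self):
        rng = np.random.default_rng(9)
        cfg = ConsensusConfig(grammar=SMALL)
        for _ in range(25):
            prof = _random_profile(rng, int(rng.integers(5, 50)), 5)
            res = decode_consensus(prof, cfg)
            assert validate_topology(res.topology, SMALL).valid

    def test_smoothing_insensitive_without_zeros(self):
        rng = np.random.default_rng(17)
        raw = rng.random((30, 4)) + 0.3
        frac = raw / raw.sum(axis=1, keepdims=True)
        prof = TopologyProfile(frac, n_methods=5)
        a = decode_consensus(prof, ConsensusConfig(grammar=SMALL, pseudocount=1e-6))
        b = decode_consensus(prof, ConsensusConfig(grammar=SMALL, pseudocount=0.0))
        assert a.topology.labels == b.topology.labels

    def test_globular_paths_can_be_disallowed(self):
        prof = TopologyProfile(np.full((30, 4), 0.25), n_methods=4)
        g = GrammarConfig(min_helix_len=3, allow_globular_paths=False)
        res = decode_consensus(prof, ConsensusConfig(grammar=g))
        assert "M" in res.topology.labels or "S" in res.topology.labels
        assert validate_topology(res.topology, g).valid

    def test_no_valid_path_raises(self):
        prof = TopologyProfile(np.full((2, 4), 0.25), n_methods=4)
        g = GrammarConfig(allow_globular_paths=False)  # needs >= 5 residues of S
        with pytest.raises(ValueError, match="no grammar-valid"):
            decode_consensus(prof, ConsensusConfig(grammar=g))


class TestOptimalityAtScale:
    def test_dp_beats_every_input_method_and_truth(self, default_ensemble):
        """The decoded path must score at least as high as any grammar-valid
        candidate, in particular each method's own prediction and the truth."""
        cfg, data = default_ensemble
        pids = sorted(data.truths)[:60]
        for pid in pids:
            preds = data.predictions[pid]
            prof = build_profile(preds)
            res = decode_consensus(prof)
            for cand in [data.truths[pid], *preds]:
                assert res.log_geometric_mean_score >= score_path(prof, cand) - 1e-12
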