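"""Two-state HMM posterior decoding against path enumeration, smoothing,
region calling and classification."""

import numpy as np
import pytest

from bgcmine.clusterfinder import (CfModel, CfRegion, Token, UNKNOWN,
                                   call_regions, classify_region,
                                   integrate_with_rules, load_cf_model,
                                   posterior_decode, predict,
                                   sequence_loglik, smooth, tokenize)
from bgcmine.data import default_cf_model_path
from bgcmine.records import BgcmineError, DomainHit, Gene

from _oracles import brute_posteriors, log_forward_backward_loglik


def toks(names):
    return [Token(n, f"g{i}", i * 1000, i * 1000 + 900)
            for i, n in enumerate(names)]


def small_model(initial=(0.5, 0.5), stay=(0.8, 0.9),
                e_bgc=(0.6, 0.3, 0.1), e_bg=(0.1, 0.4, 0.5)):
    vocab = ["a", "b", UNKNOWN]
    return CfModel(
        initial=np.array(initial),
        transitions=np.array([[stay[0], 1 - stay[0]],
                              [1 - stay[1], stay[1]]]),
        emissions=(dict(zip(vocab, e_bgc)), dict(zip(vocab, e_bg))))


class TestPosteriorDecoding:
    @pytest.mark.parametrize("length", [1, 2, 3, 5, 8])
    def test_matches_path_enumeration(self, rng, length):
        """Scaled forward-backward equals summation over all 2^n paths."""
        model = small_model()
        for _ in range(5):
            names = [["a", "b", UNKNOWN][i]
                     for i in rng.integers(0, 3, size=length)]
            ours = posterior_decode(toks(names), model)
            truth = brute_posteriors(names, model)
            assert np.allclose(ours, truth, atol=1e-9)

    def test_single_token_closed_form(self):
        """Bayes: 0.3*0.9 / (0.3*0.9 + 0.7*0.1) = 27/34."""
        model = small_model(initial=(0.3, 0.7), e_bgc=(0.9, 0.05, 0.05),
                            e_bg=(0.1, 0.45, 0.45))
        (p,) = posterior_decode(toks(["a"]), model)
        assert p == pytest.approx(27 / 34, abs=1e-12)

    def test_symmetric_model_gives_half(self):
        model = small_model(initial=(0.5, 0.5), stay=(0.7, 0.7),
                            e_bgc=(0.2, 0.3, 0.5), e_bg=(0.2, 0.3, 0.5))
        posts = posterior_decode(toks(["a", "b", UNKNOWN, "a"]), model)
        assert np.allclose(posts, 0.5, atol=1e-12)

    def test_posteriors_normalized_and_loglik_consistent(self, rng):
        model = small_model()
        names = [["a", "b", UNKNOWN][i] for i in rng.integers(0, 3, size=40)]
        posts = posterior_decode(toks(names), model)
        assert all(0 <= p <= 1 for p in posts)
        fwd, bwd = log_forward_backward_loglik(names, model)
        assert fwd == pytest.approx(bwd, abs=1e-9)
        assert sequence_loglik(toks(names), model) == pytest.approx(
            fwd, abs=1e-9)

    def test_zero_emission_in_both_states_is_an_error(self):
        model = small_model(e_bgc=(0.0, 0.5, 0.5), e_bg=(0.0, 0.5, 0.5))
        with pytest.raises(BgcmineError, match="zero emission"):
            posterior_decode(toks(["a"]), model)

    def test_empty_tokens_rejected(self):
        with pytest.raises(BgcmineError):
            posterior_decode([], small_model())

    def test_against_hmmlearn_reference(self, rng):
        """Independent cross-check with a categorical-HMM library."""
        from hmmlearn.hmm import CategoricalHMM
        model = small_model()
        names = [["a", "b", UNKNOWN][i] for i in rng.integers(0, 3, size=30)]
        ours = posterior_decode(toks(names), model)
        hm = CategoricalHMM(n_components=2, init_params="")
        hm.startprob_ = np.asarray(model.initial)
        hm.transmat_ = np.asarray(model.transitions)
        hm.emissionprob_ = np.array(
            [[model.emissions[s][t] for t in ("a", "b", UNKNOWN)]
             for s in (0, 1)])
        obs = np.array([["a", "b", UNKNOWN].index(n) for n in names]
                       ).reshape(-1, 1)
        theirs = hm.predict_proba(obs)[:, 0]
        assert np.allclose(ours, theirs, atol=1e-9)


class TestTokenize:
    def test_ordering_and_unknown_mapping(self):
        genes = [Gene("g1", "r", [(0, 900)], 1, "M"),
                 Gene("g2", "r", [(2000, 2900)], 1, "M")]
        hits = [DomainHit("g2", "novel", 0, 10, 30.0),
                DomainHit("g1", "b", 20, 30, 30.0),
                DomainHit("g1", "a", 0, 10, 30.0)]
        tokens = tokenize(genes, hits, vocabulary={"a", "b", UNKNOWN})
        assert [t.name for t in tokens] == ["a", "b", UNKNOWN]
        assert tokens[0].start == 0 and tokens[2].start == 2000

    def test_empty_hits_empty_tokens(self):
        assert tokenize([], [], vocabulary={UNKNOWN}) == []


class TestSmooth:
    def test_window_one_is_identity(self):
        assert smooth([0.1, 0.9, 0.4], 1) == [0.1, 0.9, 0.4]

    def test_constant_input_unchanged(self):
        assert smooth([0.3] * 7, 5) == pytest.approx([0.3] * 7)

    def test_hand_computed_average(self):
        assert smooth([0, 1, 0], 3) == pytest.approx([0.5, 1 / 3, 0.5])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth([0.5], 2)


class TestCallRegions:
    def test_all_below_threshold(self):
        tokens = toks(["a"] * 6)
        assert call_regions(tokens, [0.2] * 6, 0.6, 2, 1) == []

    def test_min_tokens_filter(self):
        tokens = toks(["a"] * 4)
        assert call_regions(tokens, [0.9] * 4, 0.6, 5, 1) == []

    def test_runs_split_by_gap(self):
        tokens = toks(["a"] * 7)
        smoothed = [0.9, 0.9, 0.9, 0.1, 0.9, 0.9, 0.9]
        regions = call_regions(tokens, smoothed, 0.6, 3, 3)
        assert [(r.start_token, r.end_token) for r in regions] == [(0, 3),
                                                                   (4, 7)]
        assert regions[0].start == 0 and regions[0].end == 2900

    def test_min_genes_counts_distinct_genes(self):
        tokens = [Token("a", "g1", 0, 900)] * 5
        assert call_regions(tokens, [0.9] * 5, 0.6, 5, 2) == []

    def test_threshold_monotonicity(self, rng):
        """Raising the threshold never increases total called length."""
        tokens = toks(["a"] * 30)
        smoothed = list(rng.random(30))
        prev = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            total = sum(r.end_token - r.start_token
                        for r in call_regions(tokens, smoothed, thr, 1, 1))
            if prev is not None:
                assert total <= prev
            prev = total


class TestClassify:
    def _region(self, n):
        return CfRegion(0, n, 0, n * 1000, 0.9)

    def test_putative_without_markers(self):
        tokens = toks(["a", "b", "a"])
        assert classify_region(self._region(3), tokens) == "Cf_putative"

    def test_saccharide_and_precedence(self):
        tokens = toks(["Glycos_transf", "Sugar_epim", "FabH", "FabF"])
        assert classify_region(self._region(4), tokens) == "Cf_saccharide"

    def test_fatty_acid(self):
        tokens = toks(["FabH", "FabF", "a"])
        assert classify_region(self._region(3), tokens) == "Cf_fatty_acid"


class TestIntegration:
    def _rule_cluster(self):
        from bgcmine.rules import ClusterPrediction
        return ClusterPrediction("r", 1, ["t1pks"], 5000, 9000, 0, 14000)

    def test_disjoint_regions_become_cf_clusters(self):
        region = CfRegion(0, 5, 20000, 30000, 0.8, "Cf_putative")
        unified = integrate_with_rules([self._rule_cluster()], [region],
                                       "r", 50000)
        assert len(unified) == 2
        assert unified[1].detection == "clusterfinder"
        assert unified[1].types == ["Cf_putative"]
        assert unified[0].cluster_number == 1
        assert unified[1].cluster_number == 2

    def test_overlap_annotates_probability(self):
        region = CfRegion(0, 5, 8000, 16000, 0.8, "Cf_putative")
        unified = integrate_with_rules([self._rule_cluster()], [region],
                                       "r", 50000)
        assert len(unified) == 1
        assert unified[0].probability == pytest.approx(0.8)

    def test_single_bp_overlap_counts(self):
        region = CfRegion(0, 5, 13999, 20000, 0.8, "Cf_putative")
        unified = integrate_with_rules([self._rule_cluster()], [region],
                                       "r", 50000)
        assert len(unified) == 1 and unified[0].probability is not None


class TestParameterRecovery:
    def test_emissions_recovered_from_confident_posteriors(self, rng):
        """Simulating 10k tokens from the bundled model, state-conditional
        emission frequencies at posterior >= 0.9 recover the planted
        emissions within +/- 0.05."""
        model = load_cf_model(str(default_cf_model_path()))
        vocab = sorted(model.emissions[0])
        p_bgc = np.array([model.emissions[0][t] for t in vocab])
        p_bg = np.array([model.emissions[1][t] for t in vocab])
        n = 10_000
        states = np.empty(n, dtype=int)
        states[0] = rng.choice(2, p=np.asarray(model.initial))
        for i in range(1, n):
            states[i] = rng.choice(2, p=np.asarray(
                model.transitions)[states[i - 1]])
        names = [vocab[rng.choice(len(vocab),
                                  p=(p_bgc if s == 0 else p_bg))]
                 for s in states]
        posts = np.array(posterior_decode(toks(names), model))
        for state, planted in ((0, p_bgc), (1, p_bg)):
            confident = (posts >= 0.9) if state == 0 else (posts <= 0.1)
            assert confident.sum() > 500
            chosen = [names[i] for i in np.flatnonzero(confident)]
            for t, p_true in zip(vocab, planted):
                freq = sum(1 for c in chosen if c == t) / len(chosen)
                assert abs(freq - p_true) <= 0.05


def test_predict_pipeline_on_planted_tokens():
    """High-emission tokens in a background sea yield one classified region."""
    model = load_cf_model(str(default_cf_model_path()))
    genes, hits = [], []
    layout = (["ABC_tran"] * 4 + ["KS", "AT", "KR", "ACP", "C", "A", "PCP",
                                  "TE"] + ["MFS_1"] * 4)
    for i, name in enumerate(layout):
        gid = f"g{i}"
        genes.append(Gene(gid, "r", [(i * 1000, i * 1000 + 900)], 1, "M"))
        hits.append(DomainHit(gid, name, 0, 10, 50.0))
    prediction = predict(genes, hits, model)
    assert len(prediction.regions) == 1
    region = prediction.regions[0]
    assert region.cf_type == "Cf_putative"
    # smoothing erodes the run edges but the call stays inside the planted
    # block and covers most of it
    assert 4000 <= region.start and region.end <= 11900
    assert region.end - region.start >= 5000
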