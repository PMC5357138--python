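import numpy as np
import pandas as pd
import pytest

from cyclops_screen import cyclops as cyc
from cyclops_screen.config import RunConfig

from oracles import delta_oracle


def _sample_annotation(n, n_lineages=4):
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "lineage": [f"lin{i % n_lineages}" for i in range(n)],
    })


def _planted_screen_inputs(rng, n_genes=50, n_samples=100, n_loss=20,
                           delta=-1.15, sd=0.3):
    """One planted CYCLOPS gene (exact n_loss/neutral split) among nulls."""
    samples = [f"s{i}" for i in range(n_samples)]
    genes = [f"g{i}" for i in range(n_genes)]
    cn = pd.DataFrame(rng.normal(0.0, 0.05, size=(n_genes, n_samples)),
                      index=genes, columns=samples)
    loss_cols = rng.choice(n_samples, size=n_loss, replace=False)
    cn.iloc[0, loss_cols] = -1.0 + rng.normal(0.0, 0.05, size=n_loss)
    # give null genes loss lines too, so they are tested
    for i in range(1, n_genes):
        k = rng.integers(5, 30)
        cols = rng.choice(n_samples, size=k, replace=False)
        cn.iloc[i, cols] = -1.0 + rng.normal(0.0, 0.05, size=k)
    dep = pd.DataFrame(rng.normal(0.0, sd, size=(n_genes, n_samples)),
                       index=genes, columns=samples)
    dep.iloc[0, loss_cols] += delta
    return cn, dep


class TestCopyState:
    @pytest.mark.parametrize("value,expected", [
        (-0.35, "loss"),     # the boundary itself is a loss
        (0.0, "neutral"),
        (0.40, "gain"),
        (-0.349, "neutral"),
    ])
    def test_thresholds(self, value, expected):
        assert cyc.classify_copy_state([value])[0] == expected

    def test_na_propagates(self):
        assert cyc.classify_copy_state([np.nan])[0] is None

    def test_infinite_gain_threshold_gives_two_classes(self):
        states = cyc.classify_copy_state([5.0, 0.0, -1.0], gain_threshold=np.inf)
        assert list(states) == ["neutral", "neutral", "loss"]

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            cyc.classify_copy_state([0.0], loss_threshold=0.5, gain_threshold=-0.5)


class TestDeltaDependency:
    def test_group_mean_difference(self):
        scores = [-1.2, -1.0, 0.0, 0.1]
        states = ["loss", "loss", "neutral", "neutral"]
        assert cyc.delta_dependency(scores, states) == pytest.approx(-1.15)

    def test_sf3b1_scale_group_means(self):
        # groups engineered to the -1.14 / 0.01 means give delta -1.15
        scores = [-1.24, -1.04, 0.0, 0.02]
        states = ["loss", "loss", "neutral", "neutral"]
        assert cyc.delta_dependency(scores, states) == pytest.approx(-1.15)

    def test_identical_groups_zero(self):
        assert cyc.delta_dependency([1, 1, 1, 1],
                                    ["loss", "loss", "neutral", "neutral"]) == 0.0

    def test_gain_samples_excluded(self):
        scores = [-1.0, 0.0, 99.0]
        states = ["loss", "neutral", "gain"]
        assert cyc.delta_dependency(scores, states) == pytest.approx(-1.0)

    def test_empty_group_is_nan(self):
        assert np.isnan(cyc.delta_dependency([1.0, 2.0], ["loss", "loss"]))

    def test_shift_invariance_and_scale_equivariance(self, rng):
        scores = rng.normal(size=30)
        states = np.where(rng.random(30) < 0.3, "loss", "neutral")
        d = cyc.delta_dependency(scores, states)
        assert cyc.delta_dependency(scores + 5.0, states) == pytest.approx(d)
        assert cyc.delta_dependency(scores * 3.0, states) == pytest.approx(3 * d)

    def test_matches_scalar_oracle(self, rng):
        scores = rng.normal(size=40)
        is_loss = rng.random(40) < 0.25
        if is_loss.sum() == 0 or is_loss.sum() == 40:
            is_loss[:2] = [True, False]
        states = np.where(is_loss, "loss", "neutral")
        assert cyc.delta_dependency(scores, states) == pytest.approx(
            delta_oracle(scores, is_loss))


class TestStratifiedPermutation:
    def test_minimal_attainable_p(self, rng):
        # complete separation: p = 1/(B+1) with B = 999
        scores = np.concatenate([np.full(5, -2.0), np.zeros(45)])
        states = np.array(["loss"] * 5 + ["neutral"] * 45, dtype=object)
        lineages = np.array([f"lin{i % 2}" for i in range(50)])
        _, p = cyc.stratified_permutation_test(scores, states, lineages, 999, rng)
        assert p == pytest.approx(1 / 1000)

    def test_per_stratum_loss_counts_preserved(self, rng):
        # stratum A scores dwarf stratum B; if any permutation moved loss
        # labels across strata, the null deltas would jump by ~1000
        nA, nB, kA, kB = 12, 12, 4, 2
        scores = np.concatenate([1000.0 + rng.normal(size=nA), rng.normal(size=nB)])
        is_loss = np.zeros(nA + nB, dtype=bool)
        is_loss[rng.choice(nA, kA, replace=False)] = True
        is_loss[nA + rng.choice(nB, kB, replace=False)] = True
        strata = np.array(["A"] * nA + ["B"] * nB)
        null = cyc._stratified_null_deltas(scores, is_loss, strata, 500, rng)
        n_loss, n_neut = kA + kB, nA + nB - kA - kB
        expected = 1000.0 * (kA / n_loss - (nA - kA) / n_neut)
        assert np.all(np.abs(null - expected) < 50)

    def test_degenerate_strata_give_na(self, rng):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        states = np.array(["loss", "loss", "neutral", "neutral"], dtype=object)
        lineages = np.array(["A", "A", "B", "B"])  # each stratum one class
        with pytest.warns(UserWarning, match="degenerate"):
            delta, p = cyc.stratified_permutation_test(scores, states, lineages,
                                                       100, rng)
        assert np.isnan(p) and np.isfinite(delta)

    def test_null_p_roughly_uniform(self, rng):
        # small-scale calibration; the full-size check lives in acceptance
        ps = []
        lineages = np.array([f"lin{i % 4}" for i in range(60)])
        for _ in range(200):
            scores = rng.normal(size=60)
            states = np.array(["loss"] * 12 + ["neutral"] * 48, dtype=object)
            rng.shuffle(states)
            _, p = cyc.stratified_permutation_test(scores, states, lineages, 199, rng)
            ps.append(p)
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.005


class TestScreen:
    def test_single_gene_single_record(self, rng):
        cn, dep = _planted_screen_inputs(rng, n_genes=1)
        ann = _sample_annotation(cn.shape[1])
        out = cyc.run_cyclops_screen(cn, dep, ann, RunConfig(seed=1, n_permutations=200))
        assert len(out) == 1 and not out.loc[0, "excluded"]

    def test_fewer_than_two_loss_lines_excluded(self):
        samples = [f"s{i}" for i in range(30)]
        cn = pd.DataFrame([np.zeros(30)], index=["g"], columns=samples)
        cn.iloc[0, 0] = -1.0
        dep = pd.DataFrame(np.zeros((1, 30)), index=["g"], columns=samples)
        out = cyc.run_cyclops_screen(cn, dep, _sample_annotation(30),
                                     RunConfig(seed=1, n_permutations=200))
        assert bool(out.loc[0, "excluded"])
        assert out.loc[0, "reason"] == cyc.REASON_FEW_LOSS
        assert np.isnan(out.loc[0, "p_perm"]) and np.isnan(out.loc[0, "q"])

    def test_planted_gene_recovered(self, rng):
        cn, dep = _planted_screen_inputs(rng)
        out = cyc.run_cyclops_screen(cn, dep, _sample_annotation(cn.shape[1]),
                                     RunConfig(seed=2, n_permutations=1000))
        cand = cyc.cyclops_candidates(out, 0.1)
        assert "g0" in set(cand["gene"])
        assert out.set_index("gene").loc["g0", "delta"] == pytest.approx(-1.15, abs=0.25)

    def test_power_monotone_in_effect_size(self):
        rejections = []
        for delta in (0.0, -0.6, -1.2):
            hits = 0
            for rep in range(8):
                rng = np.random.default_rng(100 + rep)
                cn, dep = _planted_screen_inputs(rng, n_genes=20, delta=delta)
                out = cyc.run_cyclops_screen(
                    cn, dep, _sample_annotation(cn.shape[1]),
                    RunConfig(seed=rep, n_permutations=300))
                cand = cyc.cyclops_candidates(out, 0.1)
                hits += "g0" in set(cand["gene"])
            rejections.append(hits / 8)
        assert rejections[0] <= rejections[1] <= rejections[2]


class TestSecondaryValidation:
    def test_shared_effects_validate(self, rng):
        cn, dep = _planted_screen_inputs(rng, n_genes=10)
        cn2, dep2 = _planted_screen_inputs(np.random.default_rng(5), n_genes=10)
        res = cyc.validate_against_secondary(
            ["g0"], dep2, cn2, _sample_annotation(cn2.shape[1]),
            RunConfig(seed=3, n_permutations=500))
        assert res["fraction"] == 1.0
        assert res["p_binomial"] < 0.1

    def test_pure_noise_rarely_validates(self):
        rng = np.random.default_rng(8)
        hits = [f"g{i}" for i in range(30)]
        cn2, dep2 = _planted_screen_inputs(rng, n_genes=30, delta=0.0)
        res = cyc.validate_against_secondary(
            hits, dep2, cn2, _sample_annotation(cn2.shape[1]),
            RunConfig(seed=4, n_permutations=500))
        assert res["fraction"] <= 0.2  # near the nominal alpha = 0.05

    def test_no_overlap_rejected(self, rng):
        cn, dep = _planted_screen_inputs(rng, n_genes=3)
        with pytest.raises(ValueError):
            cyc.validate_against_secondary(["absent"], dep, cn,
                                           _sample_annotation(cn.shape[1]),
                                           RunConfig(seed=1))
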