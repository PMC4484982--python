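import numpy as np
import pandas as pd
import pytest

from refstab import (
    NormFinder,
    ValidationError,
    aggregate_replicates,
    log_quantities,
    normfinder_stability,
    relative_quantities,
)
from refstab.synthetic_data import GeneProfile, SimulationConfig, simulate_ct
from tests.conftest import ct_matrix_from_frame, random_q
from tests.oracles import normfinder_oracle


def _two_group_logq(seed, n_genes=5, per_group=4, effects=None, sigma=0.3):
    """Log quantities for a two-group layout with optional per-gene group shifts."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1}" for i in range(n_genes)]
    samples = [f"a{j}" for j in range(per_group)] + [f"b{j}" for j in range(per_group)]
    groups = {s: s[0] for s in samples}
    effects = effects or {}
    data = {}
    for g in genes:
        base = rng.uniform(-3, 0)
        row = base + rng.normal(0, sigma, 2 * per_group)
        row[per_group:] += effects.get(g, 0.0)
        data[g] = row
    return pd.DataFrame.from_dict(data, orient="index", columns=samples), groups


class TestLogQuantities:
    def test_powers_of_two(self):
        q = pd.DataFrame({"s1": [1.0], "s2": [0.5], "s3": [0.25]}, index=["g"])
        assert np.allclose(log_quantities(q).loc["g"], [0, -1, -2])

    def test_round_trip(self):
        q = random_q(1)
        assert np.allclose(2.0 ** log_quantities(q), q)


class TestNormFinderStability:
    def test_noise_free_data_gives_zero_stability(self):
        # constant centered values within and across groups: no variance, no shift
        logq, groups = _two_group_logq(0, sigma=0.0)
        res = normfinder_stability(logq, groups)
        assert np.allclose(res.stability, 0.0, atol=1e-12)
        assert np.allclose(res.intragroup_variance, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_group_shifted_gene_less_stable_than_quiet_gene(self, seed):
        logq, groups = _two_group_logq(
            seed, n_genes=6, effects={"g1": 0.0, "g2": 2.0}, sigma=0.1
        )
        res = normfinder_stability(logq, groups)
        assert res.stability["g1"] < res.stability["g2"]

    @pytest.mark.parametrize("seed", range(10))
    def test_brute_force_oracle_equivalence(self, seed):
        logq, groups = _two_group_logq(seed, n_genes=4, per_group=3)
        res = normfinder_stability(logq, groups)
        oracle = normfinder_oracle(logq, groups)
        for g in logq.index:
            assert res.stability[g] == pytest.approx(oracle["stability"][g], abs=1e-10)
            for lab in res.groups:
                assert res.intragroup_variance.at[g, lab] == pytest.approx(
                    oracle["sigma2"][(g, lab)], abs=1e-10
                )
                assert res.intergroup_deviation.at[g, lab] == pytest.approx(
                    oracle["dev"][(g, lab)], abs=1e-10
                )

    def test_single_group_falls_back_to_variance_ranking(self):
        logq, _ = _two_group_logq(3)
        res = normfinder_stability(logq, None)
        assert res.groups == ("all",)
        assert np.allclose(
            res.stability, np.sqrt(res.intragroup_variance["all"]), atol=1e-12
        )

    def test_per_gene_constant_offset_invariance(self):
        logq, groups = _two_group_logq(5)
        shifted = logq.add(pd.Series({g: i * 5.0 for i, g in enumerate(logq.index)}), axis=0)
        a = normfinder_stability(logq, groups).stability
        b = normfinder_stability(shifted, groups).stability
        assert np.allclose(a, b, atol=1e-10)

    def test_per_sample_global_shift_invariance(self):
        logq, groups = _two_group_logq(6)
        shifted = logq.add(
            pd.Series(np.linspace(-2, 2, logq.shape[1]), index=logq.columns), axis=1
        )
        a = normfinder_stability(logq, groups).stability
        b = normfinder_stability(shifted, groups).stability
        assert np.allclose(a, b, atol=1e-10)

    def test_noise_monotonicity_on_average(self):
        # inflating one gene's noise raises its mean stability across seeds
        small, large = [], []
        for seed in range(15):
            lo, groups = _two_group_logq(seed, sigma=0.1)
            res_lo = normfinder_stability(lo, groups)
            rng = np.random.default_rng(1000 + seed)
            hi = lo.copy()
            hi.loc["g1"] += rng.normal(0, 1.0, lo.shape[1])
            res_hi = normfinder_stability(hi, groups)
            small.append(res_lo.stability["g1"])
            large.append(res_hi.stability["g1"])
        assert np.mean(large) > np.mean(small)

    def test_group_with_single_sample_rejected(self):
        logq, groups = _two_group_logq(2)
        groups = dict(groups)
        groups[list(groups)[0]] = "lonely"
        with pytest.raises(ValidationError, match="at least 2 samples"):
            normfinder_stability(logq, groups)

    def test_fewer_than_three_genes_rejected(self):
        logq, groups = _two_group_logq(2, n_genes=2)
        with pytest.raises(ValidationError, match="3 genes"):
            normfinder_stability(logq, groups)


class TestNormFinderEstimator:
    def test_fit_matches_functional_path(self):
        logq, groups = _two_group_logq(9)
        q = 2.0 ** logq
        est = NormFinder().fit(q.T, groups=[groups[s] for s in q.columns])
        res = normfinder_stability(logq, groups)
        assert np.allclose(est.stability_, res.stability, atol=1e-12)
        assert est.ranking_ == res.ranking

    def test_simulated_treatment_responsive_genes_rank_last(self):
        profiles = [
            GeneProfile("quiet1", 22.0, {}, 0.08, 0.06),
            GeneProfile("quiet2", 24.0, {}, 0.08, 0.06),
            GeneProfile("loud1", 20.0, {"B": 2.0}, 0.2, 0.1),
            GeneProfile("loud2", 26.0, {"B": -1.5}, 0.2, 0.1),
        ]
        config = SimulationConfig(profiles, {"A": 4, "B": 4}, seed=13)
        ct = aggregate_replicates(simulate_ct(config))
        logq = log_quantities(relative_quantities(ct))
        res = normfinder_stability(logq, dict(ct.groups))
        assert set(res.ranking[:2]) == {"quiet1", "quiet2"}
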