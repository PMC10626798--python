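"""Size factors, BH, the NB Wald test and the decoupling correlation skeleton."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from archatac import SimConfig, Simulation
from archatac.differential import (
    bh_fdr,
    feature_counts,
    nb_differential,
    signal_correlation,
    size_factors,
)
from archatac.types import CountTable


class TestSizeFactors:
    def test_identical_libraries_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 10, 20], "b": [5, 10, 20]})
        np.testing.assert_allclose(size_factors(counts), 1.0)

    def test_featurewise_doubling(self):
        counts = pd.DataFrame({"a": [5, 10, 20], "b": [10, 20, 40]})
        sf = size_factors(counts)
        np.testing.assert_allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(rng.integers(1, 500, (50, 4)),
                              columns=list("abcd"))
        got = size_factors(counts)
        # direct per-definition recomputation
        arr = counts.to_numpy(float)
        gmean = np.exp(np.log(arr).mean(axis=1))
        raw = np.array([np.median(arr[:, j] / gmean) for j in range(4)])
        want = raw / np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(got, want)

    def test_all_zero_feature_only_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="nonzero"):
            size_factors(counts)

    def test_scaling_one_library(self):
        """x10 on one library multiplies factor ratios by 10; log2FCs at
        pseudocount 0 are unchanged."""
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.integers(5, 500, (40, 4)),
                              columns=["a1", "a2", "b1", "b2"])
        scaled = counts.copy()
        scaled["b1"] = scaled["b1"] * 10
        sf0, sf1 = size_factors(counts), size_factors(scaled)
        np.testing.assert_allclose((sf1["b1"] / sf1["a1"]),
                                   10 * sf0["b1"] / sf0["a1"])
        r0 = nb_differential(counts, ["a1", "a2"], ["b1", "b2"], pseudocount=0.0)
        r1 = nb_differential(scaled, ["a1", "a2"], ["b1", "b2"], pseudocount=0.0)
        np.testing.assert_allclose(r0["log2fc"], r1["log2fc"])


class TestBH:
    def test_hand_arithmetic(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.01, 0.02, 0.03])),
                                   [0.03, 0.03, 0.03])

    def test_single_p_passthrough(self):
        assert bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr(np.ones(5)), 1.0)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.random(rng.integers(2, 200))
            _, want, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_fdr(p), want)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(9)
        p = rng.random(100)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestNbDifferential:
    def test_identical_counts_null(self):
        counts = pd.DataFrame({c: [10, 50, 200] for c in ("a1", "a2", "b1", "b2")})
        res = nb_differential(counts, ["a1", "a2"], ["b1", "b2"])
        np.testing.assert_allclose(res["log2fc"], 0.0)
        assert (res["p"] >= 0.99).all()

    def test_single_strong_feature_ranks_first(self):
        rng = np.random.default_rng(10)
        base = rng.integers(20, 60, 50)
        counts = pd.DataFrame({
            "a1": base, "a2": base, "b1": base, "b2": base,
        })
        counts.iloc[7] = [10, 10, 40, 40]
        res = nb_differential(counts, ["a1", "a2"], ["b1", "b2"])
        assert res["p"].idxmin() == 7
        assert abs(res.loc[7, "log2fc"]) == pytest.approx(2.0, abs=0.25)
        # direction check against an exhaustive label-permutation oracle:
        # of the 6 balanced 2v2 relabelings, the true split is the most extreme
        from itertools import combinations
        f = counts.iloc[7].to_numpy(float)
        obs = abs(f[2:].mean() - f[:2].mean())
        extremes = [
            abs(f[list(set(range(4)) - set(c))].mean() - f[list(c)].mean())
            for c in combinations(range(4), 2)
        ]
        assert obs == max(extremes)

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(rng.integers(1, 300, (30, 4)),
                              columns=["a1", "a2", "b1", "b2"])
        r_ab = nb_differential(counts, ["a1", "a2"], ["b1", "b2"])
        r_ba = nb_differential(counts, ["b1", "b2"], ["a1", "a2"])
        np.testing.assert_allclose(r_ab["log2fc"], -r_ba["log2fc"])
        np.testing.assert_allclose(r_ab["p"], r_ba["p"])

    def test_single_library_poisson_fallback_warns(self):
        counts = pd.DataFrame({"a1": [10, 20], "b1": [12, 18]})
        with pytest.warns(UserWarning, match="Poisson"):
            res = nb_differential(counts, ["a1"], ["b1"])
        assert np.isfinite(res["p"]).all()

    def test_type_one_error_near_nominal(self):
        """Null Poisson counts: fraction with p < 0.05 near 0.05."""
        rng = np.random.default_rng(12)
        m = 2000
        counts = pd.DataFrame(
            rng.poisson(50, (m, 8)),
            columns=["a1", "a2", "a3", "a4", "b1", "b2", "b3", "b4"])
        res = nb_differential(counts, ["a1", "a2", "a3", "a4"],
                              ["b1", "b2", "b3", "b4"])
        rate = (res["p"] < 0.05).mean()
        tol = 3 * np.sqrt(0.05 * 0.95 / m)
        assert abs(rate - 0.05) < tol + 0.02


@pytest.fixture(scope="module")
def decoupled_counts(default_sim):
    """One matched ATAC/KAS library pair on the default (decoupled) genome."""
    sim = default_sim
    atac = {"atac": sim.atac("exponential", 100_000, 21)}
    kas = {"kas": sim.kas("exponential", 100_000, 22)}
    ct_a = feature_counts(atac, sim.genome, feature="promoter")
    ct_k = feature_counts(kas, sim.genome, feature="gene_body")
    # per-bp density removes gene-length units from the gene-body counts
    lengths = ct_k.coords["end"] - ct_k.coords["start"]
    return ct_a.counts["atac"], ct_k.counts["kas"] / lengths


class TestCorrelation:
    def test_perfect_correlation(self):
        x = pd.Series([1.0, 5.0, 9.0, 20.0])
        res = signal_correlation(x, x, transform="none")
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        x = pd.Series([1.0, 1.0, 1.0, 1.0])
        y = pd.Series([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="constant"):
            signal_correlation(x, y, transform="none")

    def test_decoupled_simulation_uncorrelated(self, decoupled_counts):
        """Accessibility and transcription drawn independently: |rho| small."""
        x, y = decoupled_counts
        res = signal_correlation(x, y)
        assert abs(res.spearman_rho) < 0.15

    def test_decoupled_over_seeds(self, default_sim):
        """|rho| < 0.15 and p > 0.01 in at least 90% of replicate simulations."""
        sim = default_sim
        ok = 0
        n_seeds = 20
        for s in range(n_seeds):
            atac = feature_counts({"a": sim.atac("exponential", 30_000, 500 + s)},
                                  sim.genome, feature="promoter")
            kas = feature_counts({"k": sim.kas("exponential", 30_000, 800 + s)},
                                 sim.genome, feature="gene_body")
            lengths = kas.coords["end"] - kas.coords["start"]
            res = signal_correlation(atac.counts["a"], kas.counts["k"] / lengths)
            if abs(res.spearman_rho) < 0.15 and res.spearman_p > 0.01:
                ok += 1
        assert ok / n_seeds >= 0.9

    def test_coupled_simulation_strongly_correlated(self):
        """Positive control: transcription tied to accessibility -> rho > 0.8."""
        cfg = SimConfig.small()
        sim = Simulation(cfg)
        coupled = {g: 2.0 * a for g, a in sim.truth.accessibility.items()}
        sim.truth.kas_rates["exponential"] = coupled
        atac = feature_counts({"a": sim.atac("exponential", 100_000, 31)},
                              sim.genome, feature="promoter")
        kas = feature_counts({"k": sim.kas("exponential", 100_000, 32)},
                             sim.genome, feature="gene_body")
        lengths = kas.coords["end"] - kas.coords["start"]
        res = signal_correlation(atac.counts["a"], kas.counts["k"] / lengths)
        assert res.spearman_rho > 0.8


class TestDecouplingPipeline:
    def test_kas_changes_without_atac_changes(self, default_sim):
        """KAS flags most truly changed genes; ATAC flags almost nothing."""
        sim = default_sim
        kas_libs = {f"e{r}": sim.kas("exponential", 100_000, 100 + r) for r in (1, 2, 3)}
        kas_libs |= {f"s{r}": sim.kas("stationary", 100_000, 200 + r) for r in (1, 2, 3)}
        atac_libs = {f"e{r}": sim.atac("exponential", 100_000, 300 + r) for r in (1, 2, 3)}
        atac_libs |= {f"s{r}": sim.atac("stationary", 100_000, 400 + r) for r in (1, 2, 3)}
        groups = (["e1", "e2", "e3"], ["s1", "s2", "s3"])

        kas_res = nb_differential(
            feature_counts(kas_libs, sim.genome, feature="gene_body"), *groups)
        atac_res = nb_differential(
            feature_counts(atac_libs, sim.genome, feature="promoter"), *groups)

        changed = set(sim.truth.changed_genes)
        kas_called = set(kas_res[kas_res["q"] <= 0.1].index)
        assert len(kas_called & changed) / len(changed) > 0.8
        unchanged = set(kas_res.index) - changed
        atac_called = set(atac_res[atac_res["q"] <= 0.1].index)
        assert len(atac_called) / len(atac_res) <= 0.05

        # changes-vs-changes correlation (the decoupling figure's skeleton)
        both = kas_res.join(atac_res, lsuffix="_kas", rsuffix="_atac")
        res = signal_correlation(both["log2fc_atac"], both["log2fc_kas"],
                                 transform="none")
        assert abs(res.spearman_rho) < 0.2
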