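"""Single-molecule matrices, absolute protection, metaprofiles, footprints."""

import numpy as np
import pandas as pd
import pytest

from archatac import SimConfig, Simulation
from archatac.footprints import (
    ACCESSIBLE,
    NO_DATA,
    PROTECTED,
    absolute_protection,
    build_molecule_matrix,
    detect_upstream_footprint,
    protection_metaprofile,
)
from archatac.tss import Metaprofile
from archatac.types import MethylCallTable


def _calls(rows):
    return MethylCallTable(pd.DataFrame(
        rows, columns=list(MethylCallTable.COLUMNS)))


class TestMoleculeMatrix:
    def test_encoding(self):
        calls = _calls([
            ("m1", "chr", 0, 100, 10, "GpC", True),
            ("m1", "chr", 0, 100, 20, "GpC", False),
            ("m1", "chr", 0, 100, 30, "GpC", True),
        ])
        mat = build_molecule_matrix(calls, ("chr", 0, 100))
        np.testing.assert_array_equal(mat.matrix[0], [ACCESSIBLE, PROTECTED, ACCESSIBLE])

    def test_no_data_at_uncovered_sites(self):
        calls = _calls([
            ("m1", "chr", 0, 50, 10, "GpC", True),
            ("m2", "chr", 40, 100, 60, "GpC", False),
        ])
        mat = build_molecule_matrix(calls, ("chr", 0, 100))
        # sites are {10, 60}; each molecule covers exactly one
        assert (mat.matrix == NO_DATA).sum() == 2

    def test_bookkeeping_rows_sum_to_site_count(self):
        sim = Simulation(SimConfig.small())
        calls = sim.methyl_molecules("exponential", 300, 200, seed=8)
        g = sim.genome.genes[0]
        region = (g.replicon, max(g.tss - 150, 0), g.tss + 150)
        mat = build_molecule_matrix(calls, region)
        n_sites = len(mat.sites)
        per_row = ((mat.matrix == NO_DATA).sum(axis=1)
                   + (mat.matrix == PROTECTED).sum(axis=1)
                   + (mat.matrix == ACCESSIBLE).sum(axis=1))
        assert (per_row == n_sites).all()

    def test_marginals_match_independent_tally(self):
        sim = Simulation(SimConfig.small())
        calls = sim.methyl_molecules("exponential", 300, 200, seed=8)
        g = sim.genome.genes[1]
        region = (g.replicon, max(g.tss - 150, 0), g.tss + 150)
        mat = build_molecule_matrix(calls, region)
        df = calls.records
        kept = set(mat.molecule_ids)
        sub = df[(df["replicon"] == region[0]) & (df["pos"] >= region[1])
                 & (df["pos"] < region[2]) & df["molecule_id"].isin(kept)]
        tally = sub.groupby("pos")["methylated"].mean()
        got = mat.per_site_methylated_fraction()
        for pos, frac in tally.items():
            assert got[list(mat.sites).index(pos)] == pytest.approx(frac)

    def test_no_qualifying_molecules_rejected(self):
        calls = _calls([("m1", "chr", 0, 50, 10, "GpC", True)])
        with pytest.raises(ValueError, match="no molecules"):
            build_molecule_matrix(calls, ("chr", 500, 600))


class TestAbsoluteProtection:
    def test_all_methylated_zero_protection(self):
        calls = _calls([("m1", "chr", 0, 99, p, "GpC", True) for p in range(0, 90, 10)])
        assert absolute_protection(calls).fraction == 0.0

    def test_arithmetic(self):
        rows = [("m1", "chr", 0, 200, p, "GpC", p < 30) for p in range(0, 200, 10)]
        # 3 methylated of 20 -> 17/20 protected
        est = absolute_protection(calls=_calls(rows))
        assert est.fraction == pytest.approx(0.85)
        assert est.ci_low < 0.85 < est.ci_high

    def test_molecule_filter(self):
        rows = ([("m1", "chr", 0, 99, p, "GpC", True) for p in (10, 20, 30)]
                + [("m2", "chr", 0, 99, 40, "GpC", False)])
        est = absolute_protection(_calls(rows), min_sites_per_molecule=3)
        assert est.n_informative == 3  # m2 filtered out

    def test_recovery_exponential_and_stationary(self, default_sim):
        est = absolute_protection(
            default_sim.methyl_molecules("exponential", 10_000, 200, seed=7))
        assert 100 * est.fraction == pytest.approx(85.0, abs=1.0)
        est_s = absolute_protection(
            default_sim.methyl_molecules("stationary", 10_000, 200, seed=7))
        assert 100 * est_s.fraction == pytest.approx(89.0, abs=1.0)

    def test_parameter_recovery_across_accessibilities(self):
        """Estimator mean over seeds within 0.5 points of 1 - accessibility."""
        for a in (0.05, 0.15, 0.25):
            cfg = SimConfig.small(accessibility_prob={"exponential": a},
                                  footprint_occupancy=0.0)
            sim = Simulation(cfg)
            ests = [absolute_protection(
                sim.methyl_molecules("exponential", 400, 200, seed=s)).fraction
                for s in range(50)]
            assert abs(np.mean(ests) - (1 - a)) < 0.005

    def test_per_molecule_mode_reported(self, small_sim):
        calls = small_sim.methyl_molecules("exponential", 500, 200, seed=2)
        pooled = absolute_protection(calls)
        permol = absolute_protection(calls, per_molecule=True)
        assert permol.mode == "molecule-averaged"
        assert abs(pooled.fraction - permol.fraction) < 0.02


class TestProtectionMetaprofile:
    def test_flat_on_homogeneous_simulation(self):
        cfg = SimConfig.small(footprint_occupancy=0.0)
        sim = Simulation(cfg)
        calls = sim.methyl_molecules("exponential", 4000, 200, seed=3)
        prof = protection_metaprofile(calls, sim.genome, flank=80, min_calls=50)
        vals = prof.mean[~np.isnan(prof.mean)]
        # every offset is a binomial draw around the global level
        assert vals.std() < 0.05
        assert abs(np.nanmean(vals) - 0.85) < 0.02

    def test_pooled_identity_with_absolute_protection(self, small_sim):
        """Call-weighted mean over offsets equals the pooled estimate."""
        calls = small_sim.methyl_molecules("exponential", 1000, 200, seed=4)
        flank = 100
        prof = protection_metaprofile(calls, small_sim.genome, flank=flank, min_calls=1)
        # restrict the pooled estimate to calls inside some TSS +/- flank window
        df = calls.records
        tsses = small_sim.genome.tss_table()
        keep = np.zeros(len(df), bool)
        for row in tsses.itertuples():
            keep |= ((df["replicon"] == row.replicon).to_numpy()
                     & (df["pos"].to_numpy() >= row.tss - flank)
                     & (df["pos"].to_numpy() <= row.tss + flank))
        # offsets are pooled per (gene, call): a call near two TSSs counts twice
        # in the profile, so compare against the profile's own totals
        pooled = np.nansum(prof.mean * prof.n) / prof.n.sum()
        within = df[keep]
        assert pooled == pytest.approx(1 - within["methylated"].mean(), abs=0.01)

    def test_footprint_elevation_visible_in_window(self):
        """Occupied upstream footprints elevate pooled protection in [-60,-10)."""
        sim = Simulation(SimConfig.small(molecule_promoter_fraction=1.0))
        calls = sim.methyl_molecules("exponential", 50_000, 200, seed=9)
        prof = protection_metaprofile(calls, sim.genome, flank=100, min_calls=10)
        lo, hi = sim.truth.footprint_window
        in_fp = (prof.offsets >= lo) & (prof.offsets < hi)
        out_fp = ~in_fp
        fp_mean = np.nansum(prof.mean[in_fp] * prof.n[in_fp]) / prof.n[in_fp].sum()
        base = np.nansum(prof.mean[out_fp] * prof.n[out_fp]) / prof.n[out_fp].sum()
        n_fp = prof.n[in_fp].sum()
        se = np.sqrt(base * (1 - base) / n_fp)
        assert fp_mean - base > 2 * se


def _step_profile(flank=200, step=0.05, baseline=0.85, n_per_offset=5000,
                  noise_seed=None):
    offsets = np.arange(-flank, flank + 1)
    mean = np.full(len(offsets), baseline)
    mean[(offsets >= -60) & (offsets < -10)] += step
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        k = rng.binomial(n_per_offset, mean)
        mean = k / n_per_offset
    return Metaprofile(offsets=offsets, mean=mean,
                       n=np.full(len(offsets), n_per_offset))


class TestFootprintDetector:
    def test_flat_profile_returns_none(self):
        prof = _step_profile(step=0.0)
        assert detect_upstream_footprint(prof, seed=1) is None

    def test_recovers_constructed_step(self):
        prof = _step_profile(step=0.05)
        call = detect_upstream_footprint(prof, n_permutations=1000, seed=1)
        assert call is not None
        assert call.interval == (-60, -10)
        assert call.p_value < 0.01
        assert call.elevation == pytest.approx(0.05, abs=0.01)

    def test_recovers_noisy_step(self):
        prof = _step_profile(step=0.05, noise_seed=11)
        call = detect_upstream_footprint(prof, n_permutations=1000, seed=1)
        assert call is not None
        assert call.p_value < 0.01
        # interval recovered to within a few offsets
        assert abs(call.interval[0] - -60) <= 5
        assert abs(call.interval[1] - -10) <= 5

    def test_null_detection_rate_calibrated(self):
        """Null detection rate stays at the nominal alpha (binomial tolerance)."""
        n = 100
        hits = 0
        for s in range(n):
            prof = _step_profile(step=0.0, noise_seed=100 + s, n_per_offset=2000)
            if detect_upstream_footprint(prof, n_permutations=200, seed=s) is not None:
                hits += 1
        bound = 0.05 + 2 * np.sqrt(0.05 * 0.95 / n)
        assert hits / n <= bound

    def test_fully_masked_search_window_rejected(self):
        prof = _step_profile()
        prof.mean[(prof.offsets >= -100) & (prof.offsets < 0)] = np.nan
        with pytest.raises(ValueError, match="masked"):
            detect_upstream_footprint(prof, seed=1)
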