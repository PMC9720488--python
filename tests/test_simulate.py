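import numpy as np
import pandas as pd
import pytest

from conftest import make_pedigree
from resgwas import indicators as ind
from resgwas.simulate import (
    ConfigError,
    SimulationConfig,
    batch_anchor_curve,
    default_snp_map,
    simulate_batch,
    simulate_breeding_values,
    simulate_egg_production,
    simulate_genotypes,
    simulate_nab_phenotypes,
    simulate_pedigree,
)


class TestPedigree:
    def test_single_family_of_full_sibs(self, rng):
        cfg = SimulationConfig(n_hens=5, n_families=1, n_sires=1, n_genotyped=5)
        ped = simulate_pedigree(cfg, rng)
        hens = ped.hens
        assert len(hens) == 5
        assert hens["dam"].nunique() == 1
        assert hens["sire"].nunique() == 1

    def test_default_batch_size_and_structure(self, rng):
        ped = simulate_pedigree(SimulationConfig(), rng)
        hens = ped.hens
        assert len(hens) == 2494
        assert (hens["sex"] == "F").all()
        assert set(hens["hatch_week"]) == {1, 2, 3}
        assert hens["family"].nunique() == 500
        # hatch weeks in roughly equal thirds
        assert hens["hatch_week"].value_counts().min() > 600

    def test_same_seed_identical(self):
        cfg = SimulationConfig(n_hens=50, n_families=10, n_sires=3, n_genotyped=20)
        p1 = simulate_pedigree(cfg, np.random.default_rng(5))
        p2 = simulate_pedigree(cfg, np.random.default_rng(5))
        pd.testing.assert_frame_equal(p1.table, p2.table)

    def test_invalid_sizes_rejected(self, rng):
        with pytest.raises(ConfigError):
            simulate_pedigree(SimulationConfig(n_hens=0), rng)
        with pytest.raises(ConfigError):
            SimulationConfig(depth_low=0.9, depth_high=0.2).validate()

    def test_own_parent_rejected(self):
        with pytest.raises(ValueError, match="own parent"):
            make_pedigree([("A", "A", "", "F", 1)])


class TestGenotypes:
    @staticmethod
    def snp_map(freqs, chroms=None):
        chroms = chroms or ["1"] * len(freqs)
        return pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(len(freqs))],
                "chromosome": chroms,
                "position_bp": np.arange(1, len(freqs) + 1) * 100,
                "founder_freq": freqs,
            }
        )

    def test_founders_in_hardy_weinberg(self, rng):
        cfg = SimulationConfig(n_hens=1500, n_families=1500, n_sires=10, n_genotyped=10)
        ped = simulate_pedigree(cfg, rng)
        panel = simulate_genotypes(ped, self.snp_map([0.5]), rng)
        dams = panel.calls[10:1510, 0]  # founder dams
        freq = np.bincount(dams, minlength=3) / dams.size
        assert np.allclose(freq, [0.25, 0.5, 0.25], atol=0.05)

    def test_female_z_calls_never_heterozygous(self, rng):
        cfg = SimulationConfig(n_hens=200, n_families=40, n_sires=5, n_genotyped=10)
        ped = simulate_pedigree(cfg, rng)
        panel = simulate_genotypes(ped, self.snp_map([0.4, 0.6], ["Z", "Z"]), rng)
        females = ped.table["sex"].to_numpy() == "F"
        assert set(np.unique(panel.calls[females])) <= {0, 2}

    def test_homozygous_parents_transmit_deterministically(self, rng):
        ped = make_pedigree(
            [("S", "", "", "M", 0), ("D", "", "", "F", 0), ("H", "S", "D", "F", 1)]
        )
        hits = 0
        for seed in range(300):
            panel = simulate_genotypes(
                ped, self.snp_map([0.5]), np.random.default_rng(seed)
            )
            s, d, h = panel.calls[:, 0]
            if s == 2 and d == 2:
                assert h == 2
                hits += 1
        assert hits > 5  # the conditioning event occurred

    def test_missing_rate_applied(self, rng):
        cfg = SimulationConfig(n_hens=100, n_families=20, n_sires=4, n_genotyped=10)
        ped = simulate_pedigree(cfg, rng)
        panel = simulate_genotypes(ped, self.snp_map([0.5] * 50), rng, missing_rate=0.2)
        assert abs((panel.calls == -1).mean() - 0.2) < 0.03


class TestBreedingValues:
    def test_zero_variance_gives_zeros(self, rng):
        ped = simulate_pedigree(
            SimulationConfig(n_hens=20, n_families=4, n_sires=2, n_genotyped=5), rng
        )
        assert (simulate_breeding_values(ped, 0.0, rng) == 0).all()

    def test_negative_variance_rejected(self, rng):
        ped = make_pedigree([("S", "", "", "M", 0)])
        with pytest.raises(ValueError):
            simulate_breeding_values(ped, -1.0, rng)

    def test_parent_offspring_and_full_sib_covariance(self):
        # full sibs H1, H2 from unrelated founders
        ped = make_pedigree(
            [
                ("S", "", "", "M", 0),
                ("D", "", "", "F", 0),
                ("H1", "S", "D", "F", 1),
                ("H2", "S", "D", "F", 1),
            ]
        )
        draws = np.array(
            [
                simulate_breeding_values(ped, 1.0, np.random.default_rng(s)).to_numpy()
                for s in range(4000)
            ]
        )
        cov = np.cov(draws.T)
        # cov(parent, offspring) = 0.5; cov(full sibs) = 0.5; var = 1
        assert abs(cov[0, 2] - 0.5) < 0.06
        assert abs(cov[2, 3] - 0.5) < 0.06
        assert abs(cov[2, 2] - 1.0) < 0.08

    def test_covariance_matches_amatrix_on_small_pedigree(self, rng):
        from resgwas.kinship import additive_relationship_matrix

        cfg = SimulationConfig(n_hens=12, n_families=3, n_sires=2, n_genotyped=5)
        ped = simulate_pedigree(cfg, rng)
        A = additive_relationship_matrix(ped).matrix
        draws = np.array(
            [
                simulate_breeding_values(ped, 1.0, np.random.default_rng(s)).to_numpy()
                for s in range(6000)
            ]
        )
        emp = np.cov(draws.T)
        assert np.max(np.abs(emp - A)) < 0.1


class TestNab:
    def test_all_effects_zero_gives_constant_titer(self, rng):
        cfg = SimulationConfig(
            n_hens=30, n_families=6, n_sires=2, n_genotyped=30,
            igm_var=0.0, igg_var=0.0, plate_var=0.0,
            age_effects={112: 0.0, 123: 0.0, 124: 0.0, 138: 0.0},
        )
        ped = simulate_pedigree(cfg, rng)
        zeros = pd.Series(0.0, index=ped.animals)
        nab = simulate_nab_phenotypes(ped, {"IgM": zeros, "IgG": zeros}, cfg, rng)
        igm = nab[nab["isotype"] == "IgM"]
        assert np.allclose(igm["titer"], 6.85)

    def test_realized_heritability_near_target(self, rng):
        cfg = SimulationConfig(n_hens=4000, n_families=800, n_sires=40, n_genotyped=4000)
        ped = simulate_pedigree(cfg, rng)
        a = simulate_breeding_values(ped, cfg.igm_var * cfg.igm_h2, rng)
        nab = simulate_nab_phenotypes(ped, {"IgM": a, "IgG": a}, cfg, rng)
        igm = nab[nab["isotype"] == "IgM"].set_index("hen")
        av = a.reindex(igm.index)
        ratio = av.var() / (av.var() + (igm["titer"] - av).var() - cfg.plate_var)
        assert abs(ratio - 0.39) < 0.06


class TestEggProduction:
    def test_counts_bounded_zero_to_seven(self, small_batch):
        weekly = ind.weekly_production(small_batch.egg_logs, coverage_start=7 * 15)
        vals = weekly.to_numpy()
        vals = vals[~np.isnan(vals)]
        assert vals.min() >= 0 and vals.max() <= 7
        assert np.allclose(vals, vals.astype(int))

    def test_no_disturbance_no_genetics_tracks_anchor_curve(self, rng):
        cfg = SimulationConfig(
            n_hens=600, n_families=120, n_sires=10, n_genotyped=10,
            disturbance_rate=0.0, var_level=0.0, var_persistency=0.0,
            weekly_hazard=0.0,
        )
        ped = simulate_pedigree(cfg, rng)
        zeros = pd.Series(0.0, index=ped.animals)
        logs = simulate_egg_production(ped, zeros, zeros, cfg, rng)
        weekly = ind.weekly_production(logs, coverage_start=7 * 15)
        curve = ind.batch_mean(weekly)
        anchor = batch_anchor_curve(cfg, curve.index.to_numpy())
        for wk in (29, 50, 92):
            assert abs(curve[wk] - anchor[curve.index.get_loc(wk)]) < 0.15

    def test_hens_exchangeable_across_hatch_weeks(self, rng):
        cfg = SimulationConfig(
            n_hens=900, n_families=180, n_sires=10, n_genotyped=10,
            disturbance_rate=0.0, var_level=0.0, var_persistency=0.0,
            weekly_hazard=0.0,
        )
        ped = simulate_pedigree(cfg, rng)
        zeros = pd.Series(0.0, index=ped.animals)
        logs = simulate_egg_production(ped, zeros, zeros, cfg, rng)
        weekly = ind.weekly_production(logs, coverage_start=7 * 15)
        dev = ind.deviations(weekly, ind.batch_mean(weekly))
        table, _ = ind.resilience_indicators(dev, weekly)
        merged = table.merge(
            ped.hens[["animal", "hatch_week"]], left_on="hen", right_on="animal"
        )
        sub = merged[merged["period"] == "25-83"]
        means = sub.groupby("hatch_week")["ln_var"].mean()
        assert means.max() - means.min() < 0.25

    def test_records_stop_at_death(self, small_batch):
        logs = small_batch.egg_logs
        last = logs.records.groupby("hen")["day"].max()
        assert (last <= logs.last_day.reindex(last.index)).all()

    def test_collection_gaps_between_one_and_four_days(self, small_batch):
        rec = small_batch.egg_logs.records
        gaps = rec.groupby("hen")["day"].diff().dropna()
        assert gaps.between(1, 4).all()


class TestReproducibility:
    def test_same_seed_byte_identical(self):
        cfg = SimulationConfig(
            n_hens=80, n_families=16, n_sires=4, n_genotyped=40, n_snps=60
        )
        b1 = simulate_batch(cfg, seed=42)
        b2 = simulate_batch(cfg, seed=42)
        pd.testing.assert_frame_equal(b1.nab, b2.nab)
        pd.testing.assert_frame_equal(b1.egg_logs.records, b2.egg_logs.records)
        assert np.array_equal(b1.panel.calls, b2.panel.calls)
        assert b1.genotyped_hens == b2.genotyped_hens

    def test_snp_map_positions_increasing_within_chromosome(self, rng):
        smap = default_snp_map(SimulationConfig(n_snps=800), rng)
        for _, grp in smap.groupby("chromosome"):
            assert grp["position_bp"].is_monotonic_increasing
            assert grp["position_bp"].is_unique
        assert (smap["founder_freq"] > 0).all() and (smap["founder_freq"] < 1).all()
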