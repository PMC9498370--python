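import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import spearmanr

from sna_qgen import pedigree_kinship as pk
from sna_qgen import synthetic_data as sd

from .conftest import MINI_CONFIG


class TestConfig:
    def test_defaults_mirror_the_study_design(self):
        cfg = sd.SimulationConfig()
        assert cfg.n_offspring == 900 and cfg.n_pens * cfg.pen_size == 900
        assert cfg.n_sires == 116 and cfg.n_dams == 391
        assert cfg.pedigree_total == 4104
        assert cfg.n_founders == 2697

    def test_inconsistent_pen_layout_rejected(self):
        with pytest.raises(ValueError, match="pen_size"):
            sd.SimulationConfig(n_pens=10, pen_size=10, n_offspring=90)


class TestPedigreeSimulation:
    def test_default_pedigree_has_study_size(self):
        ped = sd.simulate_pedigree(sd.SimulationConfig(), seed=1)
        assert ped.n == 4104
        founders = int(((ped.sire == 0) & (ped.dam == 0)).sum())
        assert founders == 2697

    def test_same_seed_reproduces_table(self):
        cfg = sd.SimulationConfig(seed=9, **MINI_CONFIG)
        p1 = sd.simulate_pedigree(cfg)
        p2 = sd.simulate_pedigree(cfg)
        assert p1.labels == p2.labels
        np.testing.assert_array_equal(p1.sire, p2.sire)

    def test_offspring_have_both_parents_and_right_families(self):
        cfg = sd.SimulationConfig(seed=2, **MINI_CONFIG)
        ped = sd.simulate_pedigree(cfg)
        pigs = [i for i, lab in enumerate(ped.labels) if lab.startswith("P")]
        assert len(pigs) == cfg.n_offspring
        assert all(ped.sire[i] and ped.dam[i] for i in pigs)
        dams = {ped.dam[i] for i in pigs}
        assert len(dams) == cfg.n_dams


class TestBreedingValues:
    def test_zero_genetic_variance_gives_zero_values(self):
        ped = sd.simulate_pedigree(sd.SimulationConfig(seed=1, **MINI_CONFIG))
        a = sd.simulate_breeding_values(ped, [[0.0]], seed=3)
        assert (a == 0).all()

    def test_founder_variance_matches_G0(self):
        ped = pk.PedigreeTable.from_records(
            [str(i) for i in range(10_000)], ["0"] * 10_000, ["0"] * 10_000)
        a = sd.simulate_breeding_values(ped, [[1.0]], seed=4)[:, 0]
        assert a.var() == pytest.approx(1.0, abs=0.05)

    def test_parent_offspring_covariance_is_half_G0(self):
        n_trio = 10_000
        labels, sires, dams = [], [], []
        for k in range(n_trio):
            labels += [f"s{k}", f"d{k}", f"o{k}"]
            sires += ["0", "0", f"s{k}"]
            dams += ["0", "0", f"d{k}"]
        ped = pk.PedigreeTable.from_records(labels, sires, dams)
        a = sd.simulate_breeding_values(ped, [[1.0]], seed=5)[:, 0]
        idx = ped.index_of
        s = np.array([a[idx[f"s{k}"] - 1] for k in range(n_trio)])
        o = np.array([a[idx[f"o{k}"] - 1] for k in range(n_trio)])
        assert np.cov(s, o)[0, 1] == pytest.approx(0.5, abs=0.05)
        assert o.var() == pytest.approx(1.0, abs=0.05)

    def test_bivariate_genetic_correlation_realized(self):
        ped = pk.PedigreeTable.from_records(
            [str(i) for i in range(8000)], ["0"] * 8000, ["0"] * 8000)
        G0 = [[1.0, -0.8], [-0.8, 1.0]]
        a = sd.simulate_breeding_values(ped, G0, seed=6)
        assert np.corrcoef(a[:, 0], a[:, 1])[0, 1] == pytest.approx(-0.8, abs=0.03)


class TestPenAssignment:
    def test_study_layout(self, study_metadata):
        cfg, ped, animals, rosters = study_metadata
        assert len(rosters) == 50
        sexes = pd.Series({p: r.sex for p, r in rosters.items()})
        assert (sexes == "female").sum() == 25
        assert all(len(r.members) == 18 for r in rosters.values())
        assert animals["batch"].nunique() == 9
        assert animals["line"].nunique() == 9
        assert (animals["mixing_weight_kg"] > 0).all()

    def test_pens_are_single_sex_across_seeds(self):
        cfg = sd.SimulationConfig(seed=0, **MINI_CONFIG)
        ped = sd.simulate_pedigree(cfg, seed=0)
        for seed in (1, 2, 3):
            animals, _ = sd.assign_pens(ped, cfg, seed=seed)
            assert (animals.groupby("pen_id")["sex"].nunique() == 1).all()
            assert (animals.groupby("pen_id")["batch"].nunique() == 1).all()

    def test_tiny_layout(self):
        cfg = sd.SimulationConfig(n_sires=2, n_dams=2, n_offspring=4,
                                  pedigree_total=12, pen_size=2, n_pens=2,
                                  n_batches=1, n_lines=2, seed=1)
        ped = sd.simulate_pedigree(cfg)
        animals, rosters = sd.assign_pens(ped, cfg, seed=1)
        assert len(rosters) == 2


class TestFightNetwork:
    @staticmethod
    def _rosters(n_pens=20, pen_size=18):
        from sna_qgen.io_formats import PenRoster
        rosters = {}
        k = 0
        for p in range(n_pens):
            members = tuple(f"A{k + i}" for i in range(pen_size))
            k += pen_size
            rosters[f"P{p}"] = PenRoster(f"P{p}", members, "female", "B1")
        return rosters

    def test_neutral_loadings_give_logistic_edge_density(self):
        cfg = sd.SimulationConfig(seed=0, alpha=-2.0, lam=0.0, kappa=0.0)
        rosters = self._rosters()
        latent = {f"A{i}": 0.0 for i in range(20 * 18)}
        recs = sd.simulate_fight_network(rosters, latent, cfg, seed=1)
        n_dyads = 20 * 18 * 17 // 2
        p = expit(-2.0)
        se = np.sqrt(p * (1 - p) / n_dyads)
        assert len(recs) / n_dyads == pytest.approx(p, abs=4 * se)

    def test_hostile_limit_is_empty(self):
        cfg = sd.SimulationConfig(seed=0, alpha=-60.0)
        rosters = self._rosters(n_pens=3)
        latent = {f"A{i}": 0.0 for i in range(3 * 18)}
        assert sd.simulate_fight_network(rosters, latent, cfg, seed=1) == []

    def test_durations_floored_at_one_second(self):
        cfg = sd.SimulationConfig(seed=0, alpha=2.0, mu=-3.0, sigma=0.5)
        rosters = self._rosters(n_pens=2)
        latent = {f"A{i}": 0.0 for i in range(2 * 18)}
        recs = sd.simulate_fight_network(rosters, latent, cfg, seed=2)
        assert recs and all(r.duration >= 1.0 for r in recs)

    def test_aggressive_animals_fight_longer_in_rank(self):
        from sna_qgen import network_traits as nt
        cfg = sd.SimulationConfig(seed=0)
        rosters = self._rosters(n_pens=56, pen_size=18)  # ~1000 animals
        rng = np.random.default_rng(3)
        latent = {f"A{i}": float(u) for i, u in
                  enumerate(rng.normal(0, np.sqrt(2), 56 * 18))}
        recs = sd.simulate_fight_network(rosters, latent, cfg, seed=4)
        traits = nt.traits_from_records(recs, rosters)
        u = np.array([latent[a] for a in traits.index])
        rho = spearmanr(u, traits["weighted_degree"]).statistic
        assert rho > 0.2


class TestPhenotypes:
    def test_noise_free_limit_returns_breeding_values(self, study_metadata):
        cfg, ped, animals, _ = study_metadata
        pheno, truth = sd.simulate_phenotypes(
            ped, animals, {"y": (0.5, 0.0, 0.0)}, seed=1, fixed_effect_sd=0.0)
        idx = [ped.index_of[a] - 1 for a in animals.index]
        np.testing.assert_allclose(
            pheno["y"].to_numpy(),
            truth.breeding_values["y"].to_numpy()[idx], atol=1e-10)

    def test_within_pen_intraclass_correlation(self):
        # unrelated penmates: ICC across penmates ~ c2
        cfg = sd.SimulationConfig(seed=3, **MINI_CONFIG)
        ped = pk.PedigreeTable.from_records(
            [f"P{i + 1}" for i in range(cfg.n_offspring)],
            ["0"] * cfg.n_offspring, ["0"] * cfg.n_offspring)
        animals, _ = sd.assign_pens(ped, cfg, seed=4)
        pheno, _ = sd.simulate_phenotypes(ped, animals, {"y": (0.0, 0.3, 0.7)},
                                          seed=5, fixed_effect_sd=0.0)
        df = animals.join(pheno)
        grand = df["y"].mean()
        nbar = cfg.pen_size
        msb = nbar * df.groupby("pen_id")["y"].mean().var(ddof=1)
        msw = df.groupby("pen_id")["y"].var(ddof=1).mean()
        icc = (msb - msw) / (msb + (nbar - 1) * msw)
        assert icc == pytest.approx(0.3, abs=0.12)

    def test_same_seed_reproduces_table(self, study_metadata):
        cfg, ped, animals, _ = study_metadata
        p1, _ = sd.simulate_phenotypes(ped, animals, {"y": (0.3, 0.1, 0.6)}, seed=6)
        p2, _ = sd.simulate_phenotypes(ped, animals, {"y": (0.3, 0.1, 0.6)}, seed=6)
        pd.testing.assert_frame_equal(p1, p2)


class TestStudyBundle:
    def test_study_bundle_is_complete_and_fe_derived(self, mini_study):
        study = mini_study
        assert study.pedigree.n == MINI_CONFIG["pedigree_total"]
        assert len(study.animals) == MINI_CONFIG["n_offspring"]
        assert set(sd.PERFORMANCE_DEFAULTS) | {"FE"} == \
            set(study.performance.columns)
        ratio = study.performance["TDG"] / study.performance["DFI"]
        pd.testing.assert_series_equal(study.performance["FE"], ratio,
                                       check_names=False)

    def test_write_study_emits_loadable_csvs(self, mini_study, tmp_path):
        from sna_qgen import io_formats as io
        paths = sd.write_study(mini_study, tmp_path)
        animals = io.read_animals(paths["animals"])
        rosters = io.rosters_from_animals(animals)
        recs = io.read_fight_records(paths["fights"], rosters)
        ped = io.read_pedigree(paths["pedigree"])
        assert len(recs) == len(mini_study.fights)
        assert ped.n == mini_study.pedigree.n
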