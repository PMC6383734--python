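"""Synthetic population generator: structure, truth pedigree, observation
model and the negative-binomial offspring-count marginal."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hatchboost as hb
from hatchboost import BetaConfig, SimConfig


class TestStructure:
    def test_same_seed_reproduces_exactly(self):
        cfg = SimConfig(n_years=8, founders_per_year=60, n_loci=20, seed=4)
        a_ind, a_gm, a_truth = hb.simulate_population(cfg)
        b_ind, b_gm, b_truth = hb.simulate_population(cfg)
        pd.testing.assert_frame_equal(a_ind, b_ind)
        pd.testing.assert_frame_equal(a_truth, b_truth)
        assert np.array_equal(a_gm.calls, b_gm.calls)

    def test_broodstock_pair_cap(self, small_sim):
        cfg, individuals, _, _ = small_sim
        per_year = individuals[individuals["broodstock"]].groupby(
            "return_year").size()
        assert (per_year <= 2 * cfg.max_broodstock_pairs).all()

    def test_age_consistent_pedigree(self, small_sim):
        _, individuals, _, truth = small_sim
        meta = individuals.set_index("id")
        linked = truth[truth["mother_id"].notna()]
        for rec in linked.sample(min(len(linked), 400), random_state=0).itertuples():
            child = meta.loc[rec.individual_id]
            mom = meta.loc[rec.mother_id]
            dad = meta.loc[rec.father_id]
            # both parents spawned in the same year, 3-5 years before return
            assert mom["return_year"] == dad["return_year"]
            assert child["return_year"] - mom["return_year"] in (3, 4, 5)
            assert child["return_year"] - mom["return_year"] == child["age"]

    def test_origin_matches_broodstock_parentage(self, small_sim):
        _, individuals, _, truth = small_sim
        bs = set(individuals.loc[individuals["broodstock"], "id"])
        linked = truth[truth["mother_id"].notna()]
        hor = linked["origin"] == "HOR"
        assert (linked.loc[hor, "mother_id"].isin(bs)).all()
        assert (linked.loc[hor, "father_id"].isin(bs)).all()
        assert (~linked.loc[~hor, "mother_id"].isin(bs)).all()

    def test_broodstock_are_natural_origin(self, small_sim):
        _, individuals, _, _ = small_sim
        assert (individuals.loc[individuals["broodstock"], "origin"]
                == "NOR").all()

    def test_generations_acyclic(self, small_sim):
        _, individuals, _, truth = small_sim
        gen = truth.set_index("individual_id")["generation"]
        linked = truth[truth["mother_id"].notna()]
        assert (gen[linked["individual_id"]].to_numpy()
                > np.maximum(gen[linked["mother_id"]].to_numpy(),
                             gen[linked["father_id"]].to_numpy()) - 1).all()

    def test_rare_classes_absent(self, small_sim):
        _, individuals, _, _ = small_sim
        assert individuals["age"].isin([3, 4, 5]).all()
        assert not ((individuals["age"] == 3)
                    & (individuals["sex"] == "F")).any()

    def test_length_age_correlation(self, small_sim):
        _, individuals, _, _ = small_sim
        r = np.corrcoef(individuals["age"], individuals["body_length_mm"])[0, 1]
        assert 0.5 < r < 0.9

    def test_population_crash_raises(self):
        with pytest.raises(hb.PopulationCrashError):
            hb.simulate_population(SimConfig(n_years=3, founders_per_year=0,
                                             n_loci=5))


class TestMendelianTransmission:
    def test_error_free_offspring_have_zero_mismatches(self, clean_parentage_sim):
        _, individuals, gm, truth = clean_parentage_sim
        linked = truth[truth["mother_id"].notna()]
        for rec in linked.sample(min(len(linked), 200), random_state=1).itertuples():
            mm = hb.count_mismatches(gm.row(rec.individual_id),
                                     gm.row(rec.mother_id),
                                     gm.row(rec.father_id))
            assert mm == 0


class TestObservationModel:
    def test_full_sampling_is_identity(self, small_sim):
        cfg, individuals, gm, _ = small_sim
        cfg1 = SimConfig(**{**cfg.to_dict(),
                            "beta": cfg.beta, "sampling_rate": 1.0})
        obs_ind, obs_gm = hb.apply_observation_model(individuals, gm, cfg1)
        assert list(obs_ind["id"]) == list(individuals["id"])

    def test_half_error_on_homozygotes_gives_half_heterozygotes(self):
        # flipping each of two alleles independently with p=0.5 turns a
        # homozygote into a heterozygote with probability 2*0.5*0.5 = 0.5
        cfg = SimConfig(n_years=3, founders_per_year=10, n_loci=2,
                        sampling_rate=1.0, per_allele_error=0.5,
                        missing_rate=0.0, seed=9)
        n, L = 400, 50
        ind = pd.DataFrame({"id": [f"i{k}" for k in range(n)]})
        gm = hb.GenotypeMatrix(
            np.array([f"i{k}" for k in range(n)], dtype=object),
            np.array([f"L{j}" for j in range(L)], dtype=object),
            np.zeros((n, L)))
        _, obs = hb.apply_observation_model(ind, gm, cfg, seed=2)
        het = (obs.calls == 1.0).mean()
        assert het == pytest.approx(0.5, abs=0.02)

    def test_missing_rate(self):
        cfg = SimConfig(n_years=3, founders_per_year=10, n_loci=2,
                        sampling_rate=1.0, per_allele_error=0.0,
                        missing_rate=0.10, seed=9)
        n, L = 200, 50  # 10,000 calls
        ind = pd.DataFrame({"id": [f"i{k}" for k in range(n)]})
        gm = hb.GenotypeMatrix(
            np.array([f"i{k}" for k in range(n)], dtype=object),
            np.array([f"L{j}" for j in range(L)], dtype=object),
            np.ones((n, L)))
        _, obs = hb.apply_observation_model(ind, gm, cfg, seed=3)
        frac = np.isnan(obs.calls).mean()
        assert 0.08 <= frac <= 0.12  # P(outside) < 1e-3 for Bin(1e4, 0.1)


class TestOffspringCountDistribution:
    def test_negative_binomial_marginal(self, null_beta):
        """Per-female offspring counts in one spawn year, with covariate
        effects off, follow a negative binomial with the configured theta
        (chi-square GOF, alpha = 0.01, n >= 2000)."""
        cfg = SimConfig(n_years=6, founders_per_year=4200, carrying_k=2100,
                        n_loci=2, seed=21, beta=null_beta,
                        max_broodstock_pairs=0)
        individuals, _, truth = hb.simulate_population(cfg)
        meta = individuals.set_index("id")
        year = cfg.first_year  # offspring of this spawn year all observable
        mothers = meta[(meta["return_year"] == year) & (meta["sex"] == "F")]
        linked = truth[truth["mother_id"].isin(mothers.index)]
        counts = (linked.groupby("mother_id").size()
                  .reindex(mothers.index, fill_value=0).to_numpy())
        assert counts.size >= 2000
        theta = cfg.nb_dispersion
        mu = counts.mean()
        p = theta / (theta + mu)
        kmax = int(np.quantile(counts, 0.99)) + 1
        probs = stats.nbinom.pmf(np.arange(kmax), theta, p)
        probs = np.append(probs, 1 - probs.sum())
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        keep = probs * counts.size >= 5
        chi2 = (((obs[keep] - probs[keep] * counts.size) ** 2)
                / (probs[keep] * counts.size)).sum()
        dof = keep.sum() - 2  # mu estimated, theta fixed
        pval = stats.chi2.sf(chi2, dof)
        assert pval > 0.01
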