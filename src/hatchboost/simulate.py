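"""Synthetic supplemented-population generator.

Simulates a multi-year salmon population under a hatchery supplementation
program with 100% natural-origin broodstock: each year, up to a fixed
number of natural-origin (NOR) pairs are removed at the weir and spawned in
the hatchery (their progeny are hatchery-origin, HOR, and enjoy a juvenile
survival advantage), while all remaining returns spawn naturally. Offspring
counts per female are negative-binomial with log-linear covariate effects;
fathers are drawn by weighted random mating. Fish return to spawn at ages
3-5 (age-3 females effectively absent), with age-dependent body length and
a bimodal return-day distribution.

The generator returns the full truth (pedigree, error-free genotypes,
phenotypes); :func:`apply_observation_model` then produces the imperfectly
sampled, error-injected dataset that the analysis stages see.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig
from .genotypes import GenotypeMatrix

INDIVIDUAL_COLUMNS = [
    "id", "return_year", "sex", "age", "origin", "broodstock",
    "body_length_mm", "return_day",
]
TRUTH_COLUMNS = [
    "individual_id", "mother_id", "father_id", "generation",
    "was_broodstock", "origin",
]


class PopulationCrashError(RuntimeError):
    """Raised when a simulated year contains no potential spawners."""


def _draw_ages(rng, sexes, age_probs):
    ages = np.empty(len(sexes), dtype=int)
    for sex in ("M", "F"):
        mask = sexes == sex
        probs = age_probs[sex]
        support = np.array(sorted(probs))
        p = np.array([probs[a] for a in support], dtype=float)
        ages[mask] = rng.choice(support, size=mask.sum(), p=p / p.sum())
    return ages


def _draw_return_days(rng, n, modes):
    (m1, s1), (m2, s2), w = modes
    pick = rng.random(n) < w
    days = np.where(pick, rng.normal(m1, s1, n), rng.normal(m2, s2, n))
    return np.clip(np.rint(days), 1, 366).astype(int)


def _mendelian_offspring(rng, g_mother, g_father, n):
    """Draw n offspring genotypes (ref-allele counts) from two parents."""
    L = g_mother.size
    a = rng.random((n, L)) < g_mother / 2.0
    b = rng.random((n, L)) < g_father / 2.0
    return (a.astype(np.int8) + b.astype(np.int8))


class _Builder:
    """Accumulates individuals while the year loop runs."""

    def __init__(self):
        self.rows = []
        self.genos = []
        self.serial = 0

    def add(self, year, sex, age, origin, broodstock, length, day,
            mother, father, generation, geno):
        self.serial += 1
        iid = f"FISH{self.serial:06d}"
        self.rows.append((iid, year, sex, age, origin, broodstock,
                          length, day, mother, father, generation))
        self.genos.append(geno)
        return iid


def simulate_population(config: SimConfig):
    """Simulate the full (truth-level) population.

    Returns
    -------
    individuals : DataFrame
        One row per fish: id, return_year, sex, age, origin, broodstock,
        body_length_mm, return_day.
    genotypes : GenotypeMatrix
        Error-free Mendelian genotypes for every fish.
    truth : DataFrame
        Truth pedigree: individual_id, mother_id, father_id, generation,
        was_broodstock, origin.

    Raises
    ------
    PopulationCrashError
        If any return year contains no potential spawners.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.allele_freq_range
    freqs = rng.uniform(lo, hi, config.n_loci)
    beta = config.beta
    year_effects = rng.normal(0.0, beta.year_sd, config.n_years)
    last_year = config.first_year + config.n_years - 1

    b = _Builder()
    by_year: dict[int, list[int]] = {y: [] for y in
                                     range(config.first_year, last_year + 1)}

    def register(idx_list, year, **kw):
        iid = b.add(year=year, **kw)
        idx_list.append(len(b.rows) - 1)
        return iid

    # founder injection over the first five return years (the span of
    # parental brood years feeding any later return year)
    n_founder_years = min(5, config.n_years)
    for y in range(config.first_year, config.first_year + n_founder_years):
        n = config.founders_per_year
        sexes = np.where(rng.random(n) < 0.5, "F", "M").astype(object)
        ages = _draw_ages(rng, sexes, config.age_probs)
        days = _draw_return_days(rng, n, config.return_day_modes)
        for k in range(n):
            geno = (rng.random((2, config.n_loci)) < freqs).sum(0).astype(np.int8)
            length = rng.normal(config.length_by_age[ages[k]], config.length_sd)
            register(by_year[y], y, sex=sexes[k], age=int(ages[k]),
                     origin="NOR", broodstock=False, length=length,
                     day=int(days[k]), mother=None, father=None,
                     generation=0, geno=geno)

    rows = b.rows  # live reference; tuples appended as we go

    def row(i):
        return rows[i]

    def z_length(i):
        r = rows[i]
        return (r[6] - config.length_by_age[r[3]]) / config.length_sd

    def z_day(i):
        (m1, s1), (m2, s2), w = config.return_day_modes
        mean = w * m1 + (1 - w) * m2
        var = w * (s1 ** 2 + m1 ** 2) + (1 - w) * (s2 ** 2 + m2 ** 2) - mean ** 2
        return (rows[i][7] - mean) / np.sqrt(var)

    def log_predictor(i):
        r = rows[i]
        eta = beta.body_length * z_length(i) + beta.return_day * z_day(i)
        if r[4] == "NOR":
            eta += beta.origin_nor
        return eta

    def spawn_offspring(year, mother_i, father_i, mu, origin):
        theta = config.nb_dispersion
        n = rng.negative_binomial(theta, theta / (theta + mu)) if mu > 0 else 0
        if n == 0:
            return
        gm, gf = b.genos[mother_i], b.genos[father_i]
        kid_genos = _mendelian_offspring(rng, gm, gf, n)
        sexes = np.where(rng.random(n) < 0.5, "F", "M").astype(object)
        ages = _draw_ages(rng, sexes, config.age_probs)
        days = _draw_return_days(rng, n, config.return_day_modes)
        gen = max(rows[mother_i][10], rows[father_i][10]) + 1
        for k in range(n):
            ret = year + int(ages[k])
            if ret > last_year:
                continue  # returns after the study horizon are unobserved
            length = rng.normal(config.length_by_age[ages[k]], config.length_sd)
            register(by_year[ret], ret, sex=sexes[k], age=int(ages[k]),
                     origin=origin, broodstock=False, length=length,
                     day=int(days[k]), mother=rows[mother_i][0],
                     father=rows[father_i][0], generation=gen,
                     geno=kid_genos[k])

    broodstock_flags = {}

    for y in range(config.first_year, last_year + 1):
        returners = by_year[y]
        if not returners:
            raise PopulationCrashError(
                f"return year {y} has zero potential spawners; the population "
                "crashed under the chosen parameters"
            )
        females = [i for i in returners if rows[i][2] == "F"]
        males = [i for i in returners if rows[i][2] == "M"]

        # broodstock: NOR adults (age >= 4), up to max pairs, random choice
        bs_f = [i for i in females if rows[i][4] == "NOR" and rows[i][3] >= 4]
        bs_m = [i for i in males if rows[i][4] == "NOR" and rows[i][3] >= 4]
        n_pairs = min(config.max_broodstock_pairs, len(bs_f), len(bs_m))
        pair_f = list(rng.choice(bs_f, n_pairs, replace=False)) if n_pairs else []
        pair_m = list(rng.choice(bs_m, n_pairs, replace=False)) if n_pairs else []
        for i in pair_f + pair_m:
            broodstock_flags[i] = True
        taken = set(pair_f) | set(pair_m)

        nat_f = [i for i in females if i not in taken]
        nat_m = [i for i in males if i not in taken]

        dd = 1.0 / (1.0 + len(nat_f) / config.carrying_k)
        base_mu = (config.max_offspring_per_female * dd
                   * np.exp(year_effects[y - config.first_year]))

        # hatchery production: pair means scale with the juvenile survival
        # multiplier; no individual covariate effects (artificial spawning)
        for fi, mi in zip(pair_f, pair_m):
            spawn_offspring(y, fi, mi, base_mu *
                            config.hatchery_survival_multiplier, "HOR")

        # natural production: weighted random mating, one mate per female
        if nat_f and nat_m:
            w = np.exp([log_predictor(i) for i in nat_m])
            w /= w.sum()
            fathers = rng.choice(nat_m, size=len(nat_f), p=w)
            for fi, mi in zip(nat_f, fathers):
                spawn_offspring(y, fi, int(mi), base_mu *
                                np.exp(log_predictor(fi)), "NOR")

    individuals = pd.DataFrame(
        rows, columns=INDIVIDUAL_COLUMNS + ["mother_id", "father_id",
                                            "generation"],
    )
    individuals["broodstock"] = [
        broodstock_flags.get(i, False) for i in range(len(rows))
    ]
    truth = pd.DataFrame({
        "individual_id": individuals["id"],
        "mother_id": individuals.pop("mother_id"),
        "father_id": individuals.pop("father_id"),
        "generation": individuals.pop("generation"),
        "was_broodstock": individuals["broodstock"],
        "origin": individuals["origin"],
    })
    gm = GenotypeMatrix(
        individuals["id"].to_numpy(dtype=object),
        np.array([f"L{j:04d}" for j in range(config.n_loci)], dtype=object),
        np.asarray(b.genos, dtype=float),
    )
    return individuals, gm, truth


def apply_observation_model(individuals: pd.DataFrame, genotypes: GenotypeMatrix,
                            config: SimConfig, seed: int | None = None):
    """Thin the truth through the sampling and genotyping process.

    Each fish is sampled independently with probability
    ``config.sampling_rate``; each observed allele flips with probability
    ``config.per_allele_error``; each genotype call is masked (missing)
    with probability ``config.missing_rate``. Truth linkage is untouched
    (identifiers are preserved), so simulated results can be scored.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = len(individuals)
    keep = rng.random(n) < config.sampling_rate
    obs_ind = individuals.loc[keep].reset_index(drop=True)
    gm = genotypes.subset(individuals=obs_ind["id"].tolist())

    g = gm.calls.astype(int)
    eps = config.per_allele_error
    if eps > 0:
        ref_kept = rng.binomial(g, 1.0 - eps)
        alt_flipped = rng.binomial(2 - g, eps)
        g = ref_kept + alt_flipped
    calls = g.astype(float)
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = np.nan
    return obs_ind, GenotypeMatrix(gm.individual_ids, gm.locus_ids, calls)


@dataclass
class SimulatedDataset:
    """Truth plus observed views of one simulated population."""

    config: SimConfig
    individuals: pd.DataFrame      # truth-level metadata, all fish
    genotypes: GenotypeMatrix      # error-free genotypes, all fish
    truth: pd.DataFrame            # truth pedigree
    obs_individuals: pd.DataFrame  # sampled fish only
    obs_genotypes: GenotypeMatrix  # with error + missingness


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the generator and the observation model in one call."""
    individuals, gm, truth = simulate_population(config)
    obs_ind, obs_gm = apply_observation_model(individuals, gm, config)
    return SimulatedDataset(config, individuals, gm, truth, obs_ind, obs_gm)


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write the observed tables and the truth pedigree as CSV."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds.obs_individuals.to_csv(out / "individuals.csv", index=False)
    ds.obs_genotypes.write_csv(out / "genotypes.csv")
    ds.truth[["individual_id", "mother_id", "father_id"]].to_csv(
        out / "truth_pedigree.csv", index=False)
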