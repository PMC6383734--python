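"""Simulation configuration for a supplemented salmon population.

The defaults emulate the program structure the analysis assumes: a 19-year
run of returns, up to 40 natural-origin broodstock pairs per year, a
hatchery juvenile survival advantage of roughly 4.5x, negative-binomially
distributed offspring counts with log-linear covariate effects, a bimodal
return-day distribution, ~93% sampling efficiency and a realized per-allele
genotyping error well below the 1% assumed downstream by the parentage
likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Tuple


@dataclass
class BetaConfig:
    """Log-linear effects on expected offspring number.

    All continuous effects are per within-class standard unit (body length
    is centred within age class, return day within year), so their scale is
    comparable across ages and years.

    Attributes
    ----------
    year_sd : float
        SD of the random per-year log-scale effect shared by all spawners
        of a spawn year (brood-year quality).
    origin_nor : float
        Log advantage of natural-origin over hatchery-origin naturally
        spawning fish. 0 means no origin effect.
    body_length : float
        Effect per within-age-class SD of body length.
    return_day : float
        Effect per overall SD of return day (negative = late fish do worse).
    """

    year_sd: float = 0.5
    origin_nor: float = 0.15
    body_length: float = 0.3
    return_day: float = -0.1


@dataclass
class SimConfig:
    """Parameters of the synthetic supplemented-population generator."""

    n_years: int = 19
    first_year: int = 1998
    n_loci: int = 290
    allele_freq_range: Tuple[float, float] = (0.2, 0.8)
    max_broodstock_pairs: int = 40
    hatchery_survival_multiplier: float = 4.5
    #: sex -> {age: probability}; age-3 females are effectively absent.
    age_probs: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {
            "M": {3: 0.25, 4: 0.55, 5: 0.20},
            "F": {3: 0.0, 4: 0.60, 5: 0.40},
        }
    )
    nb_dispersion: float = 0.7  # theta of the negative binomial
    beta: BetaConfig = field(default_factory=BetaConfig)
    sampling_rate: float = 0.93
    #: realized per-allele miscall probability (QC-concordance scale error,
    #: an order of magnitude below the 1% the parentage likelihood assumes).
    per_allele_error: float = 0.001
    missing_rate: float = 0.02
    #: two (mean, sd) pairs plus the weight of the first mode.
    return_day_modes: Tuple[Tuple[float, float], Tuple[float, float], float] = (
        (190.0, 8.0), (215.0, 8.0), 0.45,
    )
    seed: int = 0

    # population-dynamics knobs (abundance is a free parameter)
    founders_per_year: int = 250  # injected in the first 5 return years
    max_offspring_per_female: float = 4.0  # density-free expected returners
    carrying_k: float = 125.0  # females at which fecundity halves

    # phenotype model
    length_by_age: Mapping[int, float] = field(
        default_factory=lambda: {3: 560.0, 4: 780.0, 5: 870.0}
    )
    length_sd: float = 45.0

    def __post_init__(self) -> None:
        for sex, probs in self.age_probs.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"age_probs[{sex!r}] sums to {total}, not 1")
            if any(a not in (3, 4, 5) for a in probs):
                raise ValueError("return ages are restricted to {3, 4, 5}")
        for name in ("sampling_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.per_allele_error < 1.0:
            raise ValueError("per_allele_error must lie in [0, 1)")
        if self.hatchery_survival_multiplier <= 0:
            raise ValueError("hatchery_survival_multiplier must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion (theta) must be positive")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele_freq_range must lie inside (0, 1)")
        if self.n_years < 1 or self.n_loci < 1:
            raise ValueError("n_years and n_loci must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "beta" in d and isinstance(d["beta"], Mapping):
            d["beta"] = BetaConfig(**d["beta"])
        if "age_probs" in d:
            d["age_probs"] = {
                sex: {int(a): float(p) for a, p in probs.items()}
                for sex, probs in d["age_probs"].items()
            }
        if "length_by_age" in d:
            d["length_by_age"] = {
                int(a): float(v) for a, v in d["length_by_age"].items()
            }
        if "allele_freq_range" in d:
            d["allele_freq_range"] = tuple(d["allele_freq_range"])
        if "return_day_modes" in d:
            m1, m2, w = d["return_day_modes"]
            d["return_day_modes"] = (tuple(m1), tuple(m2), float(w))
        return cls(**d)
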