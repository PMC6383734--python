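"""Relative reproductive success and demographic-boost statistics.

RRS is the ratio of mean reproductive success (RS) of a focal group to a
reference group (hatchery vs natural origin, or cross types against
N x N). Confidence intervals use the delta method for a ratio of two
independent sample means:

    Var(R) ~= Var(x_num) / mean_den^2 + mean_num^2 Var(x_den) / mean_den^4

with Var(x) = s^2 / n, giving R +/- 1.96 SE floored at 0 — a linear-scale
interval that can span 0 like the published error bars. The demographic
boost compares broodstock against natural spawners over one generation
(F0DB) and, after removing F1 fish recycled into broodstock, over two
(F1DB = F0DB x RRS of F1 hatchery- vs natural-origin natural spawners).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959963984540054


@dataclass
class RatioEstimate:
    """A ratio-of-means statistic with a delta-method 95% CI."""

    ratio: float
    ci_low: float
    ci_high: float
    se: float
    mean_num: float
    mean_den: float
    n_num: int
    n_den: int
    estimand: str = "all_candidates"
    stratum: dict = field(default_factory=dict)
    defined: bool = True

    @property
    def excludes_one(self) -> bool:
        """Whether the 95% CI excludes 1.0 (the no-difference value)."""
        return self.defined and (self.ci_high < 1.0 or self.ci_low > 1.0)

    def to_dict(self):
        d = {"ratio": self.ratio, "ci_low": self.ci_low,
             "ci_high": self.ci_high, "se": self.se,
             "mean_num": self.mean_num, "mean_den": self.mean_den,
             "n_num": self.n_num, "n_den": self.n_den,
             "estimand": self.estimand, "defined": self.defined}
        d.update(self.stratum)
        return d


def _undefined(estimand, stratum) -> RatioEstimate:
    return RatioEstimate(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                         0, 0, estimand, stratum or {}, defined=False)


def delta_ratio_ci(num, den) -> tuple[float, float, float, float]:
    """(ratio, se, lo, hi) for the ratio of the two sample means."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    xn, xd = num.mean(), den.mean()
    vn = num.var(ddof=1) / num.size if num.size > 1 else 0.0
    vd = den.var(ddof=1) / den.size if den.size > 1 else 0.0
    r = xn / xd
    var = vn / xd ** 2 + (xn ** 2) * vd / xd ** 4
    se = float(np.sqrt(var))
    return r, se, max(0.0, r - Z95 * se), r + Z95 * se


def rrs(rs_num, rs_den, estimand: str = "all_candidates",
        stratum: dict | None = None) -> RatioEstimate:
    """Relative reproductive success: mean(rs_num) / mean(rs_den).

    Under ``successful_only``, zero-RS individuals are dropped from both
    groups before averaging. Empty groups or a zero denominator mean give
    an undefined estimate (flagged, not an exception), mirroring dropped
    low-sample strata.
    """
    if estimand not in ("all_candidates", "successful_only"):
        raise ValueError(f"unknown estimand: {estimand!r}")
    num = np.asarray(list(rs_num), dtype=float)
    den = np.asarray(list(rs_den), dtype=float)
    if estimand == "successful_only":
        num, den = num[num > 0], den[den > 0]
    if num.size == 0 or den.size == 0 or den.mean() == 0:
        return _undefined(estimand, stratum)
    r, se, lo, hi = delta_ratio_ci(num, den)
    return RatioEstimate(r, lo, hi, se, num.mean(), den.mean(),
                         num.size, den.size, estimand, stratum or {})


def f0_db(rs_broodstock, rs_natural, stratum: dict | None = None) -> RatioEstimate:
    """First-generation demographic boost: mean broodstock RS over mean
    natural-spawner RS (sexes and jacks combined)."""
    est = rrs(rs_broodstock, rs_natural, "all_candidates", stratum)
    est.estimand = "f0_db"
    return est


def f1_db(f0: RatioEstimate, rs_hor, rs_nor,
          stratum: dict | None = None) -> RatioEstimate:
    """Second-generation demographic boost: F0DB times the RRS of F1
    hatchery- versus natural-origin natural spawners (broodstock-removed
    RS lists). The CI combines the two independent ratios by the delta
    method for a product."""
    if not f0.defined:
        return _undefined("f1_db", stratum)
    r2 = rrs(rs_hor, rs_nor, "all_candidates")
    if not r2.defined:
        return _undefined("f1_db", stratum)
    ratio = f0.ratio * r2.ratio
    var = (r2.ratio ** 2) * f0.se ** 2 + (f0.ratio ** 2) * r2.se ** 2
    se = float(np.sqrt(var))
    return RatioEstimate(ratio, max(0.0, ratio - Z95 * se), ratio + Z95 * se,
                         se, r2.mean_num, r2.mean_den, r2.n_num, r2.n_den,
                         "f1_db", stratum or {})


def group_mean_test(rs_a, rs_b) -> float:
    """One-way two-group ANOVA p-value for equal mean RS (equivalent to a
    pooled-variance t-test). Degenerate zero-variance groups: p = 1 when
    the means are equal, p = 0 otherwise."""
    a = np.asarray(list(rs_a), dtype=float)
    b = np.asarray(list(rs_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if a.var() == 0 and b.var() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    f, p = stats.f_oneway(a, b)
    return float(p)


def cross_factor_test(rs_by_cross: dict) -> float:
    """One-way ANOVA over the 4-level cross-type factor."""
    groups = [np.asarray(v, dtype=float) for v in rs_by_cross.values()
              if len(v) > 0]
    if len(groups) < 2:
        raise ValueError("need at least two nonempty cross groups")
    return float(stats.f_oneway(*groups)[1])


# ---------------------------------------------------------------------
# Stratified summaries

SEX_CLASSES = {
    "female": lambda df: (df["sex"] == "F") & df["age"].isin([4, 5]),
    "male": lambda df: (df["sex"] == "M") & df["age"].isin([4, 5]),
    "jack": lambda df: (df["sex"] == "M") & (df["age"] == 3),
}


def yearly_summary(fitness: pd.DataFrame,
                   estimands=("all_candidates", "successful_only"),
                   rs_column: str = "rs") -> pd.DataFrame:
    """Per return-year x sex-class x estimand RRS of naturally spawning
    hatchery- versus natural-origin fish.

    ``fitness`` must carry return_year, sex, age, origin, broodstock,
    ``rs_column`` and the ``include_rrs`` flag. Broodstock are not natural
    spawners and are excluded. Empty or undefined strata are flagged via
    the ``defined`` column, never dropped silently.
    """
    df = fitness[fitness["include_rrs"] & ~fitness["broodstock"].astype(bool)]
    rows = []
    for year in sorted(df["return_year"].unique()):
        sub_y = df[df["return_year"] == year]
        for cls, selector in SEX_CLASSES.items():
            sub = sub_y[selector(sub_y)]
            hor = sub.loc[sub["origin"] == "HOR", rs_column]
            nor = sub.loc[sub["origin"] == "NOR", rs_column]
            for estimand in estimands:
                stratum = {"return_year": year, "sex_class": cls}
                est = rrs(hor, nor, estimand, stratum)
                rec = est.to_dict()
                if len(hor) and len(nor):
                    rec["p_value"] = group_mean_test(hor, nor)
                else:
                    rec["p_value"] = np.nan
                rows.append(rec)
    return pd.DataFrame(rows)


def across_year_means(summary: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of yearly RRS values per sex class x estimand
    (matching how yearly ranges with means are reported)."""
    ok = summary[summary["defined"]]
    return (ok.groupby(["sex_class", "estimand"])["ratio"]
              .agg(["mean", "min", "max", "count"]).reset_index())


FOCAL_CROSS = {
    # contrast -> (focal cross by sex, reference cross)
    "HH_vs_NN": ({"female": "HH", "male": "HH"}, "NN"),
    "HN_vs_NN": ({"female": "HN", "male": "NH"}, "NN"),
    "HH_vs_HN": ({"female": "HH", "male": "HH"},
                 {"female": "HN", "male": "NH"}),
}


def _cross_rs(fitness, crosses, cross_label, parent_col, generations,
              pedigree=None, broodstock_ids=None):
    """Per-parent offspring (or grand-offspring) counts through offspring
    of one cross type; parents with zero such offspring are not listed
    (successful-cross framing)."""
    sub = crosses[crosses["cross"] == cross_label]
    if generations == 1:
        return sub.groupby(parent_col).size()
    bs = set(broodstock_ids or [])
    counts = {}
    for rec in sub.itertuples():
        parent = getattr(rec, parent_col)
        child = rec.offspring_id
        if child in bs:
            continue
        counts[parent] = counts.get(parent, 0) + len(pedigree.children(child))
    return pd.Series(counts, dtype=float)


def cross_rrs(fitness: pd.DataFrame, crosses: pd.DataFrame, contrast: str,
              generations: int = 1, sex: str = "female",
              pedigree=None, broodstock_ids=None, by_year: bool = False):
    """RRS between cross types, one or two generations, per parent sex.

    The numerator (and denominator) lists are per-parent counts of
    offspring produced in the focal (reference) cross type, restricted to
    parents that actually participated in that cross; jacks never enter
    (the cross tables are built from the jack-excluded cohort). For
    ``generations=2`` the counts are grand-offspring through offspring of
    the cross type, with F1 broodstock removed from the path
    (``pedigree`` and ``broodstock_ids`` required).

    With ``by_year=True`` returns a DataFrame of per-spawn-year estimates;
    otherwise a single pooled :class:`RatioEstimate`.
    """
    if contrast not in FOCAL_CROSS:
        raise ValueError(f"unknown contrast: {contrast!r}")
    if generations == 2 and pedigree is None:
        raise ValueError("generations=2 requires the pedigree")
    focal_map, ref = FOCAL_CROSS[contrast]
    focal = focal_map[sex]
    ref_label = ref if isinstance(ref, str) else ref[sex]
    parent_col = "mother_id" if sex == "female" else "father_id"

    # natural matings only: hatchery (broodstock) pairs are not crosses,
    # and jacks (plus the rare excluded classes) never enter cross analyses
    meta = fitness.set_index("id")
    eligible = set(meta.index[meta["include_cross"]
                              & ~meta["broodstock"].astype(bool)])
    crosses = crosses[crosses["mother_id"].isin(eligible)
                      & crosses["father_id"].isin(eligible)]

    def estimate(cr, stratum):
        num = _cross_rs(fitness, cr, focal, parent_col, generations,
                        pedigree, broodstock_ids)
        den = _cross_rs(fitness, cr, ref_label, parent_col, generations,
                        pedigree, broodstock_ids)
        est = rrs(num, den, "successful_only", stratum)
        est.estimand = f"cross_{contrast}_gen{generations}"
        return est

    if not by_year:
        return estimate(crosses, {"sex": sex, "contrast": contrast})
    rows = []
    for year in sorted(crosses["spawn_year"].dropna().unique()):
        est = estimate(crosses[crosses["spawn_year"] == year],
                       {"sex": sex, "contrast": contrast,
                        "spawn_year": int(year)})
        rows.append(est.to_dict())
    return pd.DataFrame(rows)


def demographic_boost_by_year(fitness: pd.DataFrame, pedigree,
                              brood_years=None,
                              rs_column: str = "rs") -> pd.DataFrame:
    """Per-brood-year F0 and F1 demographic boost.

    For each brood (return) year, F0DB compares broodstock RS with
    natural-spawner RS (sexes and jacks combined); F1DB multiplies it by
    the RRS of F1 hatchery- vs natural-origin natural spawners descending
    from that brood year, with F1 broodstock removed. ``fitness`` must be
    the full table (the F1 generation is looked up in it); ``brood_years``
    restricts which years are evaluated. Years with no broodstock are
    flagged undefined.
    """
    rows = []
    meta = fitness.set_index("id")
    if brood_years is None:
        brood_years = sorted(fitness["return_year"].unique())
    for year in brood_years:
        sub = fitness[fitness["return_year"] == year]
        bs = sub[sub["broodstock"].astype(bool)]
        ns = sub[~sub["broodstock"].astype(bool) & (sub["origin"] == "NOR")]
        stratum = {"brood_year": int(year)}
        if len(bs) == 0 or len(ns) == 0:
            f0 = _undefined("f0_db", stratum)
            f1 = _undefined("f1_db", stratum)
        else:
            f0 = f0_db(bs[rs_column], ns[rs_column], stratum)
            # F1 natural spawners descending from this brood year
            f1_ids = [c for p in pd.concat([bs, ns])["id"]
                      for c in pedigree.children(p)]
            f1_meta = meta.loc[[i for i in set(f1_ids) if i in meta.index]]
            f1_nat = f1_meta[~f1_meta["broodstock"].astype(bool)]
            hor = f1_nat.loc[f1_nat["origin"] == "HOR", rs_column]
            nor = f1_nat.loc[f1_nat["origin"] == "NOR", rs_column]
            f1 = (f1_db(f0, hor, nor, stratum)
                  if len(hor) and len(nor) else _undefined("f1_db", stratum))
        rows.append({**f0.to_dict(), "statistic": "f0_db"})
        rows.append({**f1.to_dict(), "statistic": "f1_db"})
    return pd.DataFrame(rows)


def bootstrap_ratio_ci(num, den, n_boot: int = 10_000, seed: int = 0,
                       alpha: float = 0.05) -> tuple[float, float]:
    """Nonparametric percentile bootstrap CI for the ratio of means
    (independent resampling of the two groups). Used as a cross-check of
    the delta-method interval."""
    rng = np.random.default_rng(seed)
    num = np.asarray(list(num), dtype=float)
    den = np.asarray(list(den), dtype=float)
    bn = num[rng.integers(0, num.size, (n_boot, num.size))].mean(axis=1)
    bd = den[rng.integers(0, den.size, (n_boot, den.size))].mean(axis=1)
    ratios = bn / bd
    lo, hi = np.quantile(ratios, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
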