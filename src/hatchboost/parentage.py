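"""Likelihood-based categorical trio parentage for biallelic SNPs.

Assigns each offspring the candidate parent pair with the highest LOD
score, where LOD is the log10 ratio of the trio likelihood under the
parental hypothesis versus the fully-unrelated hypothesis. True genotypes
of all three trio members are marginalised over the 3x3x3 genotype grid
using Hardy-Weinberg priors for the parents, Mendelian transmission for
the offspring, and a per-allele genotyping-error confusion matrix.

Confidence is assessed with a Monte-Carlo null of unrelated pseudo-trios:
per-offspring p-values are converted to q-values by Benjamini-Hochberg,
and assignments are filtered on FDR, trio Mendelian mismatches, a
category-posterior check (is the parental hypothesis the maximum
a-posteriori category?), same-sex pairs, and hatchery broodstock rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MISSING_CODE

LOG10_FLOOR = -300.0  # log10 of the zero-likelihood guard (1e-300)

ACCEPTED = "accepted"
REJECTED_FDR = "rejected_fdr"
REJECTED_MISMATCH = "rejected_mismatch"
REJECTED_SAME_SEX = "rejected_same_sex"
REJECTED_BROODSTOCK = "rejected_broodstock_rule"
REJECTED_CATEGORY = "rejected_not_top_category"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ErrorModel:
    """Per-allele genotyping error: each observed allele is independently
    miscalled with probability ``per_allele_error`` (the assumed rate used
    in the likelihood, conventionally a conservative overestimate of the
    realized rate)."""

    per_allele_error: float = 0.01

    def __post_init__(self):
        if not 0.0 <= self.per_allele_error < 0.5:
            raise ValueError("per_allele_error must lie in [0, 0.5)")

    def confusion_matrix(self) -> np.ndarray:
        """C[true, observed] for ref-allele-count genotypes."""
        e = self.per_allele_error
        return np.array([
            [(1 - e) ** 2, 2 * e * (1 - e), e ** 2],
            [e * (1 - e), (1 - e) ** 2 + e ** 2, e * (1 - e)],
            [e ** 2, 2 * e * (1 - e), (1 - e) ** 2],
        ])


@dataclass
class TrioAssignment:
    offspring_id: str
    parent1_id: str | None
    parent2_id: str | None
    spawn_year: int | None
    lod: float
    n_mismatch: int
    fdr: float
    status: str

    def to_dict(self):
        return asdict(self)


# ---------------------------------------------------------------------
# Mendelian machinery


def _transmission_table() -> np.ndarray:
    """T[g1, g2, go]: P(offspring true genotype | both parents' true
    genotypes) under Mendelian segregation."""
    T = np.zeros((3, 3, 3))
    for g1 in range(3):
        for g2 in range(3):
            a1, a2 = g1 / 2.0, g2 / 2.0
            T[g1, g2, 2] = a1 * a2
            T[g1, g2, 0] = (1 - a1) * (1 - a2)
            T[g1, g2, 1] = a1 * (1 - a2) + (1 - a1) * a2
    return T


TRANSMISSION = _transmission_table()
INCOMPATIBLE = TRANSMISSION == 0.0  # [g1, g2, go]


def transmission_prob(off_code: int, p1_code: int, p2_code: int) -> float:
    """Mendelian P(offspring genotype | parental genotypes)."""
    return float(TRANSMISSION[p1_code, p2_code, off_code])


def hwe_priors(freqs: np.ndarray) -> np.ndarray:
    """H[L, g]: Hardy-Weinberg genotype priors per locus for ref-allele
    frequency ``freqs``."""
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    return np.stack([q * q, 2 * p * q, p * p], axis=-1)


def count_mismatches(off, p1, p2) -> int:
    """Number of loci where all three calls are non-missing and the
    observed trio is Mendelian-impossible."""
    o, a, b = (np.asarray(v, dtype=float) for v in (off, p1, p2))
    ok = ~(np.isnan(o) | np.isnan(a) | np.isnan(b))
    if not ok.any():
        return 0
    return int(INCOMPATIBLE[a[ok].astype(int), b[ok].astype(int),
                            o[ok].astype(int)].sum())


# ---------------------------------------------------------------------
# Per-locus likelihood tables


class LikelihoodTables:
    """Precomputed per-locus log10 likelihood tables over observed codes.

    Index order is [locus, off_obs, p1_obs, p2_obs] with a 4th state
    (``MISSING_CODE``) whose entries are 0 in the LOD table (a locus with
    any missing member contributes nothing) and 0 in the per-hypothesis
    log-likelihood tables (dropped consistently across hypotheses).
    """

    def __init__(self, freqs: np.ndarray, error_model: ErrorModel):
        freqs = np.asarray(freqs, dtype=float)
        L = freqs.size
        C = error_model.confusion_matrix()
        H = hwe_priors(freqs)                      # [L, 3]
        # parental joint over observed codes:
        # sum_{g1,g2,go} H[g1] H[g2] T[g1,g2,go] C[go,oo] C[g1,o1] C[g2,o2]
        M = np.einsum("li,lj,ijk->lijk", H, H, TRANSMISSION)
        p_par = np.einsum("lijk,kc,ia,jb->lcab", M, C, C, C)
        # observed-genotype marginal under HWE + error
        p_marg = H @ C                              # [L, 3]
        p_unr = np.einsum("lc,la,lb->lcab", p_marg, p_marg, p_marg)
        # single-parent joint: one parent true, the other unrelated
        p_go_g1 = np.einsum("lj,ijk->lik", H, TRANSMISSION)  # [L, g1, go]
        p_po = np.einsum("li,lik,kc,ia->lca", H, p_go_g1, C, C)  # [L, oo, o1]
        p_pu = np.einsum("lca,lb->lcab", p_po, p_marg)  # p1 parental
        p_up = np.einsum("lcb,la->lcab", p_po, p_marg)  # p2 parental

        with np.errstate(divide="ignore"):
            log_par = np.maximum(np.log10(p_par), LOG10_FLOOR)
            log_unr = np.maximum(np.log10(p_unr), LOG10_FLOOR)
            log_pu = np.maximum(np.log10(p_pu), LOG10_FLOOR)
            log_up = np.maximum(np.log10(p_up), LOG10_FLOOR)
            log_marg = np.maximum(np.log10(p_marg), LOG10_FLOOR)
            log_po = np.maximum(np.log10(p_po), LOG10_FLOOR)

        uninformative = (freqs <= 0.0) | (freqs >= 1.0)

        def pad(t, fill=0.0):
            out = np.full((L, 4, 4, 4), fill)
            out[:, :3, :3, :3] = t
            out[uninformative] = fill
            return out

        self.freqs = freqs
        self.error_model = error_model
        self.lod = pad(log_par - log_unr)
        self.log_par = pad(log_par)
        self.log_unr = pad(log_unr)
        self.log_pu = pad(log_pu)
        self.log_up = pad(log_up)
        # pairwise parent-offspring LOD, [locus, off_obs, cand_obs]
        lod1 = log_po - (log_marg[:, :, None] + log_marg[:, None, :])
        pair = np.zeros((L, 4, 4))
        pair[:, :3, :3] = lod1
        pair[uninformative] = 0.0
        self.lod_pair = pair
        self.obs_marginal = p_marg  # [L, 3], rows sum to ~1

    # -- scalar evaluation --------------------------------------------

    def trio_lod(self, off, p1, p2) -> float:
        idx = np.arange(self.freqs.size)
        o, a, b2 = (_as_codes(v) for v in (off, p1, p2))
        return float(self.lod[idx, o, a, b2].sum())

    def trio_loglik(self, table, off, p1, p2) -> float:
        idx = np.arange(self.freqs.size)
        o, a, b2 = (_as_codes(v) for v in (off, p1, p2))
        return float(table[idx, o, a, b2].sum())

    def category_posterior(self, off, p1, p2) -> np.ndarray:
        """Posterior over {both-parents, single-parent, unrelated} with
        equal category priors (single-parent takes the better of the two
        one-true-parent configurations)."""
        ll = np.array([
            self.trio_loglik(self.log_par, off, p1, p2),
            max(self.trio_loglik(self.log_pu, off, p1, p2),
                self.trio_loglik(self.log_up, off, p1, p2)),
            self.trio_loglik(self.log_unr, off, p1, p2),
        ])
        w = 10.0 ** (ll - ll.max())
        return w / w.sum()

    def parental_is_map(self, off, p1, p2) -> bool:
        """True when the both-parents category is the maximum a-posteriori
        category for this trio (equal priors)."""
        post = self.category_posterior(off, p1, p2)
        return bool(np.argmax(post) == 0)


def _as_codes(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    out = np.where(np.isnan(v), MISSING_CODE, v).astype(np.int64)
    return out


def trio_lod(off, p1, p2, freqs, error_model: ErrorModel) -> float:
    """LOD (log10 parental-vs-unrelated likelihood ratio) for one trio.

    Loci with any missing member, or with allele frequency exactly 0 or 1,
    contribute 0. With ``per_allele_error == 0`` a Mendelian-impossible
    locus contributes the log10 of a 1e-300 floor rather than -inf so that
    ranking stays total.
    """
    return LikelihoodTables(freqs, error_model).trio_lod(off, p1, p2)


# ---------------------------------------------------------------------
# Cohort assignment


def _pair_scores(tables: LikelihoodTables, off_codes, cand_codes):
    """Parent-offspring LOD of every candidate for every offspring.

    off_codes: [O, L]; cand_codes: [C, L] -> [O, C] score matrix.
    """
    L = tables.freqs.size
    O, C = off_codes.shape[0], cand_codes.shape[0]
    scores = np.zeros((O, C))
    # accumulate per locus; tables.lod_pair[l] is a 4x4 lookup
    for l in range(L):
        scores += tables.lod_pair[l][np.ix_(off_codes[:, l], cand_codes[:, l])]
    return scores


def _null_lod_distribution(tables: LikelihoodTables, n_null: int,
                           rng: np.random.Generator) -> np.ndarray:
    """LODs of unrelated pseudo-trios drawn from the observed-genotype
    marginal (HWE pushed through the error model) at each locus."""
    L = tables.freqs.size
    pm = tables.obs_marginal / tables.obs_marginal.sum(axis=1, keepdims=True)
    cum = pm.cumsum(axis=1)
    u = rng.random((3, n_null, L))
    codes = (u[..., None] > cum[None, None, :, :]).sum(-1)  # [3, n, L]
    idx = np.arange(L)
    lods = np.zeros(n_null)
    # sum lookups per locus (vectorised over the null trios)
    for l in idx:
        lods += tables.lod[l, codes[0, :, l], codes[1, :, l], codes[2, :, l]]
    return lods


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Step-up FDR q-values."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def assign_cohort(offspring_gm: GenotypeMatrix, offspring_meta: pd.DataFrame,
                  candidate_gm: GenotypeMatrix, candidate_meta: pd.DataFrame,
                  freqs: np.ndarray | None = None,
                  error_model: ErrorModel = ErrorModel(),
                  n_null: int = 10_000, seed: int = 0,
                  top_k: int = 30) -> pd.DataFrame:
    """Assign every offspring its best candidate parent pair.

    Candidate pairs are restricted to spawners of return years Y-3, Y-4,
    Y-5 for an offspring returning in year Y, with both members from the
    same spawn year and the same spawning pool (hatchery broodstock pairs
    never mix with natural spawners). Parent sex is not used. For each
    offspring the top-LOD pair is reported with its Mendelian mismatch
    count, a Monte-Carlo q-value (``fdr``), and the category posterior of
    the parental hypothesis; filter statuses are set later by
    :func:`apply_assignment_filters`.

    Candidate pruning: single-parent LODs rank all candidates and only
    pairs among the best ``top_k`` are evaluated exhaustively.

    Parameters
    ----------
    offspring_meta, candidate_meta : DataFrame
        Must contain ``id`` and ``return_year``; candidates additionally
        ``broodstock`` (bool). Candidate spawn year equals return year.

    Returns
    -------
    DataFrame with one row per offspring: offspring_id, parent1_id,
    parent2_id, spawn_year, lod, n_mismatch, fdr, p_value,
    posterior_parental, status (``unassigned`` or empty pending filters).
    """
    if freqs is None:
        from .qc import allele_frequencies
        freqs = allele_frequencies(candidate_gm)
    if list(offspring_gm.locus_ids) != list(candidate_gm.locus_ids):
        raise ValueError("offspring and candidate matrices must share loci")
    tables = LikelihoodTables(freqs, error_model)
    rng = np.random.default_rng(seed)
    null_lods = np.sort(_null_lod_distribution(tables, n_null, rng))

    cand_pos = {iid: i for i, iid in enumerate(candidate_gm.individual_ids)}
    cand_meta = candidate_meta[candidate_meta["id"].isin(cand_pos)]
    cand_codes_all = candidate_gm.codes()
    off_codes_all = offspring_gm.codes()
    off_pos = {iid: i for i, iid in enumerate(offspring_gm.individual_ids)}
    L_idx = np.arange(tables.freqs.size)

    records = []
    for year, group in offspring_meta.groupby("return_year"):
        off_ids = [i for i in group["id"] if i in off_pos]
        if not off_ids:
            continue
        spawn_years = {year - a for a in (3, 4, 5)}
        sub = cand_meta[cand_meta["return_year"].isin(spawn_years)]
        cids = sub["id"].tolist()
        if not cids:
            for oid in off_ids:
                records.append((oid, None, None, None, np.nan, -1, np.nan,
                                np.nan, np.nan, True, UNASSIGNED))
            continue
        c_codes = cand_codes_all[[cand_pos[i] for i in cids]]
        c_year = sub["return_year"].to_numpy()
        c_pool = sub["broodstock"].to_numpy(dtype=bool)
        o_codes = off_codes_all[[off_pos[i] for i in off_ids]]
        pair_lod = _pair_scores(tables, o_codes, c_codes)

        for r, oid in enumerate(off_ids):
            order = np.argsort(pair_lod[r])[::-1][:top_k]
            best = None
            for ii in range(len(order)):
                for jj in range(ii + 1, len(order)):
                    a, b = order[ii], order[jj]
                    if c_year[a] != c_year[b] or c_pool[a] != c_pool[b]:
                        continue
                    lod = float(tables.lod[
                        L_idx, o_codes[r], c_codes[a], c_codes[b]].sum())
                    mm = int(_count_mm(o_codes[r], c_codes[a], c_codes[b]))
                    key = (-lod, mm, tuple(sorted((cids[a], cids[b]))))
                    if best is None or key < best[0]:
                        best = (key, a, b, lod, mm)
            if best is None:
                records.append((oid, None, None, None, np.nan, -1, np.nan,
                                np.nan, np.nan, True, UNASSIGNED))
                continue
            _, a, b, lod, mm = best
            p1, p2 = sorted((cids[a], cids[b]))
            n_ge = null_lods.size - np.searchsorted(null_lods, lod,
                                                    side="left")
            pval = (1 + n_ge) / (n_null + 1)
            post = tables.category_posterior(
                o_codes[r].astype(float),
                c_codes[a].astype(float), c_codes[b].astype(float))
            records.append((oid, p1, p2, int(c_year[a]), lod, mm, np.nan,
                            pval, float(post[0]),
                            bool(np.argmax(post) == 0), ""))

    df = pd.DataFrame(records, columns=[
        "offspring_id", "parent1_id", "parent2_id", "spawn_year", "lod",
        "n_mismatch", "fdr", "p_value", "posterior_parental",
        "parental_map", "status"])
    assigned = df["parent1_id"].notna()
    if assigned.any():
        df.loc[assigned, "fdr"] = benjamini_hochberg(
            df.loc[assigned, "p_value"].to_numpy())
    return df


def _count_mm(o_codes, a_codes, b_codes) -> int:
    ok = (o_codes != MISSING_CODE) & (a_codes != MISSING_CODE) & \
         (b_codes != MISSING_CODE)
    if not ok.any():
        return 0
    return int(INCOMPATIBLE[a_codes[ok], b_codes[ok], o_codes[ok]].sum())


def apply_assignment_filters(assignments: pd.DataFrame,
                             metadata: pd.DataFrame,
                             fdr_threshold: float = 0.05,
                             max_mismatch: int = 2,
                             min_posterior_rank: bool = True) -> pd.DataFrame:
    """Set the final status of each assignment.

    Rules, in precedence order (the first violated rule names the status):
    more than ``max_mismatch`` trio Mendelian mismatches; Monte-Carlo FDR
    above ``fdr_threshold``; two same-sex parents; broodstock rules (a
    hatchery-origin offspring must assign to two broodstock parents, and
    mixed broodstock/non-broodstock pairs are spurious for any offspring);
    parental hypothesis not the maximum a-posteriori category. Assignments
    passing every rule are ``accepted``.

    ``metadata`` must carry ``id``, ``sex``, ``origin``, ``broodstock``
    for every individual referenced; an unknown id raises ``KeyError``.
    """
    meta = metadata.set_index("id")
    out = assignments.copy()
    statuses = []
    for rec in out.itertuples():
        if rec.parent1_id is None or (isinstance(rec.parent1_id, float)
                                      and np.isnan(rec.parent1_id)):
            statuses.append(UNASSIGNED)
            continue
        for iid in (rec.offspring_id, rec.parent1_id, rec.parent2_id):
            if iid not in meta.index:
                raise KeyError(f"unknown individual id in assignment: {iid}")
        p1, p2 = meta.loc[rec.parent1_id], meta.loc[rec.parent2_id]
        off = meta.loc[rec.offspring_id]
        both_bs = bool(p1["broodstock"]) and bool(p2["broodstock"])
        mixed_bs = bool(p1["broodstock"]) != bool(p2["broodstock"])
        if rec.n_mismatch > max_mismatch:
            statuses.append(REJECTED_MISMATCH)
        elif not np.isnan(rec.fdr) and rec.fdr > fdr_threshold:
            statuses.append(REJECTED_FDR)
        elif p1["sex"] == p2["sex"]:
            statuses.append(REJECTED_SAME_SEX)
        elif mixed_bs or (off["origin"] == "HOR" and not both_bs) \
                or (off["origin"] == "NOR" and both_bs):
            statuses.append(REJECTED_BROODSTOCK)
        elif min_posterior_rank and hasattr(rec, "parental_map") \
                and not rec.parental_map:
            statuses.append(REJECTED_CATEGORY)
        else:
            statuses.append(ACCEPTED)
    out["status"] = statuses
    return out


def assignment_success(assignments: pd.DataFrame,
                       offspring_meta: pd.DataFrame,
                       fully_sampled_years: Sequence[int]) -> dict[int, float]:
    """Accepted assignments / eligible offspring for each return year the
    caller declares completely sampled on the parental side."""
    meta = offspring_meta.set_index("id")
    out = {}
    for year in fully_sampled_years:
        eligible = [i for i in meta.index
                    if meta.at[i, "return_year"] == year]
        if not eligible:
            raise ValueError(f"no eligible offspring for return year {year}")
        sub = assignments[assignments["offspring_id"].isin(eligible)]
        accepted = (sub["status"] == ACCEPTED).sum()
        out[year] = accepted / len(eligible)
    return out


def assignments_to_trios(assignments: pd.DataFrame) -> list[TrioAssignment]:
    """DataFrame rows as TrioAssignment dataclass instances."""
    out = []
    for rec in assignments.itertuples():
        out.append(TrioAssignment(
            rec.offspring_id, rec.parent1_id, rec.parent2_id,
            rec.spawn_year, rec.lod, rec.n_mismatch, rec.fdr, rec.status))
    return out
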