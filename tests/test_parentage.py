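"""Trio likelihoods, mismatch counting, FDR machinery and filters."""

import itertools

import numpy as np
import pandas as pd
import pytest

import hatchboost as hb
from hatchboost.parentage import (ACCEPTED, LOG10_FLOOR, REJECTED_BROODSTOCK,
                                  REJECTED_CATEGORY, REJECTED_FDR,
                                  REJECTED_MISMATCH, REJECTED_SAME_SEX,
                                  TRANSMISSION, LikelihoodTables,
                                  benjamini_hochberg, hwe_priors)


def brute_force_lod(off, p1, p2, freqs, eps):
    """Independent 27-cell marginalisation oracle, explicit loops."""
    def confusion(e):
        return [
            [(1 - e) ** 2, 2 * e * (1 - e), e ** 2],
            [e * (1 - e), (1 - e) ** 2 + e ** 2, e * (1 - e)],
            [e ** 2, 2 * e * (1 - e), (1 - e) ** 2],
        ]

    C = confusion(eps)
    total = 0.0
    for l, p in enumerate(freqs):
        if np.isnan(off[l]) or np.isnan(p1[l]) or np.isnan(p2[l]):
            continue
        if p <= 0.0 or p >= 1.0:
            continue
        q = 1 - p
        h = [q * q, 2 * p * q, p * p]
        oo, o1, o2 = int(off[l]), int(p1[l]), int(p2[l])
        par = 0.0
        for g1 in range(3):
            for g2 in range(3):
                for go in range(3):
                    par += (h[g1] * h[g2] * TRANSMISSION[g1, g2, go]
                            * C[g1][o1] * C[g2][o2] * C[go][oo])
        marg = [sum(h[g] * C[g][o] for g in range(3)) for o in range(3)]
        unr = marg[o1] * marg[o2] * marg[oo]
        par = max(par, 1e-300)
        unr = max(unr, 1e-300)
        total += np.log10(par) - np.log10(unr)
    return total


class TestTransmission:
    def test_rows_sum_to_one(self):
        for g1, g2 in itertools.product(range(3), range(3)):
            s = sum(hb.transmission_prob(o, g1, g2) for o in range(3))
            assert s == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("off, p1, p2, expected", [
        (1, 0, 2, 1.0),   # forced heterozygote
        (2, 0, 0, 0.0),   # impossible
        (1, 1, 1, 0.5),   # 4 gamete pairs, 2 heterozygous
    ])
    def test_hand_values(self, off, p1, p2, expected):
        assert hb.transmission_prob(off, p1, p2) == expected


class TestMismatchCount:
    @pytest.mark.parametrize("off, p1, p2, expected", [
        ([2], [0], [0], 1),
        ([1], [0], [2], 0),
        # locus 1: off 0 impossible from p1=2; locus 2: off 2 impossible
        # from p2=0; locus 3 skipped (p1 missing)
        ([0, 2, 1], [2, 2, np.nan], [0, 0, 1], 2),
    ])
    def test_hand_enumeration(self, off, p1, p2, expected):
        assert hb.count_mismatches(off, p1, p2) == expected


class TestTrioLod:
    def test_forced_het_closed_form(self):
        # eps=0, freq 0.5: parental P(off=1 | 0, 2) = 1, unrelated
        # P(het under HWE) = 0.5 -> LOD = log10(2)
        lod = hb.trio_lod([1.0], [0.0], [2.0], np.array([0.5]),
                          hb.ErrorModel(0.0))
        assert lod == pytest.approx(np.log10(2.0), abs=1e-12)

    def test_impossible_locus_floored_at_zero_error(self):
        lod = hb.trio_lod([2.0], [0.0], [0.0], np.array([0.5]),
                          hb.ErrorModel(0.0))
        assert lod < 100 + LOG10_FLOOR  # hits the 1e-300 guard
        assert np.isfinite(lod)

    def test_impossible_locus_finite_with_error(self):
        lod = hb.trio_lod([2.0], [0.0], [0.0], np.array([0.5]),
                          hb.ErrorModel(0.01))
        assert np.isfinite(lod) and lod > LOG10_FLOOR / 2 and lod < 0

    def test_fixed_frequency_contributes_zero(self):
        lod = hb.trio_lod([1.0, 1.0], [0.0, 1.0], [2.0, 1.0],
                          np.array([0.5, 1.0]), hb.ErrorModel(0.01))
        only_first = hb.trio_lod([1.0], [0.0], [2.0], np.array([0.5]),
                                 hb.ErrorModel(0.01))
        assert lod == pytest.approx(only_first, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        L = 20
        freqs = rng.uniform(0.05, 0.95, L)
        em = hb.ErrorModel(0.01)
        tables = LikelihoodTables(freqs, em)
        for _ in range(50):
            trio = rng.integers(0, 3, (3, L)).astype(float)
            trio[rng.random((3, L)) < 0.1] = np.nan
            fast = tables.trio_lod(trio[0], trio[1], trio[2])
            slow = brute_force_lod(trio[0], trio[1], trio[2], freqs,
                                   em.per_allele_error)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_true_parents_dominate_unrelated(self):
        """True-parent LODs separate cleanly from unrelated pairs
        (ROC AUC > 0.99 at 290 informative loci)."""
        rng = np.random.default_rng(12)
        L, n = 290, 120
        freqs = rng.uniform(0.2, 0.8, L)
        tables = LikelihoodTables(freqs, hb.ErrorModel(0.01))
        h = hwe_priors(freqs)
        def draw(n):
            u = rng.random((n, L, 1))
            return (u > h.cumsum(axis=1)[None]).sum(-1).astype(float)
        moms, dads, unrel = draw(n), draw(n), draw(2 * n)
        kid_a = np.where(rng.random((n, L)) < moms / 2, 1, 0)
        kid_b = np.where(rng.random((n, L)) < dads / 2, 1, 0)
        kids = (kid_a + kid_b).astype(float)
        true_lods = [tables.trio_lod(kids[i], moms[i], dads[i])
                     for i in range(n)]
        false_lods = [tables.trio_lod(kids[i], unrel[2 * i], unrel[2 * i + 1])
                      for i in range(n)]
        both = np.concatenate([true_lods, false_lods])
        ranks = both.argsort().argsort()[:n]
        auc = (ranks.sum() - n * (n - 1) / 2) / n ** 2
        assert auc > 0.99


class TestFdrMachinery:
    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(3)
        p = rng.random(50) ** 2
        ours = benjamini_hochberg(p)
        _, theirs, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, theirs)


def _filter_fixture():
    meta = pd.DataFrame({
        "id": ["off_nor", "off_hor", "m_nat", "f_nat", "m_bs", "f_bs",
               "f_nat2"],
        "sex": ["F", "M", "M", "F", "M", "F", "F"],
        "origin": ["NOR", "HOR", "NOR", "NOR", "NOR", "NOR", "NOR"],
        "broodstock": [False, False, False, False, True, True, False],
        "return_year": [2006, 2006, 2002, 2002, 2002, 2002, 2002],
    })

    def row(off, p1, p2, fdr=0.001, mm=0, parental_map=True):
        return dict(offspring_id=off, parent1_id=p1, parent2_id=p2,
                    spawn_year=2002, lod=30.0, n_mismatch=mm, fdr=fdr,
                    p_value=fdr, posterior_parental=0.99,
                    parental_map=parental_map, status="")

    return meta, row


class TestAssignmentFilters:
    def test_each_rule_sets_its_status(self):
        meta, row = _filter_fixture()
        frame = pd.DataFrame([
            row("off_nor", "f_nat", "m_nat"),                  # accepted
            row("off_nor", "f_nat", "m_nat", fdr=0.2),         # fdr
            row("off_nor", "f_nat", "m_nat", mm=3),            # mismatches
            row("off_nor", "f_nat", "f_nat2"),                 # same sex
            row("off_hor", "f_nat", "m_nat"),                  # HOR x non-BS
            row("off_nor", "f_bs", "m_nat"),                   # mixed pair
            row("off_nor", "f_nat", "m_nat", parental_map=False),
        ])
        out = hb.apply_assignment_filters(frame, meta)
        assert list(out["status"]) == [
            ACCEPTED, REJECTED_FDR, REJECTED_MISMATCH, REJECTED_SAME_SEX,
            REJECTED_BROODSTOCK, REJECTED_BROODSTOCK, REJECTED_CATEGORY,
        ]

    def test_hor_offspring_to_broodstock_accepted(self):
        meta, row = _filter_fixture()
        out = hb.apply_assignment_filters(
            pd.DataFrame([row("off_hor", "f_bs", "m_bs")]), meta)
        assert list(out["status"]) == [ACCEPTED]

    def test_unknown_id_raises(self):
        meta, row = _filter_fixture()
        with pytest.raises(KeyError):
            hb.apply_assignment_filters(
                pd.DataFrame([row("ghost", "f_nat", "m_nat")]), meta)

    def test_assignment_success_ratio(self):
        meta = pd.DataFrame({
            "id": [f"o{i}" for i in range(100)],
            "return_year": [2013] * 100,
        })
        frame = pd.DataFrame({
            "offspring_id": [f"o{i}" for i in range(100)],
            "status": [ACCEPTED] * 76 + ["rejected_fdr"] * 24,
        })
        out = hb.assignment_success(frame, meta, [2013])
        assert out[2013] == pytest.approx(0.76)
        with pytest.raises(ValueError):
            hb.assignment_success(frame, meta, [1999])


class TestCohortAssignment:
    def test_error_free_cohort_assigns_true_parents(self, clean_parentage_sim):
        cfg, individuals, gm, truth = clean_parentage_sim
        year = cfg.first_year + 6
        linked = truth[truth["mother_id"].notna()].set_index("individual_id")
        off_meta = individuals[(individuals["return_year"] == year)
                               & individuals["id"].isin(linked.index)]
        cand_meta = individuals[individuals["return_year"].isin(
            {year - 3, year - 4, year - 5})]
        asn = hb.assign_cohort(
            gm.subset(individuals=off_meta["id"].tolist()), off_meta,
            gm.subset(individuals=cand_meta["id"].tolist()), cand_meta,
            error_model=hb.ErrorModel(0.0), n_null=2000, seed=1)
        asn = hb.apply_assignment_filters(asn, individuals)
        correct = 0
        for rec in asn.itertuples():
            if rec.status != ACCEPTED:
                continue
            t = linked.loc[rec.offspring_id]
            if {rec.parent1_id, rec.parent2_id} == {t["mother_id"],
                                                    t["father_id"]}:
                correct += 1
        assert len(asn) > 30
        assert correct / len(asn) >= 0.99

    def test_removed_parents_leave_offspring_unassigned(self, clean_parentage_sim):
        """Offspring whose true parents are withheld from the candidate
        pool are unassigned or rejected nearly always."""
        cfg, individuals, gm, truth = clean_parentage_sim
        year = cfg.first_year + 6
        linked = truth[truth["mother_id"].notna()].set_index("individual_id")
        off_meta = individuals[(individuals["return_year"] == year)
                               & individuals["id"].isin(linked.index)].head(40)
        true_parents = set(linked.loc[off_meta["id"], "mother_id"]) | \
            set(linked.loc[off_meta["id"], "father_id"])
        cand_meta = individuals[
            individuals["return_year"].isin({year - 3, year - 4, year - 5})
            & ~individuals["id"].isin(true_parents)]
        asn = hb.assign_cohort(
            gm.subset(individuals=off_meta["id"].tolist()), off_meta,
            gm.subset(individuals=cand_meta["id"].tolist()), cand_meta,
            error_model=hb.ErrorModel(0.0), n_null=2000, seed=2)
        asn = hb.apply_assignment_filters(asn, individuals)
        not_accepted = (asn["status"] != ACCEPTED).mean()
        assert not_accepted >= 0.95
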