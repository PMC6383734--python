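"""Per-individual reproductive success from accepted parentage trios.

Reproductive success (RS) is the number of returning adult offspring
assigned to a parent; grand-RS extends the count over two generations with
the hatchery broodstock accounting: an F1 fish taken as broodstock is cut
out of the grand-offspring path entirely (its hatchery progeny are not
credited to the F0 grandparents), which is the conservative choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CROSS_LABELS = ("HH", "HN", "NH", "NN")


@dataclass
class Pedigree:
    """Accepted parent-offspring structure with metadata access.

    Parameters
    ----------
    trios : DataFrame
        Columns ``offspring_id``, ``mother_id``, ``father_id`` and
        optionally ``spawn_year``. Mother/father may be NaN for founders
        (such rows contribute no edges).
    metadata : DataFrame
        Per-individual table with ``id``, ``sex``, ``origin``,
        ``broodstock``, ``return_year`` (and typically ``age``).
    """

    trios: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        self._meta = self.metadata.set_index("id")
        t = self.trios
        linked = t[t["mother_id"].notna() & t["father_id"].notna()]
        self._children_of: dict[str, list[str]] = {}
        for rec in linked.itertuples():
            for pid in (rec.mother_id, rec.father_id):
                self._children_of.setdefault(pid, []).append(rec.offspring_id)
        self._parents_of = {
            rec.offspring_id: (rec.mother_id, rec.father_id)
            for rec in linked.itertuples()
        }

    @classmethod
    def from_assignments(cls, assignments: pd.DataFrame,
                         metadata: pd.DataFrame) -> "Pedigree":
        """Build from an assignment table, keeping accepted trios only and
        orienting parents as mother/father from metadata sex (deferring to
        the pedigree position when field sex conflicts)."""
        acc = assignments[assignments["status"] == "accepted"]
        meta = metadata.set_index("id")
        rows = []
        for rec in acc.itertuples():
            s1 = meta.at[rec.parent1_id, "sex"]
            s2 = meta.at[rec.parent2_id, "sex"]
            if s1 == s2:
                log.warning(
                    "accepted trio %s has same-sex parents; skipping",
                    rec.offspring_id)
                continue
            mother, father = ((rec.parent1_id, rec.parent2_id)
                              if s1 == "F" else
                              (rec.parent2_id, rec.parent1_id))
            rows.append((rec.offspring_id, mother, father,
                         getattr(rec, "spawn_year", None)))
        trios = pd.DataFrame(
            rows, columns=["offspring_id", "mother_id", "father_id",
                           "spawn_year"])
        return cls(trios, metadata)

    @classmethod
    def from_truth(cls, truth: pd.DataFrame,
                   metadata: pd.DataFrame) -> "Pedigree":
        """Build from a simulator truth table (individual_id, mother_id,
        father_id)."""
        trios = truth.rename(columns={"individual_id": "offspring_id"})[
            ["offspring_id", "mother_id", "father_id"]].copy()
        return cls(trios, metadata)

    def children(self, parent_id) -> list[str]:
        return self._children_of.get(parent_id, [])

    def parents(self, offspring_id):
        return self._parents_of.get(offspring_id)


def compute_rs(ped: Pedigree, cohort) -> pd.Series:
    """RS (count of accepted offspring) for every individual in ``cohort``;
    members with no assigned offspring get 0."""
    cohort = list(cohort)
    return pd.Series({i: len(ped.children(i)) for i in cohort},
                     name="rs", dtype=int)


def compute_grand_rs(ped: Pedigree, f0_cohort, broodstock_ids) -> pd.Series:
    """Grand-offspring counts for F0 individuals.

    Only F1 offspring that spawned naturally contribute: F1 fish in
    ``broodstock_ids`` are excluded along with their (hatchery) progeny.
    """
    broodstock_ids = set(broodstock_ids)
    out = {}
    for f0 in f0_cohort:
        total = 0
        for f1 in ped.children(f0):
            if f1 in broodstock_ids:
                continue
            total += len(ped.children(f1))
        out[f0] = total
    return pd.Series(out, name="grand_rs", dtype=int)


def classify_cross(ped: Pedigree, offspring_id) -> str | None:
    """Cross-type label (female origin first) for an offspring with two
    accepted opposite-sex parents; ``None`` when undefined."""
    parents = ped.parents(offspring_id)
    if parents is None:
        return None
    mother, father = parents
    meta = ped._meta
    try:
        sm, sf = meta.at[mother, "sex"], meta.at[father, "sex"]
        om, of = meta.at[mother, "origin"], meta.at[father, "origin"]
    except KeyError:
        return None
    if sm == sf:
        return None
    label = ("H" if om == "HOR" else "N") + ("H" if of == "HOR" else "N")
    return label


def cross_table(ped: Pedigree) -> pd.DataFrame:
    """Per-offspring cross table: offspring_id, mother_id, father_id,
    cross, spawn_year (if present in the trio table)."""
    rows = []
    meta = ped._meta
    for rec in ped.trios.itertuples():
        if pd.isna(rec.mother_id) or pd.isna(rec.father_id):
            continue
        label = classify_cross(ped, rec.offspring_id)
        year = getattr(rec, "spawn_year", None)
        if year is None or pd.isna(year):
            # parents spawn in their return year
            year = (meta.at[rec.mother_id, "return_year"]
                    if rec.mother_id in meta.index else None)
        rows.append((rec.offspring_id, rec.mother_id, rec.father_id, label,
                     year))
    return pd.DataFrame(rows, columns=[
        "offspring_id", "mother_id", "father_id", "cross", "spawn_year"])


def apply_cohort_exclusions(individuals: pd.DataFrame) -> pd.DataFrame:
    """Flag the analysis cohorts.

    Age-2, age-6 and age-3-female returns (rare classes) are excluded from
    every analysis; jacks (age-3 males) stay in RRS but are excluded from
    cross analyses. Unknown ages are excluded with a logged warning.

    Adds boolean columns ``include_rrs`` and ``include_cross``.
    """
    out = individuals.copy()
    age = pd.to_numeric(out["age"], errors="coerce")
    unknown = age.isna()
    if unknown.any():
        log.warning("%d individuals with unknown age excluded", unknown.sum())
    rare = age.isin([2, 6]) | ((age == 3) & (out["sex"] == "F"))
    jack = (age == 3) & (out["sex"] == "M")
    out["include_rrs"] = ~(rare | unknown)
    out["include_cross"] = out["include_rrs"] & ~jack
    return out


def fitness_table(ped: Pedigree, individuals: pd.DataFrame,
                  broodstock_ids=None) -> pd.DataFrame:
    """Per-individual fitness table: metadata plus rs, grand_rs and the
    cohort inclusion flags."""
    out = apply_cohort_exclusions(individuals)
    rs = compute_rs(ped, out["id"])
    out = out.set_index("id")
    out["rs"] = rs
    bs = (set(broodstock_ids) if broodstock_ids is not None
          else set(out.index[out["broodstock"].astype(bool)]))
    out["grand_rs"] = compute_grand_rs(ped, out.index, bs)
    return out.reset_index()
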