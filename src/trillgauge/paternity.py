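"""Microsatellite parentage: trio mismatch rules, extra-pair sire assignment,
and male-year mating/reproductive success roll-ups.

Classification is deliberately rule-based (no likelihood machinery): an
offspring is called extra-pair (EP) when it shows more than one trio-wise
mismatch with its social parents that cannot be attributed to a null allele,
single non-null mismatches being tolerated as mutations with either putative
parent.  Null-allele consistency uses the standard microsatellite signature:
an apparent homozygote offspring whose incompatible parent is itself an
apparent homozygote (each could carry an unamplified null allele).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Genotype",
    "MismatchRecord",
    "PaternityCall",
    "MaleYearSuccess",
    "genotypes_from_frame",
    "pairwise_mismatch",
    "trio_mismatch_loci",
    "classify_offspring",
    "assign_ep_sire",
    "classify_all",
    "male_year_success",
    "locus_summaries",
]


class Genotype:
    """Multilocus genotype: per-locus unordered allele pairs, 0 = missing.

    Alleles are integer ids (fragment sizes); a locus is *typed* when both
    observed alleles are nonzero.
    """

    def __init__(self, loci: list[tuple[int, int]]):
        self.loci = [tuple(sorted(map(int, pair))) for pair in loci]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def typed(self, k: int) -> bool:
        a, b = self.loci[k]
        return a != 0 and b != 0

    def alleles(self, k: int) -> set[int]:
        return set(self.loci[k])

    def is_homozygous(self, k: int) -> bool:
        a, b = self.loci[k]
        return a == b and a != 0

    def __repr__(self) -> str:  # pragma: no cover
        return f"Genotype({self.loci})"


@dataclass
class MismatchRecord:
    locus: int
    parties: str  # "mother" | "father" | "trio"
    null_consistent: bool


@dataclass
class PaternityCall:
    offspring_id: str
    status: str  # WP | EP | unresolved
    n_trio_mismatches_non_null: int
    n_trio_mismatches_total: int
    n_loci_compared: int
    assigned_sire: str | None = None


@dataclass
class MaleYearSuccess:
    male_id: str
    year: int
    wp_proportion: float
    ep_success: bool
    polygynous: bool
    annual_rs: int
    n_social: int
    n_ep_sired: int


def genotypes_from_frame(frame: pd.DataFrame, n_loci: int | None = None) -> dict[str, Genotype]:
    """Build ``{id: Genotype}`` from a wide CSV frame with columns
    ``L{k}_a1, L{k}_a2`` (0 = missing allele).  Duplicate ids (individuals
    present in several years) collapse to the first row."""
    if n_loci is None:
        n_loci = sum(c.endswith("_a1") and c.startswith("L") for c in frame.columns)
    out: dict[str, Genotype] = {}
    for _, row in frame.iterrows():
        iid = str(row["id"])
        if iid in out:
            continue
        out[iid] = Genotype(
            [(row[f"L{k}_a1"], row[f"L{k}_a2"]) for k in range(1, n_loci + 1)]
        )
    return out


def pairwise_mismatch(parent: Genotype, offspring: Genotype, locus: int) -> MismatchRecord | None:
    """Parent-offspring mismatch at one locus, or None when compatible.

    A mismatch occurs when the pair shares no allele; it is flagged
    null-consistent when both individuals are apparent homozygotes for
    different alleles (each could carry a non-amplifying null allele).
    Untyped loci are excluded (returns None).
    """
    if not parent.typed(locus) or not offspring.typed(locus):
        return None
    if parent.alleles(locus) & offspring.alleles(locus):
        return None
    null_ok = parent.is_homozygous(locus) and offspring.is_homozygous(locus)
    return MismatchRecord(locus=locus, parties="parent", null_consistent=null_ok)


def _trio_compatible_at(mother: Genotype, father: Genotype, offspring: Genotype, k: int) -> bool:
    """Exhaustive check: does some (maternal allele, paternal allele)
    assignment explain the offspring's observed allele set?"""
    off = offspring.loci[k]
    o1, o2 = off
    for m in mother.alleles(k):
        for f in father.alleles(k):
            if (m, f) in ((o1, o2), (o2, o1)):
                return True
            # an apparent homozygote o/o is also explained by o from one
            # parent when the offspring truly carries o twice
            if o1 == o2 and m == o1 and f == o1:
                return True
    return False


def _trio_null_consistent_at(mother: Genotype, father: Genotype, offspring: Genotype, k: int) -> bool:
    """A mismatching locus is attributable to null alleles when the
    offspring is an apparent homozygote and every parent not carrying its
    allele is itself an apparent homozygote (the double-homozygote
    signature, possibly on both sides)."""
    if not offspring.is_homozygous(k):
        return False
    j = next(iter(offspring.alleles(k)))
    for parent in (mother, father):
        if j not in parent.alleles(k) and not parent.is_homozygous(k):
            return False
    return True


def trio_mismatch_loci(
    mother: Genotype, father: Genotype, offspring: Genotype
) -> tuple[list[MismatchRecord], int]:
    """All trio-wise mismatching loci plus the number of loci compared
    (typed in all three individuals)."""
    records = []
    n_compared = 0
    for k in range(offspring.n_loci):
        if not (mother.typed(k) and father.typed(k) and offspring.typed(k)):
            continue
        n_compared += 1
        if _trio_compatible_at(mother, father, offspring, k):
            continue
        records.append(
            MismatchRecord(
                locus=k,
                parties="trio",
                null_consistent=_trio_null_consistent_at(mother, father, offspring, k),
            )
        )
    return records, n_compared


def classify_offspring(
    offspring: Genotype,
    mother: Genotype,
    social_father: Genotype,
    offspring_id: str = "",
    max_missing: int = 2,
) -> PaternityCall:
    """Within-pair / extra-pair call from the social trio.

    Non-null trio-wise mismatches are counted; 0 or 1 such mismatch keeps
    the offspring within-pair (single mismatches tolerated as mutation with
    either parent), more than 1 calls it extra-pair.  Trios with more than
    ``max_missing`` untyped loci are unresolved.
    """
    records, n_compared = trio_mismatch_loci(mother, social_father, offspring)
    n_missing = offspring.n_loci - n_compared
    n_non_null = sum(not r.null_consistent for r in records)
    if n_missing > max_missing:
        status = "unresolved"
    elif n_non_null > 1:
        status = "EP"
    else:
        status = "WP"
    return PaternityCall(
        offspring_id=offspring_id,
        status=status,
        n_trio_mismatches_non_null=n_non_null,
        n_trio_mismatches_total=len(records),
        n_loci_compared=n_compared,
    )


def assign_ep_sire(
    offspring: Genotype,
    mother: Genotype,
    candidates: dict[str, Genotype],
    exclude: tuple[str, ...] = (),
) -> str | None:
    """Assign the extra-pair sire among candidate males.

    A candidate qualifies when the (mother, candidate, offspring) trio is
    compatible at every compared locus except at most one null-consistent
    mismatch.  A unique qualifier is returned; with several qualifiers the
    single zero-mismatch candidate wins if unique, otherwise the assignment
    is left open (None) rather than guessed.
    """
    qualifiers: list[tuple[str, int]] = []
    for cid, geno in candidates.items():
        if cid in exclude:
            continue
        records, _ = trio_mismatch_loci(mother, geno, offspring)
        non_null = sum(not r.null_consistent for r in records)
        if non_null == 0 and len(records) <= 1:
            qualifiers.append((cid, len(records)))
    if not qualifiers:
        return None
    if len(qualifiers) == 1:
        return qualifiers[0][0]
    zero = [cid for cid, nm in qualifiers if nm == 0]
    if len(zero) == 1:
        return zero[0]
    return None


def classify_all(
    genotypes: pd.DataFrame,
    nests: pd.DataFrame | None = None,
    assign_sires: bool = True,
) -> pd.DataFrame:
    """Classify every offspring in a genotype table.

    The table holds one row per individual with ``id``, ``role``
    (adult_male / adult_female / offspring), ``year``, ``mother_id``,
    ``social_father_id`` and the ``L{k}_a1/L{k}_a2`` allele columns.
    Candidate EP sires are all genotyped adult males present in the
    offspring's year, excluding the social father.
    """
    genos = genotypes_from_frame(genotypes)
    off_rows = genotypes[genotypes.role == "offspring"]
    males_by_year: dict[int, dict[str, Genotype]] = {}
    adult_males = genotypes[genotypes.role == "adult_male"]
    for year, grp in adult_males.groupby("year"):
        males_by_year[year] = {str(r["id"]): genos[str(r["id"])] for _, r in grp.iterrows()}

    rows = []
    for _, row in off_rows.iterrows():
        oid, mid, fid = str(row["id"]), str(row["mother_id"]), str(row["social_father_id"])
        year = row["year"]
        call = classify_offspring(genos[oid], genos[mid], genos[fid], offspring_id=oid)
        sire = None
        if call.status == "EP" and assign_sires:
            sire = assign_ep_sire(
                genos[oid],
                genos[mid],
                males_by_year.get(year, {}),
                exclude=(fid,),
            )
        rows.append(
            {
                "offspring_id": oid,
                "nest_id": row.get("nest_id", ""),
                "year": year,
                "mother_id": mid,
                "social_father_id": fid,
                "status": call.status,
                "n_mismatch_non_null": call.n_trio_mismatches_non_null,
                "n_mismatch_total": call.n_trio_mismatches_total,
                "n_loci_compared": call.n_loci_compared,
                "assigned_sire": sire if sire is not None else "",
            }
        )
    return pd.DataFrame(rows)


def male_year_success(calls: pd.DataFrame, nests: pd.DataFrame) -> pd.DataFrame:
    """Roll paternity calls up to male-year mating/reproductive success.

    * ``wp_proportion`` pools all of a male's social nests within a year
      (resolved offspring only).
    * ``polygynous`` requires a second nest whose active window overlaps the
      primary nest's window (simultaneous polygyny).
    * ``annual_rs`` counts within-pair offspring retained in his own nests
      plus extra-pair offspring assigned to him elsewhere, assuming banded
      young fledge.
    * Nests flagged for desertion, ambiguous mate switching, or brood-size
      manipulation are excluded from the affected summaries.
    """
    flag_cols = ["exclude_desertion", "exclude_mate_switch", "exclude_brood_manip"]
    nests = nests.copy()
    for c in flag_cols:
        if c not in nests:
            nests[c] = 0
    excluded_nests = set(nests.loc[nests[flag_cols].any(axis=1), "nest_id"])

    calls = calls.copy()
    for col in ("status", "nest_id", "social_father_id", "assigned_sire", "year"):
        if col not in calls:
            calls[col] = pd.Series(dtype=object)
    resolved = calls[calls.status != "unresolved"]
    ep_by_sire = (
        resolved[resolved.status == "EP"]
        .loc[lambda d: d.assigned_sire != ""]
        .groupby(["assigned_sire", "year"])
        .size()
    )

    rows = []
    for (mid, year), grp in nests.groupby(["male_id", "year"]):
        grp = grp.sort_values(["is_secondary", "begin_day"]) if "is_secondary" in grp else grp
        # simultaneity: any later nest overlapping the primary's window
        polygynous = False
        if len(grp) > 1:
            g = grp.sort_values("begin_day")
            first = g.iloc[0]
            for _, other in g.iloc[1:].iterrows():
                if other.begin_day < first.end_day and other.end_day > first.begin_day:
                    if str(other.get("female_id", "")) != str(first.get("female_id", "")):
                        polygynous = True
        own_nests = [n for n in grp.nest_id if n not in excluded_nests]
        own = resolved[resolved.nest_id.isin(own_nests) & (resolved.social_father_id == mid)]
        n_social = len(own)
        n_wp = int((own.status == "WP").sum())
        n_ep = int(ep_by_sire.get((mid, year), 0))
        rows.append(
            {
                "male_id": mid,
                "year": year,
                "wp_proportion": n_wp / n_social if n_social else np.nan,
                "ep_success": n_ep > 0,
                "polygynous": polygynous,
                "annual_rs": n_wp + n_ep,
                "n_social": n_social,
                "n_ep_sired": n_ep,
            }
        )
    return pd.DataFrame(rows)


def locus_summaries(adult_genotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-locus allele counts and observed / unbiased expected
    heterozygosity over typed adults."""
    adults = adult_genotypes[adult_genotypes.role.str.startswith("adult")]
    adults = adults.drop_duplicates(subset="id")
    n_loci = sum(c.endswith("_a1") and c.startswith("L") for c in adults.columns)
    if len(adults) < 2:
        raise ValueError("need at least 2 typed adults")
    rows = []
    for k in range(1, n_loci + 1):
        a1 = adults[f"L{k}_a1"].to_numpy(int)
        a2 = adults[f"L{k}_a2"].to_numpy(int)
        typed = (a1 != 0) & (a2 != 0)
        a1, a2 = a1[typed], a2[typed]
        n = a1.size
        alleles = np.concatenate([a1, a2])
        uniq, counts = np.unique(alleles, return_counts=True)
        p = counts / counts.sum()
        h_obs = float(np.mean(a1 != a2)) if n else np.nan
        h_exp = float((1.0 - np.sum(p**2)) * (2 * n) / (2 * n - 1)) if n > 0 else np.nan
        rows.append(
            {
                "locus": f"L{k}",
                "n_typed": int(n),
                "n_alleles": int(uniq.size),
                "H_obs": h_obs,
                "H_exp": h_exp,
            }
        )
    return pd.DataFrame(rows)
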