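"""Derived kinship statistics over camps.

Implements the shared-reproductive-interest statistic, the three levels of
relatedness aggregation, kin-network dispersion across camps, camp
stability, and spouse consanguinity/age-gap summaries.

Shared reproductive interest ``s`` measures how related ego expects to be
to an alter's future offspring relative to ego's own future offspring:

    s(i, j) = (r_B + r_D) / (1 + r_C)

where r_B = r(i, j), r_D = r(i, spouse(j)) (0 if j is unmarried) and
r_C = r(i, spouse(i)) (0 if i is unmarried).  Unlike r it also credits
affinal (in-law) ties and is generally asymmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, RelatednessMatrix, _LabelledMatrix

__all__ = [
    "SharedInterestMatrix",
    "CampPanel",
    "AggregationReport",
    "shared_interest_matrix",
    "aggregate",
    "population_mean_relatedness",
    "campmate_means",
    "kin_camp_count",
    "household_residence_options",
    "camp_stability",
    "spouse_summary",
    "load_camp_panel",
]

#: Kin threshold used throughout for "has consanguineal kin in a camp":
#: r = 0.0625, the relatedness of an individual to a first cousin's child.
DEFAULT_KIN_THRESHOLD = 0.0625


class SharedInterestMatrix(_LabelledMatrix):
    """Pairwise shared reproductive interest; asymmetric, NaN diagonal."""

    value_name = "s"


def _check_mutual(spouse_map: Mapping[str, str]) -> None:
    for i, j in spouse_map.items():
        if spouse_map.get(j) != i:
            raise ValueError(f"spouse link not mutual: {i!r} -> {j!r}")


def shared_interest_matrix(
    r: RelatednessMatrix, spouse_map: Mapping[str, str]
) -> SharedInterestMatrix:
    """Compute s(i, j) = (r(i,j) + r(i, spouse_j)) / (1 + r(i, spouse_i)).

    Absent spouses contribute zero: for unmarried j the affinal term r_D
    vanishes, for unmarried i the denominator is 1.  When nobody is married
    to a consanguineal relative and spouses are unrelated to ego, s equals
    r exactly.
    """
    _check_mutual(spouse_map)
    for i in spouse_map:
        if i not in r:
            raise ValueError(f"spouse map id {i!r} not covered by the matrix")
    ids = r.ids
    n = len(ids)
    rv = np.where(np.isnan(r.values), 0.0, r.values)
    # column j of r_D is ego's relatedness to j's spouse
    r_d = np.zeros((n, n))
    r_c = np.zeros(n)
    for j, jid in enumerate(ids):
        sp = spouse_map.get(jid)
        if sp is not None and sp in r.index:
            r_d[:, j] = rv[:, r.index[sp]]
            r_c[j] = rv[j, r.index[sp]]
    s = (rv + r_d) / (1.0 + r_c)[:, None]
    np.fill_diagonal(s, np.nan)
    return SharedInterestMatrix(ids, s)


# ---------------------------------------------------------------------------
# Camp panel
# ---------------------------------------------------------------------------

@dataclass
class CampPanel:
    """Camp memberships, coordinates, visit rosters and covariates.

    ``memberships`` maps individual -> camp at census; ``visit_rosters``
    maps camp -> ordered list of member-id sets, one per visit;
    ``coordinates`` maps camp -> (latitude deg, longitude deg);
    ``covariates`` maps camp -> {"foraging_proportion": ..., ...}.
    """

    memberships: dict[str, str]
    coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)
    visit_rosters: dict[str, list[set[str]]] = field(default_factory=dict)
    covariates: dict[str, dict[str, float]] = field(default_factory=dict)

    def camps(self) -> list[str]:
        return sorted(set(self.memberships.values()))

    def members(self, camp_id: str) -> list[str]:
        return sorted(i for i, c in self.memberships.items() if c == camp_id)

    def validate_against(self, ped: Pedigree) -> None:
        orphans = sorted(
            {i for i in self.memberships if i not in ped}
            | {
                i
                for rosters in self.visit_rosters.values()
                for roster in rosters
                for i in roster
                if i not in ped
            }
        )
        if orphans:
            raise ValueError(
                f"camp panel references {len(orphans)} unknown individuals, "
                f"e.g. {orphans[:5]}"
            )

    def stability(self) -> pd.Series:
        """Per-camp stability index from the visit rosters (NaN if <2 visits)."""
        out = {}
        for camp, rosters in self.visit_rosters.items():
            out[camp] = (
                camp_stability(rosters) if len(rosters) >= 2 else np.nan
            )
        return pd.Series(out, name="stability", dtype=float)


def load_camp_panel(
    attributes_path: str | Path,
    rosters_path: str | Path | None = None,
    coordinates_path: str | Path | None = None,
    covariates_path: str | Path | None = None,
) -> CampPanel:
    """Assemble a CampPanel from the delimited-text inputs.

    Attribute CSV: columns ``id``, ``camp`` (others ignored here);
    roster CSV: ``camp, visit_index, member_id``;
    coordinate CSV: ``camp, lat, lon``;
    covariate CSV: ``camp, foraging_proportion`` (extra columns kept).
    """
    attrs = pd.read_csv(attributes_path, dtype={"id": str, "camp": str})
    attrs.columns = [c.strip().lower() for c in attrs.columns]
    memberships = {
        str(row["id"]): str(row["camp"])
        for _, row in attrs.iterrows()
        if "camp" in attrs.columns and not pd.isna(row["camp"])
    }
    panel = CampPanel(memberships=memberships)
    if rosters_path is not None:
        rosters = pd.read_csv(
            rosters_path, dtype={"camp": str, "member_id": str}
        )
        for camp, grp in rosters.groupby("camp"):
            visits = []
            for _, visit_grp in sorted(grp.groupby("visit_index")):
                visits.append(set(visit_grp["member_id"]))
            panel.visit_rosters[str(camp)] = visits
    if coordinates_path is not None:
        coords = pd.read_csv(coordinates_path, dtype={"camp": str})
        panel.coordinates = {
            str(row["camp"]): (float(row["lat"]), float(row["lon"]))
            for _, row in coords.iterrows()
        }
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path, dtype={"camp": str})
        for _, row in cov.iterrows():
            panel.covariates[str(row["camp"])] = {
                k: float(v)
                for k, v in row.items()
                if k != "camp" and not pd.isna(v)
            }
    return panel


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class AggregationReport:
    """The three aggregation levels of within-camp relatedness.

    r_group averages per-camp mean pairwise relatedness across camps;
    r_individual averages each individual's mean relatedness to campmates
    across individuals; r_dyads averages over all co-resident dyads.  With
    unequal camp sizes and larger camps less related (the typical case),
    r_dyads <= r_individual <= r_group.
    """

    subset: str
    r_group: float
    r_individual: float
    r_dyads: float
    n_groups: int
    n_individuals: int
    n_dyads: int
    per_camp: pd.DataFrame          # index camp_id; columns size, mean_r
    per_individual: pd.Series       # index id; mean r to campmates
    sd_individual: float = float("nan")

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": ["r_group", "r_individual", "r_dyads"],
                "value": [self.r_group, self.r_individual, self.r_dyads],
                "n": [self.n_groups, self.n_individuals, self.n_dyads],
            }
        )


_SUBSETS = ("everyone", "adults_only", "adult_to_child", "child_to_child")


def _adult_lookup(ped_or_flags) -> Mapping[str, bool]:
    if ped_or_flags is None:
        raise ValueError("this subset needs adult flags (pass a Pedigree "
                         "or an id -> bool mapping)")
    if isinstance(ped_or_flags, Pedigree):
        return {i: rec.is_adult for i, rec in ped_or_flags.records.items()}
    return ped_or_flags


def aggregate(
    r: RelatednessMatrix,
    memberships: Mapping[str, str],
    subset: str = "everyone",
    adults: "Pedigree | Mapping[str, bool] | None" = None,
) -> AggregationReport:
    """Aggregate pairwise relatedness within camps at all three levels.

    ``subset`` selects the dyads considered: ``everyone`` and
    ``adults_only`` use all (or adult-only) co-resident pairs;
    ``adult_to_child`` uses adult-child co-resident pairs, with
    r_individual the mean over adults of their mean relatedness to
    co-resident children; ``child_to_child`` mirrors ``adults_only`` for
    children.  Individuals with no counterpart in their camp are excluded
    from r_individual and camps without a qualifying dyad from r_group.
    """
    if subset not in _SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; choose from {_SUBSETS}")
    members = {i: c for i, c in memberships.items() if i in r}
    if subset == "everyone":
        rows = cols = set(members)
    else:
        flags = _adult_lookup(adults)
        adults_set = {i for i in members if flags.get(i, True)}
        children = set(members) - adults_set
        if subset == "adults_only":
            rows = cols = adults_set
        elif subset == "child_to_child":
            rows = cols = children
        else:  # adult_to_child
            rows, cols = adults_set, children
    if not rows or not cols:
        raise ValueError(f"subset {subset!r} selects no individuals")

    per_ind: dict[str, float] = {}
    per_camp_vals: dict[str, list[float]] = {}
    per_camp_size: dict[str, int] = {}
    all_dyads: list[float] = []
    camps: dict[str, list[str]] = {}
    for i, c in members.items():
        camps.setdefault(c, []).append(i)
    symmetric = rows == cols
    for camp, ids in camps.items():
        camp_rows = [i for i in ids if i in rows]
        camp_cols = [i for i in ids if i in cols]
        if not camp_rows or not camp_cols:
            continue
        sub = r.values[
            np.ix_([r.index[i] for i in camp_rows],
                   [r.index[j] for j in camp_cols])
        ]
        vals: list[float] = []
        for a, ia in enumerate(camp_rows):
            others = [
                sub[a, b] for b, ib in enumerate(camp_cols) if ib != ia
            ]
            if others:
                per_ind[ia] = float(np.mean(others))
            if symmetric:
                # unordered pairs counted once
                vals.extend(
                    sub[a, b]
                    for b in range(a + 1, len(camp_cols))
                )
            else:
                vals.extend(others)
        if vals:
            per_camp_vals[camp] = vals
            per_camp_size[camp] = len(camp_rows)
            all_dyads.extend(vals)
    if not all_dyads:
        raise ValueError(
            f"no qualifying co-resident dyads for subset {subset!r}"
        )
    per_camp = pd.DataFrame(
        {
            "size": pd.Series(per_camp_size),
            "mean_r": pd.Series(
                {c: float(np.mean(v)) for c, v in per_camp_vals.items()}
            ),
        }
    ).sort_index()
    per_individual = pd.Series(per_ind, name="mean_r_to_campmates").sort_index()
    return AggregationReport(
        subset=subset,
        r_group=float(per_camp["mean_r"].mean()),
        r_individual=float(per_individual.mean()),
        r_dyads=float(np.mean(all_dyads)),
        n_groups=len(per_camp),
        n_individuals=len(per_individual),
        n_dyads=len(all_dyads),
        per_camp=per_camp,
        per_individual=per_individual,
        sd_individual=float(per_individual.std(ddof=1))
        if len(per_individual) > 1
        else float("nan"),
    )


def campmate_means(
    r: _LabelledMatrix,
    memberships: Mapping[str, str],
    include: Iterable[str] | None = None,
) -> pd.Series:
    """Each individual's mean matrix value to campmates (any labelled
    matrix: r or s).  ``include`` restricts both egos and campmates."""
    keep = set(include) if include is not None else set(r.ids)
    members = {i: c for i, c in memberships.items() if i in r and i in keep}
    camps: dict[str, list[str]] = {}
    for i, c in members.items():
        camps.setdefault(c, []).append(i)
    out: dict[str, float] = {}
    for ids in camps.values():
        if len(ids) < 2:
            continue
        idx = [r.index[i] for i in ids]
        sub = r.values[np.ix_(idx, idx)]
        for a, ia in enumerate(ids):
            others = np.delete(sub[a], a)
            out[ia] = float(np.mean(others))
    return pd.Series(out, name=f"mean_{r.value_name}_to_campmates").sort_index()


def population_mean_relatedness(
    r: _LabelledMatrix, subset: Iterable[str] | None = None
) -> tuple[float, float, pd.Series]:
    """Mean relatedness of each individual to everyone else in the subset,
    averaged across individuals; returns (mean, SD across individuals,
    per-individual series)."""
    ids = list(subset) if subset is not None else list(r.ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 individuals")
    idx = [r.index[i] for i in ids]
    sub = r.values[np.ix_(idx, idx)]
    per = {}
    for a, ia in enumerate(ids):
        per[ia] = float(np.mean(np.delete(sub[a], a)))
    series = pd.Series(per).sort_index()
    sd = float(series.std(ddof=1)) if len(series) > 1 else float("nan")
    return float(series.mean()), sd, series


# ---------------------------------------------------------------------------
# Kin dispersion across camps
# ---------------------------------------------------------------------------

def kin_camp_count(
    r: RelatednessMatrix,
    memberships: Mapping[str, str],
    ego: str,
    threshold: float = DEFAULT_KIN_THRESHOLD,
    include_own_camp: bool = True,
) -> int:
    """Number of camps containing at least one individual (other than ego)
    with r(ego, .) >= threshold.

    Ego's own camp is counted when it contains such kin (the default); set
    ``include_own_camp=False`` to count only other camps.
    """
    if ego not in r:
        raise KeyError(f"unknown ego {ego!r}")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    ego_camp = memberships.get(ego)
    camps: set[str] = set()
    ei = r.index[ego]
    for j, camp in memberships.items():
        if j == ego or j not in r.index:
            continue
        if not include_own_camp and camp == ego_camp:
            continue
        if r.values[ei, r.index[j]] >= threshold:
            camps.add(camp)
    return len(camps)


def _kin_camps(r, memberships, ego, threshold) -> set[str]:
    ei = r.index[ego]
    return {
        camp
        for j, camp in memberships.items()
        if j != ego and j in r.index
        and r.values[ei, r.index[j]] >= threshold
    }


def household_residence_options(
    r: RelatednessMatrix,
    memberships: Mapping[str, str],
    couple: tuple[str, str],
    threshold: float = DEFAULT_KIN_THRESHOLD,
) -> int:
    """Number of camps where a married household could reside: camps with
    kin at r >= threshold of either spouse, plus each spouse's current camp."""
    a, b = couple
    for i in (a, b):
        if i not in r:
            raise KeyError(f"unknown individual {i!r}")
    camps = _kin_camps(r, memberships, a, threshold) | _kin_camps(
        r, memberships, b, threshold
    )
    for i in (a, b):
        if i in memberships:
            camps.add(memberships[i])
    return len(camps)


# ---------------------------------------------------------------------------
# Camp stability
# ---------------------------------------------------------------------------

def camp_stability(rosters: Sequence[Iterable[str]]) -> float:
    """Membership persistence across repeated visits, in [0, 1].

    Operationalised as the mean Jaccard similarity of consecutive visit
    rosters: 1 means identical composition throughout, 0 means complete
    turnover between every pair of consecutive visits.
    """
    rosters = [set(v) for v in rosters]
    if len(rosters) < 2:
        raise ValueError("camp stability needs at least 2 visits")
    sims = []
    for prev, cur in zip(rosters[:-1], rosters[1:]):
        union = prev | cur
        sims.append(len(prev & cur) / len(union) if union else 1.0)
    return float(np.mean(sims))


# ---------------------------------------------------------------------------
# Spouses
# ---------------------------------------------------------------------------

def spouse_summary(
    ped: Pedigree, r: RelatednessMatrix
) -> tuple[pd.DataFrame, dict]:
    """One row per marriage: spousal relatedness and the signed age gap
    (husband age minus wife age; positive = husband older).

    Couples with a missing age keep their consanguinity entry but have a
    missing gap.  The summary dict reports mean/SD/range of the gap and
    the proportion of marriages with an older husband.
    """
    rows = []
    seen = set()
    for i, rec in ped.records.items():
        j = rec.spouse_id
        if j is None or (j, i) in seen:
            continue
        seen.add((i, j))
        other = ped.records[j]
        if rec.sex == "male":
            husband, wife = rec, other
        else:
            husband, wife = other, rec
        gap = (
            husband.age_years - wife.age_years
            if husband.age_years is not None and wife.age_years is not None
            else np.nan
        )
        rows.append(
            {
                "husband": husband.id,
                "wife": wife.id,
                "r_spouses": r.loc(husband.id, wife.id),
                "age_gap": gap,
            }
        )
    table = pd.DataFrame(
        rows, columns=["husband", "wife", "r_spouses", "age_gap"]
    )
    gaps = table["age_gap"].dropna()
    summary = {
        "n_marriages": len(table),
        "n_consanguineous": int((table["r_spouses"] > 0).sum()),
        "n_with_ages": int(len(gaps)),
        "mean_gap": float(gaps.mean()) if len(gaps) else np.nan,
        "sd_gap": float(gaps.std(ddof=1)) if len(gaps) > 1 else np.nan,
        "min_gap": float(gaps.min()) if len(gaps) else np.nan,
        "max_gap": float(gaps.max()) if len(gaps) else np.nan,
        "prop_husband_older": float((gaps > 0).mean()) if len(gaps) else np.nan,
    }
    return table, summary
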