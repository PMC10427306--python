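"""Synthetic genealogies and camp structures for pipeline testing.

The generator emulates the demographic scales of a small mobile forager
population: ~15 residential camps averaging ~18 adults, a four-generation
genealogy, monogamous marriages between (mostly) genealogically unrelated
partners from different camps, bilocal post-marital residence (couples
settle with either spouse's camp), husband-older spousal age gaps, camp
coordinates over a few tens of kilometres, and repeated camp visits with
partial household turnover.

Dispersal is the experimental lever: under the bilocal default no
systematic sex difference in within-camp relatedness should arise, while
patrilocal (matrilocal) settings keep men (women) with their natal kin and
produce the corresponding asymmetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable

import numpy as np
import yaml

from .pedigree import (
    FEMALE,
    MALE,
    IndividualRecord,
    Pedigree,
    RelatednessMatrix,
)
from .stats import CampPanel

__all__ = [
    "GeneratorConfig",
    "generate_population",
    "worked_example_fixture",
    "named_pedigree_fixtures",
    "write_population",
]

#: Reference point for synthetic camp coordinates (northeastern Luzon).
BASE_LAT = 17.05
BASE_LON = 122.40
KM_PER_DEG_LAT = 111.32


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic population.

    Defaults reproduce, in expectation, the descriptive scales the
    analysis assumes: 15 camps of ~18 adults; four genealogical
    generations; near-absolute prohibition of kin marriage with a rare
    exception rate (2 in 80 marriages); husband-older age gap of mean
    4.29 y (SD 5.31); camps spread over a ~40 km extent with marriage
    partners preferentially drawn from nearby camps; visit rosters with
    partial per-visit household turnover.

    Households (a couple with dependent children, or a lone unmarried
    individual) are the mobile unit.  After post-marital settlement,
    ``relocation_rounds`` rounds of mobility churn residence before the
    census: each round a household moves with probability
    ``turnover_per_visit``, choosing a destination among camps where
    either adult has a kin tie at r >= ``kin_tie_threshold`` (joining a
    camp requires kinship to a member, as in mobile forager ethnography),
    weighted towards nearby camps by ``distance_decay_km``.  The same
    process continues between visit rosters.
    """

    n_camps: int = 15
    mean_adults_per_camp: float = 18.1
    n_generations: int = 4
    dispersal: str = "bilocal"          # bilocal | patrilocal | matrilocal | custom
    p_settle_husband: float | None = None   # used when dispersal == "custom"
    marriage_kin_threshold: float = 0.0  # max spousal r; 0 = no known ancestry
    consanguineous_exception_rate: float = 2.0 / 80.0
    husband_age_gap_mean: float = 4.29
    husband_age_gap_sd: float = 5.31
    camp_extent_km: float = 40.0
    distance_decay_km: float | None = 20.0
    turnover_per_visit: float = 0.33
    n_visits: int = 4
    kin_tie_threshold: float = 0.0625
    relocation_rounds: int = 2
    mean_offspring: float = 3.0
    generation_interval_years: float = 25.0
    adult_age_years: float = 18.0
    seed: int = 0

    def settle_probability(self) -> float:
        table = {"bilocal": 0.5, "patrilocal": 1.0, "matrilocal": 0.0}
        if self.dispersal in table:
            return table[self.dispersal]
        if self.dispersal == "custom":
            if self.p_settle_husband is None:
                raise ValueError("custom dispersal needs p_settle_husband")
            return float(self.p_settle_husband)
        raise ValueError(f"unknown dispersal rule {self.dispersal!r}")

    def validate(self) -> None:
        if self.n_camps < 2:
            raise ValueError(
                "need at least 2 camps: marriage partners come from other camps"
            )
        if self.n_generations < 2:
            raise ValueError("need at least 2 generations")
        for name in ("consanguineous_exception_rate", "turnover_per_visit"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.mean_adults_per_camp <= 0 or self.mean_offspring <= 0:
            raise ValueError("counts and rates must be positive")
        self.settle_probability()  # raises on bad dispersal spec

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------

class _Builder:
    """Mutable state while growing one synthetic population."""

    def __init__(self, cfg: GeneratorConfig):
        cfg.validate()
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.records: dict[str, dict] = {}
        self.camps = [f"C{k+1:02d}" for k in range(cfg.n_camps)]
        self._next = 1
        # planar camp positions (km) mapped onto a lat/lon patch
        ext = cfg.camp_extent_km
        xy = self.rng.uniform(0.0, ext, size=(cfg.n_camps, 2))
        self.camp_xy = {c: tuple(xy[k]) for k, c in enumerate(self.camps)}
        self.coordinates = {
            c: (
                BASE_LAT + y / KM_PER_DEG_LAT,
                BASE_LON + x / (KM_PER_DEG_LAT *
                                math.cos(math.radians(BASE_LAT))),
            )
            for c, (x, y) in self.camp_xy.items()
        }
        self._phi_memo: dict[tuple[str, str], float] = {}

    # -- bookkeeping ----------------------------------------------------

    def new_id(self) -> str:
        iid = f"I{self._next:04d}"
        self._next += 1
        return iid

    def add(self, sex, generation, camp, father=None, mother=None) -> str:
        iid = self.new_id()
        self.records[iid] = {
            "id": iid,
            "sex": sex,
            "generation": generation,
            "camp": camp,
            "natal_camp": camp,
            "father": father,
            "mother": mother,
            "spouse": None,
            "age": None,
        }
        return iid

    def kinship(self, a: str, b: str) -> float:
        """Recursive kinship on the partial pedigree (memoised)."""
        if a == b:
            ra = self.records[a]
            f, m = ra["father"], ra["mother"]
            fi = self.kinship(f, m) if (f and m) else 0.0
            return 0.5 * (1.0 + fi)
        key = (a, b) if a < b else (b, a)
        if key in self._phi_memo:
            return self._phi_memo[key]
        ra, rb = self.records[a], self.records[b]
        # recurse through the younger individual's parents
        if ra["generation"] < rb["generation"]:
            a, b, ra, rb = b, a, rb, ra
        f, m = ra["father"], ra["mother"]
        if f is None and m is None:
            if rb["father"] is None and rb["mother"] is None:
                val = 0.0
            else:
                f, m = rb["father"], rb["mother"]
                val = 0.5 * (
                    (self.kinship(f, a) if f else 0.0)
                    + (self.kinship(m, a) if m else 0.0)
                )
        else:
            val = 0.5 * (
                (self.kinship(f, b) if f else 0.0)
                + (self.kinship(m, b) if m else 0.0)
            )
        self._phi_memo[key] = val
        return val

    def relatedness(self, a: str, b: str) -> float:
        return 2.0 * self.kinship(a, b)

    # -- demographic steps ----------------------------------------------

    def founders_per_camp(self) -> int:
        cfg = self.cfg
        growth = cfg.mean_offspring / 2.0
        gens_of_adults = cfg.n_generations - 1
        expected_adults_per_couple = 2.0 * sum(
            growth**t for t in range(gens_of_adults)
        )
        return max(1, round(cfg.mean_adults_per_camp /
                            expected_adults_per_couple))

    def seed_founders(self) -> list[tuple[str, str]]:
        couples = []
        for camp in self.camps:
            for _ in range(self.founders_per_camp()):
                h = self.add(MALE, 0, camp)
                w = self.add(FEMALE, 0, camp)
                self.marry(h, w, camp)
                couples.append((h, w))
        return couples

    def marry(self, husband: str, wife: str, camp: str) -> None:
        self.records[husband]["spouse"] = wife
        self.records[wife]["spouse"] = husband
        self.records[husband]["camp"] = camp
        self.records[wife]["camp"] = camp

    def bear_children(self, couples: Iterable[tuple[str, str]],
                      generation: int) -> list[str]:
        kids = []
        for h, w in couples:
            camp = self.records[h]["camp"]
            for _ in range(self.rng.poisson(self.cfg.mean_offspring)):
                sex = MALE if self.rng.random() < 0.5 else FEMALE
                kids.append(self.add(sex, generation, camp, father=h, mother=w))
        return kids

    def marriage_round(self, cohort: list[str]) -> list[tuple[str, str]]:
        """Match unmarried cohort members across camps.

        Each man samples a wife among women of the cohort whose natal camp
        differs from his, weighted by exp(-distance/decay) when a decay
        scale is set.  Candidates with known shared ancestry (r above the
        kin threshold) are excluded, except that with the configured
        exception probability a related candidate is chosen instead,
        emulating the rare consanguineous marriage.
        """
        cfg = self.cfg
        p_husband = cfg.settle_probability()
        men = [i for i in cohort if self.records[i]["sex"] == MALE]
        women = [i for i in cohort if self.records[i]["sex"] == FEMALE]
        self.rng.shuffle(men)
        free_women = set(women)
        couples = []
        for man in men:
            mcamp = self.records[man]["camp"]
            candidates = [
                w for w in sorted(free_women)
                if self.records[w]["natal_camp"] != mcamp
            ]
            if not candidates:
                continue
            related = [
                w for w in candidates
                if self.relatedness(man, w) > cfg.marriage_kin_threshold
            ]
            unrelated = [w for w in candidates if w not in set(related)]
            pool = unrelated
            if related and (
                not unrelated
                or self.rng.random() < cfg.consanguineous_exception_rate
            ):
                pool = related
            if not pool:
                continue
            if cfg.distance_decay_km:
                d = np.array([
                    math.dist(self.camp_xy[mcamp],
                              self.camp_xy[self.records[w]["natal_camp"]])
                    for w in pool
                ])
                weights = np.exp(-d / cfg.distance_decay_km)
                weights /= weights.sum()
                wife = pool[self.rng.choice(len(pool), p=weights)]
            else:
                wife = pool[self.rng.integers(len(pool))]
            free_women.discard(wife)
            settle = (
                mcamp
                if self.rng.random() < p_husband
                else self.records[wife]["natal_camp"]
            )
            self.marry(man, wife, settle)
            couples.append((man, wife))
        return couples

    def assign_ages(self) -> None:
        cfg = self.cfg
        G = cfg.n_generations
        for rec in self.records.values():
            g = rec["generation"]
            if g == G - 1:
                rec["age"] = float(self.rng.uniform(1.0, cfg.adult_age_years - 2))
                continue
            mean_age = (
                cfg.adult_age_years / 2.0
                + (G - 1 - g) * cfg.generation_interval_years
            )
            if rec["sex"] == FEMALE:
                rec["age"] = float(
                    max(cfg.adult_age_years, self.rng.normal(mean_age, 5.0))
                )
        # husbands' ages follow their wives with the configured gap
        for rec in self.records.values():
            if rec["sex"] != MALE or rec["generation"] == G - 1:
                continue
            spouse = rec["spouse"]
            gap = self.rng.normal(cfg.husband_age_gap_mean,
                                  cfg.husband_age_gap_sd)
            if spouse is not None:
                rec["age"] = float(
                    max(cfg.adult_age_years, self.records[spouse]["age"] + gap)
                )
            else:
                mean_age = (
                    cfg.adult_age_years / 2.0
                    + (G - 1 - rec["generation"])
                    * cfg.generation_interval_years
                )
                rec["age"] = float(
                    max(cfg.adult_age_years, self.rng.normal(mean_age, 5.0))
                )

    def households(self) -> list[list[str]]:
        """Mobile units: a couple plus their last-generation children, or a
        lone unmarried individual."""
        G = self.cfg.n_generations
        units: dict[str, list[str]] = {}
        singles: list[list[str]] = []
        for iid, rec in self.records.items():
            if rec["spouse"] is not None and rec["sex"] == MALE:
                units[iid] = [iid, rec["spouse"]]
        for iid, rec in self.records.items():
            if rec["generation"] == G - 1:
                father = rec["father"]
                if father in units:
                    units[father].append(iid)
                else:
                    singles.append([iid])
            elif rec["spouse"] is None:
                singles.append([iid])
        return list(units.values()) + singles

    def _pairwise_relatedness(self) -> tuple[dict[str, int], np.ndarray]:
        """Full r matrix on the records built so far (vectorised DP)."""
        from .pedigree import kinship_matrix

        recs = [
            IndividualRecord(
                id=rec["id"], father_id=rec["father"], mother_id=rec["mother"],
                sex=rec["sex"], spouse_id=rec["spouse"],
            )
            for rec in self.records.values()
        ]
        k = kinship_matrix(Pedigree(recs))
        return k.index, 2.0 * k.values

    def _mobility_step(
        self,
        assignment: dict[tuple[str, ...], str],
        adult_heads: dict[tuple[str, ...], list[str]],
        ridx: dict[str, int],
        rmat: np.ndarray,
    ) -> None:
        """One round of household mobility: with the turnover probability,
        move to a camp where either adult head has a kin tie at
        r >= kin_tie_threshold (distance-decay weighted); stay put if no
        such camp exists."""
        cfg = self.cfg
        camp_rows: dict[str, list[int]] = {c: [] for c in self.camps}
        for household, camp in assignment.items():
            camp_rows[camp].extend(ridx[m] for m in household)
        for household, camp in list(assignment.items()):
            if self.rng.random() >= cfg.turnover_per_visit:
                continue
            head_rows = [ridx[h] for h in adult_heads[household]]
            own = set(ridx[m] for m in household)
            eligible = []
            for cand in self.camps:
                if cand == camp:
                    continue
                members = [m for m in camp_rows[cand] if m not in own]
                if members and np.any(
                    rmat[np.ix_(head_rows, members)] >= cfg.kin_tie_threshold
                ):
                    eligible.append(cand)
            if eligible:
                if cfg.distance_decay_km:
                    d = np.array([
                        math.dist(self.camp_xy[camp], self.camp_xy[c])
                        for c in eligible
                    ])
                    w = np.exp(-d / cfg.distance_decay_km)
                    dest = eligible[self.rng.choice(len(eligible),
                                                    p=w / w.sum())]
                else:
                    dest = eligible[self.rng.integers(len(eligible))]
                for m in household:
                    camp_rows[camp].remove(ridx[m])
                camp_rows[dest].extend(ridx[m] for m in household)
                assignment[household] = dest

    def churn_and_rosters(self) -> dict[str, list[set[str]]]:
        """Run pre-census mobility, fix census camps, then record visit
        rosters with the same mobility process continuing in between."""
        cfg = self.cfg
        units = self.households()
        assignment = {
            tuple(h): self.records[h[0]]["camp"] for h in units
        }
        adult_heads = {
            tuple(h): [m for m in h
                       if self.records[m]["generation"] < cfg.n_generations - 1]
            or list(h)[:1]
            for h in units
        }
        ridx, rmat = self._pairwise_relatedness()
        for _ in range(cfg.relocation_rounds):
            self._mobility_step(assignment, adult_heads, ridx, rmat)
        for household, camp in assignment.items():
            for m in household:
                self.records[m]["camp"] = camp
        rosters: dict[str, list[set[str]]] = {c: [] for c in self.camps}
        for v in range(cfg.n_visits):
            current: dict[str, set[str]] = {c: set() for c in self.camps}
            for household, camp in assignment.items():
                current[camp].update(household)
            for c in self.camps:
                rosters[c].append(current[c])
            if v < cfg.n_visits - 1:
                self._mobility_step(assignment, adult_heads, ridx, rmat)
        return rosters

    # -- assembly --------------------------------------------------------

    def build(self) -> tuple[Pedigree, CampPanel]:
        cfg = self.cfg
        couples = self.seed_founders()
        for g in range(1, cfg.n_generations):
            cohort = self.bear_children(couples, g)
            if g < cfg.n_generations - 1:
                couples = self.marriage_round(cohort)
            else:
                couples = []
        self.assign_ages()
        rosters = self.churn_and_rosters()

        records = [
            IndividualRecord(
                id=rec["id"],
                father_id=rec["father"],
                mother_id=rec["mother"],
                sex=rec["sex"],
                age_years=rec["age"],
                camp_id=rec["camp"],
                spouse_id=rec["spouse"],
                is_adult=rec["age"] >= cfg.adult_age_years,
            )
            for rec in self.records.values()
        ]
        ped = Pedigree(records)
        memberships = {r.id: r.camp_id for r in records}
        adult_counts = {c: 0 for c in self.camps}
        for r in records:
            if r.is_adult:
                adult_counts[r.camp_id] += 1
        covariates = {
            c: {
                "foraging_proportion": float(self.rng.uniform(0.195, 1.0)),
                "size": float(adult_counts[c]),
            }
            for c in self.camps
        }
        panel = CampPanel(
            memberships=memberships,
            coordinates=dict(self.coordinates),
            visit_rosters=rosters,
            covariates=covariates,
        )
        return ped, panel


def generate_population(cfg: GeneratorConfig | None = None,
                        **overrides) -> tuple[Pedigree, CampPanel]:
    """Generate one synthetic population (Pedigree + CampPanel).

    Fully reproducible from ``cfg.seed``; keyword overrides are applied to
    the default configuration for convenience.
    """
    if cfg is None:
        cfg = GeneratorConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    return _Builder(cfg).build()


def write_population(ped: Pedigree, panel: CampPanel, out_dir) -> dict:
    """Write genealogy, attribute, roster, coordinate and covariate files
    in the formats the loaders consume; returns the path map."""
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genealogy": out / "genealogy.csv",
        "attributes": out / "attributes.csv",
        "rosters": out / "rosters.csv",
        "coordinates": out / "coordinates.csv",
        "covariates": out / "covariates.csv",
    }
    recs = [ped.records[i] for i in sorted(ped.records)]
    pd.DataFrame(
        {
            "id": [r.id for r in recs],
            "father": [r.father_id or "0" for r in recs],
            "mother": [r.mother_id or "0" for r in recs],
            "sex": [r.sex for r in recs],
        }
    ).to_csv(paths["genealogy"], index=False)
    pd.DataFrame(
        {
            "id": [r.id for r in recs],
            "age": [r.age_years for r in recs],
            "camp": [r.camp_id for r in recs],
            "spouse": [r.spouse_id or "0" for r in recs],
            "adult": [int(r.is_adult) for r in recs],
        }
    ).to_csv(paths["attributes"], index=False)
    roster_rows = [
        {"camp": c, "visit_index": v, "member_id": m}
        for c, visits in sorted(panel.visit_rosters.items())
        for v, roster in enumerate(visits)
        for m in sorted(roster)
    ]
    pd.DataFrame(roster_rows,
                 columns=["camp", "visit_index", "member_id"]).to_csv(
        paths["rosters"], index=False
    )
    pd.DataFrame(
        [
            {"camp": c, "lat": lat, "lon": lon}
            for c, (lat, lon) in sorted(panel.coordinates.items())
        ]
    ).to_csv(paths["coordinates"], index=False)
    pd.DataFrame(
        [
            {"camp": c, **cov}
            for c, cov in sorted(panel.covariates.items())
        ]
    ).to_csv(paths["covariates"], index=False)
    return paths


# ---------------------------------------------------------------------------
# Deterministic fixtures
# ---------------------------------------------------------------------------

def worked_example_fixture() -> tuple[RelatednessMatrix, dict[str, str]]:
    """Two communities with constant internal relatedness: 20 members at
    r = 0.1 and 100 members at r = 0.02, unrelated across communities.

    The matrix is set directly (no pedigree); the fixture exercises the
    divergence of the three aggregation levels under unequal group sizes.
    """
    ids_a = [f"A{k:02d}" for k in range(1, 21)]
    ids_b = [f"B{k:03d}" for k in range(1, 101)]
    ids = ids_a + ids_b
    n = len(ids)
    r = np.zeros((n, n))
    r[:20, :20] = 0.1
    r[20:, 20:] = 0.02
    np.fill_diagonal(r, np.nan)
    memberships = {i: "camp_small" for i in ids_a}
    memberships.update({i: "camp_large" for i in ids_b})
    return RelatednessMatrix(ids, r), memberships


def _rec(iid, sex, father=None, mother=None, spouse=None, **kw):
    return IndividualRecord(id=iid, sex=sex, father_id=father,
                            mother_id=mother, spouse_id=spouse, **kw)


def named_pedigree_fixtures() -> dict[str, dict]:
    """Hand-built pedigrees for the canonical relationship classes.

    Each entry carries the pedigree, the target pair, and the expected
    kinship (phi) and relatedness (r) values for a fully outbred pedigree
    (except the deliberately inbred case).
    """
    out: dict[str, dict] = {}

    out["trio"] = {
        "pedigree": Pedigree([
            _rec("F", MALE), _rec("M", FEMALE),
            _rec("C", FEMALE, father="F", mother="M"),
        ]),
        "pair": ("F", "C"), "phi": 0.25, "r": 0.5,
    }

    out["full_siblings"] = {
        "pedigree": Pedigree([
            _rec("F", MALE), _rec("M", FEMALE),
            _rec("S1", MALE, father="F", mother="M"),
            _rec("S2", FEMALE, father="F", mother="M"),
        ]),
        "pair": ("S1", "S2"), "phi": 0.25, "r": 0.5,
    }

    out["half_siblings"] = {
        "pedigree": Pedigree([
            _rec("F", MALE), _rec("M1", FEMALE), _rec("M2", FEMALE),
            _rec("H1", MALE, father="F", mother="M1"),
            _rec("H2", FEMALE, father="F", mother="M2"),
        ]),
        "pair": ("H1", "H2"), "phi": 0.125, "r": 0.25,
    }

    # Married first cousins: the husband's mother and the wife's father
    # are full siblings; every in-marrying spouse is an unrelated founder.
    out["first_cousin_spouses"] = {
        "pedigree": Pedigree([
            _rec("GF", MALE), _rec("GM", FEMALE),
            _rec("AUNT", FEMALE, father="GF", mother="GM"),   # husband's mother
            _rec("UNCLE", MALE, father="GF", mother="GM"),    # wife's father
            _rec("AH", MALE), _rec("UW", FEMALE),
            _rec("HUSB", MALE, father="AH", mother="AUNT", spouse="WIFE"),
            _rec("WIFE", FEMALE, father="UNCLE", mother="UW", spouse="HUSB"),
        ]),
        "pair": ("HUSB", "WIFE"), "phi": 0.0625, "r": 0.125,
    }

    # Second cousins: shared great-grandparental founder couple.
    out["second_cousins"] = {
        "pedigree": Pedigree([
            _rec("GGF", MALE), _rec("GGM", FEMALE),
            _rec("GA", MALE, father="GGF", mother="GGM"),
            _rec("GB", FEMALE, father="GGF", mother="GGM"),
            _rec("GAW", FEMALE), _rec("GBH", MALE),
            _rec("PA", MALE, father="GA", mother="GAW"),
            _rec("PB", FEMALE, father="GBH", mother="GB"),
            _rec("PAW", FEMALE), _rec("PBH", MALE),
            _rec("X", MALE, father="PA", mother="PAW"),
            _rec("Y", FEMALE, father="PBH", mother="PB"),
        ]),
        "pair": ("X", "Y"), "phi": 0.015625, "r": 0.03125,
    }

    # Ego and ego's first cousin's child (first cousin once removed).
    out["cousins_child"] = {
        "pedigree": Pedigree([
            _rec("GF", MALE), _rec("GM", FEMALE),
            _rec("PA", MALE, father="GF", mother="GM"),
            _rec("PB", FEMALE, father="GF", mother="GM"),
            _rec("PAW", FEMALE), _rec("PBH", MALE),
            _rec("EGO", FEMALE, father="PA", mother="PAW"),
            _rec("CUZ", MALE, father="PBH", mother="PB"),
            _rec("CUZW", FEMALE),
            _rec("KID", MALE, father="CUZ", mother="CUZW"),
        ]),
        "pair": ("EGO", "KID"), "phi": 0.03125, "r": 0.0625,
    }

    # Child of a full-sibling mating: F = 0.25, phi(self, self) = 0.625.
    out["inbred_child_self_kinship"] = {
        "pedigree": Pedigree([
            _rec("F", MALE), _rec("M", FEMALE),
            _rec("S1", MALE, father="F", mother="M"),
            _rec("S2", FEMALE, father="F", mother="M"),
            _rec("K", MALE, father="S1", mother="S2"),
        ]),
        "pair": ("K", "K"), "phi": 0.625, "F": 0.25,
    }

    return out
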