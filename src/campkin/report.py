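"""End-to-end analysis orchestration and report assembly.

``run_full_analysis`` ties the pipeline together: pedigree -> kinship ->
relatedness -> shared interest -> camp aggregations, correlations,
permutation tests, kin dispersion, spatial analysis and spouse summaries.
Every analysis directory gets exactly one RunManifest recording inputs,
seed, package version and the methodological decision flags in effect, so
identical manifests reproduce identical numbers.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .pedigree import (
    Pedigree,
    RelatednessMatrix,
    kinship_matrix,
    load_pedigree,
    relatedness_matrix,
)
from .stats import (
    DEFAULT_KIN_THRESHOLD,
    CampPanel,
    aggregate,
    campmate_means,
    household_residence_options,
    kin_camp_count,
    load_camp_panel,
    population_mean_relatedness,
    shared_interest_matrix,
    spouse_summary,
)
from .inference import (
    camp_pair_analysis,
    correlation,
    partial_correlation,
    permutation_test,
)

__all__ = ["RunManifest", "run_full_analysis", "analyze"]

#: Decision flags recorded in every manifest: methodological choices the
#: source field protocol leaves open, fixed here and auditable at runtime.
DECISION_FLAGS = {
    "relatedness_definition": "r = 2*phi (no inbreeding adjustment)",
    "aggregation_headline": "r_individual (mean over individuals)",
    "stability_formula": "mean consecutive-visit Jaccard similarity",
    "kin_camp_counting": "ego's own camp included when it contains kin",
    "household_options": "camps with kin (r >= threshold) of either spouse, "
                         "plus each spouse's current camp",
    "permutation_scheme": "global label shuffle (not camp-stratified)",
    "distance_formula": "haversine great-circle, R = 6371.0088 km",
    "age_bins_years": 5,
}


@dataclass
class RunManifest:
    command: str
    inputs: dict[str, str]
    config: dict[str, Any]
    seed: int
    version: str = __version__
    timestamp: str = ""
    decision_flags: dict[str, Any] = field(default_factory=lambda:
                                           dict(DECISION_FLAGS))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _round(x, nd=3):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) \
        else round(float(x), nd)


def _age_profile(ped: Pedigree, means: pd.Series, bin_years: int = 5
                 ) -> pd.DataFrame:
    """Mean campmate statistic by 5-year age bin and sex."""
    rows = []
    for iid, value in means.items():
        rec = ped.records[iid]
        if rec.age_years is None:
            continue
        rows.append({
            "age_bin": int(rec.age_years // bin_years) * bin_years,
            "sex": rec.sex,
            "value": value,
        })
    if not rows:
        return pd.DataFrame(columns=["age_bin", "sex", "mean", "n"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["age_bin", "sex"])["value"]
        .agg(mean="mean", n="size")
        .reset_index()
        .sort_values(["age_bin", "sex"])
        .reset_index(drop=True)
    )
    return out


def analyze(
    ped: Pedigree,
    panel: CampPanel,
    seed: int = 0,
    n_permutations: int = 10_000,
    kin_threshold: float = DEFAULT_KIN_THRESHOLD,
) -> dict[str, Any]:
    """Run every analysis stage that the supplied inputs support.

    Returns a nested dict of results; stages whose inputs are missing
    (e.g. no rosters -> no stability) are skipped with a notice collected
    under ``"notices"``.
    """
    notices: list[str] = []
    results: dict[str, Any] = {"notices": notices}

    kin = kinship_matrix(ped)
    r = relatedness_matrix(kin)
    spouse_map = ped.spouse_map()
    s = shared_interest_matrix(r, spouse_map)
    adults = [i for i, rec in ped.records.items() if rec.is_adult]
    sex_of = {i: rec.sex for i, rec in ped.records.items()}
    memberships = panel.memberships

    # population-wide and campmate means, adults and everyone, r and s
    headline: dict[str, Any] = {}
    for label, matrix in (("r", r), ("s", s)):
        pop_mean, pop_sd, _ = population_mean_relatedness(matrix, adults)
        camp_means_adults = campmate_means(matrix, memberships, include=adults)
        camp_means_all = campmate_means(matrix, memberships)
        headline[label] = {
            "population_adults_mean": pop_mean,
            "population_adults_sd": pop_sd,
            "campmates_adults_mean": float(camp_means_adults.mean()),
            "campmates_adults_sd": float(camp_means_adults.std(ddof=1)),
            "campmates_all_mean": float(camp_means_all.mean()),
            "campmates_all_sd": float(camp_means_all.std(ddof=1)),
            "n_adults": len(adults),
            "n_all": len(ped),
        }
    results["headline"] = headline

    # the three aggregation levels (adults)
    agg = aggregate(r, memberships, subset="adults_only", adults=ped)
    results["aggregation"] = {
        "r_group": agg.r_group,
        "r_individual": agg.r_individual,
        "r_dyads": agg.r_dyads,
        "n_groups": agg.n_groups,
        "n_individuals": agg.n_individuals,
        "n_dyads": agg.n_dyads,
    }
    try:
        a2c = aggregate(r, memberships, subset="adult_to_child", adults=ped)
        c2c = aggregate(r, memberships, subset="child_to_child", adults=ped)
        results["aggregation"]["adult_to_child_mean"] = a2c.r_individual
        results["aggregation"]["child_to_child_mean"] = c2c.r_individual
    except ValueError as exc:
        notices.append(f"adult/child aggregation skipped: {exc}")

    # per-camp table
    per_camp = agg.per_camp.copy()
    stability = panel.stability()
    if len(stability):
        per_camp = per_camp.join(stability, how="left")
    else:
        notices.append("no visit rosters: stability column skipped")
    foraging = pd.Series(
        {c: cov.get("foraging_proportion") for c, cov in
         panel.covariates.items()},
        name="foraging_proportion", dtype=float,
    )
    if len(foraging):
        per_camp = per_camp.join(foraging, how="left")
    results["per_camp"] = per_camp

    # camp size vs relatedness, plus covariate (partial) correlations
    correlations: dict[str, Any] = {}
    if len(per_camp) >= 3:
        coef, p = correlation(per_camp["size"], per_camp["mean_r"])
        correlations["size_vs_relatedness"] = {"r": coef, "p": p,
                                               "n": len(per_camp)}
    for cov_name in ("stability", "foraging_proportion"):
        if cov_name not in per_camp.columns:
            continue
        sub = per_camp.dropna(subset=[cov_name])
        if len(sub) < 4:
            notices.append(f"{cov_name} correlation skipped: <4 camps")
            continue
        try:
            coef, p = correlation(sub[cov_name], sub["mean_r"])
            pcoef, pp = partial_correlation(
                sub[cov_name], sub["mean_r"], sub["size"]
            )
            correlations[f"{cov_name}_vs_relatedness"] = {
                "r": coef, "p": p,
                "partial_r_given_size": pcoef, "partial_p": pp,
                "n": len(sub),
            }
        except ValueError as exc:
            notices.append(f"{cov_name} correlation skipped: {exc}")
    results["correlations"] = correlations

    # sex permutation tests on campmate means (r and s, adults)
    sex_tests: dict[str, Any] = {}
    for label, matrix in (("r", r), ("s", s)):
        means = campmate_means(matrix, memberships, include=adults)
        labels = {i: sex_of[i] for i in means.index}
        if len(set(labels.values())) == 2:
            res = permutation_test(
                means.to_dict(), labels, n_permutations=n_permutations,
                seed=seed,
            )
            sex_tests[label] = {
                "observed_difference": res.observed_difference,
                "p_two_tailed": res.p_two_tailed,
                "groups": res.group_labels,
                "group_means": {
                    sex: float(means[[i for i in means.index
                                      if sex_of[i] == sex]].mean())
                    for sex in ("female", "male")
                },
            }
    results["sex_permutation_tests"] = sex_tests

    # age profiles (5-year bins)
    results["age_profile_r"] = _age_profile(
        ped, campmate_means(r, memberships))
    results["age_profile_s"] = _age_profile(
        ped, campmate_means(s, memberships))

    # kin dispersion across camps
    counts = pd.Series(
        {i: kin_camp_count(r, memberships, i, threshold=kin_threshold)
         for i in adults},
        name="kin_camp_count",
    )
    kin_disp: dict[str, Any] = {
        "threshold": kin_threshold,
        "mean": float(counts.mean()),
        "sd": float(counts.std(ddof=1)) if len(counts) > 1 else np.nan,
        "min": int(counts.min()),
        "max": int(counts.max()),
        "by_sex": {
            sex: {
                "mean": float(counts[[i for i in counts.index
                                      if sex_of[i] == sex]].mean()),
                "n": sum(1 for i in counts.index if sex_of[i] == sex),
            }
            for sex in ("female", "male")
        },
    }
    sex_labels = {i: sex_of[i] for i in counts.index}
    if len(set(sex_labels.values())) == 2:
        res = permutation_test(counts.to_dict(), sex_labels,
                               n_permutations=n_permutations, seed=seed + 1)
        kin_disp["sex_permutation_p"] = res.p_two_tailed
    couples = {
        tuple(sorted((i, j))) for i, j in ped.spouse_map().items()
    }
    if couples:
        options = pd.Series(
            {c: household_residence_options(r, memberships, c,
                                            threshold=kin_threshold)
             for c in sorted(couples)}
        )
        kin_disp["household_options_mean"] = float(options.mean())
        kin_disp["household_options_min"] = int(options.min())
        kin_disp["household_options_max"] = int(options.max())
        kin_disp["n_households"] = len(options)
    results["kin_dispersion"] = kin_disp
    results["kin_camp_counts"] = counts

    # camp-pair relatedness vs distance
    if panel.coordinates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table, (rho, p) = camp_pair_analysis(
                    r, memberships, panel.coordinates, include=adults
                )
            results["camp_pairs"] = table
            results["distance_spearman"] = {"rho": rho, "p": p,
                                            "n_pairs": len(table)}
        except ValueError as exc:
            notices.append(f"camp-pair analysis skipped: {exc}")
    else:
        notices.append("no coordinates: camp-pair analysis skipped")

    # spouses
    table, summary = spouse_summary(ped, r)
    results["spouse_table"] = table
    results["spouse_summary"] = summary

    return results


def run_full_analysis(
    genealogy: str | Path,
    attributes: str | Path,
    rosters: str | Path | None = None,
    coordinates: str | Path | None = None,
    covariates: str | Path | None = None,
    out_dir: str | Path | None = None,
    seed: int = 0,
    n_permutations: int = 10_000,
    kin_threshold: float = DEFAULT_KIN_THRESHOLD,
) -> dict[str, Any]:
    """Load the input files, run :func:`analyze`, and (optionally) write
    the report bundle (CSV tables + JSON summary + RunManifest)."""
    ped = load_pedigree(genealogy, attributes_path=attributes)
    panel = load_camp_panel(attributes, rosters, coordinates, covariates)
    panel.validate_against(ped)
    results = analyze(ped, panel, seed=seed, n_permutations=n_permutations,
                      kin_threshold=kin_threshold)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        inputs = {"genealogy": _digest(genealogy),
                  "attributes": _digest(attributes)}
        for name, path in (("rosters", rosters), ("coordinates", coordinates),
                           ("covariates", covariates)):
            if path is not None:
                inputs[name] = _digest(path)
        manifest = RunManifest(
            command="report",
            inputs=inputs,
            config={"n_permutations": n_permutations,
                    "kin_threshold": kin_threshold},
            seed=seed,
            timestamp=datetime.datetime.now(datetime.timezone.utc)
            .isoformat(timespec="seconds"),
        )
        (out / "manifest.json").write_text(manifest.to_json() + "\n")
        _write_bundle(results, out)
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    return obj


def _write_bundle(results: Mapping[str, Any], out: Path) -> None:
    scalar = {
        k: v for k, v in results.items()
        if not isinstance(v, (pd.DataFrame, pd.Series))
    }
    (out / "summary.json").write_text(
        json.dumps(_jsonable(scalar), indent=2, sort_keys=True) + "\n"
    )
    for key, value in results.items():
        if isinstance(value, pd.DataFrame):
            value.to_csv(out / f"{key}.csv",
                         index=not isinstance(value.index, pd.RangeIndex))
        elif isinstance(value, pd.Series):
            value.rename_axis("id").to_csv(out / f"{key}.csv")
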