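"""Permutation tests, correlations, and the relatedness-distance analysis.

All randomised procedures take an explicit integer seed and are bit
reproducible.  P-values from sampled permutation tests use the add-one
correction (b + 1) / (m + 1), which is never exactly zero and is exact
under the null for exchangeable data.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pedigree import RelatednessMatrix

__all__ = [
    "PermutationResult",
    "permutation_test",
    "correlation",
    "partial_correlation",
    "haversine_km",
    "camp_pair_analysis",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a two-sample permutation test on a difference of means."""

    observed_difference: float
    p_two_tailed: float
    n_permutations: int
    seed: int
    group_labels: tuple[tuple[str, int], tuple[str, int]]

    def __str__(self) -> str:
        (la, na), (lb, nb) = self.group_labels
        return (
            f"mean({la}, n={na}) - mean({lb}, n={nb}) = "
            f"{self.observed_difference:+.4f}; two-tailed p = "
            f"{self.p_two_tailed:.4f} ({self.n_permutations} permutations, "
            f"seed {self.seed})"
        )


def _align(values: Mapping[str, float] | Sequence[float],
           labels: Mapping[str, str] | Sequence[str]):
    if isinstance(values, Mapping):
        ids = sorted(values)
        v = np.array([float(values[i]) for i in ids])
        lab = np.array([str(labels[i]) for i in ids])
    else:
        v = np.asarray(values, dtype=float)
        lab = np.asarray([str(x) for x in labels])
        if len(v) != len(lab):
            raise ValueError("values and labels differ in length")
    return v, lab


def permutation_test(
    values: Mapping[str, float] | Sequence[float],
    labels: Mapping[str, str] | Sequence[str],
    n_permutations: int = 10_000,
    seed: int = 0,
    stratify: Mapping[str, str] | Sequence[str] | None = None,
) -> PermutationResult:
    """Two-tailed permutation test for a difference in group means.

    The observed statistic is mean(group A) - mean(group B) with groups in
    sorted label order.  The null is built by globally shuffling the labels
    over individuals; passing ``stratify`` (e.g. camp of each individual)
    instead shuffles labels within strata.  The two-tailed p-value is
    (#{|perm| >= |obs|} + 1) / (n_permutations + 1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    v, lab = _align(values, labels)
    uniq = sorted(set(lab))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 group labels, got {uniq}")
    la, lb = uniq
    mask_a = lab == la
    n_a, n_b = int(mask_a.sum()), int((~mask_a).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    observed = float(v[mask_a].mean() - v[~mask_a].mean())

    rng = np.random.default_rng(seed)
    if stratify is None:
        strata = np.zeros(len(v), dtype=int)
    else:
        if isinstance(stratify, Mapping):
            if not isinstance(values, Mapping):
                raise ValueError("mapping stratify requires mapping values")
            ids = sorted(values)
            strata_tokens = [str(stratify[i]) for i in ids]
        else:
            strata_tokens = [str(x) for x in stratify]
        _, strata = np.unique(strata_tokens, return_inverse=True)

    total = v.sum()
    perm_stats = np.empty(n_permutations)
    is_a = mask_a.astype(float)
    idx_by_stratum = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    assign = is_a.copy()
    for k in range(n_permutations):
        for idx in idx_by_stratum:
            assign[idx] = is_a[idx][rng.permutation(len(idx))]
        sum_a = float(v @ assign)
        perm_stats[k] = sum_a / n_a - (total - sum_a) / n_b
    b = int(np.sum(np.abs(perm_stats) >= abs(observed) - 1e-12))
    p = (b + 1) / (n_permutations + 1)
    return PermutationResult(
        observed_difference=observed,
        p_two_tailed=float(p),
        n_permutations=n_permutations,
        seed=seed,
        group_labels=((la, n_a), (lb, n_b)),
    )


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def correlation(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Product-moment or rank correlation with a two-sided p-value.

    Pairs with a missing value in either vector are dropped.  For the
    Spearman coefficient the p-value is computed by exhaustive permutation
    enumeration for n <= 9 and the t approximation above that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    if method == "pearson":
        res = sps.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue)
    if method != "spearman":
        raise ValueError(f"unknown method {method!r}")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(sps.pearsonr(rx, ry).statistic)
    if n <= 9:
        # exact two-sided p over all n! rank permutations
        count = 0
        total = 0
        rx_c = rx - rx.mean()
        denom = math.sqrt(float(rx_c @ rx_c))
        for perm in itertools.permutations(range(n)):
            ry_p = ry[list(perm)]
            ry_c = ry_p - ry_p.mean()
            r_p = float(rx_c @ ry_c) / (denom * math.sqrt(float(ry_c @ ry_c)))
            total += 1
            if abs(r_p) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(min(1.0, p))


def partial_correlation(
    x: Sequence[float], y: Sequence[float], z: Sequence[float]
) -> tuple[float, float]:
    """First-order partial correlation of x and y controlling for z.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); the
    p-value comes from the t distribution with n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (len(x) == len(y) == len(z)):
        raise ValueError("x, y, z differ in length")
    keep = ~(np.isnan(x) | np.isnan(y) | np.isnan(z))
    x, y, z = x[keep], y[keep], z[keep]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 complete triples")
    r_xy = float(sps.pearsonr(x, y).statistic)
    r_xz = float(sps.pearsonr(x, z).statistic)
    r_yz = float(sps.pearsonr(y, z).statistic)
    denom_sq = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom_sq <= 1e-14:
        raise ValueError(
            "partial correlation degenerate: a variable is collinear with z"
        )
    r_p = (r_xy - r_xz * r_yz) / math.sqrt(denom_sq)
    r_p = float(np.clip(r_p, -1.0, 1.0))
    df = n - 3
    if abs(r_p) >= 1.0:
        return r_p, 0.0
    t = r_p * math.sqrt(df / (1.0 - r_p * r_p))
    return r_p, float(2.0 * sps.t.sf(abs(t), df=df))


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------

def haversine_km(
    a: tuple[float, float], b: tuple[float, float]
) -> float:
    """Great-circle distance in km between (lat deg, lon deg) points on a
    sphere of radius 6371.0088 km."""
    for lat, lon in (a, b):
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            raise ValueError(f"coordinate out of range: ({lat}, {lon})")
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = (
        math.sin(dlat / 2.0) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def camp_pair_analysis(
    r: RelatednessMatrix,
    memberships: Mapping[str, str],
    coordinates: Mapping[str, tuple[float, float]],
    include: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Mean cross-camp relatedness versus great-circle distance.

    One row per unordered camp pair: mean r over all dyads spanning the
    two camps (restricted to ``include`` when given, e.g. adults only) and
    the haversine distance between the camps.  Returns the table and the
    Spearman (coefficient, p) of relatedness against distance.  Camps
    lacking coordinates or qualifying members are excluded with a warning.
    """
    keep = set(include) if include is not None else None
    camp_members: dict[str, list[int]] = {}
    for i, c in memberships.items():
        if i not in r or (keep is not None and i not in keep):
            continue
        camp_members.setdefault(c, []).append(r.index[i])
    usable = []
    for c in sorted(camp_members):
        if c not in coordinates:
            warnings.warn(f"camp {c!r} has no coordinates; excluded")
            continue
        usable.append(c)
    if len(usable) < 3:
        raise ValueError("need at least 3 camps with coordinates and members")
    rows = []
    for ca, cb in itertools.combinations(usable, 2):
        sub = r.values[np.ix_(camp_members[ca], camp_members[cb])]
        rows.append(
            {
                "camp_a": ca,
                "camp_b": cb,
                "mean_r": float(np.mean(sub)),
                "distance_km": haversine_km(coordinates[ca], coordinates[cb]),
            }
        )
    table = pd.DataFrame(rows)
    rho, p = correlation(table["mean_r"], table["distance_km"],
                         method="spearman")
    return table, (rho, p)
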