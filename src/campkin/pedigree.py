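"""Pedigree parsing, validation, and kinship computation.

The genealogy is the only evidence source for relatedness here: dyadic
kinship coefficients (phi) are computed by the classical tabular recurrence
over a topological ordering of the pedigree, and Wright's coefficient of
relatedness is derived as r = 2*phi for distinct individuals.  A
gene-dropping Monte-Carlo simulator of allele transmission provides an
independent identity-by-descent oracle for the recursion.

Glossary
--------
kinship coefficient phi(i, j)
    Probability that a randomly drawn allele from i and one from j at the
    same autosomal locus are identical by descent.  phi(i, i) = (1 + F_i)/2.
inbreeding coefficient F_i
    Kinship of i's parents; 0 for founders and for any individual with a
    missing parent (missing parents are treated as unique founders).
coefficient of relatedness r(i, j)
    Expected genome sharing; 2*phi(i, j) for an outbred pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IndividualRecord",
    "Pedigree",
    "KinshipMatrix",
    "RelatednessMatrix",
    "PedigreeError",
    "PedigreeValidationError",
    "PedigreeStructureError",
    "load_pedigree",
    "kinship_matrix",
    "relatedness_matrix",
    "gene_drop_ibd",
    "gene_drop_kinship",
]

MISSING_PARENT_TOKENS = {"", "0", "na", "nan", "none"}

FEMALE = "female"
MALE = "male"

_SEX_ALIASES = {
    "f": FEMALE, "female": FEMALE, "2": FEMALE, "w": FEMALE,
    "m": MALE, "male": MALE, "1": MALE,
}


class PedigreeError(Exception):
    """Base class for genealogy input problems."""


class PedigreeValidationError(PedigreeError):
    """Referential or attribute inconsistencies (dangling parent, parent sex)."""


class PedigreeStructureError(PedigreeError):
    """Structural impossibilities: the parent relation contains a cycle."""


@dataclass(frozen=True)
class IndividualRecord:
    """One person in the genealogy.

    ``father_id``/``mother_id`` are ``None`` for unknown parents; an
    individual with both parents unknown is a founder.  ``spouse_id``
    records the current marriage (mutual by validation).
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = FEMALE
    age_years: float | None = None
    camp_id: str | None = None
    spouse_id: str | None = None
    is_adult: bool = True

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """A validated genealogy: acyclic parent links with a topological order.

    Parameters
    ----------
    records
        Iterable of :class:`IndividualRecord`.  Parent references must
        resolve, father records must be male and mother records female,
        the parent relation must be acyclic, and spouse links (when
        present) must be mutual.
    """

    def __init__(self, records: Iterable[IndividualRecord]):
        self.records: dict[str, IndividualRecord] = {}
        for rec in records:
            if rec.id in self.records:
                raise PedigreeValidationError(f"duplicate individual id {rec.id!r}")
            self.records[rec.id] = rec
        self._validate_links()
        self.generation_order: list[str] = self._topological_order()
        self.founder_set: frozenset[str] = frozenset(
            i for i, rec in self.records.items() if rec.is_founder
        )

    # -- validation -----------------------------------------------------

    def _validate_links(self) -> None:
        bad_rows: list[str] = []
        for rec in self.records.values():
            for pid, want in ((rec.father_id, MALE), (rec.mother_id, FEMALE)):
                if pid is None:
                    continue
                parent = self.records.get(pid)
                if parent is None:
                    raise PedigreeValidationError(
                        f"individual {rec.id!r} references unknown parent {pid!r}"
                    )
                if parent.sex != want:
                    bad_rows.append(
                        f"{rec.id}: {'father' if want is MALE else 'mother'} "
                        f"{pid} has sex {parent.sex}"
                    )
            if rec.spouse_id is not None:
                spouse = self.records.get(rec.spouse_id)
                if spouse is None:
                    raise PedigreeValidationError(
                        f"individual {rec.id!r} references unknown spouse "
                        f"{rec.spouse_id!r}"
                    )
                if spouse.spouse_id != rec.id:
                    raise PedigreeValidationError(
                        f"spouse link not mutual: {rec.id} -> {rec.spouse_id} "
                        f"but {rec.spouse_id} -> {spouse.spouse_id}"
                    )
        if bad_rows:
            raise PedigreeValidationError(
                "parent sex inconsistencies: " + "; ".join(sorted(bad_rows))
            )

    def _topological_order(self) -> list[str]:
        # Kahn's algorithm on the parent -> child relation; a leftover node
        # proves a cycle, and we name one individual on it.
        children: dict[str, list[str]] = {i: [] for i in self.records}
        n_parents: dict[str, int] = {}
        for rec in self.records.values():
            parents = [p for p in (rec.father_id, rec.mother_id) if p is not None]
            if rec.id in parents:
                raise PedigreeStructureError(
                    f"individual {rec.id!r} is listed as its own parent"
                )
            n_parents[rec.id] = len(parents)
            for p in parents:
                children[p].append(rec.id)
        ready = sorted(i for i, n in n_parents.items() if n == 0)
        order: list[str] = []
        while ready:
            node = ready.pop()
            order.append(node)
            for child in children[node]:
                n_parents[child] -= 1
                if n_parents[child] == 0:
                    ready.append(child)
        if len(order) != len(self.records):
            on_cycle = min(i for i, n in n_parents.items() if n > 0)
            raise PedigreeStructureError(
                f"pedigree contains an ancestry cycle through {on_cycle!r}"
            )
        return order

    # -- basic queries ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.records

    def ids(self) -> list[str]:
        return list(self.generation_order)

    def parents(self, individual_id: str) -> tuple[str | None, str | None]:
        rec = self.records[individual_id]
        return rec.father_id, rec.mother_id

    def spouse_map(self) -> dict[str, str]:
        """Current marriages as a mutual id -> id mapping."""
        return {
            i: rec.spouse_id
            for i, rec in self.records.items()
            if rec.spouse_id is not None
        }

    def ancestors(self, individual_id: str) -> set[str]:
        """All strict ancestors of ``individual_id`` (excluding self)."""
        out: set[str] = set()
        stack = [p for p in self.parents(individual_id) if p is not None]
        while stack:
            a = stack.pop()
            if a in out:
                continue
            out.add(a)
            stack.extend(p for p in self.parents(a) if p is not None)
        return out

    def depth(self, individual_id: str) -> int:
        """Generational depth: length of the longest known ancestor chain,
        counting the individual itself (a founder has depth 1)."""
        memo: dict[str, int] = {}
        for i in self.generation_order:
            f, m = self.parents(i)
            memo[i] = 1 + max(
                (memo[p] for p in (f, m) if p is not None), default=0
            )
        return memo[individual_id]

    def depths(self) -> pd.Series:
        memo: dict[str, int] = {}
        for i in self.generation_order:
            f, m = self.parents(i)
            memo[i] = 1 + max(
                (memo[p] for p in (f, m) if p is not None), default=0
            )
        return pd.Series(memo, name="depth")

    def mean_depth(self) -> float:
        return float(self.depths().mean())

    def max_depth(self) -> int:
        return int(self.depths().max())

    def with_attributes(self, attributes: pd.DataFrame) -> "Pedigree":
        """Return a new Pedigree with age/camp/spouse/adult columns merged in."""
        attributes = attributes.copy()
        attributes["id"] = attributes["id"].astype(str)
        updated: dict[str, IndividualRecord] = dict(self.records)
        for _, row in attributes.iterrows():
            iid = row["id"]
            if iid not in updated:
                raise PedigreeValidationError(
                    f"attribute row for unknown individual {iid!r}"
                )
            kwargs: dict = {}
            if "age" in row and not pd.isna(row["age"]):
                kwargs["age_years"] = float(row["age"])
            if "camp" in row and not pd.isna(row["camp"]):
                kwargs["camp_id"] = str(row["camp"])
            if "spouse" in row and not pd.isna(row["spouse"]):
                token = str(row["spouse"])
                if token.lower() not in MISSING_PARENT_TOKENS:
                    kwargs["spouse_id"] = token
            if "adult" in row and not pd.isna(row["adult"]):
                kwargs["is_adult"] = _parse_bool(row["adult"])
            updated[iid] = replace(updated[iid], **kwargs)
        return Pedigree(updated.values())


def _parse_bool(token) -> bool:
    if isinstance(token, (bool, np.bool_)):
        return bool(token)
    s = str(token).strip().lower()
    if s in {"1", "true", "t", "yes", "adult"}:
        return True
    if s in {"0", "false", "f", "no", "child"}:
        return False
    raise PedigreeValidationError(f"cannot interpret adult flag {token!r}")


def _parse_sex(token) -> str:
    s = str(token).strip().lower()
    if s not in _SEX_ALIASES:
        raise PedigreeValidationError(f"cannot interpret sex code {token!r}")
    return _SEX_ALIASES[s]


def _parse_parent(token) -> str | None:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None
    s = str(token).strip()
    if s.lower() in MISSING_PARENT_TOKENS:
        return None
    return s


def load_pedigree(
    path: str | Path,
    attributes_path: str | Path | None = None,
) -> Pedigree:
    """Read a PED-like genealogy file, optionally merging an attribute table.

    The genealogy file is whitespace- or comma-delimited text with a header
    containing columns ``id``, ``father``, ``mother``, ``sex``; a missing
    parent is encoded as ``0`` or an empty field.  The attribute file is a
    CSV with columns ``id`` and any of ``age``, ``camp``, ``spouse``,
    ``adult``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "," if "," in header else r"\s+"
    table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    table.columns = [c.strip().lower() for c in table.columns]
    required = {"id", "father", "mother", "sex"}
    missing = required - set(table.columns)
    if missing:
        raise PedigreeValidationError(
            f"genealogy file missing columns: {sorted(missing)}"
        )
    records = [
        IndividualRecord(
            id=str(row["id"]).strip(),
            father_id=_parse_parent(row["father"]),
            mother_id=_parse_parent(row["mother"]),
            sex=_parse_sex(row["sex"]),
        )
        for _, row in table.iterrows()
    ]
    ped = Pedigree(records)
    if attributes_path is not None:
        attrs = pd.read_csv(attributes_path, dtype={"id": str, "camp": str,
                                                    "spouse": str})
        attrs.columns = [c.strip().lower() for c in attrs.columns]
        ped = ped.with_attributes(attrs)
    return ped


# ---------------------------------------------------------------------------
# Kinship and relatedness matrices
# ---------------------------------------------------------------------------

class _LabelledMatrix:
    """Square matrix with id labels and (id, id) indexing."""

    value_name = "value"

    def __init__(self, ids: Sequence[str], values: np.ndarray):
        self.ids: list[str] = list(ids)
        self.values: np.ndarray = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id list")
        self.index: dict[str, int] = {i: k for k, i in enumerate(self.ids)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.index[a], self.index[b]])

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.index

    def subset(self, ids: Sequence[str]):
        idx = np.array([self.index[i] for i in ids])
        return type(self)(list(ids), self.values[np.ix_(idx, idx)])

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: one row per unordered off-diagonal pair."""
        n = len(self.ids)
        ia, ib = np.triu_indices(n, k=1)
        return pd.DataFrame(
            {
                "id_a": [self.ids[i] for i in ia],
                "id_b": [self.ids[j] for j in ib],
                self.value_name: self.values[ia, ib],
            }
        )

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


class KinshipMatrix(_LabelledMatrix):
    """Symmetric kinship coefficients; diagonal is (1 + F_i)/2."""

    value_name = "phi"

    def inbreeding(self) -> pd.Series:
        """Per-individual inbreeding coefficient F_i = 2*phi(i,i) - 1."""
        return pd.Series(2.0 * np.diag(self.values) - 1.0, index=self.ids,
                         name="F")


class RelatednessMatrix(_LabelledMatrix):
    """Wright's r for all distinct pairs; diagonal is NaN.

    The diagonal sentinel is deliberately not-a-number so that any
    aggregation accidentally including self-pairs fails loudly.
    """

    value_name = "r"


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Compute all pairwise kinship coefficients by the tabular recurrence.

    Individuals are processed in ``generation_order`` (ancestors first), so
    for every non-founder i and any previously processed j the recurrence

        phi(i, j) = (phi(father_i, j) + phi(mother_i, j)) / 2

    is valid (a missing parent contributes 0), and the diagonal is

        phi(i, i) = (1 + phi(father_i, mother_i)) / 2.

    Each entry is computed exactly once; the computation is O(n^2).
    """
    order = ped.generation_order
    n = len(order)
    pos = {iid: k for k, iid in enumerate(order)}
    phi = np.zeros((n, n))
    for k, iid in enumerate(order):
        f, m = ped.parents(iid)
        fi = pos[f] if f is not None else None
        mi = pos[m] if m is not None else None
        if fi is None and mi is None:
            phi[k, k] = 0.5
            continue
        row = np.zeros(k)
        if fi is not None:
            row += phi[fi, :k]
        if mi is not None:
            row += phi[mi, :k]
        row *= 0.5
        phi[k, :k] = row
        phi[:k, k] = row
        f_i = phi[fi, mi] if (fi is not None and mi is not None) else 0.0
        phi[k, k] = 0.5 * (1.0 + f_i)
    return KinshipMatrix(order, phi)


def relatedness_matrix(
    k: KinshipMatrix, inbreeding_adjusted: bool = False
) -> RelatednessMatrix:
    """Derive Wright's coefficient of relatedness from kinship.

    By default r(i, j) = 2*phi(i, j), the convention of standard pedigree
    software and exact for outbred individuals.  With
    ``inbreeding_adjusted=True`` the normalised form
    2*phi / sqrt((1 + F_i)(1 + F_j)) is used instead, which keeps r(i, j)
    interpretable as a correlation when either member is inbred.
    """
    phi = k.values
    r = 2.0 * phi
    if inbreeding_adjusted:
        scale = np.sqrt(2.0 * np.diag(phi))  # sqrt(1 + F_i)
        r = r / np.outer(scale, scale)
    r = r.copy()
    np.fill_diagonal(r, np.nan)
    return RelatednessMatrix(k.ids, r)


# ---------------------------------------------------------------------------
# Gene-dropping oracle
# ---------------------------------------------------------------------------

def _drop_alleles(
    ped: Pedigree, needed: set[str], n_reps: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Simulate allele transmission for ``needed`` ids and their ancestors.

    Every founder carries two globally unique allele labels; each
    non-founder inherits one uniformly random allele from each parent per
    replicate.  Returns id -> (n_reps, 2) integer array of allele labels.
    """
    closure: set[str] = set()
    for i in needed:
        closure.add(i)
        closure |= ped.ancestors(i)
    alleles: dict[str, np.ndarray] = {}
    next_label = 0
    for iid in ped.generation_order:
        if iid not in closure:
            continue
        f, m = ped.parents(iid)
        pair = np.empty((n_reps, 2), dtype=np.int64)
        for col, parent in enumerate((f, m)):
            if parent is None:
                pair[:, col] = next_label
                next_label += 1
            else:
                src = alleles[parent]
                choice = rng.integers(0, 2, size=n_reps)
                pair[:, col] = src[np.arange(n_reps), choice]
        alleles[iid] = pair
    return alleles


def gene_drop_kinship(
    ped: Pedigree,
    pairs: Sequence[tuple[str, str]],
    n_reps: int = 100_000,
    seed: int = 0,
) -> dict[tuple[str, str], float]:
    """Monte-Carlo kinship estimates for several pairs from one allele drop.

    For each replicate the probability that a random allele from each pair
    member is identical by descent is the mean of the four allele-pair
    indicator comparisons; averaging over replicates gives an unbiased
    estimator of phi with variance at most the binomial phi(1-phi)/n_reps.
    """
    for a, b in pairs:
        for i in (a, b):
            if i not in ped:
                raise KeyError(f"unknown individual id {i!r}")
    rng = np.random.default_rng(seed)
    needed = {i for pair in pairs for i in pair}
    alleles = _drop_alleles(ped, needed, n_reps, rng)
    out: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        aa, bb = alleles[a], alleles[b]
        ibd = np.zeros(n_reps)
        for i in range(2):
            for j in range(2):
                ibd += aa[:, i] == bb[:, j]
        out[(a, b)] = float(ibd.mean() / 4.0)
    return out


def gene_drop_ibd(
    ped: Pedigree, pair: tuple[str, str], n_reps: int = 100_000, seed: int = 0
) -> float:
    """Estimate kinship phi for one pair by gene dropping (see
    :func:`gene_drop_kinship`)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    return gene_drop_kinship(ped, [tuple(pair)], n_reps=n_reps, seed=seed)[
        tuple(pair)
    ]
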