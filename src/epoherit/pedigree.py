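"""Pedigree handling for wild-population quantitative genetics.

A pedigree here is the parentage record of a nest-box population: each
individual has an optional dam and sire, a sex, and a birth cohort.
Immigrants and individuals of unknown origin enter as founders.  The module
validates pedigrees, prunes them to the informative subset for a given set of
phenotyped individuals, computes the additive (numerator) relationship matrix
A by the tabular method, and produces the kinship summary statistics
(sibship counts, relatedness histogram, generation depths) that describe how
much information a sparse wild pedigree actually carries.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "PedigreeError",
    "AdditiveRelationshipMatrix",
    "KinshipSummary",
    "read_pedigree",
    "write_pedigree",
    "prune_informative",
    "additive_relationship_matrix",
    "kinship_summary",
    "generation_depth",
    "inbreeding_coefficients",
    "mean_relatedness_from_histogram",
]

MISSING = "NA"


class PedigreeError(ValueError):
    """Raised for structural pedigree defects (duplicates, cycles, sex conflicts)."""


def _norm(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    s = str(value).strip()
    if s == "" or s.upper() in {"NA", "NAN", "NONE"}:
        return None
    return s


@dataclass
class Pedigree:
    """Validated parentage structure.

    ``ids`` is in input order (founder-promoted parents appended at the
    front so that a topological order can keep ties in input order).  ``dam``
    and ``sire`` map to ids or ``None``; ``sex`` values are 'F', 'M' or 'U';
    ``cohort`` values are ints or ``None``.
    """

    ids: list[str]
    dam: dict[str, str | None]
    sire: dict[str, str | None]
    sex: dict[str, str] = field(default_factory=dict)
    cohort: dict[str, int | None] = field(default_factory=dict)
    n_promoted_founders: int = 0

    def __post_init__(self) -> None:
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        dup = [i for i, c in Counter(self.ids).items() if c > 1]
        if dup:
            raise PedigreeError(f"duplicate individual ids: {sorted(dup)}")
        idset = set(self.ids)
        dams_seen, sires_seen = set(), set()
        for i in self.ids:
            d, s = self.dam.get(i), self.sire.get(i)
            if d is not None and d == s:
                raise PedigreeError(f"record {i!r} lists the same id {d!r} as dam and sire")
            for p in (d, s):
                if p is not None and p not in idset:
                    raise PedigreeError(f"parent {p!r} of {i!r} is not an individual")
            if d is not None:
                dams_seen.add(d)
            if s is not None:
                sires_seen.add(s)
        both = dams_seen & sires_seen
        if both:
            raise PedigreeError(
                f"ids used both as dam and as sire (sex conflict): {sorted(both)}"
            )
        self.sex = {i: self.sex.get(i, "U") or "U" for i in self.ids}
        for i in dams_seen:
            if self.sex[i] == "U":
                self.sex[i] = "F"
        for i in sires_seen:
            if self.sex[i] == "U":
                self.sex[i] = "M"
        self.cohort = {i: self.cohort.get(i) for i in self.ids}
        self._order = self._topological_order()

    def _topological_order(self) -> list[str]:
        """Kahn's algorithm, parents before offspring, ties in input order."""
        children: dict[str, list[str]] = defaultdict(list)
        n_parents: dict[str, int] = {}
        for i in self.ids:
            ps = [p for p in (self.dam[i], self.sire[i]) if p is not None]
            n_parents[i] = len(ps)
            for p in ps:
                children[p].append(i)
        queue = [i for i in self.ids if n_parents[i] == 0]
        order: list[str] = []
        head = 0
        while head < len(queue):
            i = queue[head]
            head += 1
            order.append(i)
            for c in children[i]:
                n_parents[c] -= 1
                if n_parents[c] == 0:
                    queue.append(c)
        if len(order) != len(self.ids):
            cyclic = sorted(set(self.ids) - set(order))
            raise PedigreeError(
                f"pedigree contains a cycle (an individual is its own ancestor): {cyclic}"
            )
        return order

    # -- convenience -------------------------------------------------------

    @property
    def order(self) -> list[str]:
        """Topological order, parents before offspring."""
        return list(self._order)

    def __len__(self) -> int:
        return len(self.ids)

    def parents(self, i: str) -> tuple[str | None, str | None]:
        return self.dam[i], self.sire[i]

    def is_founder(self, i: str) -> bool:
        return self.dam[i] is None and self.sire[i] is None

    @property
    def n_maternities(self) -> int:
        return sum(1 for i in self.ids if self.dam[i] is not None)

    @property
    def n_paternities(self) -> int:
        return sum(1 for i in self.ids if self.sire[i] is not None)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        sex: Mapping[str, str] | None = None,
        cohort: Mapping[str, int] | None = None,
    ) -> "Pedigree":
        """Build from (id, dam, sire) triples, auto-promoting unlisted parents.

        Parents that never appear as individuals are added as founder records
        (immigrants and unsampled birds enter the pedigree this way).
        """
        recs = [(_norm(i), _norm(d), _norm(s)) for i, d, s in records]
        ids = [r[0] for r in recs]
        if any(i is None for i in ids):
            raise PedigreeError("missing individual id in records")
        idset = set(ids)
        promoted: list[str] = []
        seen_promoted: set[str] = set()
        for _, d, s in recs:
            for p in (d, s):
                if p is not None and p not in idset and p not in seen_promoted:
                    promoted.append(p)
                    seen_promoted.add(p)
        all_ids = promoted + ids
        dam = {i: None for i in promoted}
        sire = {i: None for i in promoted}
        for i, d, s in recs:
            dam[i], sire[i] = d, s
        return cls(
            ids=all_ids,
            dam=dam,
            sire=sire,
            sex=dict(sex or {}),
            cohort=dict(cohort or {}),
            n_promoted_founders=len(promoted),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "dam": [self.dam[i] or MISSING for i in self.ids],
                "sire": [self.sire[i] or MISSING for i in self.ids],
                "sex": [self.sex[i] for i in self.ids],
                "cohort": [self.cohort[i] if self.cohort[i] is not None else MISSING
                           for i in self.ids],
            }
        )


def read_pedigree(path, **csv_options) -> Pedigree:
    """Read a pedigree CSV with columns id, dam, sire and optional sex, cohort.

    Missing parents are encoded as ``NA``.  Parents that are not listed as
    individuals are promoted to founders; the count is available as
    ``Pedigree.n_promoted_founders``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, **csv_options)
    cols = {c.lower(): c for c in df.columns}
    for needed in ("id", "dam", "sire"):
        if needed not in cols:
            raise PedigreeError(f"pedigree file {path} lacks required column {needed!r}")
    sex = {}
    cohort = {}
    if "sex" in cols:
        sex = {_norm(i): (_norm(s) or "U").upper()[:1]
               for i, s in zip(df[cols["id"]], df[cols["sex"]])}
    if "cohort" in cols:
        for i, c in zip(df[cols["id"]], df[cols["cohort"]]):
            c = _norm(c)
            cohort[_norm(i)] = int(float(c)) if c is not None else None
    records = zip(df[cols["id"]], df[cols["dam"]], df[cols["sire"]])
    return Pedigree.from_records(records, sex=sex, cohort=cohort)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def prune_informative(ped: Pedigree, phenotyped: set[str] | Sequence[str]) -> Pedigree:
    """Restrict to the informative pedigree: phenotyped individuals plus all
    their ancestors.

    Everything else carries no information for variance-component estimation
    on the phenotyped set and is removed; parent links pointing at removed
    individuals become missing.  Pruning is idempotent.
    """
    phenotyped = set(phenotyped)
    if not phenotyped:
        raise PedigreeError("phenotyped set is empty")
    unknown = phenotyped - set(ped.ids)
    if unknown:
        raise PedigreeError(f"phenotyped ids absent from pedigree: {sorted(unknown)[:10]}")
    keep: set[str] = set()
    stack = list(phenotyped)
    while stack:
        i = stack.pop()
        if i in keep:
            continue
        keep.add(i)
        for p in ped.parents(i):
            if p is not None and p not in keep:
                stack.append(p)
    ids = [i for i in ped.ids if i in keep]
    dam = {i: (ped.dam[i] if ped.dam[i] in keep else None) for i in ids}
    sire = {i: (ped.sire[i] if ped.sire[i] in keep else None) for i in ids}
    return Pedigree(
        ids=ids,
        dam=dam,
        sire=sire,
        sex={i: ped.sex[i] for i in ids},
        cohort={i: ped.cohort[i] for i in ids},
    )


@dataclass
class AdditiveRelationshipMatrix:
    """Numerator relationship matrix A with inbreeding on the diagonal.

    ``ids`` gives the row/column order (topological).  ``entries[i, j]`` is
    the expected additive relationship A_ij = 2 * kinship(i, j); the diagonal
    is 1 + F_i.
    """

    ids: list[str]
    entries: np.ndarray

    @property
    def inbreeding(self) -> pd.Series:
        return pd.Series(np.diag(self.entries) - 1.0, index=self.ids, name="F")

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        pos = {v: k for k, v in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return self.entries[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=self.ids, columns=self.ids)


def additive_relationship_matrix(ped: Pedigree) -> AdditiveRelationshipMatrix:
    """Tabular-method A matrix.

    In parent-before-offspring order: A_ij = (A_{j,dam(i)} + A_{j,sire(i)})/2
    for previously processed j, and A_ii = 1 + A_{dam(i),sire(i)}/2.  A
    missing parent contributes zero relationship (founder convention, which
    also covers immigrants).
    """
    order = ped.order
    n = len(order)
    pos = {v: k for k, v in enumerate(order)}
    A = np.zeros((n, n))
    for i_name in order:
        i = pos[i_name]
        d, s = ped.parents(i_name)
        di = pos[d] if d is not None else -1
        si = pos[s] if s is not None else -1
        row = np.zeros(i)
        if di >= 0:
            row += A[di, :i]
        if si >= 0:
            row += A[si, :i]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[di, si] if (di >= 0 and si >= 0) else 0.0)
    return AdditiveRelationshipMatrix(ids=order, entries=A)


@dataclass
class KinshipSummary:
    n_individuals: int
    n_maternities: int
    n_paternities: int
    n_full_sib_pairs: int
    n_maternal_half_sib_pairs: int
    n_paternal_half_sib_pairs: int
    n_maternal_sib_pairs: int
    n_paternal_sib_pairs: int
    mean_maternal_sibship: float
    mean_paternal_sibship: float
    relatedness_histogram: dict[float, int]
    mean_pairwise_relatedness: float
    generation_depth: dict[str, int]
    depth_mean: float
    depth_min: int
    depth_max: int

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["relatedness_histogram"] = {str(k): v for k, v in self.relatedness_histogram.items()}
        return d


def _pairs(k: int) -> int:
    return k * (k - 1) // 2


def generation_depth(ped: Pedigree) -> tuple[dict[str, int], float, int, int]:
    """Ancestral generation count per individual.

    Founders are depth 0; otherwise 1 + max depth over known parents.  Returns
    (per-individual map, mean, min, max).
    """
    depth: dict[str, int] = {}
    for i in ped.order:
        ps = [p for p in ped.parents(i) if p is not None]
        depth[i] = 1 + max(depth[p] for p in ps) if ps else 0
    vals = np.array([depth[i] for i in ped.ids])
    return depth, float(vals.mean()), int(vals.min()), int(vals.max())


def kinship_summary(
    ped: Pedigree,
    A: AdditiveRelationshipMatrix | None = None,
    bin_width: float = 0.025,
) -> KinshipSummary:
    """Pedigree information content: parent links, sibship structure,
    relatedness histogram, and generation depth.

    A maternal (paternal) sib pair shares a known dam (sire); a full-sib pair
    shares both; half-sib counts are the remainders, so
    maternal sibs = full sibs + maternal half sibs by construction.  Mean
    sibship is offspring per parent among parents with at least one offspring.
    The histogram tallies off-diagonal A values rounded to the nearest
    multiple of ``bin_width`` (keys rounded to 3 decimals).
    """
    if A is None:
        A = additive_relationship_matrix(ped)
    if set(A.ids) != set(ped.ids):
        raise PedigreeError("relationship matrix id set does not match pedigree")

    by_dam: dict[str, int] = Counter()
    by_sire: dict[str, int] = Counter()
    by_pair: dict[tuple[str, str], int] = Counter()
    for i in ped.ids:
        d, s = ped.parents(i)
        if d is not None:
            by_dam[d] += 1
        if s is not None:
            by_sire[s] += 1
        if d is not None and s is not None:
            by_pair[(d, s)] += 1

    full = sum(_pairs(k) for k in by_pair.values())
    mat = sum(_pairs(k) for k in by_dam.values())
    pat = sum(_pairs(k) for k in by_sire.values())

    n = len(ped)
    offdiag = A.entries[np.triu_indices(n, k=1)]
    if bin_width > 0:
        binned = np.round(np.round(offdiag / bin_width) * bin_width, 3)
    else:
        binned = np.round(offdiag, 3)
    values, counts = np.unique(binned, return_counts=True)
    hist = {float(v): int(c) for v, c in zip(values, counts)}

    depth, dmean, dmin, dmax = generation_depth(ped)
    n_mat = sum(by_dam.values())
    n_pat = sum(by_sire.values())
    return KinshipSummary(
        n_individuals=n,
        n_maternities=n_mat,
        n_paternities=n_pat,
        n_full_sib_pairs=full,
        n_maternal_half_sib_pairs=mat - full,
        n_paternal_half_sib_pairs=pat - full,
        n_maternal_sib_pairs=mat,
        n_paternal_sib_pairs=pat,
        mean_maternal_sibship=(n_mat / len(by_dam)) if by_dam else float("nan"),
        mean_paternal_sibship=(n_pat / len(by_sire)) if by_sire else float("nan"),
        relatedness_histogram=hist,
        mean_pairwise_relatedness=float(offdiag.mean()) if n > 1 else 0.0,
        generation_depth=depth,
        depth_mean=dmean,
        depth_min=dmin,
        depth_max=dmax,
    )


def inbreeding_coefficients(ped: Pedigree) -> pd.Series:
    """Inbreeding coefficients without forming the dense A matrix.

    F_i is the coancestry (kinship) of i's parents, computed by the
    memoized tabular recursion; founders and individuals with a missing
    parent have F = 0.  Scales to large shallow pedigrees where a dense A
    would not.
    """
    pos = {v: k for k, v in enumerate(ped.order)}
    memo: dict[tuple[str, str], float] = {}

    def kin(a: str | None, b: str | None) -> float:
        if a is None or b is None:
            return 0.0
        if pos[a] < pos[b]:
            a, b = b, a
        key = (a, b)
        if key in memo:
            return memo[key]
        da, sa = ped.parents(a)
        if a == b:
            val = 0.5 * (1.0 + kin(da, sa))
        else:
            val = 0.5 * (kin(da, b) + kin(sa, b))
        memo[key] = val
        return val

    return pd.Series(
        [kin(*ped.parents(i)) for i in ped.ids], index=ped.ids, name="F"
    )


def mean_relatedness_from_histogram(hist: Mapping[float, int]) -> float:
    """Count-weighted mean relatedness of a {relatedness: pair count} tally."""
    total = sum(hist.values())
    if total == 0:
        raise ValueError("empty histogram")
    return sum(float(r) * c for r, c in hist.items()) / total
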