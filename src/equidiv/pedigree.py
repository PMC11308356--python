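"""Pedigree completeness, inbreeding and coancestry-rate Ne.

A pedigree is an acyclic parent map; unknown parents are founders.
Implemented quantities:

* generation equivalents ge_i = sum over every known-ancestor slot of
  (1/2)^depth (parents at depth 1) — a completeness measure where a fully
  known g-generation pedigree gives ge = g;
* Wright's inbreeding coefficient F_i = kinship(sire_i, dam_i), computed
  through the standard additive-relationship (tabular) recursion with
  memoised pairwise kinships rather than a dense matrix, so deep pedigrees
  stay memory-bounded;
* effective population size from the mean rate of increase in coancestry:
  for a cohort pair (j, k) with kinship c_jk and generation equivalents
  ge_j, ge_k, the per-generation rate is

      delta_c_jk = 1 - (1 - c_jk) ** (1 / ((ge_j + ge_k) / 2))

  and Ne = 1 / (2 * mean delta_c) over all cohort pairs.  A cohort of
  mutually unrelated individuals has zero mean rate and an infinite Ne,
  reported as ``inf``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

UNKNOWN = ""  # internal marker for an unknown parent


class PedigreeCycleError(ValueError):
    """A pedigree contained an individual among its own ancestors."""


@dataclass
class Pedigree:
    """Parent map with optional birth years.

    ``records`` maps individual id -> (sire or None, dam or None);
    iteration order of ``topological`` guarantees parents before offspring.
    """

    records: dict[str, tuple[str | None, str | None]]
    birth_year: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # register parents that have no row of their own as founders
        for sire, dam in list(self.records.values()):
            for p in (sire, dam):
                if p is not None and p not in self.records:
                    self.records[p] = (None, None)
        self.topological = self._toposort()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        """Build from columns ``id, sire, dam[, birth_year]``; "0", empty or
        NaN mark unknown parents."""
        def norm(v: object) -> str | None:
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            s = str(v).strip()
            return None if s in ("0", "", "nan") else s

        records = {}
        birth = {}
        for row in df.itertuples(index=False):
            iid = str(row.id)
            records[iid] = (norm(row.sire), norm(row.dam))
            if hasattr(row, "birth_year") and not pd.isna(row.birth_year):
                birth[iid] = int(row.birth_year)
        return cls(records, birth)

    @classmethod
    def read(cls, path: str | Path) -> "Pedigree":
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
        df.columns = [c.lower() for c in df.columns]
        return cls.from_frame(df)

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        return self.records.get(iid, (None, None))

    def _toposort(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}  # 0 in progress, 1 done
        for root in self.records:
            if root in state:
                continue
            stack: list[tuple[str, bool]] = [(root, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    state[node] = 1
                    order.append(node)
                    continue
                if state.get(node) == 1:
                    continue
                if state.get(node) == 0:
                    raise PedigreeCycleError(
                        f"individual {node!r} is its own ancestor"
                    )
                state[node] = 0
                stack.append((node, True))
                for p in self.parents(node):
                    if p is not None and state.get(p) != 1:
                        if state.get(p) == 0:
                            raise PedigreeCycleError(
                                f"individual {p!r} is its own ancestor"
                            )
                        stack.append((p, False))
        return order


def generation_equivalents(
    ped: Pedigree, ids: list[str] | None = None
) -> pd.Series:
    """ge per individual; founders (no known parents) have ge = 0."""
    ge: dict[str, float] = {}
    for iid in ped.topological:
        total = 0.0
        for p in ped.parents(iid):
            if p is not None:
                total += 0.5 * (1.0 + ge[p])
        ge[iid] = total
    s = pd.Series(ge, name="ge")
    return s.loc[ids] if ids is not None else s


class KinshipCalculator:
    """Memoised pairwise kinship via the tabular recursion.

    kinship(x, x) = (1 + F_x)/2;  kinship(x, y) with x later in pedigree
    order = mean of kinship(parent_of_x, y) over x's (known) parents,
    unknown parents contributing 0.  Computed lazily pair-by-pair so no
    dense relationship matrix is ever formed.
    """

    def __init__(self, ped: Pedigree):
        self.ped = ped
        self.rank = {iid: i for i, iid in enumerate(ped.topological)}
        self._cache: dict[tuple[str, str], float] = {}
        self._f: dict[str, float] = {}
        # inbreeding in topological order so self-kinships are cheap
        for iid in ped.topological:
            sire, dam = ped.parents(iid)
            self._f[iid] = (
                self.kinship(sire, dam) if sire is not None and dam is not None else 0.0
            )

    def inbreeding(self, iid: str) -> float:
        return self._f[iid]

    def kinship(self, a: str | None, b: str | None) -> float:
        if a is None or b is None:
            return 0.0
        if self.rank[a] < self.rank[b]:
            a, b = b, a  # a is the later-born (recurse on its parents)
        key = (a, b)
        if key in self._cache:
            return self._cache[key]
        stack = [key]
        while stack:
            x, y = stack[-1]
            if (x, y) in self._cache:
                stack.pop()
                continue
            if x == y:
                sire, dam = self.ped.parents(x)
                if sire is None or dam is None:
                    self._cache[(x, y)] = 0.5 * (1.0 + 0.0)
                    stack.pop()
                    continue
                kkey = self._ordered(sire, dam)
                if kkey in self._cache:
                    self._cache[(x, y)] = 0.5 * (1.0 + self._cache[kkey])
                    stack.pop()
                else:
                    stack.append(kkey)
                continue
            sire, dam = self.ped.parents(x)
            needed = []
            total = 0.0
            ready = True
            for p in (sire, dam):
                if p is None:
                    continue
                pkey = self._ordered(p, y)
                if pkey in self._cache:
                    total += self._cache[pkey]
                else:
                    needed.append(pkey)
                    ready = False
            if ready:
                self._cache[(x, y)] = 0.5 * total
                stack.pop()
            else:
                stack.extend(needed)
        return self._cache[key]

    def _ordered(self, a: str, b: str) -> tuple[str, str]:
        return (a, b) if self.rank[a] >= self.rank[b] else (b, a)


def inbreeding(ped: Pedigree) -> pd.DataFrame:
    """Wright's F for every individual; columns ``sample_id, f_ped``."""
    calc = KinshipCalculator(ped)
    ids = ped.topological
    return pd.DataFrame(
        {"sample_id": ids, "f_ped": [calc.inbreeding(i) for i in ids]}
    )


def ne_coancestry(
    ped: Pedigree, reference_cohort: list[str]
) -> tuple[float, float]:
    """Coancestry-rate Ne over all pairs of the reference cohort.

    Returns (Ne, mean delta_c).  Ne is ``inf`` when the mean rate is zero
    (mutually unrelated, non-inbred cohort).
    """
    cohort = list(dict.fromkeys(reference_cohort))
    if len(cohort) < 2:
        raise ValueError("reference cohort must contain at least 2 individuals")
    calc = KinshipCalculator(ped)
    ge = generation_equivalents(ped)
    rates = []
    for i in range(len(cohort)):
        for j in range(i + 1, len(cohort)):
            a, b = cohort[i], cohort[j]
            c = calc.kinship(a, b)
            g_mean = 0.5 * (ge[a] + ge[b])
            if g_mean <= 0:
                # two founders carry no generation depth; their rate is 0
                rates.append(0.0 if c == 0 else 1.0 - (1.0 - c))
                continue
            rates.append(1.0 - (1.0 - c) ** (1.0 / g_mean))
    mean_rate = float(np.mean(rates))
    ne = float("inf") if mean_rate <= 0 else 1.0 / (2.0 * mean_rate)
    return ne, mean_rate


def pedigree_summary(
    ped: Pedigree, cohort: list[str] | None = None
) -> pd.DataFrame:
    """Per-individual F_PED and ge (cohort order if given, else pedigree
    order), the usual per-cohort report shape."""
    ids = cohort if cohort is not None else ped.topological
    calc = KinshipCalculator(ped)
    ge = generation_equivalents(ped)
    return pd.DataFrame(
        {
            "sample_id": ids,
            "f_ped": [calc.inbreeding(i) for i in ids],
            "ge": [float(ge[i]) for i in ids],
        }
    )
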