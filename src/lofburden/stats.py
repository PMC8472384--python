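"""Two-sided exact association statistics on allele-count 2x2 tables.

The two-sided p-value uses the minimum-likelihood rule: with all margins
fixed, sum the hypergeometric probabilities of every table whose point
probability is no larger than the observed one, with a relative guard of
``1 + 1e-7`` on the comparison (the convention of scipy's
``fisher_exact``).  The odds ratio is the unconditional sample estimate
``(a*d)/(b*c)`` with an ``inf``/``0`` convention for empty cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .cohorts import BurdenCount, Cohort

RELATIVE_GUARD = 1e-7
ENUMERATION_GUARD = 10**7
_EXACT_N_LIMIT = 100_000


class EnumerationGuardError(ValueError):
    """Margins too large for exact enumeration (normal approximation is out of scope)."""


@dataclass(frozen=True)
class ContingencyTable:
    """Allele-count 2x2 table: (a, b) group 1, (c, d) group 2 carriers/non-carriers."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def group1_total(self) -> int:
        return self.a + self.b

    @property
    def group2_total(self) -> int:
        return self.c + self.d

    def swapped(self) -> "ContingencyTable":
        return ContingencyTable(self.c, self.d, self.a, self.b)

    def transposed(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d)


def sample_odds_ratio(t: ContingencyTable) -> float:
    """Unconditional sample odds ratio (a*d)/(b*c).

    ``inf`` when b*c == 0 with a*d > 0, ``0`` when a*d == 0 with b*c > 0,
    ``nan`` (not applicable) when both products are zero.
    """
    ad, bc = t.a * t.d, t.b * t.c
    if bc == 0:
        return math.inf if ad > 0 else math.nan
    if ad == 0:
        return 0.0
    return ad / bc


def _support(t: ContingencyTable) -> tuple[int, int]:
    k = t.a + t.c
    lo = max(0, k - t.group2_total)
    hi = min(k, t.group1_total)
    return lo, hi


def _fisher_exact_integer(t: ContingencyTable) -> float:
    """Exact rational enumeration; used when the grand total is small."""
    n1, n2, k = t.group1_total, t.group2_total, t.a + t.c
    lo, hi = _support(t)
    weights = {x: math.comb(n1, x) * math.comb(n2, k - x) for x in range(lo, hi + 1)}
    w_obs = weights[t.a]
    # integer-exact version of  w <= w_obs * (1 + 1e-7)
    scale = 10**7
    acc = sum(w for w in weights.values() if w * scale <= w_obs * (scale + 1))
    p = Fraction(acc, math.comb(n1 + n2, k))
    return min(float(p), 1.0)


def _fisher_gammaln(t: ContingencyTable) -> float:
    """Vectorized log-space enumeration for large margins."""
    n1, n2, k = t.group1_total, t.group2_total, t.a + t.c
    lo, hi = _support(t)
    x = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(n1 + 1) - gammaln(x + 1) - gammaln(n1 - x + 1)
        + gammaln(n2 + 1) - gammaln(k - x + 1) - gammaln(n2 - k + x + 1)
        - (gammaln(n1 + n2 + 1) - gammaln(k + 1) - gammaln(n1 + n2 - k + 1))
    )
    log_obs = logpmf[t.a - lo]
    mask = logpmf <= log_obs + math.log1p(RELATIVE_GUARD)
    p = float(np.exp(logpmf[mask]).sum())
    return min(p, 1.0)


def fisher_two_sided(t: ContingencyTable) -> float:
    """Two-sided exact p under the minimum-likelihood rule; p in (0, 1]."""
    lo, hi = _support(t)
    if hi - lo + 1 > ENUMERATION_GUARD:
        raise EnumerationGuardError(
            f"hypergeometric support size {hi - lo + 1} exceeds the exact "
            f"enumeration guard ({ENUMERATION_GUARD}); a normal approximation "
            "is out of scope"
        )
    if t.group1_total + t.group2_total <= _EXACT_N_LIMIT:
        return _fisher_exact_integer(t)
    return _fisher_gammaln(t)


@dataclass(frozen=True)
class AssociationResult:
    variant_set: str
    group1: str
    group2: str
    table: ContingencyTable
    odds_ratio: float
    p_two_sided: float

    @property
    def significant(self) -> bool:
        return self.p_two_sided < 0.05


@dataclass(frozen=True)
class ReferencePopulation:
    """Frozen allele counts for an external reference cohort."""

    name: str
    n_alleles: int
    variant_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for vset, count in self.variant_counts.items():
            if not 0 <= count <= self.n_alleles:
                raise ValueError(
                    f"{self.name}: count {count} for {vset!r} outside [0, {self.n_alleles}]"
                )

    def burden(self, variant_set: str) -> BurdenCount:
        if variant_set not in self.variant_counts:
            raise KeyError(
                f"reference {self.name!r} has no count for variant set {variant_set!r}"
            )
        return BurdenCount(
            variant_set=variant_set,
            cohort=self.name,
            carriers=self.variant_counts[variant_set],
            allele_total=self.n_alleles,
        )


def read_reference_table(path: str | Path) -> dict[str, ReferencePopulation]:
    """Load reference populations from a TSV: population, n_alleles, variant_set, count."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    refs: dict[str, ReferencePopulation] = {}
    for name, group in df.groupby("population", sort=False):
        totals = group["n_alleles"].unique()
        if len(totals) != 1:
            raise ValueError(f"reference {name!r} has inconsistent allele totals {totals}")
        refs[str(name)] = ReferencePopulation(
            name=str(name),
            n_alleles=int(totals[0]),
            variant_counts={
                str(r.variant_set): int(r.count) for r in group.itertuples(index=False)
            },
        )
    return refs


def associate(case: BurdenCount, comparator: BurdenCount) -> AssociationResult:
    """Exact two-sided association of two burden counts on the allele scale."""
    table = ContingencyTable(
        case.carrier_alleles,
        case.non_carrier_alleles,
        comparator.carrier_alleles,
        comparator.non_carrier_alleles,
    )
    return AssociationResult(
        variant_set=case.variant_set,
        group1=case.cohort,
        group2=comparator.cohort,
        table=table,
        odds_ratio=sample_odds_ratio(table),
        p_two_sided=fisher_two_sided(table),
    )


def burden_scan(
    burdens: Sequence[BurdenCount],
    comparators: Sequence[BurdenCount | ReferencePopulation | Cohort],
    comparator_burdens: Mapping[str, Mapping[str, BurdenCount]] | None = None,
) -> list[AssociationResult]:
    """One association per (case burden x comparator).

    Comparators may be pre-computed :class:`BurdenCount` objects,
    :class:`ReferencePopulation` objects (counts looked up per variant set), or
    cohorts paired with ``comparator_burdens[cohort.name][variant_set]``.
    """
    results = []
    for burden in burdens:
        for comp in comparators:
            if isinstance(comp, BurdenCount):
                other = comp
            elif isinstance(comp, ReferencePopulation):
                try:
                    other = comp.burden(burden.variant_set)
                except KeyError as exc:
                    raise ValueError(str(exc)) from exc
            else:
                lookup = (comparator_burdens or {}).get(comp.name, {})
                if burden.variant_set not in lookup:
                    raise ValueError(
                        f"no burden for variant set {burden.variant_set!r} in "
                        f"comparator cohort {comp.name!r}"
                    )
                other = lookup[burden.variant_set]
            if other.variant_set != burden.variant_set:
                raise ValueError(
                    f"variant-set mismatch: {burden.variant_set!r} vs {other.variant_set!r}"
                )
            results.append(associate(burden, other))
    return results
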