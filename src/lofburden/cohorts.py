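"""Cohort strata, combined cohort sets, and the burden/census aggregations."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .variants import AnnotatedVariant


class CohortConfigError(ValueError):
    """Invalid cohort configuration (duplicate or unknown stratum names)."""


@dataclass(frozen=True)
class CohortStratum:
    """A named group of individuals; allele count is always 2N (diploid)."""

    name: str
    n_individuals: int
    role: str | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError(f"stratum {self.name!r} needs n_individuals >= 1")

    @property
    def n_alleles(self) -> int:
        return 2 * self.n_individuals

    @property
    def member_names(self) -> tuple[str, ...]:
        return (self.name,)


@dataclass(frozen=True)
class CohortSet:
    """A disjoint union of strata; counts are sums over members."""

    name: str
    members: tuple[CohortStratum, ...]

    def __post_init__(self) -> None:
        names = [m.name for m in self.members]
        if len(set(names)) != len(names):
            raise CohortConfigError(f"set {self.name!r} has duplicate members")
        if not self.members:
            raise CohortConfigError(f"set {self.name!r} has no members")

    @property
    def n_individuals(self) -> int:
        return sum(m.n_individuals for m in self.members)

    @property
    def n_alleles(self) -> int:
        return sum(m.n_alleles for m in self.members)

    @property
    def member_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.members)


Cohort = CohortStratum | CohortSet


def build_cohorts(
    config: Mapping | str | Path,
) -> tuple[dict[str, CohortStratum], dict[str, CohortSet]]:
    """Build strata and named combined sets from a JSON/YAML config.

    Schema: ``{"strata": [{"name", "n_individuals", "role"?}],
    "sets": [{"name", "members": [stratum names]}]}``.
    """
    if isinstance(config, (str, Path)):
        path = Path(config)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            config = yaml.safe_load(text)
        else:
            config = json.loads(text)
    strata: dict[str, CohortStratum] = {}
    for entry in config.get("strata", []):
        stratum = CohortStratum(
            name=entry["name"],
            n_individuals=int(entry["n_individuals"]),
            role=entry.get("role"),
        )
        if stratum.name in strata:
            raise CohortConfigError(f"duplicate stratum name {stratum.name!r}")
        strata[stratum.name] = stratum
    sets: dict[str, CohortSet] = {}
    for entry in config.get("sets", []):
        members = []
        for member in entry["members"]:
            if member not in strata:
                raise CohortConfigError(
                    f"set {entry['name']!r} references unknown stratum {member!r}"
                )
            members.append(strata[member])
        if entry["name"] in sets or entry["name"] in strata:
            raise CohortConfigError(f"duplicate cohort name {entry['name']!r}")
        sets[entry["name"]] = CohortSet(name=entry["name"], members=tuple(members))
    return strata, sets


# ---------------------------------------------------------------------------
# variant sets and burden counting


@dataclass(frozen=True)
class VariantSet:
    """A named, deterministic predicate over annotated variants."""

    name: str
    selector: Callable[[AnnotatedVariant], bool]

    def select(self, variants: Iterable[AnnotatedVariant]) -> list[AnnotatedVariant]:
        return [v for v in variants if self.selector(v)]


def lof_set(name: str = "all_lof") -> VariantSet:
    return VariantSet(name, lambda v: v.is_lof)


def lof_in_domain_set(domain: str, name: str | None = None) -> VariantSet:
    return VariantSet(
        name or f"{domain}_lof",
        lambda v: v.is_lof and domain in v.consequence.domains_hit,
    )


def protein_change_set(*labels: str, name: str | None = None) -> VariantSet:
    wanted = frozenset(labels)
    return VariantSet(
        name or "/".join(labels),
        lambda v: v.protein_change in wanted,
    )


@dataclass(frozen=True)
class BurdenCount:
    variant_set: str
    cohort: str
    carriers: int
    allele_total: int
    carrier_alleles: int | None = None

    def __post_init__(self) -> None:
        # tabular path: all carriers heterozygous, one allele each
        if self.carrier_alleles is None:
            object.__setattr__(self, "carrier_alleles", self.carriers)
        if self.carrier_alleles > self.allele_total:
            raise ValueError(
                f"{self.variant_set}/{self.cohort}: carrier alleles exceed allele total"
            )

    @property
    def frequency(self) -> float:
        return self.carrier_alleles / self.allele_total

    @property
    def non_carrier_alleles(self) -> int:
        return self.allele_total - self.carrier_alleles


def count_burden(
    variants: Sequence[AnnotatedVariant],
    vset: VariantSet,
    cohort: Cohort,
) -> BurdenCount:
    """Sum carriers of the selected variants over the cohort's member strata."""
    members = cohort.member_names
    strata = {m.name: m for m in (cohort.members if isinstance(cohort, CohortSet) else (cohort,))}
    carriers = 0
    for v in vset.select(variants):
        for name in members:
            count = v.carrier_counts.get(name, 0)
            if count > strata[name].n_individuals:
                raise ValueError(
                    f"variant {v.key}: {count} carriers exceed stratum "
                    f"{name!r} size {strata[name].n_individuals}"
                )
            carriers += count
    return BurdenCount(
        variant_set=vset.name,
        cohort=cohort.name,
        carriers=carriers,
        allele_total=cohort.n_alleles,
    )


@dataclass(frozen=True)
class CarrierCensus:
    n_variants: int
    total_carriers: int
    carriers_by_stratum: Mapping[str, int]
    carriers_by_domain: Mapping[str, int]

    def domain_fraction(self, domain: str) -> float:
        if self.total_carriers == 0:
            return 0.0
        return self.carriers_by_domain.get(domain, 0) / self.total_carriers

    def domain_percent(self, domain: str) -> float:
        """Carrier fraction for a domain as a percent, 1 decimal place."""
        return round(100.0 * self.domain_fraction(domain), 1)


def carrier_census(
    variants: Sequence[AnnotatedVariant],
    strata: Iterable[str] | None = None,
) -> CarrierCensus:
    """Distinct-variant and carrier totals, plus per-domain carrier counts.

    Carrier fractions are per carrier individual: a domain's count is the
    number of carriers whose variant's first affected residue lies in it.
    """
    variants = list(variants)
    if strata is None:
        seen: list[str] = []
        for v in variants:
            for name in v.carrier_counts:
                if name not in seen:
                    seen.append(name)
        strata = seen
    strata = list(strata)
    keys = {v.key for v in variants}
    by_stratum = {name: 0 for name in strata}
    by_domain: dict[str, int] = {}
    total = 0
    for v in variants:
        n = v.carriers_in(strata)
        total += n
        for name in strata:
            by_stratum[name] += v.carrier_counts.get(name, 0)
        for domain in v.consequence.domains_hit:
            by_domain[domain] = by_domain.get(domain, 0) + n
    return CarrierCensus(
        n_variants=len(keys),
        total_carriers=total,
        carriers_by_stratum=by_stratum,
        carriers_by_domain=by_domain,
    )
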