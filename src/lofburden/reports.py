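"""Run configuration and reproduction reports.

``run_discovery`` reproduces the discovery-phase LOF burden (per-variant and
total, with the exact comparison against the East Asian reference) and
``run_combined`` the combined risk grid: per-variant, domain-restricted, and
all-LOF variant sets in the familial cohort against the pooled nonfamilial
cohort and both reference populations, plus the within-study all-LOF
pairings (familial vs control, familial vs sporadic, sporadic vs control).

Every numeric cell in the rendered TSV/Markdown has its raw fraction, exact
p-value and underlying 2x2 table in the JSON sidecar.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._format import format_or, format_p, format_percent
from .cohorts import (
    BurdenCount,
    CohortSet,
    CohortStratum,
    VariantSet,
    build_cohorts,
    carrier_census,
    count_burden,
    lof_in_domain_set,
    lof_set,
    protein_change_set,
)
from .datasets import DEFAULT_EXCLUDED_POSITIONS
from .stats import (
    AssociationResult,
    ReferencePopulation,
    associate,
    read_reference_table,
)
from .transcript import TranscriptModel
from .variants import AnnotatedVariant, filter_deleterious, read_variant_table

logger = logging.getLogger("lofburden")


class ConfigError(ValueError):
    """Invalid run configuration (missing files or bad values)."""


@dataclass(frozen=True)
class RunConfig:
    variant_table: Path
    cohort_config: Path
    transcript_model: Path
    reference_table: Path
    cadd_cutoff: float = 25.0
    domain_filter: str | None = None
    exclude_positions: tuple[str, ...] = DEFAULT_EXCLUDED_POSITIONS
    out_dir: Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cadd_cutoff < 0:
            raise ConfigError("cadd_cutoff must be >= 0")
        for attr in ("variant_table", "cohort_config", "transcript_model", "reference_table"):
            path = Path(getattr(self, attr))
            object.__setattr__(self, attr, path)
            if not path.exists():
                raise ConfigError(f"{attr} path does not exist: {path}")
        if self.out_dir is not None:
            object.__setattr__(self, "out_dir", Path(self.out_dir))

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        base = path.parent
        for key in ("variant_table", "cohort_config", "transcript_model", "reference_table"):
            if key not in raw:
                raise ConfigError(f"run config {path} lacks {key!r}")
            raw[key] = (base / raw[key]) if not Path(raw[key]).is_absolute() else Path(raw[key])
        if "exclude_positions" in raw:
            raw["exclude_positions"] = tuple(raw["exclude_positions"])
        return cls(**raw)


@dataclass(frozen=True)
class PipelineInputs:
    model: TranscriptModel
    variants: list[AnnotatedVariant]
    strata: dict[str, CohortStratum]
    sets: dict[str, CohortSet]
    references: dict[str, ReferencePopulation]
    checksums: Mapping[str, str]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_inputs(config: RunConfig) -> PipelineInputs:
    model = TranscriptModel.from_json(config.transcript_model)
    variants = read_variant_table(config.variant_table, model)
    strata, sets = build_cohorts(config.cohort_config)
    references = read_reference_table(config.reference_table)
    checksums = {
        "variant_table": _sha256(config.variant_table),
        "cohort_config": _sha256(config.cohort_config),
        "transcript_model": _sha256(config.transcript_model),
        "reference_table": _sha256(config.reference_table),
    }
    for name, digest in checksums.items():
        logger.info("input %s sha256=%s", name, digest)
    return PipelineInputs(model, variants, strata, sets, references, checksums)


def table_variant_sets(
    variants: Sequence[AnnotatedVariant],
    domain: str = "zinc_hook",
    domain_filter: str | None = None,
) -> list[VariantSet]:
    """Per-variant sets for each LOF variant in the domain, the combined
    domain set, and the all-LOF set (dropped under a domain filter)."""
    target = domain_filter or domain
    labels = sorted(
        {
            v.protein_change
            for v in variants
            if v.is_lof and target in v.consequence.domains_hit and v.protein_change
        }
    )
    sets = [protein_change_set(label) for label in labels]
    if labels:
        combined = protein_change_set(*labels, name=f"{target}_lof")
        sets.append(combined)
    if domain_filter is None:
        sets.append(lof_set())
    return sets


@dataclass(frozen=True)
class Report:
    title: str
    rows: tuple[dict, ...]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.rows))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_markdown(self, path: str | Path | None = None) -> str:
        frame = self.to_frame()
        lines = [f"## {self.title}", ""]
        if not frame.empty:
            header = "| " + " | ".join(frame.columns) + " |"
            rule = "|" + "|".join(["---"] * len(frame.columns)) + "|"
            lines += [header, rule]
            for _, row in frame.iterrows():
                cells = [
                    "" if (not isinstance(v, (list, tuple)) and pd.isna(v)) else str(v)
                    for v in row
                ]
                lines.append("| " + " | ".join(cells) + " |")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "title": self.title,
            "metadata": self.metadata,
            "rows": list(self.rows),
        }
        text = json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def _association_row(result: AssociationResult, n_tests: int) -> dict:
    t = result.table
    return {
        "variant_set": result.variant_set,
        "cohort": result.group1,
        "carriers": t.a,
        "allele_total": t.a + t.b,
        "frequency": format_percent(t.a / (t.a + t.b)),
        "comparator": result.group2,
        "comparator_carriers": t.c,
        "comparator_allele_total": t.c + t.d,
        "comparator_frequency": format_percent(t.c / (t.c + t.d)),
        "odds_ratio": format_or(result.odds_ratio),
        "p_two_sided": format_p(result.p_two_sided),
        "significant": result.significant,
        "n_tests": n_tests,
        "raw_odds_ratio": result.odds_ratio,
        "raw_p": result.p_two_sided,
        "table": [t.a, t.b, t.c, t.d],
    }


def run_discovery(config: RunConfig, inputs: PipelineInputs | None = None) -> Report:
    """Discovery-stratum LOF burden with the exact comparison against the
    East Asian reference, applying the CADD filter and position blocklist."""
    inputs = inputs or load_inputs(config)
    if "discovery_fh" not in inputs.strata:
        raise ConfigError("cohort config lacks a 'discovery_fh' stratum")
    discovery = inputs.strata["discovery_fh"]
    qualifying = filter_deleterious(
        inputs.variants, config.cadd_cutoff, config.exclude_positions
    )
    lof = [v for v in qualifying if v.is_lof]
    rows = []
    for v in sorted(lof, key=lambda v: v.coding_change.cdna_start):
        carriers = v.carrier_counts.get(discovery.name, 0)
        if carriers == 0:
            continue
        rows.append(
            {
                "variant_set": v.protein_change or v.key,
                "cohort": discovery.name,
                "carriers": carriers,
                "allele_total": discovery.n_alleles,
                "frequency": format_percent(carriers / discovery.n_alleles),
                "comparator": None,
            }
        )
    results = []
    if lof:
        total = count_burden(lof, lof_set(), discovery)
        reference = inputs.references["gnomad_ea"]
        result = associate(total, reference.burden("all_lof"))
        results.append(result)
        rows.append(_association_row(result, n_tests=1))
    return Report(
        title="Discovery-cohort LOF burden",
        rows=tuple(rows),
        metadata={
            "config": {
                "cadd_cutoff": config.cadd_cutoff,
                "exclude_positions": list(config.exclude_positions),
                "seed": config.seed,
            },
            "checksums": dict(inputs.checksums),
            "n_tests": len(results),
        },
    )


def run_combined(config: RunConfig, inputs: PipelineInputs | None = None) -> Report:
    """The combined risk grid over familial vs nonfamilial/reference cohorts."""
    inputs = inputs or load_inputs(config)
    for required in ("familial", "nonfamilial"):
        if required not in inputs.sets:
            raise ConfigError(f"cohort config lacks a {required!r} set")
    familial = inputs.sets["familial"]
    nonfamilial = inputs.sets["nonfamilial"]
    qualifying = filter_deleterious(
        inputs.variants, config.cadd_cutoff, config.exclude_positions
    )
    lof = [v for v in qualifying if v.is_lof]
    vsets = table_variant_sets(lof, domain_filter=config.domain_filter)
    for name in ("gnomad_ea", "gnomad_all"):
        if name not in inputs.references:
            raise ConfigError(f"reference table lacks population {name!r}")
        if inputs.references[name].n_alleles <= 0:
            raise ConfigError(f"reference {name!r} has a zero allele total")

    results: list[AssociationResult] = []
    for vset in vsets:
        case = count_burden(lof, vset, familial)
        comparators: list[BurdenCount] = [count_burden(lof, vset, nonfamilial)]
        for ref_name in ("gnomad_ea", "gnomad_all"):
            ref = inputs.references[ref_name]
            if vset.name in ref.variant_counts:
                comparators.append(ref.burden(vset.name))
        for comp in comparators:
            results.append(associate(case, comp))
    if config.domain_filter is None:
        # within-study all-LOF pairings
        all_lof = lof_set()
        fam = count_burden(lof, all_lof, familial)
        spor = count_burden(lof, all_lof, inputs.strata["sporadic"])
        ctrl = count_burden(lof, all_lof, inputs.strata["control"])
        results.append(associate(fam, ctrl))
        results.append(associate(fam, spor))
        results.append(associate(spor, ctrl))

    n_tests = len(results)
    rows = tuple(_association_row(r, n_tests) for r in results)
    census = carrier_census(lof)
    return Report(
        title="Combined familial-risk grid (LOF variant sets)",
        rows=rows,
        metadata={
            "config": {
                "cadd_cutoff": config.cadd_cutoff,
                "domain_filter": config.domain_filter,
                "exclude_positions": list(config.exclude_positions),
                "seed": config.seed,
            },
            "checksums": dict(inputs.checksums),
            "n_tests": n_tests,
            "census": {
                "n_variants": census.n_variants,
                "total_carriers": census.total_carriers,
                "carriers_by_stratum": dict(census.carriers_by_stratum),
                "zinc_hook_carrier_percent": census.domain_percent("zinc_hook"),
            },
        },
    )


def default_run_config(**overrides) -> RunConfig:
    """A RunConfig pointing at the bundled fixture inputs."""
    from . import datasets

    kwargs = dict(
        variant_table=datasets.variant_table_path(),
        cohort_config=datasets.cohort_config_path(),
        transcript_model=datasets.transcript_model_path(),
        reference_table=datasets.reference_table_path(),
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)
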