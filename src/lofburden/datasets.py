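"""Accessors for the bundled RAD50 / Henan-cohort fixture inputs.

All inputs are small plain-text files frozen from published summary counts:
a per-variant carrier table, a cohort configuration, reference-population
allele counts (gnomAD v2.1.1 export, East Asian and all populations), and
the NM_005732 transcript/domain model.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .cohorts import CohortSet, CohortStratum, build_cohorts
from .stats import ReferencePopulation, read_reference_table
from .transcript import TranscriptModel
from .variants import AnnotatedVariant, read_variant_table

#: genomic position the published analysis removed before counting (p.L719fs)
DEFAULT_EXCLUDED_POSITIONS = ("chr5:131931451",)


def _data_path(name: str) -> Path:
    return Path(resources.files("lofburden").joinpath("data", name))


def variant_table_path() -> Path:
    return _data_path("rad50_variants.tsv")


def cohort_config_path() -> Path:
    return _data_path("henan_cohorts.json")


def reference_table_path() -> Path:
    return _data_path("gnomad_reference.tsv")


def transcript_model_path() -> Path:
    return _data_path("nm_005732.json")


def load_transcript_model() -> TranscriptModel:
    return TranscriptModel.from_json(transcript_model_path())


def load_variants(model: TranscriptModel | None = None) -> list[AnnotatedVariant]:
    model = model or load_transcript_model()
    return read_variant_table(variant_table_path(), model)


def load_cohorts() -> tuple[dict[str, CohortStratum], dict[str, CohortSet]]:
    return build_cohorts(cohort_config_path())


def load_references() -> dict[str, ReferencePopulation]:
    return read_reference_table(reference_table_path())
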