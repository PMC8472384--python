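"""Annotated variant records and tabular / VCF input.

The tabular dialect is a TSV with fixed leading columns

    chrom  pos  exon  coding_change  protein_change  cadd

followed by one carrier-count column per cohort stratum.  ``pos``, ``exon``,
``protein_change`` and ``cadd`` may be empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .coding import CodingChange, canonical, parse_coding_change
from .consequence import MISSENSE, ConsequenceCall, classify_consequence
from .transcript import TranscriptModel

FIXED_COLUMNS = ("chrom", "pos", "exon", "coding_change", "protein_change", "cadd")
ANNOTATION_COLUMNS = ("consequence", "residue", "is_lof", "domains")


@dataclass(frozen=True)
class AnnotatedVariant:
    chrom: str
    pos: int | None
    coding_change: CodingChange
    consequence: ConsequenceCall
    exon: int | None = None
    cadd_score: float | None = None
    carrier_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for stratum, count in self.carrier_counts.items():
            if count < 0:
                raise ValueError(f"negative carrier count for stratum {stratum!r}")

    @property
    def key(self) -> str:
        """Stable identity of the edit, independent of input dialect."""
        return canonical(self.coding_change)

    @property
    def is_lof(self) -> bool:
        return self.consequence.is_lof

    @property
    def protein_change(self) -> str | None:
        return self.consequence.protein_change

    def carriers_in(self, strata: Iterable[str]) -> int:
        return sum(self.carrier_counts.get(name, 0) for name in strata)

    @property
    def total_carriers(self) -> int:
        return sum(self.carrier_counts.values())


def _opt_int(value) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return int(value)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)


def read_variant_table(path: str | Path, model: TranscriptModel) -> list[AnnotatedVariant]:
    """Read, parse and classify a variant TSV against a transcript model."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    missing = [c for c in ("chrom", "coding_change") if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} lacks required columns {missing}")
    strata = [c for c in df.columns if c not in FIXED_COLUMNS + ANNOTATION_COLUMNS]
    variants: list[AnnotatedVariant] = []
    for row in df.itertuples(index=False):
        change = parse_coding_change(getattr(row, "coding_change"))
        label = getattr(row, "protein_change", None)
        if isinstance(label, float) and pd.isna(label):
            label = None
        call = classify_consequence(change, model, protein_change=label)
        counts = {name: int(getattr(row, name)) for name in strata}
        variants.append(
            AnnotatedVariant(
                chrom=str(getattr(row, "chrom")),
                pos=_opt_int(getattr(row, "pos", None)),
                exon=_opt_int(getattr(row, "exon", None)),
                coding_change=change,
                consequence=call,
                cadd_score=_opt_float(getattr(row, "cadd", None)),
                carrier_counts=counts,
            )
        )
    return variants


def to_frame(variants: Sequence[AnnotatedVariant]) -> pd.DataFrame:
    """Annotated variants as a tidy frame (adds consequence/residue/domain/LOF)."""
    strata: list[str] = []
    for v in variants:
        for name in v.carrier_counts:
            if name not in strata:
                strata.append(name)
    rows = []
    for v in variants:
        row = {
            "chrom": v.chrom,
            "pos": v.pos,
            "exon": v.exon,
            "coding_change": v.key,
            "protein_change": v.protein_change,
            "consequence": v.consequence.consequence,
            "residue": v.consequence.first_affected_residue,
            "is_lof": v.is_lof,
            "domains": ",".join(v.consequence.domains_hit),
            "cadd": v.cadd_score,
        }
        for name in strata:
            row[name] = v.carrier_counts.get(name, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_variant_table(variants: Sequence[AnnotatedVariant], path: str | Path) -> None:
    """Write the input dialect (fixed columns + strata); see ``to_frame`` for
    the annotated export with consequence/residue/domain columns."""
    frame = to_frame(variants)
    keep = [c for c in frame.columns if c not in ANNOTATION_COLUMNS]
    frame[keep].to_csv(path, sep="\t", index=False)


def filter_deleterious(
    variants: Iterable[AnnotatedVariant],
    cadd_cutoff: float = 25.0,
    exclude_positions: Iterable[str | int] = (),
) -> list[AnnotatedVariant]:
    """Retain LOF variants and missense variants with CADD >= cutoff.

    LOF (stop-gain / frameshift) variants pass regardless of CADD
    availability; a missense variant with no CADD score is dropped.  A
    genomic-position blocklist (``"chr5:131931451"`` strings or bare
    positions) is honored first.
    """
    if cadd_cutoff < 0:
        raise ValueError("cadd_cutoff must be >= 0")
    blocked: set[tuple[str | None, int]] = set()
    for entry in exclude_positions:
        if isinstance(entry, str) and ":" in entry:
            chrom, pos = entry.split(":", 1)
            blocked.add((chrom.strip(), int(pos.replace(",", ""))))
        else:
            blocked.add((None, int(entry)))
    kept = []
    for v in variants:
        if v.pos is not None and ((v.chrom, v.pos) in blocked or (None, v.pos) in blocked):
            continue
        if v.is_lof:
            kept.append(v)
        elif (
            v.consequence.consequence == MISSENSE
            and v.cadd_score is not None
            and v.cadd_score >= cadd_cutoff
        ):
            kept.append(v)
    return kept


def read_vcf_carriers(
    path: str | Path,
    sample_strata: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Carrier counts per biallelic VCF record from GT fields.

    Heterozygous carriers count once; a homozygous-alt genotype counts one
    carrier but two carrier alleles.  ``sample_strata`` maps sample name to
    stratum; unmapped samples fall into stratum ``"all"``.  Returns a frame
    with columns chrom, pos, ref, alt, stratum, carriers, carrier_alleles.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for record in vcf:
            if record.alts is None or len(record.alts) != 1:
                raise ValueError(
                    f"record {record.chrom}:{record.pos} is not biallelic"
                )
            per_stratum: dict[str, list[int]] = {}
            for sample, call in record.samples.items():
                gt = call.get("GT")
                alt_alleles = sum(1 for a in (gt or ()) if a == 1)
                stratum = (sample_strata or {}).get(sample, "all")
                per_stratum.setdefault(stratum, []).append(alt_alleles)
            for stratum, alleles in sorted(per_stratum.items()):
                rows.append(
                    {
                        "chrom": record.chrom,
                        "pos": record.pos,
                        "ref": record.ref,
                        "alt": record.alts[0],
                        "stratum": stratum,
                        "carriers": sum(1 for a in alleles if a > 0),
                        "carrier_alleles": sum(alleles),
                    }
                )
    return pd.DataFrame(rows)
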