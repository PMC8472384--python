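"""Consequence classification of coding changes on a transcript model."""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq

from .coding import DELETION, INSERTION, SUBSTITUTION, CodingChange
from .transcript import CdsRangeError, TranscriptModel

STOP_GAIN = "stop_gain"
FRAMESHIFT = "frameshift"
INFRAME_INDEL = "inframe_indel"
MISSENSE = "missense"
SYNONYMOUS = "synonymous"
UNKNOWN = "unknown"

LOF_CONSEQUENCES = frozenset({STOP_GAIN, FRAMESHIFT})

_PROTEIN_RE = re.compile(r"^p\.([A-Za-z\*])(\d+)(.*)$")


@dataclass(frozen=True)
class ConsequenceCall:
    consequence: str
    first_affected_residue: int
    is_lof: bool
    protein_change: str | None = None
    domains_hit: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.is_lof != (self.consequence in LOF_CONSEQUENCES):
            raise ValueError(
                f"is_lof={self.is_lof} inconsistent with consequence {self.consequence!r}"
            )


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _consequence_from_protein_label(label: str, residue: int) -> str:
    """Infer a substitution consequence from a p. label like 'p.Q672X'."""
    m = _PROTEIN_RE.match(label)
    if not m:
        raise ValueError(f"cannot parse protein-change label {label!r}")
    ref_aa, labelled_residue, suffix = m.group(1), int(m.group(2)), m.group(3)
    if labelled_residue != residue:
        raise ValueError(
            f"protein label {label!r} names residue {labelled_residue}, "
            f"but the coding change maps to residue {residue}"
        )
    if suffix in ("X", "*"):
        return STOP_GAIN
    if suffix.startswith("fs"):
        raise ValueError(f"frameshift label {label!r} on a substitution")
    if suffix == ref_aa or suffix in ("", "="):
        return SYNONYMOUS
    return MISSENSE


def classify_consequence(
    change: CodingChange,
    model: TranscriptModel,
    protein_change: str | None = None,
) -> ConsequenceCall:
    """Classify a parsed coding change on a transcript.

    Indels are classified purely by length arithmetic: net length change not
    divisible by 3 is a frameshift (LOF), otherwise an in-frame indel.
    Substitutions are translated against the model CDS when a sequence is
    attached; without one, a supplied protein-change label is trusted, and
    failing that the consequence is ``unknown``.
    """
    start = change.cdna_start
    if start > model.cds_length:
        raise CdsRangeError(
            f"{change.raw or change}: position {start} beyond CDS length {model.cds_length}"
        )
    if change.kind == DELETION and change.cdna_end > model.cds_length:
        raise CdsRangeError(
            f"{change.raw or change}: deletion end {change.cdna_end} beyond CDS"
        )
    residue = model.codon_index(start)
    domains = tuple(model.assign_domains(residue))

    if change.kind in (INSERTION, DELETION):
        if change.net_length_change % 3 != 0:
            consequence = FRAMESHIFT
        else:
            consequence = INFRAME_INDEL
        label = protein_change
    else:  # substitution
        label = protein_change
        if model.cds_sequence is not None:
            codon = model.codon_at(residue)
            offset = (start - 1) % 3
            if change.ref_base and codon[offset] != change.ref_base:
                raise ValueError(
                    f"{change.raw or change}: reference base mismatch at c.{start} "
                    f"(model has {codon[offset]}, change states {change.ref_base})"
                )
            mutated = codon[:offset] + change.alt_bases + codon[offset + 1:]
            ref_aa, alt_aa = _translate(codon), _translate(mutated)
            if alt_aa == "*" and ref_aa != "*":
                consequence = STOP_GAIN
            elif alt_aa == ref_aa:
                consequence = SYNONYMOUS
            else:
                consequence = MISSENSE
            if label is None:
                alt_label = "X" if alt_aa == "*" else alt_aa
                label = f"p.{ref_aa}{residue}{alt_label}"
        elif protein_change is not None:
            consequence = _consequence_from_protein_label(protein_change, residue)
        else:
            consequence = UNKNOWN

    return ConsequenceCall(
        consequence=consequence,
        first_affected_residue=residue,
        is_lof=consequence in LOF_CONSEQUENCES,
        protein_change=label,
        domains_hit=domains,
    )
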