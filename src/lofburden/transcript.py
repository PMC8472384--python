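"""Transcript coordinate model: CDS arithmetic and protein-domain mapping.

A :class:`TranscriptModel` carries the minimal information needed to place a
cDNA-level edit on the protein: the CDS length, an optional CDS sequence (for
substitution translation), optional exon intervals in cDNA space, and a list
of named protein-residue domain intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path


class CdsRangeError(ValueError):
    """A cDNA coordinate falls outside the coding sequence."""


@dataclass(frozen=True)
class DomainInterval:
    """Closed interval of 1-based protein residues, e.g. zinc_hook 635-734."""

    name: str
    start_residue: int
    end_residue: int

    def __post_init__(self) -> None:
        if self.start_residue < 1:
            raise ValueError(f"start_residue must be >= 1, got {self.start_residue}")
        if self.start_residue > self.end_residue:
            raise ValueError(
                f"domain {self.name!r}: start_residue {self.start_residue} "
                f"> end_residue {self.end_residue}"
            )

    def __contains__(self, residue: int) -> bool:
        return self.start_residue <= residue <= self.end_residue


def codon_index(cdna_pos: int, cds_length: int | None = None) -> int:
    """1-based protein residue containing a 1-based cDNA coding position.

    Residue r covers cDNA positions [3r-2, 3r], i.e. ``(pos - 1) // 3 + 1``.
    """
    if cdna_pos < 1:
        raise CdsRangeError(f"cDNA position must be >= 1, got {cdna_pos}")
    if cds_length is not None and cdna_pos > cds_length:
        raise CdsRangeError(
            f"cDNA position {cdna_pos} beyond CDS length {cds_length}"
        )
    return (cdna_pos - 1) // 3 + 1


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    cds_length: int
    domains: tuple[DomainInterval, ...] = ()
    cds_sequence: str | None = None
    exon_cdna_intervals: tuple[tuple[int, int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.cds_length < 1:
            raise ValueError("cds_length must be positive")
        object.__setattr__(self, "domains", tuple(self.domains))
        if self.cds_sequence is not None:
            seq = self.cds_sequence.upper()
            object.__setattr__(self, "cds_sequence", seq)
            if len(seq) != self.cds_length:
                raise ValueError(
                    f"cds_sequence length {len(seq)} != cds_length {self.cds_length}"
                )
            if self.cds_length % 3 != 0:
                raise ValueError("cds_length must be divisible by 3 when a sequence is given")
            if set(seq) - set("ACGTN"):
                raise ValueError("cds_sequence contains non-nucleotide characters")
        if self.exon_cdna_intervals is not None:
            ivs = tuple(tuple(iv) for iv in self.exon_cdna_intervals)
            object.__setattr__(self, "exon_cdna_intervals", ivs)
            prev_end = 0
            for exon, start, end in ivs:
                if start > end:
                    raise ValueError(f"exon {exon}: start {start} > end {end}")
                if start <= prev_end:
                    raise ValueError(f"exon {exon}: intervals overlap or are unordered")
                prev_end = end

    @property
    def n_residues(self) -> int:
        return (self.cds_length + 2) // 3

    def codon_index(self, cdna_pos: int) -> int:
        return codon_index(cdna_pos, self.cds_length)

    def codon_at(self, residue: int) -> str:
        """Reference codon (3 nt) for a 1-based residue; requires cds_sequence."""
        if self.cds_sequence is None:
            raise ValueError(f"{self.transcript_id} has no CDS sequence attached")
        if not 1 <= residue <= self.cds_length // 3:
            raise CdsRangeError(f"residue {residue} outside CDS")
        return self.cds_sequence[3 * (residue - 1): 3 * residue]

    def assign_domains(self, residue: int) -> list[str]:
        """Names of all domains whose closed interval contains ``residue``."""
        if residue < 1:
            raise ValueError(f"residue must be >= 1, got {residue}")
        return [d.name for d in self.domains if residue in d]

    @classmethod
    def from_json(cls, path: str | Path) -> "TranscriptModel":
        """Load a model from JSON.

        Schema: ``{"transcript_id", "cds_length", "domains": [{"name",
        "start", "end"}], "cds_fasta": optional path (relative to the JSON
        file), "exons": optional [[exon, cdna_start, cdna_end], ...]}``.
        """
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh)
        domains = tuple(
            DomainInterval(d["name"], int(d["start"]), int(d["end"]))
            for d in raw.get("domains", [])
        )
        cds_sequence = None
        if raw.get("cds_fasta"):
            from Bio import SeqIO

            fasta = path.parent / raw["cds_fasta"]
            record = next(SeqIO.parse(str(fasta), "fasta"))
            cds_sequence = str(record.seq)
        exons = raw.get("exons")
        return cls(
            transcript_id=raw["transcript_id"],
            cds_length=int(raw["cds_length"]),
            domains=domains,
            cds_sequence=cds_sequence,
            exon_cdna_intervals=tuple(tuple(e) for e in exons) if exons else None,
        )
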