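"""Parsing of cDNA coding-change strings.

Two dialects of the same edit are accepted:

* annotation-tool style: ``c.C2014T`` (ref base, position, alt base)
* standard HGVS style:   ``c.2014C>T``

plus simple insertions (``c.2165_2166insT``) and deletions (``c.2980_2983del``,
``c.1110delA``).  Parsed edits round-trip through :func:`canonical`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_NUC = "ACGT"

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"


class CodingChangeParseError(ValueError):
    """Raised when a coding-change string cannot be parsed."""


@dataclass(frozen=True)
class CodingChange:
    """A cDNA-level edit on a transcript coding sequence.

    Coordinates are 1-based on the CDS.  For substitutions ``cdna_start ==
    cdna_end``; for insertions the edit sits between ``cdna_start`` and
    ``cdna_end == cdna_start + 1``; for deletions the closed interval
    ``[cdna_start, cdna_end]`` is removed.
    """

    kind: str
    cdna_start: int
    cdna_end: int
    ref_base: str | None = None
    alt_bases: str | None = None
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.kind not in (SUBSTITUTION, INSERTION, DELETION):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.cdna_start < 1:
            raise ValueError(f"cdna_start must be >= 1, got {self.cdna_start}")
        if self.kind == SUBSTITUTION:
            if self.cdna_start != self.cdna_end:
                raise ValueError("substitution requires cdna_start == cdna_end")
            if not (self.ref_base and len(self.ref_base) == 1):
                raise ValueError("substitution requires a single ref_base")
            if not (self.alt_bases and len(self.alt_bases) == 1):
                raise ValueError("substitution requires a single alt base")
        elif self.kind == INSERTION:
            if self.cdna_end != self.cdna_start + 1:
                raise ValueError("insertion requires cdna_end == cdna_start + 1")
            if not self.alt_bases:
                raise ValueError("insertion requires non-empty alt_bases")
        else:  # deletion
            if self.cdna_end < self.cdna_start:
                raise ValueError("deletion requires cdna_end >= cdna_start")

    @property
    def first_affected_position(self) -> int:
        """First edited cDNA base (insertion affects the codon of cdna_start)."""
        return self.cdna_start

    @property
    def deleted_length(self) -> int:
        return self.cdna_end - self.cdna_start + 1 if self.kind == DELETION else 0

    @property
    def inserted_length(self) -> int:
        return len(self.alt_bases) if self.kind == INSERTION and self.alt_bases else 0

    @property
    def net_length_change(self) -> int:
        return self.inserted_length - self.deleted_length


_SUB_HGVS = re.compile(rf"^(\d+)([{_NUC}])>([{_NUC}])$")
_SUB_DIALECT = re.compile(rf"^([{_NUC}])(\d+)([{_NUC}])$")
_INS = re.compile(rf"^(\d+)_(\d+)ins([{_NUC}]+)$")
_DEL = re.compile(rf"^(\d+)(?:_(\d+))?del([{_NUC}]*)$")


def parse_coding_change(text: str) -> CodingChange:
    """Parse a coding-change string in either accepted dialect.

    Raises :class:`CodingChangeParseError` naming the offending token on
    malformed input, including a non-``c.`` prefix.
    """
    text = text.strip()
    if not text.startswith("c."):
        token = text.split(".", 1)[0] + "." if "." in text else text
        raise CodingChangeParseError(
            f"expected coding-level 'c.' prefix, got {token!r} in {text!r}"
        )
    body = text[2:]

    m = _SUB_HGVS.match(body)
    if m:
        pos = int(m.group(1))
        return CodingChange(SUBSTITUTION, pos, pos, m.group(2), m.group(3), raw=text)
    m = _SUB_DIALECT.match(body)
    if m:
        pos = int(m.group(2))
        return CodingChange(SUBSTITUTION, pos, pos, m.group(1), m.group(3), raw=text)
    m = _INS.match(body)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        if end != start + 1:
            raise CodingChangeParseError(
                f"insertion interval {start}_{end} is not between adjacent bases in {text!r}"
            )
        return CodingChange(INSERTION, start, end, None, m.group(3), raw=text)
    m = _DEL.match(body)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        if end < start:
            raise CodingChangeParseError(
                f"deletion interval {start}_{end} is reversed in {text!r}"
            )
        stated = m.group(3) or None
        if stated is not None and len(stated) != end - start + 1:
            raise CodingChangeParseError(
                f"deleted bases {stated!r} do not span {start}_{end} in {text!r}"
            )
        ref = stated if stated and len(stated) == 1 else None
        return CodingChange(DELETION, start, end, ref, None, raw=text)

    raise CodingChangeParseError(f"unrecognized coding-change body {body!r} in {text!r}")


def canonical(change: CodingChange) -> str:
    """Canonical HGVS-style rendering; ``parse_coding_change`` round-trips it."""
    if change.kind == SUBSTITUTION:
        return f"c.{change.cdna_start}{change.ref_base}>{change.alt_bases}"
    if change.kind == INSERTION:
        return f"c.{change.cdna_start}_{change.cdna_end}ins{change.alt_bases}"
    if change.cdna_start == change.cdna_end:
        suffix = change.ref_base or ""
        return f"c.{change.cdna_start}del{suffix}"
    return f"c.{change.cdna_start}_{change.cdna_end}del"
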