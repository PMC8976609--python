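"""Parsing of HGVS cDNA (c.) descriptions into representative CDS coordinates.

The cluster-region scan bins carriers by the position of their variant along
the coding sequence.  A multi-base variant (deletion, duplication, delins) is
anchored at its 5'-most affected base, which is how published bin boundaries
such as ``5470`` (start of the 8-bp deletion c.5470_5477del) arise.  Positions
at exon-intron boundaries keep their signed intronic offset, e.g. ``5468-1``
sorts immediately before ``5468``.

Only the coding-exon +/- near-intronic subset of HGVS is supported
(substitution, del, dup, ins, delins).  Anything else — inversions, complex
alleles, genomic or protein descriptions — is rejected loudly rather than
mis-parsed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import total_ordering

from .errors import HgvsParseError, WrongSchemeError

__all__ = ["CdsCoordinate", "parse_cdna", "parse_position"]


@total_ordering
@dataclass(frozen=True)
class CdsCoordinate:
    """A 1-based CDS position with an optional signed intronic offset.

    Ordering is lexicographic on ``(base, offset)``: for a given base,
    negative offsets (acceptor side) sort before the exonic position and
    positive offsets (donor side) after, matching transcript direction.
    """

    base: int
    offset: int = 0
    label: str = field(default="", compare=False, repr=False)

    def __post_init__(self):
        if self.base < 1:
            raise ValueError(f"CDS base must be >= 1, got {self.base}")
        if not self.label:
            object.__setattr__(self, "label", self.position_label())

    def position_label(self) -> str:
        if self.offset == 0:
            return str(self.base)
        return f"{self.base}{self.offset:+d}"

    def __lt__(self, other: "CdsCoordinate") -> bool:
        return (self.base, self.offset) < (other.base, other.offset)

    def __str__(self) -> str:
        return self.position_label()


_POSITION_RE = re.compile(r"^(\d+)([+-]\d+)?$")

# one or two positions, then the edit tail
_CDNA_RE = re.compile(
    r"^c\.(?P<start>\d+(?:[+-]\d+)?)"
    r"(?:_(?P<end>\d+(?:[+-]\d+)?))?"
    r"(?P<tail>.*)$"
)

_SUB_RE = re.compile(r"^[ACGTacgt]>[ACGTacgt]$")
_DEL_RE = re.compile(r"^del[ACGTNacgtn]*$")
_DUP_RE = re.compile(r"^dup[ACGTNacgtn]*$")
_INS_RE = re.compile(r"^ins[ACGTNacgtn]+$")
_DELINS_RE = re.compile(r"^delins[ACGTNacgtn]+$")

_OTHER_SCHEMES = ("g.", "p.", "n.", "m.", "r.", "o.")


def parse_position(token: str) -> CdsCoordinate:
    """Parse a bare CDS position token such as ``"5468-1"`` or ``"7805+1"``.

    Whitespace around the offset sign (as sometimes typeset, ``"7805 + 1"``)
    is tolerated.
    """
    compact = token.replace(" ", "")
    m = _POSITION_RE.match(compact)
    if not m:
        raise HgvsParseError(token, "unparseable CDS position")
    base = int(m.group(1))
    offset = int(m.group(2)) if m.group(2) else 0
    return CdsCoordinate(base=base, offset=offset, label=compact)


def parse_cdna(hgvs_c: str) -> CdsCoordinate:
    """Return the 5'-most affected CDS base of an HGVS c. description.

    >>> parse_cdna("c.5470_5477delATTGGGCA")
    CdsCoordinate(base=5470, offset=0)
    >>> parse_cdna("c.5468-1G>A")
    CdsCoordinate(base=5468, offset=-1)
    """
    token = hgvs_c.strip()
    for scheme in _OTHER_SCHEMES:
        if token.startswith(scheme) or ":" in token and token.split(":", 1)[1].startswith(scheme):
            raise WrongSchemeError(token)
    # tolerate "BRCA1:c.xxx" style prefixes
    if ":" in token:
        token = token.split(":", 1)[1]
    if not token.startswith("c."):
        raise WrongSchemeError(hgvs_c)
    m = _CDNA_RE.match(token)
    if not m:
        raise HgvsParseError(hgvs_c)
    start = parse_position(m.group("start"))
    end = m.group("end")
    tail = m.group("tail")
    if end is not None:
        # validate the end position even though the 5' anchor is returned
        end_coord = parse_position(end)
        if end_coord < start:
            raise HgvsParseError(hgvs_c, "span end precedes span start")
        if not any(r.match(tail) for r in (_DEL_RE, _DUP_RE, _INS_RE, _DELINS_RE)):
            raise HgvsParseError(hgvs_c)
    else:
        if not any(r.match(tail) for r in (_SUB_RE, _DEL_RE, _DUP_RE, _DELINS_RE)):
            raise HgvsParseError(hgvs_c)
    return CdsCoordinate(base=start.base, offset=start.offset, label=start.label)
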