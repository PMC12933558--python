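"""Canonical identifiers for modified residues.

A site key names one modified residue on one protein:
``PROTEIN:Y187:phosphorylation`` — colon-separated, one-letter residue
code immediately followed by the 1-based position, then the modification
type.  Row keys of PTM matrices use this grammar.
"""

from __future__ import annotations

import re
from typing import NamedTuple

__all__ = ["SiteKey", "SiteKeyError", "parse_site_key", "format_site_key"]

_SITE_RE = re.compile(r"^([A-Za-z])(\d+)$")


class SiteKeyError(ValueError):
    """Raised when a site key does not follow the grammar."""


class SiteKey(NamedTuple):
    protein: str
    residue: str
    position: int
    ptm_type: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return format_site_key(self.protein, self.residue, self.position, self.ptm_type)


def parse_site_key(key: str) -> SiteKey:
    """Parse ``PROTEIN:Y187:phosphorylation`` into its components.

    Raises
    ------
    SiteKeyError
        If the key has the wrong number of fields, a malformed residue
        token, or a position < 1.
    """
    parts = key.split(":")
    if len(parts) != 3:
        raise SiteKeyError(f"site key {key!r}: expected 3 colon-separated fields")
    protein, site, ptm_type = parts
    if not protein:
        raise SiteKeyError(f"site key {key!r}: empty protein symbol")
    m = _SITE_RE.match(site)
    if m is None:
        raise SiteKeyError(f"site key {key!r}: residue token {site!r} must be a letter followed by digits")
    residue, position = m.group(1).upper(), int(m.group(2))
    if position < 1:
        raise SiteKeyError(f"site key {key!r}: position must be >= 1")
    if not ptm_type:
        raise SiteKeyError(f"site key {key!r}: empty modification type")
    return SiteKey(protein.upper(), residue, position, ptm_type.lower())


def format_site_key(protein: str, residue: str, position: int, ptm_type: str) -> str:
    return f"{protein.upper()}:{residue.upper()}{int(position)}:{ptm_type.lower()}"
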