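"""Generic residue position labels and canonical pair keys.

Structurally equivalent residues across class A GPCRs are identified by
GPCRdb-style generic numbers of the form ``"3×50"`` (helix ``3``, index 50,
where ``×50`` marks the most conserved position of the helix).  Residue pairs
are unordered; a single canonical string key ``"a:b"`` with the two positions
in helix/index order makes pair tables comparable across structures.
"""

from __future__ import annotations

import re

# Unicode multiplication sign, as used by GPCRdb.
SEP = "×"

_GENERIC_RE = re.compile(rf"^(\d+){SEP}(\d+)$")


def is_generic(label: str) -> bool:
    """True if *label* is a well-formed generic number like ``"3×50"``."""
    return bool(_GENERIC_RE.match(label))


def position_key(label: str) -> tuple:
    """Sort key: generic numbers by (helix, index), other labels after, lexically."""
    m = _GENERIC_RE.match(label)
    if m:
        return (0, int(m.group(1)), int(m.group(2)), "")
    return (1, 0, 0, label)


def pair_key(a: str, b: str) -> str:
    """Canonical unordered pair key, e.g. ``pair_key("6×48", "3×40") == "3×40:6×48"``."""
    x, y = sorted((a, b), key=position_key)
    return f"{x}:{y}"


def split_pair(pair: str) -> tuple[str, str]:
    a, _, b = pair.partition(":")
    if not b:
        raise ValueError(f"not a pair key: {pair!r}")
    return a, b
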