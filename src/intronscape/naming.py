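"""Intron naming convention: ``<host gene>-<insertion site>``.

An intron family is identified by its host gene and the 1-based position of
the reference-gene nucleotide immediately upstream of the insertion point
(e.g. ``cox1-686`` lies between cox1 positions 686 and 687). Gene names may
themselves contain hyphens; the site is always separated by the *last* hyphen.
"""

from __future__ import annotations

import re

__all__ = ["name_intron", "parse_intron_name", "IntronNameError"]

_NAME_RE = re.compile(r"^(?P<gene>.+)-(?P<site>\d+)$")


class IntronNameError(ValueError):
    pass


def name_intron(host_gene: str, site: int) -> str:
    """Return the family name ``"<gene>-<site>"``."""
    if not host_gene:
        raise IntronNameError("host gene name must be nonempty")
    if not isinstance(site, (int,)) or isinstance(site, bool) or site <= 0:
        raise IntronNameError(f"insertion site must be a positive integer, got {site!r}")
    return f"{host_gene}-{site}"


def parse_intron_name(name: str) -> tuple[str, int]:
    """Split a family name into (gene, site); inverse of :func:`name_intron`."""
    m = _NAME_RE.match(name)
    if not m:
        raise IntronNameError(f"malformed intron name: {name!r} (expected <gene>-<site>)")
    return m.group("gene"), int(m.group("site"))
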