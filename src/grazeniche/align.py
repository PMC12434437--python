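"""Pairwise sequence comparison helpers for amplicon filtering.

Identity here is computed on the Levenshtein-optimal global alignment:
``identity = (alignment columns - edit distance) / alignment columns``,
with alignment columns = matches + mismatches + indels. For the short
trnL P6-loop fragments this pipeline handles, near-threshold pairs differ
by substitutions only, where this equals matches / aligned columns.
"""

from __future__ import annotations

import re

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def edit_distance(a: str, b: str, k: int = -1) -> int:
    """Levenshtein distance between two sequences.

    With ``k >= 0`` the search is bounded and -1 is returned when the
    distance exceeds ``k`` (much faster for neighbour screening).
    """
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]


def global_identity(a: str, b: str) -> float:
    """Fraction of identical columns in the global (NW) alignment of a and b."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    dist = res["editDistance"]
    columns = sum(int(n) for n, _ in _CIGAR_RE.findall(res["cigar"]))
    return (columns - dist) / columns
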