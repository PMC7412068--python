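"""Kimura two-parameter distances and neighbor-joining utilities.

Desk-scale corroboration for "unknown" verdicts: compute K2P distances
between queries and panel references and build a quick NJ tree; a query
sitting far from every reference clade supports a putative new taxon.
Gap and N columns are removed pairwise (pairwise deletion), as are
ambiguity codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log, sqrt
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .errors import AlignmentError, SaturationError
from .seq_io import BASES, SeqRecord

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance in substitutions/site.

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)) with P and Q the transition
    and transversion proportions over pairwise-comparable columns (both
    concrete bases). Raises :class:`SaturationError` when a log argument is
    non-positive (too divergent to estimate).
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal aligned length")
    n = p = q = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in BASES or y not in BASES:
            continue
        n += 1
        if x == y:
            continue
        if (x, y) in _TRANSITIONS:
            p += 1
        else:
            q += 1
    if n == 0:
        raise ValueError("no comparable columns after pairwise deletion")
    P, Q = p / n, q / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"substitution saturation (P={P:.3f}, Q={Q:.3f}): distance undefined"
        )
    return -0.5 * log(w1 * sqrt(w2))


def p_distance(a: str, b: str) -> float:
    """Plain proportion of differing comparable columns (pairwise deletion)."""
    n = d = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in BASES or y not in BASES:
            continue
        n += 1
        d += x != y
    if n == 0:
        raise ValueError("no comparable columns after pairwise deletion")
    return d / n


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with saturated pairs flagged."""

    ids: list[str]
    d: np.ndarray
    saturated: list[tuple[str, str]]

    def to_tsv(self) -> str:
        lines = ["\t".join(["id"] + self.ids)]
        for i, name in enumerate(self.ids):
            cells = [
                "inf" if not np.isfinite(v) else f"{v:.6f}" for v in self.d[i]
            ]
            lines.append("\t".join([name] + cells))
        return "\n".join(lines) + "\n"


def k2p_matrix(records: Sequence[SeqRecord]) -> DistanceMatrix:
    """All-pairs K2P distances; saturated pairs get +inf and a flag."""
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise AlignmentError("duplicate record ids in distance computation")
    n = len(records)
    d = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                v = k2p_distance(records[i].seq, records[j].seq)
            except SaturationError:
                v = np.inf
                saturated.append((ids[i], ids[j]))
            d[i, j] = d[j, i] = v
    return DistanceMatrix(ids=ids, d=d, saturated=saturated)


def nj_tree(m: DistanceMatrix) -> str:
    """Neighbor-joining tree as a newick string.

    Negative branch lengths are clamped to zero (standard NJ practice).
    Requires >= 3 taxa and a fully finite matrix.
    """
    if len(m.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(m.d)):
        raise ValueError(
            "distance matrix contains non-finite entries (saturated pairs): "
            + ", ".join(f"{a}~{b}" for a, b in m.saturated)
        )
    tree = _skbio_nj(_SkbioDM(m.d, ids=m.ids), neg_as_zero=True)
    return str(tree).strip()
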