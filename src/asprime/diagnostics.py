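"""Diagnostic-site discovery.

A diagnostic site is an alignment column at which one species carries a
fixed concrete base that no other species in the complex carries: the 3'
anchor point for an allele-specific primer. Records with a gap or N at a
column are excluded from that column's tally; a column where exclusions
exceed half of either the target or the non-target group is skipped.
Ambiguity codes in non-target records count as carrying the target allele
whenever the code's set contains it, which conservatively disqualifies the
column.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import AlignmentError
from .seq_io import BASES, IUPAC_SETS, SpeciesAlignment


@dataclass(frozen=True)
class DiagnosticSite:
    """One species-diagnostic alignment column."""

    column: int
    target_species: str
    target_allele: str
    other_alleles: frozenset[str]
    flank_ok: bool

    def __post_init__(self):
        if self.target_allele in self.other_alleles:
            raise ValueError("target allele observed in non-target records")
        if self.target_allele not in BASES:
            raise ValueError("target allele must be a concrete base")


def _column_alleles(seqs: list[str], col: int) -> tuple[list[str], int]:
    """Observed symbols at a column, excluding gap/N; returns (kept, excluded)."""
    kept, excluded = [], 0
    for s in seqs:
        c = s[col]
        if c in "-N":
            excluded += 1
        else:
            kept.append(c)
    return kept, excluded


def find_diagnostic_sites(
    aln: SpeciesAlignment, target: str, min_flank: int = 18
) -> list[DiagnosticSite]:
    """Scan every column for a base fixed in ``target`` and absent elsewhere.

    ``min_flank`` sets the number of non-gap columns that must precede the
    site in the target consensus for ``flank_ok`` (room for a primer body
    5' of the anchor). Output is ordered by column and independent of
    record order.
    """
    if target not in aln.species:
        raise AlignmentError(f"unknown species {target!r}")
    if min_flank < 1:
        raise ValueError("min_flank must be >= 1")
    target_seqs = [r.seq for r in aln.records_of(target)]
    other_seqs = [r.seq for r in aln.records if aln.species_of[r.id] != target]
    if not other_seqs:
        raise AlignmentError("alignment must contain at least two species")

    consensus = aln.consensus(target)
    sites: list[DiagnosticSite] = []
    nongap_prefix = 0  # non-gap consensus columns strictly before the current one
    for col in range(aln.length):
        flank_ok = nongap_prefix >= min_flank
        if consensus[col] != "-":
            nongap_prefix += 1
        t_kept, t_excl = _column_alleles(target_seqs, col)
        o_kept, o_excl = _column_alleles(other_seqs, col)
        if t_excl * 2 > len(target_seqs) or o_excl * 2 > len(other_seqs):
            continue
        t_alleles = set(t_kept)
        if len(t_alleles) != 1:
            continue
        allele = next(iter(t_alleles))
        if allele not in BASES:
            continue  # fixed ambiguity code is not a usable anchor
        # Non-target symbols: an ambiguity code containing the allele
        # counts as carrying it.
        carried = any(allele in IUPAC_SETS[c] for c in o_kept)
        if carried or not o_kept:
            continue
        others = frozenset(b for c in o_kept for b in IUPAC_SETS[c])
        sites.append(
            DiagnosticSite(
                column=col,
                target_species=target,
                target_allele=allele,
                other_alleles=others,
                flank_ok=flank_ok,
            )
        )
    return sites


def specificity_matrix(sites: list[DiagnosticSite], aln: SpeciesAlignment) -> pd.DataFrame:
    """Species x site table of target-allele carriage.

    Cell = fraction of that species' records carrying the site's target
    allele at the site's column, with gap/N records removed from the
    denominator. For a valid diagnostic site the target row is 1.0 and
    every other row 0.0.
    """
    cols = [f"{s.target_species}:{s.column}" for s in sites]
    data: dict[str, list[float]] = {}
    for species in aln.species:
        seqs = [r.seq for r in aln.records_of(species)]
        row = []
        for site in sites:
            kept, _ = _column_alleles(seqs, site.column)
            if not kept:
                row.append(float("nan"))
                continue
            n_carry = sum(1 for c in kept if site.target_allele in IUPAC_SETS[c])
            row.append(n_carry / len(kept))
        data[species] = row
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)
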