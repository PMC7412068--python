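"""Synthetic species-complex generator with a known truth ledger.

Emulates the design substrate of a COI-barcode assay: an AT-rich 684-bp
alignment of several sibling species, each carrying a few planted
species-private ("diagnostic") columns, with conserved flanks housing the
universal Folmer primer landing sites (LCO-1490 forward, HCO-2198 reverse
complement). Substitutions follow a Jukes-Cantor-style model with a 2:1
transition bias (kappa = 2) so K2P estimates are nontrivial.

Per-record intraspecies noise avoids the flanks, every planted diagnostic
column, and the 26-column upstream "primer shadow" of the record's own
species' diagnostic columns: a mutation inside a primer footprint would
stochastically delete a true band, which real reference panels are curated
to avoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seq_io import SeqRecord, SpeciesAlignment

LCO_1490 = "GGTCAACAAATCATAAAGATATTGG"
HCO_2198 = "TAAACTTCAGGGTGACCAAAAAATCA"

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
#: widest primer core the designer will lay down upstream of an anchor
PRIMER_SHADOW = 26


@dataclass(frozen=True)
class ComplexSpec:
    """Parameters of one synthetic species complex."""

    n_species: int = 5
    seq_len: int = 684
    n_records_per_species: int = 3
    n_diagnostic_per_species: int = 3
    interspecies_divergence: float = 0.06
    intraspecies_diversity: float = 0.005
    base_composition: tuple[float, float, float, float] = (0.33, 0.17, 0.17, 0.33)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        for d in (self.interspecies_divergence, self.intraspecies_diversity):
            if not 0.0 < d < 0.75:
                raise ValueError("divergences must lie in (0, 0.75)")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")

    @property
    def forward_flank(self) -> tuple[int, int]:
        return (0, len(LCO_1490))

    @property
    def reverse_flank(self) -> tuple[int, int]:
        return (self.seq_len - len(HCO_2198), self.seq_len)

    def species_names(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]


@dataclass
class TruthLedger:
    """Generator bookkeeping: what was planted where."""

    planted: dict[str, dict[int, str]]  # species -> column -> private allele
    species_of: dict[str, str]
    mutations: dict[str, list[int]]  # record id -> mutated columns
    flanks: tuple[tuple[int, int], tuple[int, int]]

    def all_diagnostic_columns(self) -> set[int]:
        return {c for cols in self.planted.values() for c in cols}


def _substitute(base: str, rng: np.random.Generator) -> str:
    """Kappa=2 substitution: transition twice as likely as each transversion."""
    ts = _TRANSITION[base]
    tv = [b for b in "ACGT" if b != base and b != ts]
    return str(rng.choice([ts] + tv, p=[0.5, 0.25, 0.25]))


def _mutate(
    seq: list[str],
    allowed: np.ndarray,
    rate: float,
    rng: np.random.Generator,
) -> list[int]:
    """In-place kappa-weighted point mutations at ``rate`` over allowed columns."""
    hits = allowed[rng.random(allowed.size) < rate]
    for col in hits:
        seq[col] = _substitute(seq[col], rng)
    return [int(c) for c in hits]


def generate_complex(spec: ComplexSpec) -> tuple[SpeciesAlignment, TruthLedger]:
    """Draw a species complex with planted diagnostic sites.

    Deterministic given ``spec.seed``: the ancestor comes from
    ``base_composition``, species diverge at ``interspecies_divergence``
    outside flanks and planted columns, each species gets
    ``n_diagnostic_per_species`` private alleles, and records add
    intraspecies noise that spares every planted column and the shadow of
    the record's own anchors.
    """
    rng = np.random.default_rng(spec.seed)
    f0, f1 = spec.forward_flank, spec.reverse_flank
    flank_cols = set(range(*f0)) | set(range(*f1))
    n_diag = spec.n_species * spec.n_diagnostic_per_species
    # anchors need a full primer shadow upstream and the reverse site downstream
    lo, hi = f0[1] + PRIMER_SHADOW, f1[0] - 1
    if hi - lo < n_diag:
        raise ValueError(
            f"seq_len={spec.seq_len} too short for flanks plus {n_diag} diagnostic columns"
        )

    ancestor = list(rng.choice(_BASES, size=spec.seq_len, p=spec.base_composition))
    ancestor[f0[0] : f0[1]] = list(LCO_1490)
    rc_hco = HCO_2198.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    ancestor[f1[0] : f1[1]] = list(rc_hco)

    diag_cols = rng.choice(np.arange(lo, hi), size=n_diag, replace=False)
    diag_cols.sort()
    names = spec.species_names()
    planted: dict[str, dict[int, str]] = {name: {} for name in names}
    owner_of = {}
    shuffled = rng.permutation(diag_cols)
    for i, col in enumerate(shuffled):
        owner_of[int(col)] = names[i % spec.n_species]
    all_diag = set(owner_of)

    free_cols = np.array(
        sorted(set(range(spec.seq_len)) - flank_cols - all_diag), dtype=int
    )
    records: list[SeqRecord] = []
    species_of: dict[str, str] = {}
    mutations: dict[str, list[int]] = {}
    for name in names:
        ref = list(ancestor)
        _mutate(ref, free_cols, spec.interspecies_divergence, rng)
        for col, owner in owner_of.items():
            if owner == name:
                allele = _substitute(ancestor[col], rng)
                ref[col] = allele
                planted[name][col] = allele
            else:
                ref[col] = ancestor[col]
        own_shadow = {
            c
            for col in planted[name]
            for c in range(max(0, col - PRIMER_SHADOW + 1), col + 1)
        }
        rec_allowed = np.array(
            sorted(set(free_cols.tolist()) - own_shadow), dtype=int
        )
        for k in range(spec.n_records_per_species):
            rec_seq = list(ref)
            muts = _mutate(rec_seq, rec_allowed, spec.intraspecies_diversity, rng)
            rid = f"{name}_r{k + 1}"
            records.append(SeqRecord(id=rid, seq="".join(rec_seq)))
            species_of[rid] = name
            mutations[rid] = sorted(muts)

    aln = SpeciesAlignment(records=records, species_of=species_of)
    ledger = TruthLedger(
        planted=planted, species_of=species_of, mutations=mutations, flanks=(f0, f1)
    )
    return aln, ledger


def generate_field_sample(
    aln: SpeciesAlignment,
    ledger: TruthLedger,
    n_per_species: int | dict[str, int] = 40,
    n_outgroup: int = 12,
    outgroup_divergence: float = 0.10,
    seed: int = 0,
) -> tuple[list[SeqRecord], dict[str, str]]:
    """Draw field specimens: in-complex queries plus divergent outgroups.

    In-complex queries are species references with intraspecies noise that
    spares all diagnostic columns and the query species' primer shadows
    (computed by a fresh diagnostic scan of the alignment, so any anchor a
    designer could have chosen stays intact). Outgroups diverge at
    ``outgroup_divergence`` and are forced to mismatch every diagnostic
    column's target allele — the signature of a taxon outside the panel.

    Returns the queries and a truth map (query id -> species name or
    ``"outgroup"``).
    """
    from .diagnostics import find_diagnostic_sites

    rng = np.random.default_rng(seed)
    f0, f1 = ledger.flanks
    flank_cols = set(range(*f0)) | set(range(*f1))
    scan = {sp: find_diagnostic_sites(aln, sp, min_flank=1) for sp in aln.species}
    all_diag = {s.column for sites in scan.values() for s in sites}

    queries: list[SeqRecord] = []
    truth: dict[str, str] = {}
    counts = (
        {sp: n_per_species for sp in aln.species}
        if isinstance(n_per_species, int)
        else dict(n_per_species)
    )
    for sp in aln.species:
        ref = aln.consensus(sp)
        own_shadow = {
            c
            for s in scan[sp]
            for c in range(max(0, s.column - PRIMER_SHADOW + 1), s.column + 1)
        }
        allowed = np.array(
            sorted(set(range(aln.length)) - flank_cols - all_diag - own_shadow),
            dtype=int,
        )
        for k in range(counts.get(sp, 0)):
            seq = list(ref)
            _mutate(seq, allowed, 0.005, rng)
            qid = f"q_{sp}_{k + 1}"
            queries.append(SeqRecord(id=qid, seq="".join(seq).replace("-", "")))
            truth[qid] = sp

    base_ref = aln.consensus(aln.species[0])
    og_allowed = np.array(
        sorted(set(range(aln.length)) - flank_cols - all_diag), dtype=int
    )
    target_alleles: dict[int, set[str]] = {}
    for sp, sites in scan.items():
        for s in sites:
            target_alleles.setdefault(s.column, set()).add(s.target_allele)
    for k in range(n_outgroup):
        seq = list(base_ref)
        _mutate(seq, og_allowed, outgroup_divergence, rng)
        for col, alleles in target_alleles.items():
            pool = sorted(set("ACGT") - alleles) or sorted(
                "ACGT", key=lambda b: sum(b == a for a in alleles)
            )
            seq[col] = str(rng.choice(np.array(pool)))
        qid = f"q_outgroup_{k + 1}"
        queries.append(SeqRecord(id=qid, seq="".join(seq).replace("-", "")))
        truth[qid] = "outgroup"
    return queries, truth
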