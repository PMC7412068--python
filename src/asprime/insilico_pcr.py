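"""In-silico multiplex PCR under an explicit, configurable binding model.

A primer binds where its core matches a template window within mismatch
thresholds; stringency (total mismatches allowed, and a zero-tolerance
window at the 3' end) is the computational analog of annealing temperature.
Tails are non-templated and excluded from matching but contribute their
length to the product size.

Ambiguity semantics: a template IUPAC code matches a primer base iff the
base is in the code's set. N matches everything, but each N-matched
position counts half toward the total mismatch budget (rounded up over the
window); inside the 3' window an N is treated as a match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .designer import MultiplexPanel, Primer
from .seq_io import IUPAC_SETS, SeqRecord, SpeciesAlignment, revcomp

_CODES = "ACGTRYSWKMBDHVN"
_CODE_INDEX = {c: i for i, c in enumerate(_CODES)}
_N_IDX = _CODE_INDEX["N"]
# match table: row = primer base (ACGT), column = template code
_MATCH = np.zeros((4, len(_CODES)), dtype=bool)
for bi, b in enumerate("ACGT"):
    for ci, c in enumerate(_CODES):
        _MATCH[bi, ci] = b in IUPAC_SETS[c]


@dataclass(frozen=True)
class BindingModel:
    """Mismatch thresholds a primer/template duplex must pass to prime."""

    max_total_mismatches: int = 3
    three_prime_window: int = 2
    window_mismatches_allowed: int = 0
    count_ambiguity_as_match: bool = True
    max_product_len: int = 2000

    def __post_init__(self):
        if min(
            self.max_total_mismatches,
            self.three_prime_window,
            self.window_mismatches_allowed,
        ) < 0:
            raise ValueError("binding-model counts must be >= 0")


@dataclass(frozen=True)
class BindingSite:
    """One primer-binding window on a template (plus-strand coordinates)."""

    primer_name: str
    template_id: str
    strand: str  # '+' or '-'
    start: int
    end: int
    mismatch_total: int
    mismatch_positions: tuple[int, ...]  # 1-based offsets from the primer 3' end


@dataclass(frozen=True)
class Amplicon:
    """A predicted product delimited by a convergent site pair.

    ``genomic_span`` runs from the forward primer's 5' position to the
    reverse primer's 5' position, inclusive; ``product_len`` adds both
    non-templated tails.
    """

    template_id: str
    forward_site: BindingSite
    reverse_site: BindingSite
    genomic_span: int
    product_len: int
    nonspecific: bool = False


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for c, i in _CODE_INDEX.items():
        out[arr == ord(c)] = i
    if (out < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(out < 0)[0]})
        raise ValueError(f"template contains non-IUPAC character(s): {bad}")
    return out


def _scan(
    tcodes: np.ndarray,
    core: str,
    model: BindingModel,
    three_prime_left: bool,
) -> Iterable[tuple[int, int, tuple[int, ...]]]:
    """Yield (start, mismatch_total, mismatch_offsets) for passing windows.

    ``three_prime_left`` is True when the primer's 3' end maps to the
    window's left (plus-strand) edge, i.e. for minus-strand scanning of a
    reverse-complemented core.
    """
    L = len(core)
    T = tcodes.size
    if T < L:
        return
    core_idx = np.array([_CODE_INDEX[b] for b in core], dtype=np.int8)
    windows = np.lib.stride_tricks.sliding_window_view(tcodes, L)
    match = _MATCH[core_idx[None, :], windows]  # (T-L+1, L)
    is_n = windows == _N_IDX
    if not model.count_ambiguity_as_match:
        # strict mode: any non-concrete template symbol is a mismatch
        match = match & (windows < 4)
        is_n = np.zeros_like(is_n)
    full_mm = (~match) & (~is_n)
    n_half = is_n.sum(axis=1)
    total = full_mm.sum(axis=1) + (n_half + 1) // 2
    w = min(model.three_prime_window, L)
    win_cols = full_mm[:, :w] if three_prime_left else full_mm[:, L - w :]
    ok = (total <= model.max_total_mismatches) & (
        win_cols.sum(axis=1) <= model.window_mismatches_allowed
    )
    for i in np.nonzero(ok)[0]:
        cols = np.nonzero(full_mm[i])[0]
        offsets = tuple(
            sorted(int(c) + 1 if three_prime_left else L - int(c) for c in cols)
        )
        yield int(i), int(total[i]), offsets


def find_binding_sites(
    template: SeqRecord, primer: Primer, model: BindingModel | None = None
) -> list[BindingSite]:
    """All windows on both strands where the primer core binds the template.

    The tail is never compared. Plus-strand sites match the core directly;
    minus-strand sites match the core's reverse complement, with the primer
    3' end at the window's left edge.
    """
    model = model or BindingModel()
    tcodes = _encode(template.seq)
    L = len(primer.core)
    sites: list[BindingSite] = []
    for start, total, offsets in _scan(tcodes, primer.core, model, False):
        sites.append(
            BindingSite(primer.name, template.id, "+", start, start + L, total, offsets)
        )
    for start, total, offsets in _scan(tcodes, revcomp(primer.core), model, True):
        sites.append(
            BindingSite(primer.name, template.id, "-", start, start + L, total, offsets)
        )
    sites.sort(key=lambda s: (s.start, s.strand, s.primer_name))
    return sites


def simulate_pcr(
    template: SeqRecord,
    primers: Sequence[Primer],
    model: BindingModel | None = None,
) -> list[Amplicon]:
    """Predict all products of a primer mix on one template.

    Every convergent (plus-site, minus-site) pair within the product-length
    cap yields an amplicon. Pairs that are not a forward-orientation primer
    extending toward a reverse-orientation primer (e.g. a primer against
    itself on opposite strands) are reported with ``nonspecific=True``.
    """
    if not primers:
        raise ValueError("primer list is empty")
    model = model or BindingModel()
    by_primer = {p.name: p for p in primers}
    plus: list[BindingSite] = []
    minus: list[BindingSite] = []
    for p in primers:
        for s in find_binding_sites(template, p, model):
            (plus if s.strand == "+" else minus).append(s)
    out: list[Amplicon] = []
    for f in plus:
        for r in minus:
            if f.start >= r.end:
                continue
            span = r.end - f.start
            fp, rp = by_primer[f.primer_name], by_primer[r.primer_name]
            product = span + len(fp.tail) + len(rp.tail)
            if product > model.max_product_len:
                continue
            nonspecific = (
                fp.orientation != "forward"
                or rp.orientation != "reverse"
                or fp.name == rp.name
            )
            out.append(
                Amplicon(
                    template_id=template.id,
                    forward_site=f,
                    reverse_site=r,
                    genomic_span=span,
                    product_len=product,
                    nonspecific=nonspecific,
                )
            )
    out.sort(
        key=lambda a: (
            a.product_len,
            a.forward_site.start,
            a.forward_site.primer_name,
            a.reverse_site.primer_name,
        )
    )
    return out


def diagnostic_bands(amplicons: Iterable[Amplicon]) -> list[Amplicon]:
    """Amplicons that count as assay bands (specific forward x reverse pairs)."""
    return [a for a in amplicons if not a.nonspecific]


@dataclass
class PanelReport:
    """Outcome of testing a panel against labeled reference sequences."""

    passed: bool
    table: pd.DataFrame
    failures: list[str] = field(default_factory=list)


def verify_panel(
    panel: MultiplexPanel,
    refs: SpeciesAlignment,
    model: BindingModel | None = None,
) -> PanelReport:
    """Run the multiplex against every reference and check the assay contract.

    PASS iff every reference yields exactly one diagnostic band, from its
    own species' primer, within ``size_tolerance`` of the expected size, and
    no primer amplifies a non-target species.
    """
    model = model or BindingModel()
    primers = list(panel.forward_primers) + [panel.reverse_primer]
    rows = []
    failures: list[str] = []
    primer_target = {p.name: p.target_species for p in panel.forward_primers}
    for rec in refs.records:
        species = refs.species_of[rec.id]
        bands = diagnostic_bands(simulate_pcr(rec.degapped(), primers, model))
        for band in bands:
            target = primer_target[band.forward_site.primer_name]
            expected = panel.expected_sizes.get(target)
            within = (
                expected is not None
                and abs(band.product_len - expected) <= panel.size_tolerance
            )
            rows.append(
                {
                    "record": rec.id,
                    "species": species,
                    "primer": band.forward_site.primer_name,
                    "primer_target": target,
                    "product_len": band.product_len,
                    "expected": expected,
                    "within_tolerance": within,
                }
            )
            if target != species:
                failures.append(
                    f"{band.forward_site.primer_name} amplifies {species} "
                    f"record {rec.id} ({band.product_len} bp): cross-species band"
                )
            elif not within:
                failures.append(
                    f"{rec.id} ({species}): band {band.product_len} bp outside "
                    f"{expected}±{panel.size_tolerance}"
                )
        if len(bands) != 1:
            failures.append(
                f"{rec.id} ({species}): {len(bands)} diagnostic bands, expected 1"
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "record",
            "species",
            "primer",
            "primer_target",
            "product_len",
            "expected",
            "within_tolerance",
        ],
    )
    return PanelReport(passed=not failures, table=table, failures=failures)


def virtual_gel(
    lanes: dict[str, list[int]],
    ladder: Sequence[int] = tuple(range(100, 1100, 100)),
    height: int = 24,
    max_bp: int = 1000,
) -> str:
    """Render band sizes as an ASCII agarose gel (log-scaled migration)."""
    names = list(lanes)
    width = max(8, max((len(n) for n in names), default=8))
    rows = []
    header = "bp".rjust(6) + " |" + "|".join(n.center(width) for n in ["M"] + names) + "|"
    rows.append(header)
    log_top, log_bot = np.log10(max_bp), np.log10(50)
    def row_of(bp: int) -> int:
        frac = (log_top - np.log10(max(bp, 50))) / (log_top - log_bot)
        return int(round(frac * (height - 1)))
    grid = [[" " * width for _ in range(len(names) + 1)] for _ in range(height)]
    labels = [""] * height
    for bp in ladder:
        r = row_of(bp)
        if 0 <= r < height:
            grid[r][0] = "=" * width
            labels[r] = str(bp)
    for j, name in enumerate(names, start=1):
        for bp in lanes[name]:
            r = row_of(bp)
            if 0 <= r < height:
                grid[r][j] = "#" * width
                labels[r] = str(bp)  # band size labels beat ladder labels
    for r in range(height):
        rows.append(labels[r].rjust(6) + " |" + "|".join(grid[r]) + "|")
    return "\n".join(rows)
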