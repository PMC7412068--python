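"""Species calling from simulated band patterns.

A query is called as a species when its simulated multiplex reaction yields
band(s) matching exactly one expected product size; zero bands mean
``unknown`` (the signature of a taxon outside the panel), anything else is
``ambiguous``. Multiple bands that all map to the same species collapse to
one call with a warning, mirroring tandem binding sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .designer import MultiplexPanel
from .insilico_pcr import BindingModel, diagnostic_bands, simulate_pcr
from .seq_io import SeqRecord

UNKNOWN = "unknown"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class SpeciesCall:
    """Identification verdict for one query."""

    query_id: str
    verdict: str  # species name, 'unknown', or 'ambiguous'
    bands: tuple[tuple[str, int], ...]  # (forward primer name, product bp)
    matched_expected: Optional[tuple[str, int, int]] = None  # (species, expected, delta)


def _match_band(
    product_len: int, panel: MultiplexPanel
) -> list[tuple[str, int, int]]:
    """Expected sizes within tolerance, nearest first; ties share rank."""
    hits = [
        (sp, exp, abs(product_len - exp))
        for sp, exp in panel.expected_sizes.items()
        if abs(product_len - exp) <= panel.size_tolerance
    ]
    hits.sort(key=lambda h: h[2])
    if len(hits) > 1 and hits[0][2] == hits[1][2]:
        return hits[:2]  # tie: ambiguous by contract
    return hits[:1]


def call_species(
    query: SeqRecord,
    panel: MultiplexPanel,
    model: BindingModel | None = None,
) -> SpeciesCall:
    """Simulate the multiplex on one query and call the species."""
    model = model or BindingModel()
    primers = list(panel.forward_primers) + [panel.reverse_primer]
    bands = diagnostic_bands(simulate_pcr(query.degapped(), primers, model))
    band_tuples = tuple(
        (a.forward_site.primer_name, a.product_len) for a in bands
    )
    if not bands:
        return SpeciesCall(query.id, UNKNOWN, band_tuples)

    matched_species: set[str] = set()
    best: Optional[tuple[str, int, int]] = None
    for _, product in band_tuples:
        hits = _match_band(product, panel)
        if len(hits) != 1:
            return SpeciesCall(query.id, AMBIGUOUS, band_tuples)
        sp, exp, delta = hits[0]
        matched_species.add(sp)
        if best is None or delta < best[2]:
            best = (sp, exp, delta)
    if len(matched_species) == 1:
        if len(band_tuples) > 1:
            warnings.warn(
                f"{query.id}: {len(band_tuples)} bands collapse to one species call",
                stacklevel=2,
            )
        return SpeciesCall(query.id, best[0], band_tuples, matched_expected=best)
    return SpeciesCall(query.id, AMBIGUOUS, band_tuples)


def batch_report(
    queries: Sequence[SeqRecord],
    panel: MultiplexPanel,
    model: BindingModel | None = None,
    truth: Mapping[str, str] | None = None,
    locations: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Concordance table of calls, one row per location plus a totals row.

    With ``truth`` (query id -> species from sequencing), cells read
    "called/total": queries of that species at that location that the assay
    called correctly, over all such queries; the Unknown column counts
    queries whose truth is outside the panel. Without truth, cells count
    assay calls alone. The totals row equals the column sums. Output is
    independent of query order.
    """
    species_cols = list(panel.expected_sizes)
    columns = species_cols + [UNKNOWN.capitalize(), "Total"]
    calls = {q.id: call_species(q, panel, model) for q in queries}
    loc_of = (lambda qid: locations.get(qid, "all")) if locations else (lambda qid: "all")
    locs = sorted({loc_of(q.id) for q in queries})

    counts: dict[str, dict[str, list[int]]] = {
        loc: {c: [0, 0] for c in columns} for loc in locs
    }
    for q in sorted(queries, key=lambda r: r.id):
        call = calls[q.id]
        row = counts[loc_of(q.id)]
        if truth is not None:
            true_sp = truth.get(q.id)
            col = true_sp if true_sp in species_cols else UNKNOWN.capitalize()
            row[col][1] += 1
            row["Total"][1] += 1
            correct = (
                call.verdict == true_sp
                if col != UNKNOWN.capitalize()
                else call.verdict == UNKNOWN
            )
            if correct and col != UNKNOWN.capitalize():
                row[col][0] += 1
                row["Total"][0] += 1
        else:
            col = call.verdict if call.verdict in species_cols else UNKNOWN.capitalize()
            row[col][0] += 1
            row[col][1] += 1
            row["Total"][0] += 1
            row["Total"][1] += 1

    rows = {}
    total_row = {c: [0, 0] for c in columns}
    for loc in locs:
        rows[loc] = {
            c: f"{counts[loc][c][0]}/{counts[loc][c][1]}" for c in columns
        }
        for c in columns:
            total_row[c][0] += counts[loc][c][0]
            total_row[c][1] += counts[loc][c][1]
    rows["Total"] = {c: f"{total_row[c][0]}/{total_row[c][1]}" for c in columns}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    df.index.name = "location"
    return df


def calls_table(
    queries: Sequence[SeqRecord],
    panel: MultiplexPanel,
    model: BindingModel | None = None,
) -> pd.DataFrame:
    """Flat per-query verdict table (for the CLI's TSV output)."""
    rows = []
    for q in queries:
        call = call_species(q, panel, model)
        rows.append(
            {
                "query_id": call.query_id,
                "verdict": call.verdict,
                "bands": ";".join(f"{p}:{bp}" for p, bp in call.bands) or ".",
                "expected_bp": call.matched_expected[1] if call.matched_expected else ".",
                "delta_bp": call.matched_expected[2] if call.matched_expected else ".",
            }
        )
    return pd.DataFrame(
        rows, columns=["query_id", "verdict", "bands", "expected_bp", "delta_bp"]
    )
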