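"""Packaged panels and synthetic stand-in reference material.

The packaged ``barbirostris_v1`` panel is the validated five-species
multiplex for the Anopheles Barbirostris Complex. The GenBank reference and
validation sequences behind the original assay must be supplied by the user
as FASTA; for offline work and testing, this module constructs SYNTHETIC
stand-in templates: deterministic pseudo-COI sequences that embed each
primer's binding site at the offset giving exactly the published product
size, plus a validation sample mirroring the published per-species specimen
counts. They are stand-ins, not the GenBank records.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .designer import MultiplexPanel, panel_from_json
from .seq_io import SeqRecord, revcomp
from .synthetic import _mutate

PACKAGED_PANELS = ("barbirostris_v1",)

#: Per-species validation specimen counts of the original field study
#: (five panel species plus divergent "unknown" specimens).
VALIDATION_COUNTS = {
    "An. barbirostris s.s.": 2,
    "An. dissidens": 49,
    "An. saeungae": 7,
    "An. wejchoochotei": 30,
    "An. barbirostris A3": 11,
}
VALIDATION_UNKNOWNS = 12

_TEMPLATE_LEN = 684
# Fixed: packaged templates are part of the package contract. The value is
# chosen so every primer's 3'-anchor column is diagnostic against the shared
# backbone (a well-formedness requirement of the stand-in, checked in tests).
_BACKBONE_SEED = 0


def load_packaged_panel(name: str = "barbirostris_v1") -> MultiplexPanel:
    """Load a panel shipped with the package by name."""
    if name not in PACKAGED_PANELS:
        raise KeyError(f"no packaged panel {name!r}; available: {PACKAGED_PANELS}")
    text = resources.files("asprime").joinpath(f"data/{name}.json").read_text()
    return panel_from_json(text)


def _backbone(rng: np.random.Generator) -> list[str]:
    bases = np.array(list("ACGT"))
    return list(rng.choice(bases, size=_TEMPLATE_LEN, p=[0.33, 0.17, 0.17, 0.33]))


def synthetic_reference_templates(
    panel: MultiplexPanel | None = None,
) -> list[SeqRecord]:
    """SYNTHETIC one-per-species reference templates for the packaged panel.

    All templates share one deterministic AT-rich backbone carrying the
    universal reverse site at the 3' end; each species' template additionally
    embeds its own forward primer core at the offset that makes the product
    exactly the panel's expected size. Stand-ins for the GenBank design
    references, which users supply as FASTA when available.
    """
    panel = panel or load_packaged_panel()
    rng = np.random.default_rng(_BACKBONE_SEED)
    backbone = _backbone(rng)
    rc_rev = revcomp(panel.reverse_primer.core)
    backbone[_TEMPLATE_LEN - len(rc_rev) :] = list(rc_rev)
    records = []
    for primer in panel.forward_primers:
        untailed = panel.expected_sizes[primer.target_species] - len(primer.tail)
        start = _TEMPLATE_LEN - untailed
        if start < 0:
            raise ValueError(f"{primer.name}: product longer than template")
        seq = list(backbone)
        seq[start : start + len(primer.core)] = list(primer.core)
        rid = "SYN_" + primer.target_species.replace(" ", "_").replace(".", "")
        records.append(SeqRecord(id=rid, seq="".join(seq)))
    return records


def synthetic_validation_sample(
    seed: int = 0, panel: MultiplexPanel | None = None
) -> tuple[list[SeqRecord], dict[str, str]]:
    """SYNTHETIC field-validation sample mirroring the published study layout.

    Per-species specimen counts follow :data:`VALIDATION_COUNTS` plus
    :data:`VALIDATION_UNKNOWNS` divergent outgroup specimens (panel species
    absent, universal site intact — amplifiable by barcode primers but
    carrying no allele-specific site). Queries add light intraspecies noise
    outside primer footprints. Returns (queries, truth map); outgroups are
    labeled ``"outgroup"``.
    """
    panel = panel or load_packaged_panel()
    rng = np.random.default_rng(seed)
    refs = {r.id: r for r in synthetic_reference_templates(panel)}
    rc_len = len(panel.reverse_primer.core)
    queries: list[SeqRecord] = []
    truth: dict[str, str] = {}
    i = 0
    for primer in panel.forward_primers:
        sp = primer.target_species
        rid = "SYN_" + sp.replace(" ", "_").replace(".", "")
        ref = refs[rid].seq
        untailed = panel.expected_sizes[sp] - len(primer.tail)
        start = _TEMPLATE_LEN - untailed
        protected = set(range(start, start + len(primer.core))) | set(
            range(_TEMPLATE_LEN - rc_len, _TEMPLATE_LEN)
        )
        allowed = np.array(
            sorted(set(range(_TEMPLATE_LEN)) - protected), dtype=int
        )
        for _ in range(VALIDATION_COUNTS.get(sp, 0)):
            i += 1
            seq = list(ref)
            _mutate(seq, allowed, 0.005, rng)
            qid = f"VAL{i:03d}"
            queries.append(SeqRecord(id=qid, seq="".join(seq)))
            truth[qid] = sp
    og_backbone = _backbone(np.random.default_rng(_BACKBONE_SEED))
    rc_rev = revcomp(panel.reverse_primer.core)
    og_backbone[_TEMPLATE_LEN - len(rc_rev) :] = list(rc_rev)
    og_allowed = np.arange(0, _TEMPLATE_LEN - rc_len)
    for _ in range(VALIDATION_UNKNOWNS):
        i += 1
        seq = list(og_backbone)
        _mutate(seq, og_allowed, 0.05, rng)
        qid = f"VAL{i:03d}"
        queries.append(SeqRecord(id=qid, seq="".join(seq)))
        truth[qid] = "outgroup"
    return queries, truth
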