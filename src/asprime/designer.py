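"""Allele-specific primer and multiplex-panel design.

The designer anchors a forward primer's 3'-terminal base on a diagnostic
site, so extension succeeds only on the target species (ARMS logic). Two
engineering tricks from the assay are implemented:

* an engineered mismatch at the third base from the 3' end, destabilizing
  near-match duplexes to suppress background amplification;
* non-templated 5' GC tails, assigned in whole units of the 26-nt tail
  sequence to spread product sizes into a gel-resolvable ladder.

Melting temperatures use nearest-neighbor thermodynamics with the unified
Allawi & SantaLucia (1997) parameter set at 50 mM monovalent salt and
0.25 uM oligo.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

from .diagnostics import DiagnosticSite, find_diagnostic_sites
from .errors import DesignError, LadderError, PanelSchemaError
from .seq_io import BASES, SeqRecord, SpeciesAlignment

#: 26-nt GC tail unit validated in the assay (5'->3').
GC_TAIL_UNIT = "GCGGGCAGGGCGGCGGGGGCGGGGCC"
#: Maximum number of tail units per primer.
MAX_TAIL_UNITS = 3

# Unified nearest-neighbor parameters (dH kcal/mol, dS cal/mol/K),
# Allawi & SantaLucia 1997.
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)
_R = 1.987  # cal/mol/K


@dataclass(frozen=True)
class EngineeredMismatch:
    """Record of a deliberate base substitution near the 3' end."""

    offset_from_3prime: int
    original_base: str
    substituted_base: str

    def __post_init__(self):
        if self.offset_from_3prime != 3:
            raise ValueError("engineered mismatch offset must be 3 in v1")


@dataclass(frozen=True)
class Primer:
    """An oriented oligo: optional non-templated 5' tail + template-matching core.

    ``source_columns`` (when the primer was designed from an alignment) maps
    each core base to its alignment column, 5'->3'.
    """

    name: str
    core: str
    tail: str = ""
    orientation: str = "forward"
    target_species: str = "universal"
    engineered_mismatch: Optional[EngineeredMismatch] = None
    source_columns: Optional[tuple[int, ...]] = None

    def __post_init__(self):
        if len(self.core) < 15:
            raise DesignError(f"primer {self.name!r}: core shorter than 15 nt")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")
        bad = set(self.core + self.tail) - set(BASES)
        if bad:
            raise DesignError(f"primer {self.name!r}: non-ACGT characters {sorted(bad)}")
        if self.source_columns is not None and len(self.source_columns) != len(self.core):
            raise ValueError("source_columns must map every core base")

    @property
    def sequence(self) -> str:
        """Full synthesized oligo, 5'->3' (tail + core)."""
        return self.tail + self.core

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MultiplexPanel:
    """Forward primer per species + one universal reverse + expected size ladder."""

    name: str
    forward_primers: list[Primer]
    reverse_primer: Primer
    expected_sizes: dict[str, int]
    size_tolerance: int = 10
    min_gap: int = 60
    notes: str = ""

    def __post_init__(self):
        names = [p.name for p in self.forward_primers] + [self.reverse_primer.name]
        if len(set(names)) != len(names):
            raise PanelSchemaError("primer names not unique", "$.forward_primers")
        sizes = sorted(self.expected_sizes.values())
        for a, b in zip(sizes, sizes[1:]):
            if b - a < self.min_gap:
                raise LadderError(
                    f"expected sizes {a} and {b} closer than min_gap={self.min_gap}"
                )

    def primer_for(self, species: str) -> Primer:
        for p in self.forward_primers:
            if p.target_species == species:
                return p
        raise KeyError(species)

    @property
    def species(self) -> list[str]:
        return [p.target_species for p in self.forward_primers]


def compute_tm(seq: str) -> float:
    """Nearest-neighbor melting temperature (deg C) of an unambiguous oligo.

    50 mM monovalent salt, 0.25 uM oligo; salt enters via the entropic
    correction 0.368*(N-1)*ln[Na+]. Tails are excluded by callers: Tm is a
    property of the template-matching core.
    """
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(f"ambiguous base(s) {sorted(bad)} not allowed in Tm calculation")
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        ih, is_ = _INIT_AT if end in "AT" else _INIT_GC
        dh += ih
        ds += is_
    for i in range(len(seq) - 1):
        nh, ns = _NN[seq[i : i + 2]]
        dh += nh
        ds += ns
    ds += 0.368 * (len(seq) - 1) * math.log(50e-3)
    k = 250e-9  # 0.25 uM primer, template in vast deficit
    return 1000.0 * dh / (ds + _R * math.log(k)) - 273.15


def _core_from_consensus(
    consensus: str, site: DiagnosticSite, length: int
) -> tuple[str, tuple[int, ...]] | None:
    """Walk 5' from the anchor collecting ``length`` non-gap consensus bases."""
    bases: list[str] = []
    cols: list[int] = []
    col = site.column
    while col >= 0 and len(bases) < length:
        c = consensus[col]
        if c != "-":
            if c not in BASES:
                return None  # ambiguous consensus base inside the core
            bases.append(c)
            cols.append(col)
        col -= 1
    if len(bases) < length:
        return None
    bases.reverse()
    cols.reverse()
    return "".join(bases), tuple(cols)


def design_primer(
    aln: SpeciesAlignment,
    site: DiagnosticSite,
    len_range: tuple[int, int] = (18, 26),
    tm_range: tuple[float, float] = (52.0, 60.0),
    name: str | None = None,
) -> Primer:
    """Design a forward primer whose 3'-terminal base sits on the site.

    The core is drawn from the target species' consensus with gaps removed.
    Among lengths in ``len_range`` the shortest whose Tm falls inside
    ``tm_range`` wins; if none does, the closest-Tm length is used and a
    warning is emitted.
    """
    if not site.flank_ok:
        raise DesignError(
            f"site at column {site.column} lacks upstream flank for a primer"
        )
    consensus = aln.consensus(site.target_species)
    if consensus[site.column] != site.target_allele:
        raise DesignError("site does not belong to this alignment/species")
    lo, hi = len_range
    candidates: list[tuple[float, int, str, tuple[int, ...]]] = []
    for length in range(lo, hi + 1):
        got = _core_from_consensus(consensus, site, length)
        if got is None:
            continue
        core, cols = got
        tm = compute_tm(core)
        candidates.append((tm, length, core, cols))
    if not candidates:
        raise DesignError(f"flank too short for any core in {len_range} at column {site.column}")
    in_window = [c for c in candidates if tm_range[0] <= c[0] <= tm_range[1]]
    if in_window:
        tm, length, core, cols = min(in_window, key=lambda c: c[1])
    else:
        mid = (tm_range[0] + tm_range[1]) / 2
        tm, length, core, cols = min(candidates, key=lambda c: (abs(c[0] - mid), c[1]))
        warnings.warn(
            f"no core length in {len_range} reaches Tm window {tm_range}; "
            f"using closest (Tm={tm:.1f} C)",
            stacklevel=2,
        )
    return Primer(
        name=name or f"{site.target_species}_c{site.column}_F",
        core=core,
        orientation="forward",
        target_species=site.target_species,
        source_columns=cols,
    )


_PURINES = set("AG")


def _same_class(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


def add_engineered_mismatch(p: Primer, aln: SpeciesAlignment) -> Primer:
    """Substitute the base third from the 3' end to destabilize near-matches.

    The substituted base differs from the template base of every species at
    that column when the alphabet allows, otherwise from as many species as
    possible. Ties prefer purine<->purine / pyrimidine<->pyrimidine pairings
    with the target template (strongest duplex destabilization), then
    alphabetical order.
    """
    if p.orientation != "forward":
        raise DesignError("engineered mismatches are applied to forward primers")
    if len(p.core) < 4:
        raise DesignError("core too short for an offset-3 substitution")
    idx = len(p.core) - 3
    original = p.core[idx]
    if p.source_columns is not None:
        col = p.source_columns[idx]
        template_bases = {
            aln.consensus(sp)[col] for sp in aln.species
        } & set(BASES)
    else:
        template_bases = {original}

    def avoided(b: str) -> int:
        return sum(1 for t in template_bases if t != b)

    best = max(avoided(b) for b in BASES if b != original)
    pool = [b for b in BASES if b != original and avoided(b) == best]
    sub = sorted(pool, key=lambda b: (0 if _same_class(b, original) else 1, b))[0]
    core = p.core[:idx] + sub + p.core[idx + 1 :]
    return replace(
        p,
        core=core,
        engineered_mismatch=EngineeredMismatch(3, original, sub),
    )


def remove_engineered_mismatch(p: Primer) -> Primer:
    """Invert :func:`add_engineered_mismatch`, restoring the template base."""
    if p.engineered_mismatch is None:
        return p
    em = p.engineered_mismatch
    idx = len(p.core) - em.offset_from_3prime
    core = p.core[:idx] + em.original_base + p.core[idx + 1 :]
    return replace(p, core=core, engineered_mismatch=None)


def assign_gc_tails(
    untailed_sizes: dict[str, int], min_gap: int
) -> dict[str, int]:
    """Choose GC-tail unit counts separating all pairwise product sizes.

    Returns species -> number of 26-nt tail units (0..MAX_TAIL_UNITS). The
    assignment tails the fewest primers, then the least total tail length;
    remaining ties break on the lexicographically smallest unit vector over
    species sorted by name. Raises :class:`LadderError` when no assignment
    within the unit cap separates every pair by ``min_gap``.
    """
    species = sorted(untailed_sizes)
    unit = len(GC_TAIL_UNIT)
    best: tuple[int, int, tuple[int, ...]] | None = None
    for combo in itertools.product(range(MAX_TAIL_UNITS + 1), repeat=len(species)):
        sizes = [untailed_sizes[s] + unit * u for s, u in zip(species, combo)]
        ok = all(
            abs(a - b) >= min_gap for a, b in itertools.combinations(sizes, 2)
        )
        if not ok:
            continue
        key = (sum(1 for u in combo if u), sum(combo) * unit, combo)
        if best is None or key < best:
            best = key
    if best is None:
        ordered = sorted(untailed_sizes.items(), key=lambda kv: kv[1])
        worst = min(
            zip(ordered, ordered[1:]), key=lambda ab: ab[1][1] - ab[0][1]
        )
        raise LadderError(
            f"no tail assignment separates {worst[0][0]} ({worst[0][1]} bp) "
            f"from {worst[1][0]} ({worst[1][1]} bp) by {min_gap} bp"
        )
    return dict(zip(species, best[2]))


def _untailed_size(primer: Primer, reverse: Primer, template: str) -> int | None:
    """Product span of a perfectly-matching primer pair on a degapped template."""
    from .seq_io import revcomp

    fwd_at = template.find(primer.core)
    rc = revcomp(reverse.core)
    rev_at = template.find(rc)
    if fwd_at < 0 or rev_at < 0 or rev_at + len(rc) <= fwd_at:
        return None
    return rev_at + len(rc) - fwd_at


def build_panel(
    aln: SpeciesAlignment,
    universal_reverse: Primer,
    name: str = "custom_panel",
    len_range: tuple[int, int] = (18, 26),
    tm_range: tuple[float, float] = (52.0, 60.0),
    min_gap: int = 60,
    size_tolerance: int = 10,
) -> MultiplexPanel:
    """Assemble one allele-specific forward primer per species plus the ladder.

    Candidate anchors are diagnostic sites whose upstream core window is
    gap-free and fixed within the target species (so every target record
    matches the designed core exactly). Site choice maximizes the spread of
    untailed product sizes greedily, then prefers the best Tm fit. Primers
    whose 3'-terminal five bases mismatch some non-target species fewer than
    two times receive the engineered offset-3 mismatch. GC tails then
    separate any residual size collisions.
    """
    chosen: dict[str, tuple[Primer, int]] = {}
    mid_tm = (tm_range[0] + tm_range[1]) / 2

    # sorted species order makes the build independent of record order
    for species in sorted(aln.species):
        consensus_gapped = aln.consensus(species)
        template = consensus_gapped.replace("-", "")
        sites = [
            s
            for s in find_diagnostic_sites(aln, species, min_flank=len_range[0])
            if s.flank_ok
        ]
        candidates: list[tuple[Primer, int]] = []
        for site in sites:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    primer = design_primer(aln, site, len_range, tm_range)
            except DesignError:
                continue
            # Fixed-within-species core: every record must carry it verbatim.
            recs = aln.records_of(species)
            if any(
                any(r.seq[c] != primer.core[k] for k, c in enumerate(primer.source_columns))
                for r in recs
            ):
                continue
            size = _untailed_size(primer, universal_reverse, template)
            if size is None:
                continue
            candidates.append((primer, size))
        if not candidates:
            raise DesignError(f"species {species!r} has no usable diagnostic site")
        taken = [sz for _, sz in chosen.values()]
        def spread_key(cand: tuple[Primer, int]) -> tuple[float, float]:
            primer, size = cand
            gap = min((abs(size - t) for t in taken), default=size)
            return (-gap, abs(compute_tm(primer.core) - mid_tm))
        chosen[species] = min(candidates, key=spread_key)

    # Engineered-mismatch trigger: <2 mismatches vs some non-target within
    # the 3'-terminal five positions.
    primers: dict[str, Primer] = {}
    for species, (primer, _) in chosen.items():
        tail5 = primer.core[-5:]
        cols5 = primer.source_columns[-5:]
        trigger = False
        for other in aln.species:
            if other == species:
                continue
            cons = aln.consensus(other)
            mm = sum(1 for k, c in enumerate(cols5) if cons[c] != tail5[k])
            if mm < 2:
                trigger = True
                break
        primers[species] = (
            add_engineered_mismatch(primer, aln) if trigger else primer
        )

    untailed = {sp: sz for sp, (_, sz) in chosen.items()}
    units = assign_gc_tails(untailed, min_gap)
    forward: list[Primer] = []
    expected: dict[str, int] = {}
    for i, species in enumerate(sorted(aln.species), start=1):
        p = primers[species]
        u = units[species]
        p = replace(p, tail=GC_TAIL_UNIT * u, name=f"{name}_{i}_F")
        forward.append(p)
        expected[species] = untailed[species] + len(GC_TAIL_UNIT) * u

    panel = MultiplexPanel(
        name=name,
        forward_primers=forward,
        reverse_primer=universal_reverse,
        expected_sizes=expected,
        size_tolerance=size_tolerance,
        min_gap=min_gap,
    )
    return panel


# ---------------------------------------------------------------------------
# Panel JSON serialization (versioned schema).

SCHEMA_VERSION = 1


def _primer_to_dict(p: Primer) -> dict:
    em = p.engineered_mismatch
    return {
        "name": p.name,
        "core": p.core,
        "tail": p.tail,
        "orientation": p.orientation,
        "target_species": p.target_species,
        "engineered_mismatch": None
        if em is None
        else {
            "offset_from_3prime": em.offset_from_3prime,
            "original_base": em.original_base,
            "substituted_base": em.substituted_base,
        },
    }


def _primer_from_dict(d: dict, path: str) -> Primer:
    for key in ("name", "core", "orientation", "target_species"):
        if key not in d:
            raise PanelSchemaError(f"missing key {key!r}", f"{path}.{key}")
    em = d.get("engineered_mismatch")
    try:
        return Primer(
            name=d["name"],
            core=d["core"],
            tail=d.get("tail", ""),
            orientation=d["orientation"],
            target_species=d["target_species"],
            engineered_mismatch=None
            if em is None
            else EngineeredMismatch(
                em["offset_from_3prime"], em["original_base"], em["substituted_base"]
            ),
        )
    except (DesignError, ValueError, KeyError, TypeError) as exc:
        raise PanelSchemaError(str(exc), path) from exc


def panel_to_json(panel: MultiplexPanel) -> str:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": panel.name,
        "forward_primers": [_primer_to_dict(p) for p in panel.forward_primers],
        "reverse_primer": _primer_to_dict(panel.reverse_primer),
        "expected_sizes": panel.expected_sizes,
        "size_tolerance": panel.size_tolerance,
        "min_gap": panel.min_gap,
        "notes": panel.notes,
    }
    return json.dumps(doc, indent=2)


def panel_from_json(text: str) -> MultiplexPanel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise PanelSchemaError(f"not valid JSON: {exc}", "$") from exc
    if not isinstance(doc, dict):
        raise PanelSchemaError("top level must be an object", "$")
    for key in ("name", "forward_primers", "reverse_primer", "expected_sizes"):
        if key not in doc:
            raise PanelSchemaError(f"missing key {key!r}", f"$.{key}")
    if not isinstance(doc["forward_primers"], list) or not doc["forward_primers"]:
        raise PanelSchemaError("must be a non-empty list", "$.forward_primers")
    forward = [
        _primer_from_dict(d, f"$.forward_primers[{i}]")
        for i, d in enumerate(doc["forward_primers"])
    ]
    reverse = _primer_from_dict(doc["reverse_primer"], "$.reverse_primer")
    sizes = doc["expected_sizes"]
    if not isinstance(sizes, dict) or not all(
        isinstance(v, int) for v in sizes.values()
    ):
        raise PanelSchemaError("must map species to integer bp", "$.expected_sizes")
    return MultiplexPanel(
        name=doc["name"],
        forward_primers=forward,
        reverse_primer=reverse,
        expected_sizes=dict(sizes),
        size_tolerance=doc.get("size_tolerance", 10),
        min_gap=doc.get("min_gap", 60),
        notes=doc.get("notes", ""),
    )


def load_panel(path: str | Path) -> MultiplexPanel:
    return panel_from_json(Path(path).read_text())


def save_panel(panel: MultiplexPanel, path: str | Path) -> None:
    Path(path).write_text(panel_to_json(panel) + "\n")
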