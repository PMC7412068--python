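"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from scratch (plain loops, local
IUPAC table) and never imports the implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math

SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "R": "Y", "Y": "R",
      "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D"}


def rc(seq: str) -> str:
    return "".join(RC[c] for c in reversed(seq))


def score_window(window: str, oriented_core: str, three_prime_left: bool):
    """(total, window_full_mm, full_offsets) for one window, or None semantics upstream."""
    L = len(oriented_core)
    full = []
    n_count = 0
    for j in range(L):
        t = window[j]
        b = oriented_core[j]
        if t == "N":
            n_count += 1
        elif b not in SETS[t]:
            full.append(j)
    total = len(full) + (n_count + 1) // 2
    offsets = sorted((j + 1) if three_prime_left else (L - j) for j in full)
    return total, full, offsets


def brute_sites(template: str, core: str, model) -> set:
    """Set of (strand, start, total, offsets) passing the binding model."""
    out = set()
    L = len(core)
    w = min(model.three_prime_window, L)
    for strand, oriented, left in (("+", core, False), ("-", rc(core), True)):
        for i in range(len(template) - L + 1):
            window = template[i : i + L]
            total, full, offsets = score_window(window, oriented, left)
            win_positions = range(0, w) if left else range(L - w, L)
            win_mm = sum(1 for j in full if j in win_positions)
            if total <= model.max_total_mismatches and win_mm <= model.window_mismatches_allowed:
                out.add((strand, i, total, tuple(offsets)))
    return out


def brute_products(template: str, primers, model) -> list[int]:
    """Sorted product lengths from exhaustive site pairing."""
    plus, minus = [], []
    for p in primers:
        for strand, start, *_ in brute_sites(template, p.core, model):
            if strand == "+":
                plus.append((start, p))
            else:
                minus.append((start + len(p.core), p))
    out = []
    for fs, fp in plus:
        for re_, rp in minus:
            if fs < re_:
                product = re_ - fs + len(fp.tail) + len(rp.tail)
                if product <= model.max_product_len:
                    out.append(product)
    return sorted(out)


def brute_tail_assignment(sizes: dict[str, int], min_gap: int, unit: int = 26,
                          max_units: int = 3):
    """All feasible unit assignments, for checking optimality claims."""
    species = sorted(sizes)
    feasible = []
    for combo in itertools.product(range(max_units + 1), repeat=len(species)):
        s = [sizes[sp] + unit * u for sp, u in zip(species, combo)]
        if all(abs(a - b) >= min_gap for a, b in itertools.combinations(s, 2)):
            feasible.append(dict(zip(species, combo)))
    return feasible


def k2p_closed_form(P: float, Q: float) -> float:
    return -0.5 * math.log((1.0 - 2.0 * P - Q) * math.sqrt(1.0 - 2.0 * Q))
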