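import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import asprime as ap


@pytest.fixture(scope="session")
def packaged_panel():
    return ap.load_packaged_panel()


@pytest.fixture(scope="session")
def packaged_refs():
    return ap.synthetic_reference_templates()


@pytest.fixture(scope="session")
def packaged_ref_aln(packaged_panel, packaged_refs):
    labels = {
        "SYN_" + p.target_species.replace(" ", "_").replace(".", ""): p.target_species
        for p in packaged_panel.forward_primers
    }
    return ap.SpeciesAlignment(records=packaged_refs, species_of=labels)


@pytest.fixture(scope="session")
def small_complex():
    """A seeded 5-species synthetic complex with its truth ledger."""
    return ap.generate_complex(ap.ComplexSpec(n_species=5, seed=11))


def make_toy_alignment(diff_col: int = 40, length: int = 60):
    """Two species x two records differing only at one column."""
    import numpy as np

    rng = np.random.default_rng(42)
    base = "".join(rng.choice(list("ACGT"), length))
    a = base[:diff_col] + "A" + base[diff_col + 1 :]
    b = base[:diff_col] + "G" + base[diff_col + 1 :]
    records = [
        ap.SeqRecord("a1", a),
        ap.SeqRecord("a2", a),
        ap.SeqRecord("b1", b),
        ap.SeqRecord("b2", b),
    ]
    labels = {"a1": "spA", "a2": "spA", "b1": "spB", "b2": "spB"}
    return ap.SpeciesAlignment(records=records, species_of=labels)


@pytest.fixture
def toy_alignment():
    return make_toy_alignment()
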