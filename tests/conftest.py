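from __future__ import annotations

import pytest

from amplimeth.panel import AmpliconTemplate
from amplimeth.simulate import synthetic_template, table1_panel


@pytest.fixture(scope="session")
def panel():
    """The three study-geometry amplicons (551/10, 405/15, 401/10)."""
    return table1_panel(seed=1)


@pytest.fixture(scope="session")
def small_template() -> AmpliconTemplate:
    """A short amplicon (120 bp, 4 CpGs) for fast unit tests."""
    return synthetic_template("mini", 120, 4, seed=11)


@pytest.fixture(scope="session")
def tiny_template() -> AmpliconTemplate:
    """Hand-built 90 bp amplicon with known CpG coordinates."""
    primer_f = "ACTGACTGACTGACTGACTGACTGACTGACTGA"
    primer_r = "TGACTGACTGACTGACTGACTGACTGACTGACT"
    seq = (
        "ATTGATTAGATTACGAATTAGGATTTACGATTAGGATTAAGG"
        "ATTCGATTAGGATTTAAGGATTACGTTAGGATTAGGATTAGGAATTAG"
    )
    return AmpliconTemplate(
        name="tiny",
        genomic_seq=seq,
        cpg_positions=tuple(
            i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"
        ),
        primer_fwd=primer_f,
        primer_rev=primer_r,
    )
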