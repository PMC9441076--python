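import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes _oracles importable

from divscan.cds import CodonAlignment
from divscan.simdata import evolve_codon_pair, random_ancestor


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def make_alignment(gene_id="g", n_codons=300, t=0.2, omega=0.2, kappa=2.0,
                   rng=None, **kw) -> CodonAlignment:
    rng = rng if rng is not None else np.random.default_rng(0)
    anc = random_ancestor(n_codons, rng)
    a, b = evolve_codon_pair(anc, t, omega, kappa, rng)
    return CodonAlignment(gene_id=gene_id, seq_A=a, seq_B=b, **kw)


@pytest.fixture
def simulated_alignments(rng):
    """50 moderately diverged neutral-ish alignments, session cheap."""
    return [make_alignment(f"g{i}", 120, 0.2, 0.5, 2.0, rng) for i in range(50)]
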