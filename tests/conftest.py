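"""Shared fixtures: toy structures, alignments, and the trained tiny model
used by the end-to-end checks (trained once per session)."""

import numpy as np
import pytest

TOY_PDB = """\
ATOM      1  N   ALA A   1      -1.000   0.500   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      -0.500   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      4  HB1 ALA A   1       0.100   0.900   0.000  1.00  0.00           H
ATOM      5  N   ALA A   2       3.000   0.500   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       3.300   0.000   0.000  1.00  0.00           C
ATOM      7  CB  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      8  N   GLY B   1       9.000   1.000   0.000  1.00  0.00           N
ATOM      9  CA  GLY B   1       9.500   0.500   0.000  1.00  0.00           C
ATOM     10  CA  SER B   2      12.000   0.500   0.000  1.00  0.00           C
ATOM     11  CB  SER B   2      12.500   0.000   0.000  1.00  0.00           C
TER
END
"""

TOY_A3M = """\
>query
ACDEF
>hom1 OS=Homo sapiens OX=9606
AC-EF
>hom2 some bacterium
ACDga-F
>hom3 OX=9606 GN=x
AADEF
>hom4 [Escherichia coli]
-CDEF
"""


@pytest.fixture
def toy_pdb_text():
    return TOY_PDB


@pytest.fixture
def toy_a3m_text():
    return TOY_A3M


# -- end-to-end training fixtures (built once; several tests share them) ----

TRAIN_N = 40
TRAIN_L = 24
TRAIN_SNR = 0.8
TRAIN_SEED = 101
HELD_SEED = 901
LADDER_SEED = 50


@pytest.fixture(scope="session")
def snr08_dataset():
    from dimerdist.synth import make_dataset

    return make_dataset(TRAIN_N, TRAIN_L, TRAIN_SNR, TRAIN_SEED)


@pytest.fixture(scope="session")
def heldout_dataset():
    from dimerdist.synth import make_dataset

    return make_dataset(10, TRAIN_L, TRAIN_SNR, HELD_SEED)


@pytest.fixture(scope="session")
def trained_predictor(snr08_dataset):
    from dimerdist.estimator import InterchainDistancePredictor

    est = InterchainDistancePredictor(
        total_conv_layers=12, filters=16, epochs=10, seed=0
    )
    est.fit([ex for _, ex in snr08_dataset])
    return est


@pytest.fixture(scope="session")
def snr_ladder_dataset():
    """40 held-out dimers over an evenly spaced snr ladder 0.2..0.9."""
    from dimerdist.synth import generate_synthetic_features, generate_toy_dimer

    rng = np.random.default_rng(LADDER_SEED)
    out = []
    for snr in np.linspace(0.2, 0.9, 40):
        dimer = generate_toy_dimer(40, 40, int(rng.integers(2**31)))
        ex = generate_synthetic_features(dimer, float(snr), int(rng.integers(2**31)))
        out.append((dimer, ex))
    return out
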