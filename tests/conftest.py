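"""Shared fixtures: a published worked example and small synthetic corpora.

MIR4704_* is the hsa-mir-4704 pre-miRNA (75 nt) with its RNAfold structure
and the published 5'-arm cleavage window starting at position 25 (centre
bond 31), used as a ground-truth worked example throughout the suite.
"""

import numpy as np
import pytest

from dicersite.dataset import build_main_dataset
from dicersite.structure import PreMiRNA
from dicersite.synthetic import HairpinSpec, generate_corpus

MIR4704_ID = "hsa-mir-4704"
MIR4704_SEQ = (
    "CUUAUCCUAGACACUAGGCAUGUGAGUGAUUGUCUUCCUCACUCAAUCAGUCACAUAUCUAGUGUCUAGAAUGAG"
)
MIR4704_DOT = (
    "(((((.((((((((((((.((((((.((((((...........)))))).)))))).)))))))))))).)))))"
)
MIR4704_PAT = "AGUGAUUGUCUUCC"
MIR4704_DOTPAT = "(.((((((......"
MIR4704_COMP = "UOACUAACOOOOOO"
MIR4704_START = 25
MIR4704_BOND5 = 31


@pytest.fixture(scope="session")
def mir4704():
    """The worked-example pre-miRNA (3' bond placed symmetrically)."""
    return PreMiRNA(MIR4704_ID, MIR4704_SEQ, MIR4704_DOT,
                    bond5=MIR4704_BOND5, bond3=51)


@pytest.fixture(scope="session")
def small_corpus():
    """60 signal-free hairpins, shared across tests (read-only)."""
    hairpins, annotations = generate_corpus(
        60, HairpinSpec(signal_strength=0.0), seed=11
    )
    return hairpins, annotations


@pytest.fixture(scope="session")
def small_dataset(small_corpus):
    hairpins, _ = small_corpus
    return build_main_dataset(hairpins, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
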