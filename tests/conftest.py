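"""Shared fixtures: small synthetic corpora built once per session.

Corpus scale (12 datasets x 20 ICs, 32 electrodes, 50 s at 256 Hz) keeps
the full pipeline — simulation, filtering, ICA, fingerprinting — tractable
while leaving every feature well defined (all five spectral bands fit under
the 128 Hz Nyquist).
"""

from __future__ import annotations

import numpy as np
import pytest

from icfp.simulate import SimulationConfig, make_labeled_corpus


CORPUS_CFG = SimulationConfig(montage_size=32, fs=256.0, duration_s=50.0, seed=0)


@pytest.fixture(scope="session")
def corpora():
    """One labeled 12-dataset corpus per artifact type (fixed seed)."""
    out = {}
    for atype in ("eyeblink", "eye-movement", "myogenic"):
        with np.errstate(all="ignore"):
            out[atype] = make_labeled_corpus(12, CORPUS_CFG, seed=42, artifact_type=atype)
    return out


@pytest.fixture(scope="session")
def blink_corpus(corpora):
    return corpora["eyeblink"]


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(2024)
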