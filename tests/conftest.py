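"""Shared fixtures: small rendered letter sets and model RDMs.

Expensive artefacts (exact-OT model RDMs) are session-scoped so the whole
suite renders and solves them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from graphot.glyphs import render_glyph
from graphot.graphetic import build_model_rdm, rank_transform_rdm

#: letter subset used for end-to-end tests; kept small so the exact
#: transport LP stays fast (66 unordered pairs)
TEST_LETTERS = tuple("abcdefghijkl")
TEST_HEIGHT = 28


@pytest.fixture(scope="session")
def letter_images():
    return {c: render_glyph(c, max_height_px=TEST_HEIGHT) for c in TEST_LETTERS}


@pytest.fixture(scope="session")
def jaccard_rdm(letter_images):
    return build_model_rdm(letter_images, metric="jaccard")


@pytest.fixture(scope="session")
def wasserstein_rdm(letter_images):
    return build_model_rdm(letter_images, metric="wasserstein")


@pytest.fixture(scope="session")
def jaccard_rank(jaccard_rdm):
    return rank_transform_rdm(jaccard_rdm)


@pytest.fixture(scope="session")
def wasserstein_rank(wasserstein_rdm):
    return rank_transform_rdm(wasserstein_rdm)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
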