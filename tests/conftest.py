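"""Shared fixtures: one small synthetic corpus reused across the suite."""

from __future__ import annotations

import pytest

from cleftus.io import load_manifest
from cleftus.pipeline import load_chunk_dataset
from cleftus.synthdata import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A 9-participant / 18-utterance clean-ish corpus (snr 20 dB)."""
    root = tmp_path_factory.mktemp("corpus")
    cfg = SynthConfig(n_per_class=3, utterances_per_participant=2, snr_db=20.0, seed=7)
    manifest = generate_dataset(cfg, root)
    return cfg, root, manifest


@pytest.fixture(scope="session")
def small_manifest(small_corpus):
    _, root, _ = small_corpus
    return load_manifest(root / "manifest.csv")


@pytest.fixture(scope="session")
def small_chunks(small_manifest):
    return load_chunk_dataset(small_manifest)
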