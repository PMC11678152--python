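"""Shared fixtures: toy annotations and the session-scoped synthetic run.

The full synthetic discovery run (strain family -> conservation ->
structure screen -> expression -> DE -> targets) takes a few minutes, so
it is executed once per session and shared by the structure-screen and
end-to-end recovery tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from srnascan.annotation_io import AnnotationSet, FeatureRecord
from srnascan.pipeline import run_end_to_end
from srnascan.synthetic import SimulationConfig

#: study conditions for the screen/recovery evaluation: default generator
#: settings with enough genes to provide ~200 unplanted IGRs
SCREEN_SEED = 7
SCREEN_CONFIG = dict(seed=SCREEN_SEED, n_genes=225)


def make_annotation(genes, replicon_len=10_000, replicon="chr", kind="CDS"):
    """AnnotationSet from (start, end, strand) triples, 1-based inclusive."""
    feats = [
        FeatureRecord.from_one_based(
            f"g{i}", replicon, s, e, strand, kind, "test"
        )
        for i, (s, e, strand) in enumerate(genes)
    ]
    return AnnotationSet(replicons={replicon: replicon_len}, features=feats)


def random_genome(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), n, p=p))


@pytest.fixture(scope="session")
def synthetic_run():
    """One full pipeline run under the default synthetic study conditions."""
    cfg = SimulationConfig(**SCREEN_CONFIG)
    return run_end_to_end(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
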