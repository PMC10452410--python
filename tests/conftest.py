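"""Shared fixtures.

The three-topography implant experiment is expensive (several minutes per
topography), so it runs once per session and every comparison test reads
from it.
"""

from __future__ import annotations

import numpy as np
import pytest

from periflow.benchmarks import run_topography


@pytest.fixture(scope="session")
def experiment():
    """Full 3 s fill transient for all three surface topographies.

    Returns {kind: (geom, checkpoints, series, diagnostics)}.
    """
    out = {}
    for kind in ("amorphous", "nano", "hybrid"):
        out[kind] = run_topography(kind)
    return out


@pytest.fixture(scope="session")
def short_mini_run():
    """A short (0.15 s) amorphous implant run for invariant checks."""
    return run_topography("amorphous", end_time=0.15)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
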