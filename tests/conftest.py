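"""Shared fixtures: small seeded synthetic datasets.

Module tests run on proportionally scaled-down versions of the default
design so the suite stays fast; the acceptance tests use the full
default sizes.
"""

import numpy as np
import pandas as pd
import pytest

from fieldtx import io, simulate


@pytest.fixture(scope="session")
def field_small():
    """Scaled organ/tissue panel (1200 genes) with truth."""
    cfg = simulate.FieldConfig.scaled(1200, seed=11)
    return simulate.generate_field_transcriptome(cfg)


@pytest.fixture(scope="session")
def field_small_norm(field_small):
    """Percentile-normalized matrix + relative matrix for the panel."""
    raw, meta, truth = field_small
    log2 = io.percentile_normalize(raw)
    relmat = io.relative_expression(log2)
    return log2, relmat


@pytest.fixture(scope="session")
def timecourse_small():
    """Scaled weekly leaf series (800 genes) with truth."""
    cfg = simulate.TimecourseConfig.scaled(800, seed=7)
    return simulate.generate_timecourse(cfg)


@pytest.fixture(scope="session")
def fertile_sterile_small():
    """Scaled fertile/sterile series (1500 genes) with truth."""
    cfg = simulate.FertileSterileConfig.scaled(1500, seed=5)
    return simulate.generate_fertile_sterile(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_raw(rng, n_genes=40, n_samples=5, low=1.0, high=1000.0):
    values = pd.DataFrame(
        rng.uniform(low, high, size=(n_genes, n_samples)),
        index=[f"P{i:03d}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )
    return io.RawMatrix(values)
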