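"""Shared fixtures: small synthetic matrices and builders used across modules."""

import numpy as np
import pytest

from thermoshift.io_filters import ChannelMeta, IntensityMatrix


def make_matrix(intensities, channels, unique_peptides=None, reverse=None,
                contaminant=None, site_only=None, scale="raw", ids=None):
    """Build an IntensityMatrix around an intensities array with defaults."""
    intensities = np.asarray(intensities, dtype=float)
    n = intensities.shape[0]
    zeros = np.zeros(n, dtype=bool)
    if ids is None:
        ids = np.array([f"P{i:05d}" for i in range(n)], dtype=object)
    return IntensityMatrix(
        protein_ids=np.asarray(ids, dtype=object),
        gene_names=np.array([f"G{i}" for i in range(n)], dtype=object),
        reverse=zeros if reverse is None else np.asarray(reverse, bool),
        contaminant=zeros if contaminant is None else np.asarray(contaminant, bool),
        site_only=zeros if site_only is None else np.asarray(site_only, bool),
        unique_peptides=(np.full(n, 5) if unique_peptides is None
                         else np.asarray(unique_peptides, int)),
        intensities=intensities,
        channels=tuple(channels),
        scale=scale,
    )


def simple_channels(n, condition="treated", role="test"):
    return tuple(
        ChannelMeta(f"Reporter intensity corrected {i}", condition, i + 1, role)
        for i in range(n)
    )


def stpp_channels(n_replicates=3):
    """Channel metadata for a single-tube layout, plex order."""
    metas, k = [], 0
    for cond in ("treated", "untreated"):
        for rep in range(1, n_replicates + 1):
            for role in ("test", "control"):
                metas.append(ChannelMeta(
                    f"Reporter intensity corrected {k}", cond, rep, role))
                k += 1
    return tuple(metas)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
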