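"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from assemblyscape.assembly_processes import PhyloDistances
from assemblyscape.io_core import OtuTable


@pytest.fixture
def toy_tree() -> TreeNode:
    """((A:1,B:1):1,C:2); — the worked-example tree."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"), format="newick")


@pytest.fixture
def toy_distances(toy_tree) -> PhyloDistances:
    from assemblyscape.assembly_processes import patristic_distances

    return patristic_distances(toy_tree, ["A", "B", "C"])


def brute_force_beta_mntd(
    abund_a: np.ndarray,
    abund_b: np.ndarray,
    d: np.ndarray,
    abundance_weighted: bool = True,
) -> float:
    """Independent βMNTD oracle: explicit nested loops over OTU pairs."""
    pa = [i for i, v in enumerate(abund_a) if v > 0]
    pb = [j for j, v in enumerate(abund_b) if v > 0]
    if abundance_weighted:
        fa = {i: abund_a[i] for i in pa}
        fb = {j: abund_b[j] for j in pb}
    else:
        fa = {i: 1.0 / len(pa) for i in pa}
        fb = {j: 1.0 / len(pb) for j in pb}
    term_a = 0.0
    for i in pa:
        best = min(d[i][j] for j in pb)
        term_a += fa[i] * best
    term_b = 0.0
    for j in pb:
        best = min(d[i][j] for i in pa)
        term_b += fb[j] * best
    return 0.5 * (term_a + term_b)


def random_table(rng: np.random.Generator, n_samples: int, n_otus: int, high: int = 20) -> OtuTable:
    """Random sparse count table with no empty samples."""
    counts = rng.integers(0, high, size=(n_samples, n_otus))
    counts[counts < high // 3] = 0
    counts[:, 0] += 1  # guarantee non-empty rows
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"OTU_{j + 1}" for j in range(n_otus)],
        )
    )


def random_symmetric(rng: np.random.Generator, n: int) -> np.ndarray:
    m = rng.normal(size=(n, n))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return m
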