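import numpy as np
import pandas as pd
import pytest

from popkit.genotype_io import ANNOTATION_KEYS, GenotypeMatrix, PopulationMap


def make_matrix(
    calls,
    pos=None,
    scaffold="s1",
    scaffolds=None,
    scaffold_lengths=None,
    samples=None,
    depth=None,
    annotations=None,
):
    """Build a small GenotypeMatrix from plain lists for unit tests."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if pos is None:
        pos = list(range(1, n_sites + 1))
    if scaffolds is None:
        scaffolds = [scaffold] * n_sites
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {
            "scaffold": scaffolds,
            "pos": pos,
            "ref": ["A"] * n_sites,
            "alt": ["G"] * n_sites,
            "depth": depth if depth is not None else [100.0] * n_sites,
        }
    )
    for key in ANNOTATION_KEYS:
        sites[key] = np.nan
    if annotations:
        for key, values in annotations.items():
            sites[key] = values
    if scaffold_lengths is None:
        scaffold_lengths = {s: 1_000_000_000 for s in set(scaffolds)}
    return GenotypeMatrix(list(samples), sites, calls, scaffold_lengths)


@pytest.fixture
def two_pop_matrix():
    """Ten diploids in two groups of five over six sites, with missing calls."""
    calls = [
        [0, 1, 2, 0, 1, 0],
        [0, 1, 2, 1, 1, 0],
        [1, 0, 2, 0, -1, 0],
        [0, 1, 1, 0, 1, 0],
        [0, 0, 2, 1, 1, 0],
        [2, 1, 0, 2, 0, 0],
        [2, 2, 0, 2, -1, 0],
        [1, 2, 0, 2, 0, 0],
        [2, 2, 1, 1, 0, 0],
        [2, 1, 0, 2, 0, 0],
    ]
    m = make_matrix(calls, pos=[100, 200, 5000, 12000, 15000, 20000])
    popmap = PopulationMap(
        {s: ("left" if i < 5 else "right") for i, s in enumerate(m.samples)}
    )
    return m, popmap
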