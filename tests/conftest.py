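import numpy as np
import pandas as pd
import pytest

import screenconsensus as sc


def make_scores(values, genes=None, cells=None, platform="CRISPR"):
    """Build a small essentiality ScreenMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    genes = genes or [f"G{i:03d}" for i in range(m)]
    cells = cells or [f"C{j:02d}" for j in range(n)]
    return sc.ScreenMatrix(pd.DataFrame(values, index=genes, columns=cells),
                           kind="essentiality", platform=platform)


def random_graph(rng, m=None, n=None, frac=0.2):
    """Random tri-labeled bipartite graph from random scores."""
    m = m if m is not None else int(rng.integers(10, 51))
    n = n if n is not None else int(rng.integers(1, 6))
    scores = make_scores(rng.normal(size=(m, n)))
    labels = sc.assign_labels(scores, frac)
    return sc.build_bipartite(labels)


@pytest.fixture(scope="session")
def default_world():
    """Default synthetic dataset + truth (the stated benchmark world)."""
    return sc.generate(sc.SyntheticConfig())


@pytest.fixture(scope="session")
def default_fits(default_world):
    """Tri-labels and consensus fits for both platforms at frac=0.10."""
    dataset, _ = default_world
    out = {}
    for name, scores in (("CRISPR", dataset.crispr), ("SHRNA", dataset.shrna)):
        labels = sc.assign_labels(scores, 0.10)
        fit = sc.fit(sc.build_bipartite(labels), sc.ConsensusConfig())
        out[name] = (labels, fit)
    return out


@pytest.fixture(scope="session")
def default_calls(default_world, default_fits):
    """Final call sets for both platforms and classes at x = 10%."""
    dataset, _ = default_world
    matrices = {"CRISPR": dataset.crispr, "SHRNA": dataset.shrna}
    return {(name, cls): sc.call_final(matrices[name], default_fits[name][1],
                                       cls, 0.10)
            for name in matrices for cls in ("E", "NE")}
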