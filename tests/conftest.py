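from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ptmlri.reference import (
    Edge,
    IntracellularNetwork,
    LRPair,
    PathwayDef,
    PTMRefRecord,
    ReferenceBundle,
)


@pytest.fixture
def tiny_bundle() -> ReferenceBundle:
    """Hand-built bundle: 2 LR pairs, 1 pathway, 3 edges, 2 PTM records."""
    pathway = PathwayDef("PW1", "demo pathway", "user", frozenset({"R1", "S1", "T1", "T2"}))
    network = IntracellularNetwork(
        [Edge("R1", "S1", True), Edge("S1", "T1", True), Edge("S1", "T2", True)]
    )
    records = [
        PTMRefRecord("T1", "Y", 187, "phosphorylation", "added", "R1", "PW1"),
        PTMRefRecord("T2", "S", 10, "phosphorylation", "removed", "", "PW1"),
    ]
    return ReferenceBundle(
        lr_pairs=[LRPair("L1", "R1", "demo"), LRPair("L2", "R1", "demo")],
        pathways=[pathway],
        network=network,
        ptm_records=records,
    )


@pytest.fixture
def tiny_bundle_dir(tiny_bundle, tmp_path):
    from ptmlri.io import write_bundle

    d = tmp_path / "bundle"
    write_bundle(tiny_bundle, d)
    return d


def two_cluster_design(n_a: int, n_b: int):
    from ptmlri.stats import ClusterDesign

    samples = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    return ClusterDesign(samples, {s: s[0] for s in samples})


@pytest.fixture
def small_design():
    return two_cluster_design(4, 4)


def random_matrix(rows, samples, seed=0, missing_rate=0.0):
    rng = np.random.default_rng(seed)
    values = rng.normal(10.0, 1.0, size=(len(rows), len(samples)))
    if missing_rate:
        values[rng.random(values.shape) < missing_rate] = np.nan
    return pd.DataFrame(values, index=pd.Index(rows, name="row"), columns=samples)
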