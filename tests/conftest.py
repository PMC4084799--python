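"""Shared fixtures: small handcrafted bundles and synthetic datasets."""

import numpy as np
import pandas as pd
import pytest

from exoninclusion.inclusion import ExpressionBundle
from exoninclusion.simulate import SimulationParams, generate_dataset


def make_design(n_pairs: int = 4) -> pd.DataFrame:
    rows = []
    for i in range(1, n_pairs + 1):
        rows.append({"sample": f"T{i}", "pair": f"P{i}", "status": "case"})
        rows.append({"sample": f"C{i}", "pair": f"P{i}",
                     "status": "control"})
    return pd.DataFrame(rows)


def make_bundle(
    probe_values: np.ndarray,
    meta_of: list[str],
    *,
    detection: np.ndarray | None = None,
    cross_hyb: list[bool] | None = None,
    n_pairs: int = 4,
) -> ExpressionBundle:
    """Build a bundle from a probeset matrix; metaprobesets are the means."""
    design = make_design(n_pairs)
    samples = list(design["sample"])
    m = probe_values.shape[0]
    index = pd.Index([f"ps{i}" for i in range(m)], name="probeset")
    probes = pd.DataFrame(probe_values, index=index, columns=samples)
    meta = probes.groupby(pd.Series(meta_of, index=index)).mean()
    meta.index.name = "metaprobeset"
    if detection is None:
        detection = np.ones_like(probe_values, dtype=bool)
    det = pd.DataFrame(detection, index=index, columns=samples)
    annotation = pd.DataFrame(
        {
            "metaprobeset": meta_of,
            "probeset_set": "core",
            "region": "exonic",
            "splice_type": "na",
            "cross_hyb": cross_hyb if cross_hyb is not None else False,
        },
        index=index,
    )
    return ExpressionBundle(
        probesets=probes,
        metaprobesets=meta,
        annotation=annotation,
        detection=det,
        design=design,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """A mid-sized synthetic dataset at default parameters (pi0_true=0.8)."""
    params = SimulationParams(n_genes=300, seed=20240401)
    return generate_dataset(params)


@pytest.fixture(scope="session")
def strong_effect_dataset():
    """Planted effects well above noise at a size where the observed
    labeling's pi0 is clearly optimal (~20,000 probesets)."""
    params = SimulationParams(
        n_genes=2900, pi0_true=0.8, effect_size=0.35, noise_sd=0.25,
        seed=915,
    )
    return generate_dataset(params)
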