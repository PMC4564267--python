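import numpy as np
import pandas as pd
import pytest

from demeta.io import CASE, CONTROL, ExpressionDataset
from demeta.simulate import PlantedSet, default_config, generate_collection

SMALL_PLANTED = (
    PlantedSet(30, ("RA",)),
    PlantedSet(30, ("SLE",)),
    PlantedSet(30, ("OA",)),
    PlantedSet(30, ("AS",)),
    PlantedSet(8, ("RA", "SLE", "AS")),
    PlantedSet(3, ("RA", "SLE", "OA", "AS")),
)


def small_config(seed: int = 0, **overrides):
    """Scaled-down generator config for fast tests (same study layout)."""
    base = dict(
        n_genes=1200,
        dead_gene_count=120,
        planted=SMALL_PLANTED,
        unannotated_probes_per_platform=10,
    )
    base.update(overrides)
    return default_config(seed=seed, **base)


@pytest.fixture(scope="session")
def small_collection():
    return generate_collection(small_config(seed=11))


def make_dataset(values, case_ids, control_ids, genes=None, study_id="S", disease="D"):
    """Build an ExpressionDataset from a plain array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = list(case_ids) + list(control_ids)
    frame = pd.DataFrame(values, index=genes, columns=samples)
    groups = pd.Series(
        [CASE] * len(case_ids) + [CONTROL] * len(control_ids), index=samples
    )
    return ExpressionDataset(study_id, disease, frame, groups)
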