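"""Shared fixtures: a small synthetic world and a trained multi-task model.

Everything is generated programmatically at collection time; the trained
model is session-scoped because several behavioural tests (context
dependence, dose sensitivity, binary ranking, viability curves) probe the
same fit.
"""

from __future__ import annotations

import numpy as np
import pytest

from perturbcast.data_core import partition_by_quality
from perturbcast.model import DrugResponseModel
from perturbcast.synthetic_data import (
    WorldSpec,
    make_perturbation_dataset,
    make_viability_dataset,
    make_world,
)
from perturbcast.training import SupervisedData, TrainConfig


@pytest.fixture(scope="session")
def small_world():
    """A 60-gene, 16-cell, 10-drug world with planted truth."""
    spec = WorldSpec(n_genes=60, n_cells=16, n_clusters=4, n_drugs=10,
                     doses=(0.1, 1.0, 10.0), rng_seed=7)
    basal, drug_table, truth = make_world(spec)
    basal_map = {c: basal.values[:, j] for j, c in enumerate(basal.sample_ids)}
    return {"spec": spec, "basal": basal, "basal_map": basal_map,
            "drug_table": drug_table, "truth": truth}


@pytest.fixture(scope="session")
def trained(small_world):
    """A joint-trained multi-task model on the small world (seeded)."""
    spec = small_world["spec"]
    truth = small_world["truth"]
    basal = small_world["basal"]
    basal_map = small_world["basal_map"]
    sets = make_perturbation_dataset(truth)
    high, low = partition_by_quality(sets)
    records = [rs.to_record() for rs in high]
    viability = make_viability_dataset(truth, noise_std=0.0)
    smiles = dict(truth.smiles)
    sup = SupervisedData(records=records, basal=basal_map,
                         viability=viability, drug_smiles=smiles)
    model = DrugResponseModel(
        sup, ae_profiles=basal.values.T, gene_ids=list(basal.gene_ids),
        doses=spec.doses,
        tasks=("dgx_regression", "dgx_binary", "viability"))
    cfg = TrainConfig(epoch_max=10, lr=3e-3, rng_seed=3,
                      tasks=("dgx_regression", "dgx_binary", "viability"))
    results = model.fit(method="joint", cfg=cfg)
    return {"results": results, "records": records, "low": low, "sup": sup,
            **small_world}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
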