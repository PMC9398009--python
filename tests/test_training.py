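"""Training procedures: null updates, determinism, descent, augmentation."""

import numpy as np
import pytest

from perturbcast.model import DrugResponseModel
from perturbcast.synthetic_data import WorldSpec, make_perturbation_dataset, make_world
from perturbcast.data_core import partition_by_quality
from perturbcast.training import (
    SupervisedData,
    TrainConfig,
    teacher_student_augment,
    train_joint,
    train_pretrain_finetune,
)


@pytest.fixture(scope="module")
def micro_world():
    spec = WorldSpec(n_genes=24, n_cells=6, n_clusters=2, n_drugs=4,
                     doses=(0.1, 1.0), rng_seed=11)
    basal, _, truth = make_world(spec)
    basal_map = {c: basal.values[:, j] for j, c in enumerate(basal.sample_ids)}
    sets = make_perturbation_dataset(truth)
    high, low = partition_by_quality(sets)
    records = [rs.to_record() for rs in high]
    sup = SupervisedData(records=records, basal=basal_map)
    model = DrugResponseModel(sup, ae_profiles=basal.values.T,
                              gene_ids=list(basal.gene_ids), doses=spec.doses,
                              d_model=8, d_embed=8, d_hidden=16,
                              gcn_dims=(8,), d_attn=6, d_dose=4)
    return {"model": model, "sup": sup, "low": low, "ae": basal.values.T,
            "basal_map": basal_map}


def _snapshot(params):
    return [p.data.copy() for p in params.all_parameters()]


def test_zero_learning_rate_changes_nothing(micro_world):
    model = micro_world["model"]
    params = model.make_params(0)
    before = _snapshot(params)
    train_joint(params, micro_world["ae"], micro_world["sup"],
                TrainConfig(epoch_max=2, lr=0.0, rng_seed=0))
    after = _snapshot(params)
    for b, a in zip(before, after):
        np.testing.assert_array_equal(b, a)


def test_zero_lr_pretrain_finetune(micro_world):
    model = micro_world["model"]
    params = model.make_params(0)
    before = _snapshot(params)
    train_pretrain_finetune(params, micro_world["ae"], micro_world["sup"],
                            TrainConfig(epoch_max=1, lr=0.0, rng_seed=0))
    for b, a in zip(before, _snapshot(params)):
        np.testing.assert_array_equal(b, a)


def test_seeded_runs_are_identical(micro_world):
    model = micro_world["model"]
    h = []
    for _ in range(2):
        params = model.make_params(1)
        tm = train_joint(params, micro_world["ae"], micro_world["sup"],
                         TrainConfig(epoch_max=3, lr=1e-3, rng_seed=4))
        h.append(tm.history)
    assert h[0] == h[1]


def test_supervised_loss_descends(micro_world):
    model = micro_world["model"]
    params = model.make_params(2)
    tm = train_joint(params, micro_world["ae"], micro_world["sup"],
                     TrainConfig(epoch_max=6, lr=3e-3, rng_seed=0))
    losses = [e["dgx_regression"] for e in tm.history]
    assert losses[-1] < losses[0]


def test_reconstruction_loss_descends(micro_world):
    model = micro_world["model"]
    params = model.make_params(3)
    tm = train_pretrain_finetune(params, micro_world["ae"], micro_world["sup"],
                                 TrainConfig(epoch_max=6, lr=3e-3, rng_seed=0))
    recon = [e["recon_loss"] for e in tm.history if e["phase"] == "pretrain"]
    assert recon[-1] < recon[0]


def test_disabling_ae_pass_removes_reconstruction_updates(micro_world):
    model = micro_world["model"]
    params = model.make_params(4)
    tm = train_joint(params, micro_world["ae"], micro_world["sup"],
                     TrainConfig(epoch_max=2, lr=1e-3, rng_seed=0),
                     ae_enabled=False)
    assert all("recon_loss" not in e for e in tm.history)


def test_empty_datasets_rejected(micro_world):
    model = micro_world["model"]
    params = model.make_params(5)
    with pytest.raises(ValueError):
        train_joint(params, np.zeros((0, 24)), micro_world["sup"],
                    TrainConfig(epoch_max=1))
    with pytest.raises(ValueError):
        train_joint(params, micro_world["ae"],
                    SupervisedData(records=[], basal={}), TrainConfig(epoch_max=1))


# ---------------------------------------------------------------------------
# teacher-student augmentation
# ---------------------------------------------------------------------------

def test_unreachable_threshold_never_augments(micro_world):
    model = micro_world["model"]
    cfg = TrainConfig(epoch_max=2, lr=1e-3, rng_seed=0, n_augment_iters=2,
                      similarity_threshold=1.0)
    tm = teacher_student_augment(model.make_params, micro_world["ae"],
                                 micro_world["sup"], micro_world["low"], cfg)
    iters = [e for e in tm.history if "augment_iter" in e]
    assert all(e["n_pseudo"] == 0 for e in iters)
    assert all(e["n_train"] == len(micro_world["sup"].records) for e in iters)


def test_minimal_threshold_augments_everything(micro_world):
    model = micro_world["model"]
    cfg = TrainConfig(epoch_max=2, lr=1e-3, rng_seed=0, n_augment_iters=1,
                      similarity_threshold=-1.0)
    tm = teacher_student_augment(model.make_params, micro_world["ae"],
                                 micro_world["sup"], micro_world["low"], cfg)
    iters = [e for e in tm.history if "augment_iter" in e]
    assert iters[-1]["n_pseudo"] == len(micro_world["low"])


def test_pseudo_labels_are_predictions_not_measurements(micro_world):
    """The augmented label must be the model prediction, never the noisy
    experimental consensus."""
    from perturbcast.training import predict_records

    model = micro_world["model"]
    cfg = TrainConfig(epoch_max=2, lr=1e-3, rng_seed=0, n_augment_iters=1,
                      similarity_threshold=-1.0)
    seen = {}

    captured = {}
    orig_train = train_joint

    def capture(params, ae, sup, cfg_, dev_data=None):
        captured["records"] = list(sup.records)
        return orig_train(params, ae, sup, cfg_, dev_data=dev_data)

    import perturbcast.training as T
    T_train = T.train_joint
    T.train_joint = capture
    try:
        teacher_student_augment(model.make_params, micro_world["ae"],
                                micro_world["sup"], micro_world["low"], cfg)
    finally:
        T.train_joint = T_train
    aug_records = captured["records"][len(micro_world["sup"].records):]
    assert aug_records  # everything admitted at threshold -1
    low_by_key = {rs.key: rs for rs in micro_world["low"]}
    for rec in aug_records:
        consensus = low_by_key[rec.key].consensus()
        assert not np.allclose(rec.dgx, consensus)


def test_augmented_keys_are_unique(micro_world):
    model = micro_world["model"]
    cfg = TrainConfig(epoch_max=1, lr=1e-3, rng_seed=0, n_augment_iters=3,
                      similarity_threshold=-1.0)
    tm = teacher_student_augment(model.make_params, micro_world["ae"],
                                 micro_world["sup"], micro_world["low"], cfg)
    iters = [e for e in tm.history if "augment_iter" in e]
    n_low = len(micro_world["low"])
    assert all(e["n_pseudo"] <= n_low for e in iters)


def test_threshold_validation(micro_world):
    model = micro_world["model"]
    cfg = TrainConfig(epoch_max=1, similarity_threshold=2.0)
    with pytest.raises(ValueError):
        teacher_student_augment(model.make_params, micro_world["ae"],
                                micro_world["sup"], micro_world["low"], cfg)
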