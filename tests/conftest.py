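import numpy as np
import pytest

from grnpairs import (GenePairLabel, ModelConfig, PairClassifier, SyntheticSpec,
                      generate_corpus, sample_negatives, split_by_gene)
from grnpairs.dataset import image_sets_from_corpus
from grnpairs.model import build_model
from grnpairs import nn


# small image geometry used throughout the tests: 40x16 frames concatenate
# to 32x40 inputs, which the small_cnn backbone accepts (height % 16 == 0)
TINY = dict(img_width=40, img_height=16, n_regions=4,
            images_per_gene_per_orientation=(1, 2), noise_sd=3.0,
            global_scale_range=(0.6, 2.4))


@pytest.fixture(scope="session")
def tiny_corpus():
    """20-gene corpus: 5 TFs x 15 targets with planted edges."""
    spec = SyntheticSpec(n_tfs=5, n_targets=15, interaction_density=0.2,
                         seed=7, **TINY)
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def tiny_sets(tiny_corpus):
    return image_sets_from_corpus(tiny_corpus)


@pytest.fixture(scope="session")
def tiny_pairs(tiny_corpus):
    spec = tiny_corpus.spec
    positives = [GenePairLabel(t, g, 1) for t, g in sorted(tiny_corpus.truth_edges)]
    negatives = sample_negatives(spec.tf_ids, spec.target_ids,
                                 tiny_corpus.truth_edges,
                                 tiny_corpus.medium_edges, 1.0, seed=13)
    return positives + negatives


@pytest.fixture(scope="session")
def random_net():
    """Untrained small_cnn in eval mode: a deterministic nonconstant scorer."""
    cfg = ModelConfig(backbone="small_cnn", in_channels=1, head_dropout=0.0)
    return build_model(cfg, input_hw=(32, 40), seed=42)


def make_constant_stub(c: float, input_hw=(32, 40)) -> nn.Network:
    """small_cnn whose output is the constant probability c for any input."""
    cfg = ModelConfig(backbone="small_cnn", in_channels=1, head_dropout=0.0)
    net = build_model(cfg, input_hw=input_hw, seed=0)
    final = [lyr for lyr in net.layers() if isinstance(lyr, nn.Linear)][-1]
    final.params["w"][:] = 0.0
    final.params["b"][:] = np.log(c / (1.0 - c))
    return net.eval()


@pytest.fixture(scope="session")
def constant_stub():
    return make_constant_stub(0.7)


# ---------------------------------------------------------------------------
# the trained-model fixture shared by the signal-recovery, occlusion and
# acceptance tests (one real training run per session)

RECOVERY_SPEC = SyntheticSpec(
    n_tfs=16, n_targets=48, n_regions=4, img_width=80, img_height=32,
    images_per_gene_per_orientation=(1, 2), interaction_density=0.12,
    noise_sd=4.0, global_scale_range=(0.6, 2.4), seed=20260921)

RECOVERY_SEEDS = {"negatives": 101, "split": 5, "init": 3, "train": 7}


def recovery_training_setup(spec=RECOVERY_SPEC, seeds=RECOVERY_SEEDS):
    from grnpairs.dataset import enumerate_instances

    corpus = generate_corpus(spec)
    sets = image_sets_from_corpus(corpus)
    positives = [GenePairLabel(t, g, 1) for t, g in sorted(corpus.truth_edges)]
    negatives = sample_negatives(spec.tf_ids, spec.target_ids,
                                 corpus.truth_edges, corpus.medium_edges, 1.0,
                                 seeds["negatives"])
    pairs = positives + negatives
    plan = split_by_gene(pairs, 0.8, 0.1, seed=seeds["split"])
    tr, va = [], []
    for p in plan.train_pairs:
        tr += enumerate_instances(p, sets[p.tf_id], sets[p.target_id])
    for p in plan.val_pairs:
        va += enumerate_instances(p, sets[p.tf_id], sets[p.target_id])
    return corpus, sets, pairs, plan, tr, va


def recovery_train_config(seed=RECOVERY_SEEDS["train"], epochs=40):
    from grnpairs import TrainConfig
    return TrainConfig(learning_rate=0.01, momentum=0.9, epochs=epochs,
                       batch_size=32, seed=seed, lr_decay_epochs=(25, 33),
                       class_weight="balanced")


@pytest.fixture(scope="session")
def recovery_run():
    """Train small_cnn on the low-noise planted corpus (the expensive fixture)."""
    corpus, sets, pairs, plan, tr, va = recovery_training_setup()
    clf = PairClassifier(ModelConfig(backbone="small_cnn", in_channels=1),
                         input_hw=(64, 80), seed=RECOVERY_SEEDS["init"])
    results = clf.fit(tr, va, sets, recovery_train_config())
    return {"corpus": corpus, "sets": sets, "pairs": pairs, "plan": plan,
            "results": results}
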