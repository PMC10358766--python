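import copy

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stt_eeg.eeg_io import Epoch, EpochGroup, epoch_recording, group_epochs
from stt_eeg.model import ModelConfig
from stt_eeg.synth import SynthSpec, generate_corpus
from stt_eeg.train import TrainConfig, ablation_channels, run_cv

settings.register_profile(
    "fast", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("fast")


def corpus_groups(spec: SynthSpec, seed: int = 42) -> list[EpochGroup]:
    epochs = []
    for rec in generate_corpus(spec):
        epochs.extend(epoch_recording(rec))
    return group_epochs(epochs, seed=seed)


@pytest.fixture(scope="session")
def tiny_corpus_groups() -> list[EpochGroup]:
    """Small ternary corpus: 2 subjects x 3 clips of 32 s -> 12 groups."""
    spec = SynthSpec(n_subjects=2, clips_per_class=1, clip_s=32.0, seed=123)
    return corpus_groups(spec, seed=123)


@pytest.fixture(scope="session")
def study_groups() -> list[EpochGroup]:
    """The reduced study corpus: 8 subjects, default class effects."""
    return corpus_groups(SynthSpec(n_subjects=8, seed=42), seed=42)


@pytest.fixture(scope="session")
def study_model_cfg() -> ModelConfig:
    return ModelConfig(n_classes=3, D=32, L=2, n_heads=2, seed=1)


@pytest.fixture(scope="session")
def study_train_cfg() -> TrainConfig:
    return TrainConfig(seed=7)


@pytest.fixture(scope="session")
def study_ablation(study_groups, study_model_cfg, study_train_cfg):
    """Channel-ablation table on the study corpus (shared across tests)."""
    return ablation_channels(study_groups, study_model_cfg, study_train_cfg, k=3)


@pytest.fixture(scope="session")
def shuffled_label_report(study_groups, study_model_cfg, study_train_cfg):
    """CV report after destroying the label-signal association."""
    rng = np.random.default_rng(5)
    labels = np.array([g.label for g in study_groups])
    rng.shuffle(labels)
    shuffled = []
    for g, lab in zip(study_groups, labels):
        eps = [copy.copy(e) for e in g.epochs]
        for e in eps:
            e.label = int(lab)
        shuffled.append(EpochGroup(eps, int(lab)))
    return run_cv(shuffled, study_model_cfg, study_train_cfg, k=3)


def make_dummy_groups(n_per_label: int, labels=(-1, 1), n_subjects: int = 4):
    """Featureless groups for split/metric plumbing tests."""
    groups = []
    for lab in labels:
        for i in range(n_per_label):
            ep = Epoch(np.zeros((4, 2)), start_s=float(i), label=lab,
                       subject_id=f"s{i % n_subjects}")
            groups.append(EpochGroup([ep], lab))
    return groups
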