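import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppbn.synthetic import GeneratorConfig, build_calibrated_matrix, simulate_sequence

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def generator_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def calibrated_matrix(generator_config) -> np.ndarray:
    return build_calibrated_matrix(generator_config)


@pytest.fixture(scope="session")
def long_simulation(calibrated_matrix, generator_config):
    """One million epochs from the calibrated chain; shared across tests."""
    return simulate_sequence(calibrated_matrix, 1_000_000, seed=1,
                             epoch_seconds=generator_config.epoch_seconds)


@pytest.fixture(scope="session")
def medium_simulation(calibrated_matrix, generator_config):
    """200k epochs, used for transition-probability recovery checks."""
    return simulate_sequence(calibrated_matrix, 200_000, seed=2,
                             epoch_seconds=generator_config.epoch_seconds)


@pytest.fixture(scope="session")
def shuffled_label_accuracies():
    """Held-out accuracies of classifiers trained on label-shuffled data.

    Predictions from one shuffled classifier are correlated across test
    items (they share the same scrambled centroids), so chance behaviour is
    a statement about the *expectation over shuffles*; this fixture returns
    one accuracy per independent random permutation.
    """
    from ppbn.classification import classify, train_classifier
    from ppbn.pipeline import RunConfig, _features
    from ppbn.predictor import CORE_POSTURES
    from ppbn.synthetic import render_posture_image

    cfg = RunConfig(noise=0.1, seed=123)
    gen = GeneratorConfig(image_noise_sd=0.1, seed=123)
    rng = np.random.default_rng(123)
    train_feats, train_labels = [], []
    for label in CORE_POSTURES:
        for k in range(20):
            img = render_posture_image(label, gen, seed=k)
            train_feats.append(_features(img, cfg))
            train_labels.append(label)
    test = [(label, _features(render_posture_image(label, gen, seed=50_000 + k), cfg))
            for label in CORE_POSTURES for k in range(50)]

    accuracies = []
    for _ in range(20):
        shuffled = [train_labels[i] for i in rng.permutation(len(train_labels))]
        clf = train_classifier(train_feats, shuffled, temperature=cfg.temperature)
        hits = 0
        for label, feat in test:
            probs = classify(clf, feat)
            if max(probs, key=probs.get) == label:
                hits += 1
        accuracies.append(hits / len(test))
    return np.array(accuracies)


def batch_se(x: np.ndarray, n_batches: int = 100) -> float:
    """Monte-Carlo standard error of the mean of a correlated 0/1 series,
    by non-overlapping batch means."""
    x = np.asarray(x, dtype=float)
    usable = (len(x) // n_batches) * n_batches
    means = x[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))
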