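import numpy as np
import pytest

import peakshaper as ps
from peakshaper.features import featurize
from peakshaper.model import train

BENCH_TRAIN_SEED = 1
BENCH_TEST_SEED = 2
BENCH_MODEL_SEED = 0


def bench_config(seed: int) -> ps.SimulationConfig:
    """The synthetic benchmark: 1 Mb, 200 planted peaks, folds 5-20."""
    return ps.SimulationConfig(
        n_chroms=1,
        chrom_length=1_000_000,
        background_rate=1.0,
        n_peaks=200,
        peak_width_range=(300, 600),
        fold_range=(5.0, 20.0),
        fragment_length=100,
        shape_mix=1.0,
        seed=seed,
    )


def _bundles_and_labels(track, truth):
    labeled = ps.make_training_set(track, truth)
    bundles = [featurize(track, region) for region, _ in labeled]
    labels = [label for _, label in labeled]
    return bundles, labels


@pytest.fixture(scope="session")
def bench_train():
    track, truth = ps.simulate_track(bench_config(BENCH_TRAIN_SEED))
    bundles, labels = _bundles_and_labels(track, truth)
    return {"track": track, "truth": truth, "bundles": bundles, "labels": labels}


@pytest.fixture(scope="session")
def bench_test():
    track, truth = ps.simulate_track(bench_config(BENCH_TEST_SEED))
    bundles, labels = _bundles_and_labels(track, truth)
    return {"track": track, "truth": truth, "bundles": bundles, "labels": labels}


@pytest.fixture(scope="session")
def bench_scorer(bench_train):
    return train(bench_train["bundles"], bench_train["labels"], seed=BENCH_MODEL_SEED)


@pytest.fixture(scope="session")
def bench_model_dir(bench_scorer, tmp_path_factory):
    path = tmp_path_factory.mktemp("model") / "bundle"
    ps.save_models(bench_scorer, path)
    return path


def constant_track(value: float, length: int = 10_000, chrom: str = "chr1") -> ps.CoverageTrack:
    return ps.CoverageTrack([chrom], {chrom: np.full(length, float(value))})
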