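import numpy as np
import pytest

import cellfp


@pytest.fixture(scope="session")
def four_class_split():
    """Simulated 4-phenotype benchmark (30 samples/class at 950 MHz),
    preprocessed and 70/30 stratified-split.  Shared by the slower tests."""
    design = cellfp.four_class_design(1, n_per_class=30)
    spectra, truth = cellfp.simulate_dataset(design)
    matrix = cellfp.preprocess(spectra).normalized
    labels = {s: spectra.meta[s].label_str for s in spectra.sample_ids}
    train, valid = cellfp.split_train_validation(
        spectra.sample_ids, [labels[s] for s in spectra.sample_ids], 0.7, seed=1)
    return {
        "spectra": spectra, "truth": truth, "matrix": matrix, "labels": labels,
        "X_train": matrix.rows(train).values,
        "y_train": [labels[s] for s in train],
        "X_valid": matrix.rows(valid).values,
        "y_valid": [labels[s] for s in valid],
    }


@pytest.fixture()
def tiny_spectra_set():
    """Three flat-ish spectra on a short shared descending grid."""
    ppm = np.linspace(9.0, -0.4, 200)
    rng = np.random.default_rng(0)
    spectra = [cellfp.Spectrum(ppm, rng.normal(1.0, 0.1, ppm.size), f"s{i}")
               for i in range(3)]
    meta = [cellfp.SampleMeta(f"s{i}", "hek", 950.0, "cpmg") for i in range(3)]
    return cellfp.SpectraSet(spectra, meta)


def make_blobs(rng, centers, n_per, scale=0.3):
    """Gaussian blobs with string labels; returns (X, labels)."""
    X, y = [], []
    for name, c in centers.items():
        X.append(np.asarray(c) + scale * rng.normal(size=(n_per, len(c))))
        y += [name] * n_per
    return np.vstack(X), np.array(y)
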