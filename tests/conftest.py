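import numpy as np
import pytest

from wolfscan.synthetic import PhantomSpec, generate_dataset, generate_image
from wolfscan.trainers import featurize_images


@pytest.fixture(scope="session")
def phantom_dir(tmp_path_factory):
    """100 phantom DICOMs (50 PD / 50 HC) with 10 injected blanks."""
    out = tmp_path_factory.mktemp("phantoms")
    spec = PhantomSpec(seed=3, blank_fraction=0.1)
    manifest = generate_dataset(spec, 50, 50, out)
    return out, manifest


@pytest.fixture(scope="session")
def phantom_features():
    """Featurized non-blank phantom images split 60/40 train/validation."""

    def make(seed: int, n: int = 60):
        spec = PhantomSpec(seed=seed)
        rng = np.random.default_rng(seed)
        images, labels = [], []
        for i in range(n):
            label = "PD" if i % 2 else "HC"
            pixels, _, _ = generate_image(spec, label, rng, blank=False)
            images.append((pixels / 16).astype(np.uint8))
            labels.append(label)
        X = featurize_images(np.asarray(images))
        y = np.asarray(labels)
        k = int(0.6 * n)
        return (X[:k], y[:k]), (X[k:], y[k:])

    return make
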