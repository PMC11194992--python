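"""Desk-scale trainers satisfying the hyperparameter-search contract.

A trainer is any callable ``trainer(hp, train, validation, seed)`` that
returns ``{"loss": float, "accuracy": float}`` measured on the validation
set and is deterministic given identical seed and inputs.  Two are bundled:

* `make_toy_trainer` — a closed-form response surface, unimodal in the
  learning rate, for optimizer-recovery checks with a known optimum;
* `TinyImageTrainer` — a small neural network (scikit-learn MLP, Adam,
  log loss) on pooled pixel features, so the search runs end-to-end on
  phantom images in seconds rather than at GPU scale.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["make_toy_trainer", "TinyImageTrainer", "featurize_images"]


def make_toy_trainer(optimal_lr: float = 0.003, width: float = 0.35):
    """A trainer whose validation accuracy is a known function of lr only.

    accuracy = 1 - min(1, ((log10 lr - log10 lr*) / width)^2), a smooth
    unimodal bump peaking at ``optimal_lr`` with value exactly 1.
    """

    def trainer(hp, train, validation, seed):
        lr = float(hp["learning_rate"])
        z = (np.log10(lr) - np.log10(optimal_lr)) / width
        accuracy = 1.0 - min(1.0, z * z)
        return {"loss": 1.0 - accuracy, "accuracy": accuracy}

    return trainer


def featurize_images(images: np.ndarray, pool: int = 16) -> np.ndarray:
    """Mean-pool grayscale images to a ``pool x pool`` feature grid in [0,1]."""
    images = np.asarray(images, dtype=float)
    if images.ndim == 4:  # (N, H, W, C) -> grayscale
        images = images.mean(axis=-1)
    n, h, w = images.shape
    bh, bw = h // pool, w // pool
    trimmed = images[:, : bh * pool, : bw * pool]
    pooled = trimmed.reshape(n, pool, bh, pool, bw).mean(axis=(2, 4))
    return pooled.reshape(n, -1) / 255.0


class TinyImageTrainer:
    """MLP on pooled pixel features; hyperparameters map onto Adam training.

    learning_rate -> Adam step size; batch_size -> minibatch size;
    momentum -> Adam beta_1 when >= 0.9, otherwise ignored (Adam has no
    classical momentum); dense_units -> hidden sizes (d, d // 2);
    epochs -> training iterations.
    """

    def __init__(self, pool: int = 8):
        self.pool = pool
        self.calls = 0

    def __call__(self, hp, train, validation, seed):
        from sklearn.neural_network import MLPClassifier

        self.calls += 1
        X_train, y_train = train
        X_val, y_val = validation
        if X_train.ndim > 2:
            X_train = featurize_images(X_train, self.pool)
            X_val = featurize_images(X_val, self.pool)
        # standardize with train-set statistics only
        mu, sd = X_train.mean(axis=0), X_train.std(axis=0) + 1e-9
        X_train = (X_train - mu) / sd
        X_val = (X_val - mu) / sd
        momentum = float(hp.values.get("momentum", 0.9))
        beta_1 = momentum if momentum >= 0.9 else 0.9
        d1 = int(hp.values.get("dense_units", 256))
        clf = MLPClassifier(
            hidden_layer_sizes=(max(2, d1 // 32), max(2, d1 // 64)),
            solver="adam",
            learning_rate_init=float(hp["learning_rate"]),
            beta_1=min(beta_1, 0.999),
            batch_size=min(int(hp.values.get("batch_size", 32)), len(y_train)),
            max_iter=int(hp.values.get("epochs", 20)),
            random_state=seed,
            alpha=1e-4,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny budgets rarely converge fully
            clf.fit(X_train, y_train)
        proba = np.clip(clf.predict_proba(X_val)[:, 1], 1e-12, 1 - 1e-12)
        y_bin = (np.asarray(y_val) == clf.classes_[1]).astype(float)
        loss = float(-np.mean(y_bin * np.log(proba) + (1 - y_bin) * np.log(1 - proba)))
        accuracy = float(np.mean(clf.predict(X_val) == np.asarray(y_val)))
        return {"loss": loss, "accuracy": accuracy}
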