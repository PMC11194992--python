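"""Tune training hyperparameters with grey wolf optimization.

A toy trainer whose validation accuracy is a known unimodal function of
the learning rate (peak at 0.003) is searched with a 5-wolves x 5-iterations
budget over the standard ranges (learning rate 0.001-0.01, batch size
32-128, momentum 0.9-0.99, dense units 128-512, epochs 10-50).  The
optimizer should land within a few percent of the known optimum; the
evaluation log shows every decoded assignment it tried.
"""

from wolfscan.gwo import GWOConfig
from wolfscan.hpsearch import HyperParamSpace, search
from wolfscan.trainers import make_toy_trainer

trainer = make_toy_trainer(optimal_lr=0.003)
best, result, log = search(
    trainer, HyperParamSpace(), GWOConfig(n_wolves=5, n_iterations=5, seed=0),
    data=(None, None),
)

print(f"evaluations: {len(log)} (unique trainer calls: {(~log.cache_hit).sum()})")
print(f"best assignment: {best.values}")
print(f"best validation accuracy: {1 - result.best_fitness:.4f}")
err = abs(best['learning_rate'] - 0.003) / 0.003
print(f"learning-rate error vs known optimum: {100 * err:.1f}%")
print("(the search moves in continuous space; integers like batch size are")
print(" rounded only when an assignment is decoded for the trainer)")
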