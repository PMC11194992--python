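"""Build the hybrid architecture and inspect its feature-map contract.

The hybrid model chains a VGG16 backbone (13 convolutions, five pools)
into two inception-reduction blocks and a global-average-pooled head.
Shape inference runs without any deep-learning framework; the printed
trace is the architectural contract each block must honour:
7x7x512 -> 7x7x640 -> 3x3x832 -> pooled 1024 -> one sigmoid unit.
"""

from wolfscan.models import build_hybrid, build_model, infer_shapes

spec = build_hybrid()
shapes = infer_shapes(spec)
print(f"hybrid model: {len(spec.layers)} layers on input {spec.input_shape}")
for block, boundary in spec.blocks.items():
    print(f"  {block:>12}: {shapes[boundary]}")

print("\nall five architectures end in a single sigmoid unit:")
for name in ("vgg16", "densenet", "densenet_lstm", "inceptionv3", "hybrid"):
    m = build_model(name)
    print(f"  {name:>14}: output {infer_shapes(m)[m.layers[-1].name]}")
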