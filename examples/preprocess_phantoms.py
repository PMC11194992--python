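"""Generate phantom DICOMs and run the preprocessing pipeline on them.

One hundred two-class head phantoms are written (10% deliberately blank),
then converted, filtered by the mean-intensity-below-30 empty-slice rule,
skull-stripped, resized to 224x224x3 and split 80:20 (then 80:20 again)
into train/validation/test.  The retained count should be exactly the 90
non-blank images, and the split sizes follow the floor convention.
"""

import tempfile
from pathlib import Path

from wolfscan.preprocess import PipelineConfig, run_pipeline
from wolfscan.synthetic import PhantomSpec, generate_dataset

with tempfile.TemporaryDirectory() as tmp:
    raw = Path(tmp) / "raw"
    generate_dataset(PhantomSpec(seed=3, blank_fraction=0.1), 50, 50, raw)
    manifest = run_pipeline(
        PipelineConfig(input_dir=str(raw), output_dir=str(Path(tmp) / "proc"), seed=0)
    )
    print(f"retained {len(manifest.records)} images, "
          f"filtered {len(manifest.filtered)} blanks")
    print(manifest.counts().to_string())
    print("\n(test = floor(0.2*90) = 18; validation = floor(0.2*72) = 14;")
    print(" every retained image is 224x224x3 with the skull ring masked in)")
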