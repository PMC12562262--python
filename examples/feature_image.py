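"""Turn one synthetic heart-sound recording into its 64x64x3 MFCC image.

Generates a 10 s murmur-positive phonocardiogram at 2 kHz, extracts the
MFCC/delta/double-delta image both branches of the classifier consume, and
prints its geometry and channel statistics.
"""

import numpy as np

from pcgvit import FeatureConfig, SynthConfig, make_feature_image
from pcgvit.synth import generate_recording, make_profile

cfg = SynthConfig(seed=0)
profile = make_profile("demo-subject", "abnormal", cfg, np.random.default_rng(0))
record = generate_recording(profile, cfg, seed=42, duration=10.0)
print(f"recording: {record.duration:.1f} s at {record.rate} Hz, label={record.label}")

image = make_feature_image(record, FeatureConfig())
print(f"feature image shape: {image.shape}  (frames x coefficients x channels)")
for name, ch in zip(("MFCC", "delta", "double-delta"), range(3)):
    print(f"  {name:12s} min {image[..., ch].min():9.2f}  max {image[..., ch].max():8.2f}")
# A 10 s recording fills 19 of the 64 frames; the remainder is the constant
# silent-frame cepstrum, so the image geometry is duration-independent.
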