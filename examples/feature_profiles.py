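"""Recover the per-understanding feature profile through the full pipeline.

For each understanding level u in {2..5}, simulate 100 texts, run event
detection and feature extraction, and print the mean of the four
normalized features: f1 (fixations/char), f2 (forward saccades/char),
f3 (backward saccades/char) and f4 (sd of saccade velocities, px/ms).
f1 and f4 fall with understanding while f3 rises - the signal the
understanding estimator learns from.
"""

import numpy as np

from gazeread import TextStimulus, compute_feature_vector, detect_events, simulate_recording
from gazeread.simulate import ReaderParams

text = TextStimulus("demo", n_chars=210)
print("  u     f1     f2     f3     f4")
for u in (2, 3, 4, 5):
    params = ReaderParams.for_understanding(float(u))
    feats = []
    for k in range(100):
        rec = simulate_recording(text, params, seed=100 * u + k)
        feats.append(compute_feature_vector(detect_events(rec), text.n_chars).as_array())
    f1, f2, f3, f4 = np.mean(feats, axis=0)
    print(f"  {u}  {f1:.3f}  {f2:.3f}  {f3:.3f}  {f4:.3f}")
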