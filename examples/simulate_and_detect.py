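"""Simulate one reading-gaze recording and detect its oculomotor events.

A virtual reader with understanding u = 3 ("understood part of the
content") reads a 210-character text; the raw 90 Hz gaze stream is then
segmented with the dispersion-threshold (I-DT) detector.
"""

import numpy as np

from gazeread import TextStimulus, detect_events, simulate_recording
from gazeread.simulate import ReaderParams

text = TextStimulus("demo", n_chars=210, level="N4")
params = ReaderParams.for_understanding(3.0)
recording = simulate_recording(text, params, seed=1)
events = detect_events(recording)

durations = [f.duration for f in events.fixations]
velocities = [s.velocity for s in events.saccades]
print(f"samples recorded        : {len(recording)}")
print(f"fixations detected      : {len(events.fixations)}")
print(f"mean fixation duration  : {np.mean(durations):.1f} ms")
print(f"forward / backward sacc.: {events.n_forward} / {events.n_backward}")
print(f"mean saccade velocity   : {np.mean(velocities):.3f} px/ms")

# The backward saccades combine within-line regressions (rereading) with
# the return sweeps at line ends; their count rises, and the fixation
# count falls, as understanding improves.
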