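"""How estimation accuracy degrades when fewer texts are available.

For each text count k, every participant's texts are subsampled to k
(participants with fewer texts keep all of theirs), re-aggregated and
LOPO-evaluated; MAEs are averaged over 20 random subsets. Fewer texts
mean noisier participant averages, so the error grows as k shrinks.
"""

from gazeread import (
    SyntheticCohortSpec,
    evaluate_vs_text_count,
    extract_features,
    simulate_cohort,
)

cohort = simulate_cohort(SyntheticCohortSpec(seed=42))
profiles = extract_features(cohort.manifest, cohort.recordings)
curve = evaluate_vs_text_count(profiles, counts=[2, 5, 10, 19], n_repeats=20, seed=42)

print("texts  gaze-MAE  answers-MAE")
for k, maes in curve.items():
    print(f"{k:5d}   {maes['gaze']:.3f}     {maes['answers']:.3f}")
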