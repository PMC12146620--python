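"""Vagus-nerve afferent activity: normalized peak frequency after injection.

Simulates a 45 s nerve recording (20 kHz) whose Poisson firing rate triples
inside the evoked window, then runs the chain: 50 Hz high-pass ->
spontaneous-state normalization -> peak counting between the spontaneous
median + 2 SD and + 5 SD lines (larger peaks are excluded as artifacts) ->
per-second rates.
"""

from gbsig import synth
from gbsig.ephys import analyze_recording

params = synth.ephys_default_params(seed=0, evoked_multiplier=3.0)
rec, truth = synth.gen_ephys(params)
res = analyze_recording(rec)

print(f"baseline rate (30 s pre):       {res.baseline_rate:6.2f} peaks/s")
print(f"post rate ([2, 4) s):           {res.post_rate:6.2f} peaks/s")
print(f"normalized peak frequency:      {res.normalized_frequency:6.2f} "
      f"(true evoked multiplier {truth.true_rate_ratio:.0f})")
print(f"peaks excluded by the +5 SD rule: {res.excluded_artifacts:4d} "
      f"(all {len(truth.artifact_times)} injected artifacts plus the "
      "amplitude-jitter tail of unit peaks)")

print()
print("The normalized peak frequency is the post/pre ratio of per-second"
      " counted peaks; values near the true multiplier show the counting"
      " band recovers the evoked rate change. The +5 SD exclusion is"
      " stationary, so it cancels in the post/pre ratio.")
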