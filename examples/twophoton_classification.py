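"""Two-photon single-cell classification: Increase / Decrease / Nonresponse.

Simulates 200 cells drawn from a (0.2, 0.5, 0.3) mixture, classifies each
cell against its own baseline (+/- 0.5 SD inside the 15-38 s window), and
reports per-animal proportions plus class-average waveform metrics.
"""

import numpy as np

from gbsig import synth
from gbsig.twophoton import analyze_cells

params = synth.twophoton_default_params(seed=1)
traces, truth = synth.gen_twophoton(params, 200)
times = np.arange(traces.shape[1]) / params.sampling_rate \
    - params.t_injection

labels, proportions, metrics = analyze_cells(traces, times)

row = proportions.iloc[0]
print(f"proportions: Increase {row.Increase:.2f}, "
      f"Decrease {row.Decrease:.2f}, Nonresponse {row.Nonresponse:.2f} "
      f"(generator mix {params.cell_mix})")
acc = np.mean(labels.label.to_numpy() == np.array(truth.cell_labels))
print(f"agreement with ground-truth labels: {100 * acc:.1f}%")
for cls, m in metrics.items():
    print(f"{cls}: onset {m.onset:.1f} s, peak {m.peak_time:.1f} s, "
          f"HWHM {m.hwhm:.1f} s")

print()
print("A cell is 'Increase' if any sample inside 15-38 s post-injection"
      " exceeds its baseline mean + 0.5 SD, 'Decrease' below -0.5 SD;"
      " the Decrease onset lags the Increase onset by ~9 s by design.")
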