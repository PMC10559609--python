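"""The consecutive-duration video rule and its strict boundary.

A clip is cancer iff some run of consecutive positive frames lasts
strictly longer than 2 s: 50 positive frames at 25 fps (exactly 2.00 s)
is non-cancer; 51 frames (2.04 s) is cancer.
"""

from laryngoscreen import diagnose_video, select_duration_threshold

for n in (50, 51):
    d = diagnose_video([True] * n, fps=25, duration_threshold=2.0)
    print(f"{n} consecutive positives at 25 fps -> longest run "
          f"{d.longest_run_seconds:.2f} s, cancer: {d.is_cancer}")

# a single negative frame breaks the run
seq = [True] * 30 + [False] + [True] * 30
d = diagnose_video(seq, fps=25)
print(f"30+1gap+30 frames -> longest run {d.longest_run_frames} frames "
      f"({d.longest_run_seconds:.2f} s), cancer: {d.is_cancer}")

# duration-threshold selection: persistent lesions (~2.6-3 s) vs
# transient artefacts (~1.6-2 s)
import numpy as np

rng = np.random.default_rng(0)
runs = np.r_[rng.uniform(2.6, 3.0, 20), rng.uniform(1.6, 2.0, 20)]
truth = np.r_[np.ones(20, bool), np.zeros(20, bool)]
selected, table = select_duration_threshold(runs, truth)
print(table.to_string(index=False))
print(f"selected duration threshold: {selected} s")
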