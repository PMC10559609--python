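"""Build the full diagnostic-statistics report for a reader-study table.

Reconstructs the 200-video comparison set (120 cancer / 80 non-cancer
clips; 114 true positives, 74 true negatives) and prints the five
screening metrics with both Wald and exact Clopper-Pearson 95% CIs, a
McNemar comparison against a second reader, and Cohen's kappa.
"""

from laryngoscreen import build_report, compare_paired_classifiers
from laryngoscreen.experiments import competition_report

report = competition_report(ci_method="wald")
print("Wald intervals (as printed in screening reports):")
print(report.to_markdown())

report_cp = competition_report(ci_method="clopper_pearson")
print("\nExact Clopper-Pearson intervals (wider near the boundaries):")
print(report_cp.to_markdown())

# Compare against a hypothetical expert reader: 193/200 correct
truth = [True] * 120 + [False] * 80
system = [True] * 114 + [False] * 6 + [True] * 6 + [False] * 74
expert = ([True] * 116 + [False] * 4 + [True] * 3 + [False] * 77)
b, c, p = compare_paired_classifiers(system, expert, truth)
print(f"\nMcNemar vs expert: discordant pairs b={b} c={c}, two-sided p={p:.3f}")
print("(p > 0.05: no evidence the system and the expert differ)")
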