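"""Published aligned/total trajectory counts from the three experiments.

These count ratios are the recomputable level of the behavioural results
(the raw per-participant data were not deposited). Each entry gives the
number of test trajectories classified as copying the aligned (or named)
demonstrator, the total analysed, and the proportion as printed. The
proportions and the accompanying binomial tests are recomputed from the
counts by the analysis code; nothing here is an output of this package.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PrintedCount:
    label: str
    k: int
    n: int
    printed_proportion: float
    printed_p: str  # as printed, e.g. "<0.001" or "0.523"


PRINTED_COUNTS = (
    # Experiment 1: copies of the preference-aligned agent
    PrintedCount("exp1_aligned", 126, 144, 0.875, "<0.001"),
    # Experiment 2, known-agents phase (pooled across conditions)
    PrintedCount("exp2_known_agents", 414, 600, 0.690, "<0.001"),
    # Experiment 2, unknown-agents phase per condition
    PrintedCount("exp2_irrelevant_cue_invisible", 63, 120, 0.525, "0.523"),
    PrintedCount("exp2_irrelevant_cue_arbitrary", 57, 120, 0.475, "0.648"),
    PrintedCount("exp2_relevant_cue_invisible", 98, 124, 0.790, "<0.001"),
    PrintedCount("exp2_relevant_cue_matched", 91, 116, 0.784, "<0.001"),
    PrintedCount("exp2_relevant_cue_mismatched", 83, 120, 0.692, "<0.001"),
    # Experiment 3: per context x own-cue condition
    PrintedCount("exp3_colour_cue_invisible", 63, 87, 0.724, "<0.001"),
    PrintedCount("exp3_colour_cue_arbitrary", 55, 90, 0.611, "0.0263"),
    PrintedCount("exp3_shape_cue_invisible", 60, 87, 0.690, "<0.001"),
    PrintedCount("exp3_shape_cue_arbitrary", 68, 90, 0.756, "<0.001"),
)
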