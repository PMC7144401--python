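"""Objective sleepiness summaries: proportions, MVV and the ASS cascade.

Constructs interpretable 20-minute stage sequences and shows how the
mean vigilance value and arousal stability score respond.
"""

from somnostat import Stage, StageSequence, summarize_arousal

examples = {
    "rigid wakefulness (only 0/A1)":
        [Stage.STAGE_0] * 300 + [Stage.A1] * 900,
    "drowsy decline (B emerges minute 7, 40% B1)":
        [Stage.A1] * 360 + [Stage.B1] * 480 + [Stage.A1] * 360,
    "sleep onset in minute 9":
        [Stage.A1] * 420 + [Stage.B23] * 90 + [Stage.C] * 30
        + [Stage.B23] * 300 + [Stage.B1] * 360,
}

for name, labels in examples.items():
    s = summarize_arousal(StageSequence.from_labels(labels))
    print(f"{name}:")
    print(
        f"  proportions 0/A/B/C = "
        f"{s.prop_0:.2f}/{s.prop_a:.2f}/{s.prop_b:.2f}/{s.prop_c:.2f}"
        f"  MVV = {s.mvv:.2f}  ASS = {s.ass}"
    )

print(
    "\nMVV averages the per-second scores (stage 0 = 7 ... C = 1); the ASS "
    "drops from 11 (rigid) toward 1 as lower stages appear more and earlier."
)
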