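"""Score the subjective instruments and derive group membership."""

from somnostat import classify_group, compute_ssq, delta_scores, score_ess

total, eds = score_ess([2, 3, 1, 2, 1, 2, 1, 1])
print(f"ESS total {total} (excessive daytime sleepiness: {eds})")

ssq = compute_ssq([4, 4, 3, 4, 3, 3, 4, 4])
print(f"subjective sleep quality (restedness mean): {ssq:.2f} on 1-5")

print(f"KSS change after 20 min eyes closed: {delta_scores(4, 6, 'kss'):+d}")

for bmi, bdi in [(23.5, 4), (36.0, 8), (24.0, 22), (41.0, 30)]:
    print(f"BMI {bmi:5.1f}, BDI-II {bdi:2d} -> group {classify_group(bmi, bdi)}")

print(
    "\nAn ESS above 10 flags excessive daytime sleepiness; BMI >= 30 and "
    "BDI-II >= 14 define the obese and depressed strata, whose cross gives "
    "the four analysis groups."
)
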