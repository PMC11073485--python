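"""Apply the published fixed decision rules for low-LVEF screening.

The two rules combine the systolic intrinsic frequency omega1 (bpm) with
either (age, phi1) or the HR-normalised index omegai1.  The thresholds
are 107.6 bpm, 6 years, -0.65 rad, and 1.6 / 1.22.
"""

from ifscreen.screening import classify_fixed_tree_A, classify_fixed_tree_B

print("Rule A — omega1 / age / phi1:")
for w1, age, phi1 in [(100, 10, -1.0), (120, 12, 0.0), (120, 4, -0.8), (120, 4, 0.0)]:
    label, path = classify_fixed_tree_A(w1, age, phi1)
    verdict = "LOW LVEF" if label else "normal"
    print(f"  omega1={w1:5.1f} age={age:4.1f} phi1={phi1:+5.2f} -> {verdict:8s} [{' / '.join(path)}]")

print("Rule B — omega1 / omegai1 (age-universal):")
for w1, wi1 in [(90, 1.7), (150, 1.1), (110, 1.3), (100, 1.3)]:
    label, path = classify_fixed_tree_B(w1, wi1)
    verdict = "LOW LVEF" if label else "normal"
    print(f"  omega1={w1:5.1f} omegai1={wi1:4.2f} -> {verdict:8s} [{' / '.join(path)}]")

print("An elevated systolic intrinsic frequency flags reduced ejection")
print("fraction; normalising by heart rate (omegai1) makes one rule work")
print("across the whole pediatric age range.")
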