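"""Score letter grades as best-k tariff points and z-score them by entry year.

A-levels are scored A = 10, B = 8, C = 6, D = 4, E = 2 and summed over the
best three grades, so AAA = 30 is the ceiling that produces right-censorship
in selected cohorts.
"""

from clpv import DEFAULT_TARIFFS, GradeProfile, score_best_k, zscore_by_group

tariff = DEFAULT_TARIFFS["A-level"]
students = {
    "s1": ("A", "A", "A"),
    "s2": ("A", "B", "C", "D"),   # four grades: the best three count
    "s3": ("C", "C", "C"),
    "s4": ("B", "B"),             # incomplete profile: summed and flagged
}

points = {}
for name, grades in students.items():
    s = score_best_k(GradeProfile(grades, "A-level"), tariff)
    points[name] = s.points
    flag = "" if s.complete else f"  (only {s.n_graded} grades)"
    print(f"{name}: {grades} -> {s.points} points{flag}")

years = {"s1": 2007, "s2": 2007, "s3": 2008, "s4": 2008}
z = zscore_by_group([(points[n], years[n]) for n in students])
print("\nwithin-year z-scores (mean 0, SD 1 per entry year):")
for name, zi in zip(students, z):
    print(f"{name}: z = {zi:+.3f}")
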