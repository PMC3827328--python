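"""The range-restriction/unreliability correction chain on worked numbers.

An entrant-pool correlation of .20 looks unimpressive, but with a predictor
reliability of .80 in applicants, an outcome reliability of .84 in entrants,
and a selection ratio of .656 (entrant SD about two-thirds of applicant SD),
the implied construct-level correlation in the applicant pool is about .50.
"""

from clpv import hsl_case_iv, restrict_reliability, equivalent_n

r_i, r_XXa, r_YYi, u = 0.20, 0.80, 0.84, 0.656

r_XXi = restrict_reliability(r_XXa, u)
rho = hsl_case_iv(r_i, r_XXa, r_YYi, u)
print(f"entrant correlation          r_i   = {r_i:.3f}")
print(f"restricted reliability       r_XXi = {r_XXi:.3f}")
print(f"construct-level validity     rho   = {rho:.3f}")

# identity check: with perfect measures and no selection, nothing changes
print(f"identity (rel = 1, u = 1):   {hsl_case_iv(0.3, 1, 1, 1):.3f} == 0.300")

# an SE of .06 on that rho corresponds to a plain-correlation study of ~178
print(f"equivalent N for SE = .06:   {equivalent_n(rho, 0.06):.1f}")
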