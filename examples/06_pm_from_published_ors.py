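"""Proportion mediated from published odds-ratio pairs.

Given a total-effect OR and a natural-indirect-effect OR from any mediation
table, PM = log(OR_NIE)/log(OR_TE). These pairs come from a published
survey analysis of sexual-assault experience, substance use and depression.
"""

import survmediate as sm

published = [
    ("women, lifetime SAE, tobacco -> depression",     3.43, 1.02),
    ("women, lifetime SAE, cannabis -> depression",    4.09, 1.23),
    ("men, childhood SAE, alcohol -> depression",      1.52, 1.16),
    ("men, childhood SAE, tobacco -> depression",      1.48, 1.21),
    ("women, lifetime SAE, depression -> tobacco",     1.72, 1.10),
    ("men, lifetime SAE, depression -> tobacco",       2.67, 1.14),
    ("women, lifetime SAE, depression -> cannabis",    3.99, 1.45),
]

for label, or_te, or_nie in published:
    pm = sm.proportion_mediated(or_nie, or_te)
    print(f"{label:<48} TE={or_te:<5} NIE={or_nie:<5} PM={100 * pm:5.1f}%")

print()
print("PM is the fraction of the total exposure effect (log-OR scale)")
print("attributable to the pathway through the mediator.")
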