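"""Enumerate the contributor combinations consistent with a mixed stain,
using only categorical (IUPAC-coded) information."""

import mtmix as M
from mtmix import fixtures

db = fixtures.table1_database()
profs = fixtures.table1_profiles()

# A stain showing the 16093 variant in full and mixed bases (both variant
# and reference signal) at 16189 and 16293.
stain = M.parse_mixture("16093 16189Y 16293R")
outcome = M.enumerate_contributors(db, stain, m=2)
print("stain 1 outcome:", outcome.status.value)
for sol in outcome.solutions:
    print("  solution:", sol)
# -> a unique two-contributor explanation: H21 + H22.

# A mixture generated by H22 and H23 is categorically ambiguous: a second,
# different pair explains exactly the same pattern.
stain2 = M.MixtureObservation.from_contributors((profs["H22"], profs["H23"]))
outcome2 = M.enumerate_contributors(db, stain2, m=2)
print("\nstain 2 outcome:", outcome2.status.value)
for sol in outcome2.solutions:
    print("  solution:", sol)
# Resolving this ambiguity needs quantitative data (see example 03).
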