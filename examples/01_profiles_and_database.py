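"""Parse haplotype profiles, load the bundled database excerpt and look at
counting-proportion frequencies."""

import mtmix as M
from mtmix import fixtures

# A profile is the set of positions where a lineage differs from the rCRS.
# Bare numbers are transitions; letter-flanked tokens make ref/alt explicit.
suspect = M.parse_profile("T16126C C16292T C16294T A16399G", 16024, 16569)
print("suspect profile:", M.format_profile(suspect))
print("positions:", sorted(suspect.positions))

# The bundled excerpt has 9 rows; two print the same profile, so there are
# 8 distinct lineages. Frequencies are exact rationals (counts / total).
db = fixtures.table1_database()
print(f"\ndatabase: {db.total} samples, {db.k} distinct profiles")
for prof, freq in db.frequencies().items():
    print(f"  {M.format_profile(prof):30s} {freq}")

# An unseen haplotype has no counting frequency; the add-one convention
# (favorable to the defendant) adds the query once before counting.
query = M.parse_profile("16069")
print("\nadd-one frequency of unseen '16069':",
      M.frequency(db, query, M.UnseenPolicy.ADD_ONE))
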