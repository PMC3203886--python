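"""Weigh mixture evidence as likelihood ratios: forensic hypotheses,
informativeness of a random mixture, and the clinical contamination LR."""

from fractions import Fraction

import mtmix as M
from mtmix import fixtures, report

# Known contributor (e.g. a typed victim) plus the suspect's lineage vs an
# unknown lineage: LR = 1 / p(suspect haplotype). With p estimated as 1/11:
lr1 = M.lr_known_contributor(suspect_frequency=Fraction(1, 11))
print(report.render_lr_text(lr1))

# A suspect haplotype unseen in 2575 profiles, added once (add-one):
big = M.HaplotypeDatabase.from_counts([(M.parse_profile("16093"), 2575)])
case = fixtures.example3_case()
lr2 = M.lr_known_contributor(big, case.suspect,
                             unseen_policy=M.UnseenPolicy.ADD_ONE)
print("\nLR for the unseen suspect haplotype:", lr2.lr)

# Two unknown contributors: the named pair vs two random lineages.
lr3 = M.lr_two_unknown(pair_frequencies=(Fraction(1, 11), Fraction(1, 11)))
print("pair LR (p1 = p2 = 1/11):", float(lr3.lr))

# How often is a random 2-person mixture informative at all?
db = fixtures.table1_database()
p_inf = M.prob_informative(list(db.frequencies().values()), m=2)
print("\nP(informative 2-person mixture) =", p_inf, "=", float(p_inf))

# Clinical: 8 heteroplasmic positions, 100 candidate phylogenetic sites,
# contaminating haplotype frequency 0.01 -> overwhelming support for
# contamination over genuine tumor instability.
scenario = M.ContaminationScenario(S=100, x=8, p_c=Fraction(1, 100))
lr4 = M.contamination_lr(scenario)
print(f"contamination LR = {lr4.lr_float:.3g} "
      f"(log10 = {lr4.log10_lr:.1f})")
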