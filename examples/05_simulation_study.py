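"""Replicate the quantitative simulation study: fraction recovery, model
discrimination by R^2, and robustness to ignored dropout."""

import mtmix as M
from mtmix import fixtures

db = fixtures.table1_database()
profs = fixtures.table1_profiles()
true_pair = (profs["H22"], profs["H23"])
competitor = [(profs["H1263"], profs["H2135"])]

# 1000 replicates at the calibrated noise level (sigma = 0.08): simulate
# peak heights from H22 (30%) + H23 (70%), fit both candidate pairs, count
# how often the true pair wins the R^2 comparison.
summary = M.run_study(db, true_pair, competitor, beta=0.3,
                      n_sims=1000, seed=1)
print(f"correct-model rate: {summary.correct_rate:.1%}")
print(f"beta_hat mean {summary.beta_mean:.3f}, "
      f"central 95% [{summary.beta_q025:.3f}, {summary.beta_q975:.3f}]")
# The rate is ~99% and the estimates are consistent with the true 0.3.

# Generate with dropout (and a little drop-in) but keep estimating with the
# no-dropout regression: discrimination degrades slowly.
sweep = M.dropout_sweep(db, true_pair, competitor, beta=0.3,
                        d_grid=[0.01, 0.02, 0.03, 0.04],
                        n_sims=500, seed=1)
print("\ndropout sweep (no-dropout estimation):")
for _, row in sweep.iterrows():
    print(f"  d = {row.dropout:.2f}: correct rate {row.correct_rate:.1%}")
# The correct-identification rate stays above 80% for d < 0.05.
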