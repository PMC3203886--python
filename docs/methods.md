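# Methods

## Setting and data model

Mitochondrial DNA is a single, non-recombining marker: every maternal
relative carries the same sequence, so evidence attaches to *lineages*, never
to individuals. A lineage is represented as its set of variant positions
relative to the revised Cambridge Reference Sequence (rCRS) over a declared
typing window, by default HVS-I positions 16024–16365. A bare position in a
profile string denotes a transition with respect to the rCRS base (A↔G,
C↔T); `T16304C`-style tokens make ref/alt explicit and admit transversions.
Profile identity — collapsing database rows, counting frequencies,
deconvolution — is the position set alone.

A stain is coded per position as reference-only, variant-only, or mixed,
the mixed state carried by a two-base IUPAC ambiguity suffix (`Y` = C/T,
`R` = A/G). Codes covering more than two bases are accepted and flagged;
a code whose decoded bases both differ from the rCRS base is reported as a
reference-mismatch warning (error in strict mode), since one of the two
signals should normally be the reference. Optionally each site carries a
scaled variant peak height `y1` with the convention `y0 + y1 = 1`, so only
the variant height is modeled.

A curated table of rCRS bases at the commonly reported control-region
polymorphic positions is bundled for transition implication and IUPAC
validation. Positions absent from the table still parse and take part in all
arithmetic; they simply carry no base-level annotation and skip IUPAC
validation. Heteroplasmy is signal-identical to a mixture at a single site
and is not modeled separately.

## Categorical deconvolution

Under the no-dropout/no-drop-in assumption, a contributor multiset is
consistent with a stain iff every mixed position has at least one carrier and
one non-carrier among the contributors, every variant-only position is
carried by all, and no contributor carries a variant at a reference-only
position. The search enumerates all unordered m-multisets of distinct
database profiles exhaustively (guarded at m ≤ 4 and 10 000 distinct
profiles unless overridden); identical contributors are only admissible when
the stain has no mixed site, i.e. the mixture is unidentifiable. Known
contributors (a typed victim) are fixed members of every candidate set —
they constrain the search, their signal is never subtracted. Outcomes are
three-valued: no solution (suggesting contamination or a non-exhaustive
database), unique, or multiple. `superset_solutions` documents the
larger-m ambiguity: any profile whose variants all fall inside the stain's
visible positions (variant-only plus mixed) can hide behind an existing
solution. No phylogenetic plausibility filtering is attempted; reports carry
an advisory instead.

## Quantitative deconvolution

With two haploid contributors carrying indicator vectors x1, x2 over the
site design and mixing fraction β, the scaled variant height satisfies

    y_i = β·x1_i + (1−β)·x2_i + ε_i,

rewritten as the one-parameter no-intercept regression
y_i − x2_i = β(x1_i − x2_i) + ε_i, whose least-squares solution is the
closed form

    β̂ = Σ_i (y_i − x2_i)(x1_i − x2_i) / Σ_i (x1_i − x2_i)².

The standard error, the t-test of "contributor j did not contribute"
(H0: β = 0, or β = 1 for contributor 2) with n − 1 degrees of freedom, and
the conventional R² follow from ordinary least squares. Competing candidate
pairs — typically the several solutions of an ambiguous categorical search —
are ranked by R², largest first; fits within 1e−9 are reported as an
unresolved tie. Numerical choices:

* R² uses the centered total sum of squares, 1 − SS_res/SS_tot, clipped to
  [0, 1] with a flag when the fit is worse than the site mean; only the
  relative comparison between pairs matters for ranking, and centering
  penalizes both pairs identically. Whether an uncentered form would change
  any ranking was checked to be immaterial for same-y comparisons.
* Sites where the pair's indicators agree (x1 = x2, including the
  quantitative table's reference pseudo-row) carry no information about β;
  they are retained in the sums of squares and the error-variance estimate
  to mirror the full printed design.
* An identical pair (zero denominator) raises a degenerate-model error:
  the fraction is unidentifiable.
* β̂ is reported unclamped with an out-of-range flag; clamping would distort
  the simulation-study distributions.
* Errors are treated as homoscedastic ordinary-least-squares errors at
  inference time even though generation truncates them; fraction estimates
  remain valid under mild violation, while p-values and intervals are
  approximate.

## Evidence: likelihood ratios

All LRs are P(E|H_num)/P(E|H_den) for explicitly stated hypotheses, with
frequencies as exact rationals from plain counting (no coancestry/θ or
confidence-interval corrections). With a known contributor and the suspect's
lineage asserted under the numerator only, LR = 1/p with p the suspect
haplotype frequency. An unseen haplotype may be handled by the add-one
convention (add the query once before counting, giving 1/(total+1)),
regarded as favorable to the defendant. For two unknown contributors the
denominator is 2·p1·p2 for distinct profiles (both orderings of an iid draw;
the factor is configurable to 1) and p² for identical ones.

The probability that a random m-person mixture is informative (not all
contributors sharing a haplotype) is 1 − Σ_j p_j^m, with a Monte-Carlo
estimator for cross-checking.

For the clinical setting — x heteroplasmic positions that could be tumor
instability or contamination — the instability likelihood places x mutations
among S candidate phylogenetic sites. Two null placements are exposed
because the choice is genuinely open: independent uniform placement,
(1/S)^x (the default, matching the stated independence/uniformity
assumption), and a uniformly chosen set of x distinct sites, 1/C(S, x) (the
conservative alternative, never smaller). The contamination LR is
p_c / (mutation likelihood), with p_c the contaminating haplotype's
frequency, or a sum over candidate haplotypes; an empty candidate list
dismisses contamination outright (LR = 0 with an explanatory status). S has
deliberately no default: choosing a conservative lower limit is a
case-specific judgment the caller must make explicitly.

## Generative simulator

Theoretical heights t_i = β·x1_i + (1−β)·x2_i receive additive normal noise
truncated so the final height stays in [0, 1]. Truncation is by rejection
(resample until admissible), preserving a genuinely truncated distribution;
clipping is available as an option, and truncation can be disabled to study
the untruncated regression null. The extended generator adds per-site,
per-contributor dropout (a carried variant is zeroed with probability d,
with no renormalization — the lost signal is simply missing, as when an
allele fails to amplify) and drop-in (probability c of a spurious height at
a site carried by neither contributor; the spurious height defaults to a
fresh |N(0, σ)| draw since no magnitude convention exists). With d = c = 0
no dropout random numbers are consumed, so the extended generator is
bit-identical to the plain one at the same seed. All randomness flows from
one root seed through deterministically spawned per-replicate streams.

### Noise calibration

The per-site noise sd σ is the generator's one free parameter. It was fixed
by `scripts/calibrate_noise.py`: a grid search (σ ∈ 0.06–0.10, step 0.0025,
1000 replicates each, fixed seed) scoring each σ by the distance of the
correct-model rate and the 2.5%/97.5% fraction quantiles from the reference
summaries (98.9%, 0.22, 0.37) of the two-pair discrimination study. The
minimizer, σ = 0.08, is the package default. Notably, β̂ over the 11-site
design averages four informative sites, so sd(β̂) ≈ σ/2; a much smaller σ
(e.g. 0.02, the magnitude suggested by the single printed realization of the
quantitative table) would concentrate the estimates in ≈[0.28, 0.32] and
push discrimination to 100%, inconsistent with all three reference
summaries. The bundled realized column thus looks less noisy than the
calibrated generator; the calibration follows the replicated summaries, not
the single draw.

### Study harness and problem sizes

`run_study` simulates n replicates from the true pair over the full
quantitative site design (reference pseudo-row plus the union of database
positions — 11 sites for the bundled excerpt), fits every candidate pair
with the plain no-dropout regression, and summarizes the fraction estimates
(mean, 2.5%/97.5% quantiles, linear-interpolation convention) and the rate
at which the true pair attains the strictly largest R². Defaults: 1000
replicates for the discrimination study; the dropout sweep uses
d ∈ {0.01, …, 0.04} with 500 replicates each and drop-in fixed at c = 0.01
(a realistic small value; no convention for c exists, and the qualitative
conclusion is insensitive to it). These sizes give binomial standard errors
of ~0.3–1 percentage point on the reported rates.

## What the simulator does and does not emulate

It emulates scaled, single-figure peak heights per site with independent
homoscedastic truncated-normal noise, site-independent dropout/drop-in, and
frequencies from an idealized database. It does not emulate electropherogram
traces or background noise, preferential amplification (PCR bias distorting
proportions along the amplicon), correlated errors between sites, length
heteroplasmy around 16182–16193, more than two quantitative contributors,
or population substructure in the database. Passing tests therefore show
internal correctness of the estimators and their stated robustness to the
modeled perturbations — not validity of the noise model for any particular
sequencing chemistry.

## Known limitations

* The quantitative model is strictly two-contributor.
* Frequency estimation is plain counting; database-size and substructure
  uncertainty are not propagated into the LRs.
* Categorical search treats variant-only calls strictly (a variant-only
  position shared by all contributors is never reinterpreted as a missed
  mixed call).
* Phylogenetic plausibility of candidate sets must be reviewed by an
  expert; the package only says so.
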