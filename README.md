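# mtmix

Statistical interpretation of mitochondrial DNA mixtures: combinatorial
deconvolution of a mixed control-region profile against a haplotype
database, quantitative deconvolution from peak heights, and
likelihood-ratio evidence evaluation for forensic and clinical casework.

mtDNA is often the only usable genetic evidence in degraded or low-template
samples (hair shafts, aged stains), and mtDNA mixtures also arise in tumor
studies where apparent "instability" patterns may in fact be contamination.
Because mtDNA is a single non-recombining marker, all maternal relatives
share one haplotype, so every statement here concerns *lineages*, not
individuals. `mtmix` is aimed at forensic geneticists and at clinical
researchers who need to weigh a contamination explanation against a
biological one.

## What it computes

**Categorical deconvolution.** A stain is coded per rCRS position as
reference-only, variant-only, or mixed (IUPAC codes: `16189Y` means both C
and T are seen at 16189). Given a haplotype database assumed to contain all
plausible contributors, the package enumerates every m-contributor
combination consistent with the stain under the no-dropout assumption. The
outcome is no solution, unique, or multiple.

**Quantitative deconvolution.** With scaled variant peak heights
(y₀ + y₁ = 1 at each site), a two-contributor mixture follows

    yᵢ = β·x₁ᵢ + (1−β)·x₂ᵢ + εᵢ,

where x₁, x₂ are the contributors' binary variant indicators and β is the
fraction contributed by contributor 1. The least-squares estimate

    β̂ = Σᵢ (yᵢ − x₂ᵢ)(x₁ᵢ − x₂ᵢ) / Σᵢ (x₁ᵢ − x₂ᵢ)²

comes with a standard error, a t-test of "contributor j did not contribute",
and the conventional R² used to rank competing contributor pairs — which can
resolve mixtures that are categorically ambiguous.

**Evidence.** Likelihood ratios LR = P(E|H₁)/P(E|H₂) with haplotype
frequencies as exact rationals from counting (optionally with the add-one
convention for unseen haplotypes); the probability 1 − Σ pⱼᵐ that a random
m-person mixture is informative; and the clinical contamination-vs-
instability LR = p_c / (1/S)ˣ for x heteroplasmic positions among S
candidate phylogenetic sites.

**Simulation.** A generative peak-height simulator (truncated-normal noise,
optional dropout and drop-in) and a replication harness for parameter-
recovery and model-discrimination studies.

## Worked example

The bundled database excerpt (`mtmix.fixtures.table1_database()`) holds nine
HVS-I profiles, eight distinct. A stain shows the 16093 variant in full and
mixed bases at 16189 and 16293:

```python
import mtmix as M
from mtmix import fixtures

db = fixtures.table1_database()
stain = M.parse_mixture("16093 16189Y 16293R")
outcome = M.enumerate_contributors(db, stain, m=2)
print(outcome.status.value)          # unique
print(outcome.solutions[0])          # 16093 + 16093 16189 16293
```

The only two-contributor explanation is H21 (`16093`) + H22
(`16093 16189 16293`). With the suspect haplotype frequency estimated as
1/11, the known-contributor likelihood ratio is

```python
from fractions import Fraction
print(M.lr_known_contributor(suspect_frequency=Fraction(1, 11)).lr)  # 11
```

— the evidence is 11 times more likely if the suspect's lineage contributed
than if an unknown lineage did. A mixture of H22 and H23 is categorically
ambiguous (a second pair, H1263 + H2135, explains the same pattern), but
peak heights resolve it:

```python
profs = fixtures.table1_profiles()
sites, y = fixtures.table2_sites(), fixtures.table2_y()
true_pair = M.TwoContributorModel.build(profs["H22"], profs["H23"], sites=sites)
est = M.estimate_fraction(y, true_pair)
print(round(est.beta_hat, 3), round(est.r_squared, 4))   # 0.295 0.9987
```

The fitted fraction 0.295 recovers H22's 30% share, and the competing pair
fits the same heights at R² = 0.9062 — the largest R² identifies the true
explanation. Replicating this comparison 1000 times at the calibrated noise
level (`examples/05_simulation_study.py`) prints:

```
correct-model rate: 99.3%
beta_hat mean 0.298, central 95% [0.220, 0.377]
```

Each `examples/0*.py` script is a short narrative of one capability:
profiles and frequencies, categorical search, fraction estimation, LRs
(including the clinical contamination LR, which reaches 10¹⁴ for eight
heteroplasmic positions explained by a contaminant of frequency 0.01), and
the simulation study. A thin CLI mirrors the library, e.g.

```sh
mtmix deconvolve --db table1_excerpt --stain example1 --m 2
mtmix lr known --db-size 2575 --suspect-unseen --add-one   # LR = 2576
mtmix contaminate --s 100 --x 8 --pc 0.01                  # LR = 1e+14
```

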