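# resistsurv

Survival analysis of insecticide-resistance evolution in herbivorous crop
pests.

Pest populations evolve resistance to insecticides at wildly different
speeds — some within a few years of a product's registration, others not in
seventy.  A long-standing idea (the pre-adaptation hypothesis) is that the
machinery insects evolved against their host plants' defensive chemistry is
co-opted against synthetic insecticides, which predicts that resistance
should come faster to diet generalists and to insecticides that chemically
resemble the phytochemicals already in a pest's diet.  `resistsurv` is a
pipeline for testing those predictions on pest × insecticide interaction
records: it builds the chemical predictor (a fingerprint-based similarity
index), assembles right-censored time-to-resistance data, and fits three
complementary survival models.  It is written for evolutionary ecologists
and resistance-management researchers who have curated trait, registration
and resistance-report tables and want the full modelling chain — including
a synthetic-data generator that makes every stage testable with no
downloads.

## The models

For pest *i* and insecticide *j*, the record is (duration, event): years
from the insecticide's registration to the earliest documented resistance
(event = 1) or to the censor year 2020 (event = 0).

**Chemical predictor.**  Each compound's SMILES is hashed to a 1024-bit
path fingerprint; the index for a pair is the maximum Tanimoto similarity
max_p |A_j ∩ A_p| / |A_j ∪ A_p| over the phytochemicals *p* occurring in
pest *i*'s host plants.

**Mixed-effect proportional hazards (main model).**

    h_ij(t) = h0(t) · exp( β₁·diet + β₂·diet² + β₃·sim + β₄·sim²
                           + β₅·volt + β₆·volt² + β₇·doc + β₈·haplo
                           + b_moa(j) + b_fam(i) + b_sp(i) )

with log-transformed, centered, range-scaled diet breadth and
documentation, centered range-scaled voltinism, the similarity index raw on
[0, 1], and Gaussian random effects for insecticide mode of action and
species nested within taxonomic family.  Fitted by penalized partial
likelihood (Efron ties) with the variance components profiled by a Laplace
approximation.  A convex diet effect (β₂ > 0) means the fastest resistance
sits at *both* ends of the generalism spectrum; a concave similarity effect
(β₄ < 0) means risk peaks at intermediate chemical similarity.

**Aalen additive hazards** — h(t) = b₀(t) + Σ b_k(t)·x_k, estimated by
least-squares increments at event times — relaxes proportionality, at the
cost of a single random grouping (MoA, as a ridge-shrunken liability
block).

**Random survival forest** — log-rank splits, Nelson–Aalen leaves,
out-of-bag error 1 − Harrell's C, permutation importance — drops all
linearity and fixed/random distinctions.

## Worked example

Generate the default synthetic study (103 species × 72 insecticides under
a known hazard model) and fit the main model:

    python analysis/01_simulate_study.py --seed 17
    python analysis/03_fit_mixed_cox.py

which prints

       term  estimate     se  lower95  upper95       z      p
     x_diet   -0.2619 0.2232  -0.6994   0.1755 -1.1737 0.2405
    x_diet2    5.5272 0.8115   3.9366   7.1178  6.8107 0.0000
      x_sim    0.8668 0.9200  -0.9364   2.6701  0.9422 0.3461
     x_sim2   -2.6298 1.0388  -4.6659  -0.5938 -2.5316 0.0114
     x_volt    0.0957 0.3559  -0.6019   0.7933  0.2689 0.7880
    x_volt2   -0.0176 0.8345  -1.6532   1.6179 -0.0211 0.9831
      x_doc    1.7236 0.2098   1.3124   2.1348  8.2159 0.0000
    x_haplo    0.3188 0.1164   0.0906   0.5469  2.7385 0.0062

    random-effect variances: {'moa_class': 0.356, 'family': 0.275, 'pest_id': 0.111}
    penalized loglik -26738.74, AIC 53724.75, 3276 events / 4140 censored

Read this as the science would be read: the diet-breadth quadratic is
positive and significant (a U-shaped, convex effect — extreme specialists
and extreme generalists evolve resistance fastest), the similarity
quadratic is negative and significant (a hump: risk peaks at intermediate
insecticide–phytochemical similarity), heavily documented pests accrue
resistance reports faster, and mode of action carries the largest random
variance.  The generating truth here was β_diet² = +6, β_sim² = −3,
β_doc = +2, β_haplo = +0.3, var_moa = 0.5 — every recovered estimate is
within two standard errors of it.

The remaining steps fit the additive model
(`analysis/04_fit_additive_hazards.py`), the forest
(`analysis/05_fit_survival_forest.py` — on this study: OOB error 0.300,
forest-vs-Cox prediction correlation r = 0.845), and rank the
not-yet-resistant pairs by consensus risk (`analysis/06_risk_report.py`).
The same engines run on real curated tables via the `resistsurv` CLI
(`simulate`, `chemsim`, `build-dataset`, `fit-cox`, `fit-aalen`,
`fit-forest`, `run`) or the single-config pipeline
(`resistsurv run --config pipeline.yaml`).

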