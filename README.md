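# fracshift

Detection and ranking of treatment-induced protein **redistribution across
fractionation profiles**.

In gradient-fractionation proteomics (e.g. RNase-treated vs. mock-treated
lysates separated on a density gradient, "GradR"-style experiments) every
protein yields an intensity profile over the collected fractions, for several
replicates of two conditions. Proteins whose in-gradient distribution *shifts*
after treatment are candidates for RNA binding or RNA dependence; the same
logic applies to any two-condition fractionation or spatial-proteomics
(compartment) readout. `fracshift` turns a protein × sample-fraction intensity
table into a ranked candidate list with permutation statistics and shift
descriptors.

## Method

Per protein *i*, each replicate's intensity row is smoothed with a uniform
averaging kernel along the fraction axis, then normalized to a probability
distribution P<sub>j</sub><sup>i</sup>(x) over fractions x = 1..F, with
condition means P̂<sub>t</sub><sup>i</sup>(x) for treated (t = +) and control
(t = −).

**Effect size.** The Jensen–Shannon distance with log base 2,

    JSD(P, Q) = sqrt( (D(P‖M) + D(Q‖M)) / 2 ),   M = (P + Q)/2,

where D is the Kullback–Leibler divergence, is a metric bounded in [0, 1]
(0 = identical, 1 = disjoint support). The effect size is
JSD(P̂₊ ‖ P̂₋).

**Significance.** The JSDs of all pairs of replicate profiles form a
per-protein dissimilarity matrix; the rank-based ANOSIM statistic

    R = (r̄_B − r̄_W) / ((n(n−1)/2)/2)

contrasts mean between-condition against within-condition dissimilarity
ranks (midranks for ties, n = total samples), R ∈ [−1, 1]. With two balanced
groups of n replicates there are only (2n)!/(2(n!)²) distinct label
assignments — 10 for 3 vs 3 — so per-protein exact permutation p-values are
floored at 0.1. `fracshift` therefore also pools permuted R values across all
testable proteins into a **global null**, yielding per-protein p-values
(add-one estimator, Benjamini–Hochberg adjusted) and a percentile-based R
cutoff (default: the 95th percentile of the pooled null).

**Shift descriptors.** The position-wise relative entropy
w<sub>t</sub>(x) = P̂<sub>t</sub>(x) log₂(P̂<sub>t</sub>(x)/M(x)) decomposes
D(P̂<sub>t</sub>‖M) over fractions; a temperature-scaled soft-argmax
S<sub>t</sub> = Σ<sub>x</sub> softmax(β·w<sub>t</sub>)(x)·x localizes the
expected position of the strongest shift. The **relative fraction shift**
RPS = S₊ − S₋ is negative for leftward shifts; the **relative distribution
change** RDC = H(P̂₊) − H(P̂₋) (Shannon entropy, bits) is positive when
treatment broadens the distribution. (RPS, RDC, effect JSD) are the
bubble-plot coordinates for candidate triage.

Proteins are ranked by decreasing R, then decreasing effect JSD, then
identifier.

## Worked example

```sh
fracshift simulate --seed 7 --out sim/
fracshift analyze --intensities sim/intensities.tsv --design sim/design.tsv \
                  --seed 7 --out run/
```

prints

```
analyzed 100 proteins (100 testable); R cutoff 0.407407, 29 candidates -> run
```

The simulated dataset contains 100 proteins × 20 fractions × (3+3)
replicates, 20 of which redistribute leftward by 4 fractions
(`sim/truth.tsv` records which). The analysis reports the pooled-null 95th
percentile of R (0.407) as the candidate cutoff; 29 proteins pass — the 20
true shifts (all with R = 1 and large effect JSD at the top of
`run/results.tsv`) plus a handful of grazing false positives, which is
expected for a 95th-percentile cutoff. `run/results.tsv` has one row per
protein:

| column | meaning |
|---|---|
| `protein_id` | identifier from the intensity table's key column |
| `anosim_r` | ANOSIM R (−1..1; 1 = perfect condition separation) |
| `effect_jsd` | JSD between condition-mean profiles (0..1) |
| `relative_fraction_shift` | RPS = S₊ − S₋, in fractions (negative = leftward) |
| `relative_distribution_change` | RDC, entropy difference in bits |
| `rank` | 1 = strongest candidate; empty for untestable proteins |
| `p_global`, `p_adj` | pooled-null permutation p and its BH adjustment |
| `testable_flag` | false when a condition has < 2 valid replicate profiles |

`run/` also contains `candidates.tsv` (rows passing the R cutoff),
`bubble.tsv` (x = RPS, y = RDC, size = effect JSD, for any plotting
front-end), `results.json` (self-contained export incl. profiles and the
stored null, schema version `1.0`) and `manifest.json` (config echo, input
SHA-256 digests, counts). `fracshift cutoff --json run/results.json
--percentile 95` recomputes the cutoff from the stored null.

Input formats: the design table (`sample`, `condition`, `replicate`,
`fraction` columns, optional `order`) names every measurement column of the
intensity table; the intensity table has a protein-id key column and one
non-negative column per design entry; empty/NA cells are missing and are
treated as zero signal before smoothing (the tool performs **no
imputation** — impute upstream if desired; a common eligibility rule keeps
proteins within the 95 percent lowest mean within-condition JSD). For
compartment data pass `--mode categorical`: smoothing is disabled and RPS is
not reported.

Analysis config (TOML, `[analysis]` table; flags override):
`kernel_size` (odd, default 3), `beta` (default 1.0), `permutation_mode`
(`exact`/`monte_carlo`), `n_monte_carlo` (999), `seed`, `cutoff_percentile`
(95), `alpha` (0.05), `include_identity_in_null` (false).

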