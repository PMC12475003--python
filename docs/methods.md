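# Methods

## Model and assumptions

`fracshift` treats each replicate's fractionation profile as a probability
distribution over fractions and asks, per protein, whether the treated and
control distributions differ. The approach is non-parametric throughout: no
peak-shape model is fitted. Its assumptions are (i) profiles are
compositional — only the *shape* over fractions matters, so every profile is
normalized to sum to 1; (ii) replicates of the same condition are exchangeable;
(iii) for the global permutation null, the permuted ANOSIM R values of
different proteins are draws from a common distribution (the same kind of
information-sharing assumption that moderated-statistics tools make across
genes). The test is one-sided: only R above the null (between-condition
separation) counts as evidence.

## Pipeline

1. **Missing values → 0.** A missing intensity is read as NaN and converted
   to zero signal immediately before smoothing. No imputation is performed;
   absence of MS signal is conventionally treated as absence of the protein
   in that fraction. The pipeline logs a warning with the count so users who
   imputed upstream can confirm nothing was silently zeroed.
2. **Smoothing.** Uniform moving average of odd width `kernel_size`
   (default 3 — the smallest window that does any smoothing), zero-padded at
   the gradient edges. Zero padding is chosen over reflected or shrunken
   windows because no protein mass exists outside the measured gradient; the
   mass that leaks into the padding at the boundary is restored by the
   subsequent normalization, so boundary fractions are mildly flattened but
   never inflated. In categorical (compartment) mode the kernel is forced
   to 1: averaging across unordered bins is meaningless.
3. **Normalization.** Division by the vector sum. An all-zero vector cannot
   be normalized; that sample is flagged invalid rather than dropped
   silently. A protein with fewer than 2 valid samples in either condition is
   untestable and carries an explicit reason string. Condition means are
   arithmetic means over the *valid* replicate profiles, keeping them on the
   simplex when a replicate drops out.
4. **Distances.** Jensen–Shannon distance, log base 2 (KL divergence via
   `scipy.special.rel_entr`, which implements the conventions 0·log(0/q) = 0
   and p·log(p/0) = ∞; the infinite branch is unreachable against a mixture).
   The squared divergence is clamped at 0 before the square root to absorb
   rounding at the 1e−17 level. The distance function sits behind a registry
   keyed `"JSD"` so alternates can be added, but only JSD ships.
5. **ANOSIM.** Midranks (average ranks) for tied dissimilarities — the
   standard treatment. Distinct label assignments are enumerated (balanced:
   (2n)!/(2(n!)²), collapsing group-label swaps by fixing sample 0's group;
   unbalanced: all C(n₊+n₋, n₊) combinations); enumeration is used while the
   count is ≤ 10,000, otherwise seeded Monte-Carlo with `n_monte_carlo`
   draws (default 999). Unbalanced replicate counts are accepted everywhere;
   the R denominator uses the total sample count n = n₊ + n₋.
6. **p-values.** Local: share of assignments (identity included) with
   R ≥ R_observed, hence never 0 and floored at 1/#assignments — 0.1 for
   3 vs 3, which is why three replicates can never reach p ≤ 0.05 locally.
   Global: permuted R values pooled across all testable proteins, identity
   assignment *excluded* by default (`include_identity_in_null` re-includes
   it) because observed labelings may carry true signal and would contaminate
   the null. Per-protein p = (1 + #{null ≥ R}) / (1 + N), the add-one
   permutation estimator, keeping p in (0, 1]; Benjamini–Hochberg adjustment
   over testable proteins only. Pooling distinct assignments rather than all
   label *orderings* changes nothing: every distinct assignment would appear
   with equal multiplicity, so all percentiles are identical.
7. **Cutoff.** Linear-interpolation percentile (default 95) of the pooled
   null R values; candidates are testable proteins with R ≥ cutoff.
8. **Shift descriptors.** The mixture M used in the position-wise relative
   entropy w_t is the mixture of the two condition means — the only choice
   under which the w_t guard cases are coherent (M > 0 wherever either mean
   is positive). Soft-argmax uses the max-subtraction trick for overflow
   safety (softmax is shift-invariant, verified by test). RPS sign: treated
   minus control, negative = leftward. RDC sign: treated minus control,
   positive = broader after treatment. In categorical mode S_t and RPS are
   reported as NaN; RDC and effect JSD remain defined.
9. **Ranking.** Decreasing R, then decreasing effect JSD, then ascending
   identifier — a stable total order (mergesort), so the output is invariant
   to input row order. Ties broken by identifier purely for reproducibility.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| `kernel_size` | 3 | fractions | odd; 1 disables smoothing; forced to 1 for categorical axes |
| `beta` | 1.0 | 1/bits | soft-argmax temperature; small β averages over the w landscape (robust, compressed RPS), large β approaches the hard argmax (exact RPS for well-separated peaks). Must be chosen per dataset; RPS magnitudes are only comparable at fixed β |
| `permutation_mode` | exact | — | exact while #assignments ≤ 10,000, else seeded Monte-Carlo |
| `n_monte_carlo` | 999 | draws | per protein, Monte-Carlo mode |
| `cutoff_percentile` | 95 | % | of the pooled null R distribution |
| `alpha` | 0.05 | — | reporting threshold only; no decision logic depends on it |
| `include_identity_in_null` | false | — | see p-values above |

## Synthetic-data generator

The generator emulates the statistical structure of fractionation profiles,
not the MS acquisition process: localized peaks, partial mass shifts,
compositional replicate noise, whole-sample dropout. Defaults (chosen once as
the simulated study conditions): 100 proteins × 20 fractions × 3 + 3
replicates; 20 % of proteins shifted leftward by 4 fractions with their full
mass (φ = 1); discretized Gaussian peaks of width σ = 1.5 fractions (clipped
to the grid and renormalized); replicate profiles drawn from a Dirichlet
centred on the condition mean with concentration 150 (relative SD of a
mid-peak fraction ≈ 7 %, about what well-behaved replicate gradients show);
per-replicate total intensity lognormal around 10⁷; no missing samples unless
requested. `noise=None` makes replicates bit-identical copies of the
condition mean (including scale), so that zero-noise scenarios produce exact
ties and exactly zero distances.

Dirichlet noise is used because normalized profiles live on the simplex;
additive Gaussian noise would leave it. What the generator does **not**
emulate: peptide-level quantification noise, LFQ/iBAQ intensity quirks,
correlated fraction-collection drift, multi-peak (multi-complex) proteins,
and real profiles' irregular shapes. Passing tests on synthetic data
therefore demonstrate the statistics recover the structure they model, not
that any particular biological dataset will behave as cleanly.

Scenario used by the shift-recovery tests ("strong shift"): σ = 1.0,
noiseless, kernel 1, β = 1000. With peaks ≥ 4σ apart the position-wise
relative entropy is maximal at the peaks themselves and RPS equals the
injected distance to within a quarter fraction. For *overlapping* peaks the
strongest-shift position legitimately sits on the peak flank (the likelihood
ratio grows away from the other condition's peak), so RPS then overestimates
small |Δ| at large β and compresses toward 0 at small β — a property of the
definition, not an implementation artifact; the rank correlation between RPS
and Δ stays high (tested: Spearman ≥ 0.9 at concentration 300, β = 10).

## Numerical choices and degenerate inputs

- Exact tie handling everywhere via midranks; an all-tied distance matrix
  gives R = 0 and local p = 1.
- Permutation comparisons use a 1e−12 tolerance when counting R ≥ R_observed
  so that float noise cannot flip a count.
- Problem sizes in the test suite (up to 500 proteins, 4 + 4 replicates,
  20 fractions; 10⁴ random triples for the metric axioms) keep the full suite
  under ~10 s while exercising exact enumeration (35 assignments at 4 v 4)
  and the pooled null at meaningful resolution.
- All-zero proteins, single-valid-replicate conditions and empty datasets are
  flagged, never dropped silently; untestable proteins appear in every output
  with empty statistics and are excluded from the BH denominator.

## Known limitations

- The local exact test is powerless below 4 replicates per condition
  (p floor 0.1 at 3 v 3); the global pooled null trades that power for the
  common-distribution assumption above.
- RPS is only interpretable when the shift is clearly discernible (large R
  and effect JSD); for near-identical distributions the soft-argmax still
  returns a number, which should be ignored — the ranking deliberately leads
  with R and JSD for this reason.
- One distance (JSD), two conditions, no stratified or blocked permutation
  schemes, no imputation, no interactive visualization.
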