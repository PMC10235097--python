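# Methods

## Model and assumptions

The object of analysis is the distribution of per-site information
divergence χ between a methylome and a reference. The package treats
genome-wide background methylation change as a stochastic process in
thermal equilibrium with its cellular environment: maximizing entropy
under a mean-energy constraint gives a Boltzmann law, and the channel
capacity of the methylation machinery (ν = αδ independently moving
parts per operation) constrains the density of states to a power of the
dissipated energy. Together these yield the generalized gamma (GG)
density

    f(χ | α, θ, δ, μ) = α/(θ Γ(δ)) ((χ−μ)/θ)^{αδ−1} e^{−((χ−μ)/θ)^α},

with partition function Z = θΓ(δ)/α, so that Z·f(χ) is the
Boltzmann-weighted density of states (χ/θ)^{αδ−1}e^{−(χ/θ)^α}. On the
energy scale, E = (χ/θ)·k_B·T per operation; a machine at the Landauer
limit has θ = 1/ln2, making one bit cost exactly k_B·T·ln2 (at 310.15 K,
2.466e−21 J per molecule, 1.787 kJ·mol⁻¹).

Key modelling assumptions:

* the system is NVT-closed (no net change in the number or volume of
  DNA molecules over the genomic region analysed) and the machine
  operations leave the internal energy unchanged, so ΔF = −TΔS exactly;
* divergences at different sites are exchangeable draws from one law
  per (sample, chromosome) stratum — linkage between neighbouring
  cytosines is ignored;
* read counts are binomial given the true level, and the two samples
  being compared are sequenced independently.

## Quantities and identities

With ψ the digamma function and φ(α, δ) = ψ(δ)(1/α − δ) + δ:

* Gibbs entropy S = c·[ln(θΓ(δ)/α) + φ(α, δ)], c ∈ {1, k_B, R};
  the first term is S_classic = c·ln Z, the second S_machine = c·φ.
  The location μ never enters (translation invariance of differential
  entropy).
* Shannon entropy H = S/(c·ln2), in bits.
* Helmholtz free energy ΔF = −T·S = −c·T·ln2·H, with the matching
  classic/machine split.
* Information gain between system states I_m = mean(S_before) −
  mean(S_after); ΔΔF = T·I_m. Negative I_m is information loss.
* Boltzmann factors e^{−|S|/c} and e^{−ν} with ν = ⟨χ⟩; feedback model
  e^{−|S|/c} = η(1 − e^{−ν}), its linearization η·ν + c₀, and the
  sum-of-factors constancy ⟨e^{−|S|/c} + e^{−ν}⟩ = η.

The identities S = c·ln2·H, ΔF = −c·T·ln2·H and ΔΔF = T·I_m are exact
algebraically and are enforced in tests at 1e−10 relative tolerance.

Two printed-source discrepancies are handled deliberately. The raw
second moment E[χ²] = (μ²Γ(δ) + 2μθΓ(δ+1/α) + θ²Γ(δ+2/α))/Γ(δ) is
sometimes quoted as a variance; `gg_moments` exposes both
`second_moment` (that expression) and the central `variance`
(E[χ²] − mean²). Likewise the unnormalized state density is implemented
with exponent α, the only choice consistent with Z·f being the density
of states.

## Parameters, units, defaults

| parameter | meaning | default | why |
|---|---|---|---|
| T | absolute temperature | 310.15 K | reconstructing the published ΔΔF/I_m ratios gives exactly 310.15 for every group, including plant data; configurable |
| unit mode | c = R (molar) vs k_B | molar | published entropy tables are in J·K⁻¹·mol⁻¹ |
| divergence | Jeffreys vs Hellinger | jeffreys, bits | the published entropy estimates are J-divergence based; bits match the per-bit energy scale |
| shrinkage | pseudo-count on both outcomes | 0.5 | Jeffreys prior; keeps levels strictly inside (0,1) so the log terms stay finite |
| coverage filter | min/max total reads | 4 / 500 | 500 caps PCR-duplication bias; 4 is a conservative noise floor for level estimation (no published minimum exists) |
| fit floor | minimum χ values per fit | 50 | below this the 3-parameter family is not identifiable in practice |
| fit method | ECDF nonlinear LS vs MLE | ecdf_nls | robust to the heavy right tail of divergence data; MLE available |

Note on the Landauer constant: at 310.15 K, R·T·ln2 = 1787 J·mol⁻¹
(1.787 kJ·mol⁻¹). A frequently quoted value of "1.784" matches this
magnitude at ≈309.65 K; the package always reports the value computed
from CODATA constants at the configured temperature.

## Numerical choices

* **Fitting.** Free parameters are optimized on a log scale
  (Levenberg–Marquardt damped least squares of the model CDF against
  the ECDF at plotting positions (i−½)/n), with moment-matching
  initialization: log-moment matching for the Weibull start
  (sd(log χ) = π/(α√6)), gamma moment matching (δ₀ = m²/v, θ₀ = v/m)
  for the gamma/GG starts, μ₀ = 0.9·min(χ) for the 4-parameter member
  (μ is kept in [0, min χ) by a scaled logistic). Convergence tolerance
  1e−8, 500 iteration budget. Zeros are outside the support and are
  dropped with a logged count.
* **Model selection.** AIC = 2k − 2·loglik evaluated at the fitted
  parameters, ties broken toward fewer parameters. A Gaussian AIC on
  the ECDF residuals was rejected: those residuals are strongly
  autocorrelated, so residual-sum AIC essentially always selects the
  member with the most parameters and drags θ along the GG likelihood
  ridge (≈25% off on pure exponential data); the likelihood-based score
  selects the parsimonious truth and is comparable across fit methods.
* **Degenerate inputs.** Constant vectors, too-few values, empty site
  intersections and unmatched pairings raise typed errors rather than
  returning junk; a non-converged fit is flagged and excluded from
  selection.
* **Feedback fits.** The exp-exp form is constrained to its single
  constant (slope = −intercept = −η) via least squares through the
  origin on (1 − e^{−ν}); the unconstrained two-parameter line is
  reported as a diagnostic whose slope sign flags dysfunction. The
  k-means chromosome split is 1-D on ν (25 restarts, fixed seed,
  default 2 clusters, cutpoint at the midpoint between clusters), with
  an optional 2-D (ν, e^{−|S|/c}) feature space. Feedback regressions
  pool all rows by default; averaging per individual first is available
  upstream by aggregating states before building points.
* **Group tests.** The headline test is a linear mixed model
  entropy ~ group with a chromosome random intercept (REML, Wald p);
  the paired Wilcoxon alternative operates on chromosome-paired group
  means, so with 5 chromosomes its exact two-sided floor is 1/16 —
  reaching smaller p-values requires the mixed model (or pairing at
  replicate level).

## Synthetic data: what it emulates and what it does not

The count-level generator draws true levels from a bimodal beta
mixture (0.7·Beta(1,10) + 0.3·Beta(10,1)), matching the strongly
bimodal shape of real methylomes; coverage from a gamma-mixed Poisson
(mean 30, dispersion 5), matching the overdispersion of sequencing
depth; and per-chromosome random effects on depth (lognormal, σ = 0.1)
and mixture weight (logit jitter, σ = 0.3), because real chromosomes
differ in mappability and in gene/transposon composition — the
per-chromosome spread of ν that the fluctuation analysis regresses on
exists only because of such differences. Treatment effects shift a
configurable fraction of sites by a fixed amount toward the opposite
methylation state.

Under the null (no effect), the divergence between two independently
sequenced samples is pure sampling noise with delta-method expectation
E[JD] ≈ (1/n₁ + 1/n₂)/ln2 per site — about 0.09 bits at 30× (halve it
when one side is a deep pooled reference). Tests therefore calibrate
the simulated null against this oracle rather than against an absolute
small constant. The generator does **not** emulate spatial correlation
along chromosomes, sequence-context-specific machinery (CG/CHG/CHH
differences), bisulfite conversion error, or cell-type mixtures —
passing tests show the machinery is correct on exchangeable
binomial-noise methylomes, not that real data meet those assumptions.

## Problem sizes

Default test and acceptance runs use 5 chromosomes × 2000 sites per
simulated methylome, 5000 draws per parameter-recovery fit, 1e5 draws
for moment checks, 100 replicates for test-calibration rates and 50
replicates for the end-to-end null pipeline; these sizes make every
statistical check stable while keeping a full run in the minutes range
on one core.

## Known limitations

* Differential entropy is scale-dependent: S values are comparable only
  between divergences computed the same way (same divergence kind, same
  shrinkage, same log base).
* The GG family is weakly identified near its gamma/Weibull boundaries;
  parameter uncertainty along the (α, δ, θ) ridge is real, and the
  derived ν = αδ is more stable than its factors.
* The grand-mean information-gain aggregation weights replicates
  equally across chromosomes; a per-chromosome-paired variant is
  provided for designs with unbalanced chromosome coverage.
* Absolute entropies from real datasets depend on the chosen reference
  sample; only differences within a common-reference design are
  physically meaningful.
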