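# Methods

## Pore-energetics model of tension-dependent import

A transient hydrophilic pore of radius `r` (nm) in a membrane under
surface tension σ has free energy

    E(r) = 2πγr − πσr² − π a_p V_m² r²,

with line tension γ (pN) opposing pore opening, the released surface
energy −πσr² favouring it, and a capacitive term that acts as an extra
effective tension `a_p V_m²` during the pulse. Tension is supplied in
pN/µm and converted to pN/nm internally. The landscape has a single
barrier at `r* = γ/(σ_eff)`, `σ_eff = σ·10⁻³ + a_p V_m²`.

Rather than simulating pore kinetics, pore radii are weighted by a
quasi-equilibrium Boltzmann factor `exp(−E(r)/k_eff)` truncated to
`(0, r_max]`. The expected import rate per open pore for a dextran of
Stokes radius `r_s` is

    rate(σ) = μ c ∫₀^{r_max} p(r|σ) H(r_s/r) πr² dr,

with electrophoretic mobility μ, buffer concentration c, and the Renkin
hindrance `H(λ) = (1−λ)²(1 − 2.104λ + 2.09λ³ − 0.95λ⁵)` (0 for λ ≥ 1).
Because raising σ multiplies the density by a factor with monotone
likelihood ratio in r, and `H·πr²` is increasing in r, the rate is
strictly increasing in σ and strictly decreasing in `r_s` — the property
the whole assay rests on. The ratio of rates between two species is
independent of μ, c and the number of pores, which is why the
permeability ratio cancels cell-size effects.

### Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| line tension γ | 12 | pN | typical hydrophilic-pore edge energy |
| transmembrane voltage V_m | 0.5 | V | effective pulse voltage at the membrane |
| electrical coefficient a_p | 4.4 | pN/(nm·V²) | puts the barrier near 10 nm at σ = 100 pN/µm (a_pV_m² = 1.1 pN/nm) |
| fluctuation energy k_eff | 40 | pN·nm | ~10 k_BT; pulse-driven fluctuations well above thermal. With k_eff at the thermal value the ~90 k_BT barrier and the deep post-barrier well pin the ensemble to the support edge, flattening the σ→rate curve to <1% per decade; the elevated scale yields the ~16-fold rate change across 10–1000 pN/µm that makes the readout informative |
| max pore radius r_max | 20 | nm | support cap slightly above the largest catalogued Stokes radius (17 nm); pores beyond the reseal limit do not contribute to reversible import |
| reseal critical radius | 15 | nm | reported theoretical maximum radius to reseal at equilibrium (metadata) |

All defaults are overridable through `PoreModelParams`. The inversion
`infer_tension` brackets log₁₀σ on [1, 4] and reports the fixed
10^±0.39-fold uncertainty band, which is a quoted measurement-error
constant for this readout, not a quantity the model computes.

### Quadrature

Integrals use a trapezoidal rule on a uniform radius grid of 8001
points including r = 0 (where E = 0 and the payoff vanishes), with the
log-weights max-shifted before exponentiation for overflow safety.
Against a 10⁶-interval midpoint sum the relative error is below 10⁻⁶.
Root finding uses Brent's method at xtol 10⁻¹² in log₁₀σ, so forward ∘
inverse round-trips are exact to well under 0.5%.

## DTD species catalogue

Six dextran sizes (4, 10, 40, 70, 150, 500 kDa) with 8-nt
identification barcodes. The end-point Stokes radii (4.1 and 17.0 nm)
are the reported span; intermediate radii interpolate `r ∝ MW^0.29`.
Mobilities scale as 1/r (fixed oligo charge, Stokes drag) from
10⁻⁸ m²/(V·s) at 4 kDa; molar concentrations default to 1 µM. All are
synthetic placeholders exposed through the catalogue CSV format.

## Electrophoretic mobility

`μ = (AL)/(ρI)(1/t_analyte − 1/t_RB)` with channel cross-section A,
observation distance L (5 mm; 20 mm for the largest species), buffer
resistivity ρ (35.1 Ω·m for the HEPES/sucrose buffer) and current I.
Migration times come from a single-Gaussian-plus-baseline least-squares
fit; flat traces, non-convergent fits and boundary peaks are rejected
rather than deconvolved. No measured mobility values are available to
pin, so validation is by hand evaluation of the formula and recovery of
synthetic peaks.

## AFM indentation

`P = (2/π)E*d²tanϕ[1 + α_c((2σ/E*)/(d tanϕ))^β_c]` with ϕ = 45°,
α_c = 0.88, β_c = 0.87 fixed (they belong to the tip geometry, not the
cell). Unit bridge: σ in pN/µm equals mN/m, so `2σ/E*` is evaluated in
SI and has units of length; a unit test pins the conversion. Fits run
over (ln E*, ln σ) — positivity by construction — with Levenberg–
Marquardt from 5 starts spread around data-derived guesses (E*₀ from
the terminal P/d² slope, σ₀ from the small-depth excess). Curves are
assumed contact-aligned (d = 0 at contact); a freed contact offset is
deliberately not fitted. Per-cell tension is the mean ± SE of repeated
indentations. At 5% multiplicative force noise the median σ error over
100 synthetic curves is ~8%.

## Quantification choices

- **QC gates** are inclusive on the keep side: "fewer than 2000 counts"
  discards, so a cell at exactly 2000 is kept; likewise exactly 100,000
  survives the doublet gate. Presets: cancer (10%, 2000, 100,000),
  mHSPC (5%, 1000, 60,000), TIG-1 (5%, 2000, 60,000).
- **Expression** is log-normalized, `ln(1 + 10⁵·x/total)`, per cell.
- **CLR margins.** `clr_tags` defaults to the compositional per-cell
  margin (each cell's tag vector is centred, sums to zero), with
  pseudocount 1 because tag counts contain zeros. The across-cells
  margin is exposed as `across="cells"` and is what the pipeline uses
  as the tension readout: all dextran species share nearly the same
  log-slope in σ and the same per-cell pore count, so the per-cell
  margin cancels almost the entire between-cell tension signal
  (residual slope ≈ −0.04 per decade in the model), while the
  across-cells margin preserves it.
- **Hashtag demultiplexing** is a margin classifier on per-cell CLR:
  argmax wins when it leads the runner-up by 1.0 (default); closer
  calls are doublets; zero-count cells are unassigned. The rule is a
  heuristic, not a calibrated mixture model.

## Screens

Pearson r per gene against the CLR DTD readout; p from the t-transform
with n−2 df; Benjamini–Hochberg adjustment (Bonferroni by flag).
Constant genes are flagged degenerate (r = 0, p = 1) instead of
propagating NaNs. The optional `min_dtd_clr` cell filter (the ≥1 CLR
rule used for low-import populations) applies to the correlation stage
only.

Preranked enrichment is the weighted Kolmogorov–Smirnov running sum
(weight 1 on |metric|), ES the signed maximal deviation, ties broken by
gene identifier for determinism. The permutation null redraws gene
labels; NES divides by the mean |null ES| of the same sign and the
p-value is the same-sign tail with +1 smoothing. Gene sets come from
user GMT files; no ontology database is bundled.

The elastic net regresses the DTD readout on candidate-gene expression
(standardized predictors by default, so the |s| > 0.1 reporting cut
compares like with like), mixing weight 0.5 by default, penalty chosen
by seeded k-fold cross-validation at the CV-minimum. Pure ridge
(mixing 0) is approximated with a 10⁻³ L1 share because the coordinate-
descent path requires some L1; the approximation is documented rather
than hidden.

## Synthetic data: what it does and does not emulate

Per population: latent tension log-normal in log₁₀ (default sd 0.35
decades, truncated to 1–10⁴ pN/µm); adhesion areas gamma (mean 400 µm²,
CV 0.3), rank-correlated with tension through a Gaussian copula
(Spearman ρ = 0.3 by default — observed but unquantified in real data,
hence configurable); pore count = round(6.04 µm⁻² × area). DTD counts
are Poisson around `n_pores × rate(σ) × exposure`; the exposure
constant (6×10¹⁰) sets tag depth so per-cell CLR of the 4-kDa species
spans ~0–3, the range seen in real tag libraries. Optional gamma
overdispersion is off by default (UMI counting of imported tags is
Poisson given the rate). Hashtags are Poisson spikes (depth 300,
background 3). Expression is negative-binomial with each cell's
expected total rescaled to its drawn library size; planted genes tilt
their log-mean by `coupling × (log₁₀σ − population mean)`; ~5% of
background genes are labelled mitochondrial and rescaled to a 5%
expected mitochondrial fraction so QC is exercisable.

Not emulated: ambient RNA, UMI collisions, doublet transcriptomes,
batch effects, cell-cycle structure, and transcriptional programs
beyond single-gene couplings. Passing screens on these data therefore
demonstrates correctness of the statistics and the monotone
tension→import link, not robustness to every artefact of real
single-cell chemistry.

## Problem sizes

Validation experiments use 2000–4000 cells, 200 decoy genes for
recovery studies (20 seeded repeats), 1000 genes for null calibration,
100 curves for indentation noise studies, and 200×200 permutations for
enrichment-null uniformity; these sizes give stable statistics for the
properties being checked while keeping the full suite fast.

## Known limitations

- The free-energy parameters are effective, not measured; the model is
  a monotone link, not a quantitative electroporation simulator.
- `infer_tension` assumes the observed rate is per pore; in practice
  pore number must be normalized out first (by area or by ratio).
- The across-cells CLR readout preserves pore-number variation, so
  adhesion-area differences contribute to it; the permeability ratio is
  the size-free alternative, at a noise cost, mirroring the trade-off
  the assay itself faces.
- Elastic-net coefficients at the CV-optimal penalty are reported
  without post-selection inference; |s| ranks candidates, it does not
  test them.
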