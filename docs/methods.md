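# Methods

This note documents the statistical model, the numerical choices, and
the design decisions behind `sswgwas`, and states what the synthetic
test-bed does and does not establish about real data.

## Model

The single-trait animal model is `y = Xβ + Wa + e` with
`var(a) = H σ²_a` and `var(e) = I σ²_e`. Fixed effects are the overall
mean plus farm, lactation and parity as categorical factors,
treatment-coded against each factor's first observed level (any full-rank
coding gives identical fits; a factor observed at a single level is
dropped with a warning because it is confounded with the mean). `W` is
the record→animal indicator, so repeated lactation records per cow are
supported without a separate permanent-environment effect — the
simulator correspondingly draws independent residuals per record.

### Relationship matrices

* `A` is computed by the dense tabular method with exact inbreeding
  (`a(i,i) = 1 + a(s,d)/2`). Populations of interest here are at most a
  few thousand animals, where the dense recursion is simpler to verify
  than the Meuwissen–Luo sparse algorithm and costs little.
* `A⁻¹` uses Henderson's rules with inbreeding: animal `i` contributes
  `αᵢ = 1/mᵢ`, `mᵢ` its Mendelian sampling variance
  (`0.5 − 0.25(F_s + F_d)` with both parents known). Tests verify
  `A⁻¹A = I` against dense inversion up to 500 animals.
* `G* = Z D Z′ λ`, `Z = M − 2p` with current-population allele
  frequencies, `λ = 1/Σ 2pᵢ(1−pᵢ)`, `D` the marker-weight diagonal
  (identity for the unweighted pass). `G*` is tuned to `A₂₂` by
  two-moment matching — scalars `(a, b)` chosen so that `a + bG*` matches
  the mean diagonal and the overall mean of `A₂₂` — and blended,
  `G_w = (1−τ)(a + bG*) + τA₂₂` with `τ = 0.05` by default. The
  compatibility adjustment admits several published variants; the
  two-moment version is linear, deterministic, and recorded (with `τ`)
  in the output metadata. Blending is required for invertibility because
  the sample-centred `Z` makes `ZDZ′` exactly singular
  (`1′Z = 0`).
* `H⁻¹ = A⁻¹ + [0 0; 0 G_w⁻¹ − A₂₂⁻¹]`, the correction added only into
  the genotyped block. Verified against dense inversion of the explicit
  joint-covariance `H` on mixed genotyped/ungenotyped pedigrees.

### Genotype quality control

SNPs are excluded by strict inequality — call rate < 0.90, MAF < 0.05,
Hardy–Weinberg 1-df chi-square goodness-of-fit P < 1e-6 (no continuity
correction; the exact test is a possible future option but the
chi-square is adequate in the several-hundred-animal regime) — with each
removed SNP attributed to the first filter it fails in that order, so
per-filter counts are order-stable and sum correctly. Boundary values
are retained. Remaining missing calls on retained SNPs are imputed to
the rounded SNP mean; real panels are expected to arrive fully imputed,
so this path mainly serves synthetic and degenerate inputs.

### Variance components

A conjugate Gibbs sampler draws `(β, a)` jointly from their Gaussian
full conditional (via a Cholesky factorisation of the MME coefficient
matrix at the current variance ratio) and the two variances from
scaled-inverse-chi-square full conditionals with flat priors (degrees of
belief −2): `σ²_a ~ a′H⁻¹a / χ²_{q−2}`, `σ²_e ~ e′e / χ²_{n−2}`. The
chain is fully deterministic given a seed. Effective sample size of
`σ²_a` is estimated by the initial-positive-sequence method; ESS < 50
triggers a warning, not an error. Default desk-scale chain: 10,000
rounds, 1,000 burn-in, thinning 10; the full-scale analogue configured
for real analyses is 100,000/9,000. Some reference analyses interleave
Metropolis–Hastings sub-iterations within each Gibbs cycle; with no
published target or proposal for them, this implementation uses pure
conjugate Gibbs.

### Back-solving and re-weighting

`û = D Z′ (Z D Z′)⁻¹ â_g` is implemented as one linear solve against
`ZDZ′` (the `λ` of the equivalent `λDZ′G*⁻¹â_g` form cancels because
`G* = ZDZ′λ`). When `ZDZ′` is singular — always the case in-pipeline,
see above — the solve falls back, with a logged warning, to the blended
`G_w`: `û = λ D̃ Z′ G_w⁻¹ â_g`, where `D̃` is `D` rescaled to trace `M`.
The rescaling keeps the fallback consistent with the exact solve's
invariance to the overall scale of `D` (the tuning step otherwise
absorbs that scale into `G_w`). With no `G_w` available the minimum-norm
pseudo-inverse solution is used instead.

Per-SNP variances are `σ̂²_{u,i} = ûᵢ²·2pᵢ(1−pᵢ)` (the per-SNP reading of
the weighting literature; a common-constant reading would make the
weights uninformative), rescaled to sum to the marker count `M` before
becoming the next iteration's `D` — constant trace prevents scale drift
across iterations. The default is one re-weighting iteration; iteration
counts are configurable and iteration 0 reproduces plain unweighted
single-step effects. Empirically the planted-QTL rank under one
iteration is non-worsening in the large majority of replicates but can
jitter by a couple of places, so tests assert the majority property
rather than per-replicate monotonicity.

### Significance

Two p-value modes are first-class and recorded in metadata:

* `as-printed` (default): `tᵢ = ûᵢ/√(σ̂²_{u,i}/nᵢ)` with `nᵢ−1` degrees
  of freedom, `nᵢ` the number of animals genotyped at SNP i. Because
  `σ̂²_{u,i}` is itself a multiple of `ûᵢ²`, `|tᵢ|` reduces to
  `√(nᵢ/2pᵢ(1−pᵢ))` — a function of allele frequency alone. The mode
  exists for fidelity to the published recipe; a test documents the
  degeneracy.
* `empirical`: `tᵢ = ûᵢ/sd(û)` genome-wide, which behaves like a
  conventional standardised effect and calibrates correctly on pure-noise
  simulations (fraction of P < 0.05 within [0.02, 0.10]).

The genome-wide level is Bonferroni `α/N` with `α = 0.01` by default,
reported as `−log₁₀(α/N)` and computed from the formula (for
N = 586,304 this gives 7.77).

### Windows and reporting

Window genetic values are `a_win = Σ_{j∈win} Z_j ûⱼ` over genotyped
individuals; `VE% = var(a_win; ddof=1)/σ²_a × 100`. Windows contain a
fixed number of consecutive SNPs (default 5) of a single chromosome and
slide by step 1 by default (step is configurable; a non-overlap report
mode collapses runs of overlapping windows to their maximal-VE
representative). Window ids are the genome-order index of the first
member SNP *in the post-QC panel* — analyses that assign ids on the
pre-QC panel will number windows differently, which matters when
comparing id lists across studies. The informative-window filter is
inclusive (`VE ≥ 0.5 %`), and region aggregation selects windows by
start coordinate and sums their VE%, matching how published region
totals are computed. Gene annotation converts BED input (0-based
half-open) to the 1-based inclusive coordinates used throughout and
reports overlap or the signed distance to the nearest gene within 1 Mbp.

All coordinates are 1-based inclusive; chromosome labels are opaque
strings ordered by first appearance in the map; marker sort ties on
position break lexicographically by SNP id so window ids are
deterministic.

## Synthetic data

The generator emulates the emulated study's design: a cow population in
19 sire families (founder sires mated to dam pools across configurable
generations), ~614 cows, 19 farms, trait scale matching the most
abundant casein fraction (mean 35.45, SD 17.46 wt/wt%), and a genetic
architecture of a few large QTL — by default one window absorbing 25 %
of σ²_a, echoing the dominant DGAT1-region signal — over a pedigree-
covariant polygenic remainder with target heritability 0.3 (published
milk-protein heritabilities span roughly 0.05–0.8; 0.3 is a
well-identified middle value). Founder allele frequencies are uniform on
[0.05, 0.5]; genotypes descend by gene dropping, so Mendelian
consistency holds by construction. Phenotypes are affinely mapped to the
configured trait mean/SD; the recorded truth (breeding values, QTL
effects, realized variance components) is on that final scale.

Deliberate simplifications, and what they mean for test evidence:

* **No linkage disequilibrium by default.** Loci segregate
  independently, which (a) makes the QTL SNP the only marker carrying
  its signal — a *harder* localization problem than real LD mapping —
  and (b) gives the clean additivity that the window-VE conservation
  test exploits (non-overlapping window VEs sum to ~100 % of genic
  variance). An optional block mode (`ld_block_size > 1`) draws founder
  haplotypes from a small per-block pool and transmits blocks intact,
  producing within-block correlation for localization experiments.
  Passing tests therefore demonstrate correct algebra and sensible
  statistical behaviour, not performance under realistic LD structure.
* **QTL are panel SNPs** (observed-QTL regime) so back-solving can in
  principle recover them exactly; `hidden_qtl` masks them from the
  analysis panel to emulate tagging.
* **Repeated records** are independent given the breeding value (no
  permanent-environment effect), matching the fitted model exactly.

### Power and the heritability-recovery test

Variance-component recovery at a few hundred phenotyped animals is
limited by family structure, not by the sampler: REML Monte Carlo on
single-record sib designs at n = 500 gives SE(ĥ²) ≈ 0.09–0.13, and on
one such draw the Gibbs posterior mean (0.47) matched the REML estimate
(0.43) while both sat far from the simulated 0.3. The recovery test
therefore uses a design with more information per animal — two
phenotyped generations (250 + 250 cows, 19 sires, so parent–offspring
covariance contributes) with three lactation records each — for which
the same Monte Carlo gives SE ≈ 0.025, making the ±0.1 check a test of
the sampler rather than of luck. This is a statement about experimental
design: single-record field datasets of this size will constrain h²
only weakly, whatever software is used.

## Numerical choices

* All solves are direct (Cholesky; dense) with exact-solve residual
  checked against 1e-8; PCG is unnecessary at desk scale.
* `RelationshipMatrix` symmetrises its input and validates shape;
  `h_inverse` output is symmetrised to 1e-16 rounding.
* Degenerate inputs: monomorphic SNPs return HWE P = 1 (no evidence);
  `tune_and_blend` raises when G has equal diagonal and overall means
  (tuning undefined, e.g. 1×1 or constant G); QC removing every SNP is
  a hard error; `casein_index` rejects the all-zero input.
* Determinism: every stochastic component takes a seed
  (`numpy.random.default_rng`); reruns are bitwise identical, including
  the Gibbs chain and all file exports.

## Known limitations

* No metafounders or unknown-parent groups in `A`; unknown parents
  contribute zero relationship.
* Univariate analyses only; the nine traits of the motivating design are
  run one at a time.
* No binary PLINK `.bed` or VCF ingestion (text additive matrix + map
  only); documented as future work.
* The `as-printed` significance mode is degenerate by construction (see
  above) and should not be used for inference; it is retained for
  comparability.
* Dense `A`/`H⁻¹` algebra bounds practical pedigree size to a few
  thousand animals.
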