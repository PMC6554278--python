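# Methods

## Scope and model

`codonopt` implements head-region codon optimization for bacterial
expression systems in which all constructs share one vector (one promoter,
one 5′ UTR) so that differences in protein yield are dominated by
translational efficiency. The working model has two ingredients:

1. **Initiation-region structure.** The mRNA segment consisting of the
   vector 5′ UTR plus the first `head_nt` coding nucleotides folds with
   free energy ΔG_UH; weaker structure (higher ΔG_UH) eases ribosome
   loading. Designs maximize (H/C-methods) or minimize (L-series) ΔG_UH
   over all synonymous variants of the head codons, with the start codon
   fixed (cloning anchors it) and everything downstream untouched.
2. **Head codon adaptation.** The geometric mean CAI_H of normalized
   codon frequencies w_c = f_c / max_s f_s over the head codons captures
   tRNA supply at initiation. The C-method constrains designs to
   CAI_H strictly above a threshold (comparison tolerance 1e-9) and to
   zero rare codons (w_c < 0.1) in the head, applied *before* folding
   since the filter is orders of magnitude cheaper than the energies.

Both ingredients are validated on data by polyserial correlation between
continuous features and ordinal expression scores (see below).

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `head_nt` | 33 | nt (11 codons) | the window where a scan of (UTR suffix, head length) grids typically localizes the expression signal; must be a multiple of 3 |
| `cai_h_min` | 0.75 | — | middle of the useful 0.60–0.90 range; pick relative to the wild-type and endogenous CAI_H distributions |
| `rare_threshold` | 0.1 | — | conventional cutoff on normalized codon frequency |
| `temperature` | 37 | °C | standard folding temperature; the built-in model is parameterized only there |
| enumeration cap | 10^6 variants | — | worst realistic 11-codon head after constraint filtering; above it a seeded uniform sample of 10^5 distinct variants is drawn and the result is flagged `search_mode="sampled"` |
| tAI wobble constraints | 0.41 / 0.28 / 0.9999 / 0.68 | — | the widely used selective-constraint constants for G34:U, I34:C, I34:A, U34:G decoding; overridable, and a precomputed weight matrix can be loaded verbatim instead |

## Built-in folding model

The default backend is a deliberately minimal secondary-structure model:
canonical pairs (GC −3.0, AU −2.0, GU −1.0 kcal/mol, each pair an
independent additive term), minimum hairpin loop of 3 unpaired
nucleotides, no pseudoknots. MFE comes from a Nussinov-style recursion in
min-plus algebra; the ensemble energy −RT·ln Z (RT at 310.15 K) from the
McCaskill inside recursion, both vectorized row-by-row in numpy. Per-pair
constants (rather than stacking terms) were chosen so that the dynamic
programs and an exhaustive enumeration over all valid pair sets are
provably computing the same quantity — the test suite checks bit-level
agreement for all short sequences — and because every design contract in
the package depends only on the *ordering* of variant energies, which a
monotone energy model preserves. Consequences to keep in mind:

* absolute ΔG_UH values are not thermodynamic predictions; compare them
  only within one backend;
* the partition function is computed in plain double precision, which
  bounds regions at 280 nt (beyond that the Boltzmann sum overflows; the
  backend raises rather than silently rescaling);
* for publication-grade energies select the `vienna` backend (Turner
  parameters) or, when the `EnsembleEnergy` executable is installed, the
  `rnastructure` backend. All design logic is backend-agnostic.

## Polyserial correlation

Expression scores y ∈ {1,…,K} are modeled as a latent standard-normal
liability cut at thresholds τ_1 < … < τ_{K−1}; the quantity of interest
is ρ = corr(x, liability). The default estimator is the classical
two-step: τ_k = Φ⁻¹(cumulative proportions), then
ρ̂ = r_xy · s_y / Σ_k φ(τ_k) with y coded 1..K, clipped to [−1, 1];
its p-value uses the Fisher-z approximation (se 1/√(n−3) on the z scale).
The ML estimator maximizes the exact latent-Gaussian likelihood over
(atanh ρ, τ) with x standardized to sample moments, reports the standard
error from a finite-difference Hessian (delta method back to the ρ
scale), and tests ρ = 0 by Wald z. The two estimators agree within 0.02
at n ≥ 2000 on data generated from the model, and the ML/Wald test is
calibrated (type-I ≈ 5% at n = 300). Ten observations and two observed
levels are hard minimums; constant features are reported as NA rather
than raised, so a batch analysis never dies on one degenerate column. No
multiple-testing correction is applied across features — consumers see
raw p-values plus a significance flag at α = 0.05.

The window scan repeats the ΔG–score correlation over a grid of
(UTR suffix length, head length) region definitions and reports the
argmax cell; energies are cached per (gene, cell).

## Synthetic data: what it emulates and what it does not

The fixtures module generates a full offline stand-in for an expression
study: random proteins (uniform residues after the initiator),
back-translated under a GC-biased usage table (counts ∝ product over
codon positions of gc_bias vs 1−gc_bias, times lognormal noise σ=0.25 —
at gc_bias ≥ 0.9 the AT-rich codons of mixed families, e.g. TTA/ATA/AGA,
drop below the 0.1 rare cutoff), with per-gene codon-optimality exponents
(lognormal, σ=0.7) so CAI/tAI spread across genes. tRNA copy numbers are
derived from the usage table with two anticodons per codon box so every
sense codon is decodable. The 60-nt fixture UTR carries an AGGAGG motif
11 nt upstream of the start. Expression scores come from a latent
liability built from the *standardized true features* of the generated
sequences (defaults: ρ = 0.6 on ΔG_UH, 0.25 on CAI, 0.15 on tAI, residual
variance topped up to 1, cuts at ±0.5 giving roughly balanced thirds over
204 genes) — so end-to-end analysis genuinely has to recover a planted
signal, not a label permutation.

What passing these tests does *not* show about real data: real genes have
amino-acid composition bias, correlated features (note that even in the
fixtures, CAI and ΔG_UH are anticorrelated because GC-rich codons pair
more strongly — the realized CAI–score correlation is therefore smaller
than its planted coefficient), non-Gaussian liabilities, and scoring
noise that no latent-normal model captures; and the built-in energies are
not Turner energies. The fixtures establish correctness of the machinery,
not biological effect sizes.

## Numerical and design choices

* Geometric means (CAI, CAI_H, tAI) are computed in log space; a zero or
  missing weight is a hard error naming the codon. Singleton families
  (ATG, TGG) are included with weight 1 by default; an
  `exclude_singletons` flag removes them from the mean.
* Repetition rates use codon-index distances (adjacent identical codons
  give d = 1); a codon that never recurs contributes 0, keeping the rate
  within [0, (L−1)/L]. Terminal stop codons are stripped before all
  feature computation; internal stops are validation errors.
* Energy ties between variants break toward the lexicographically
  smallest head sequence, making ranked output platform-independent.
* Usage tables must contain all 64 codons; stops are carried but excluded
  from normalization, CAI, and rare sets. An all-zero family defers its
  error to the first operation that needs its normalization.
* tAI weights of codons no supplied tRNA can decode stay 0 by default
  (so a tAI computation on such a codon fails loudly); the
  geometric-mean fill convention is available via `fill_zero="geomean"`
  and is used by the fixture generator.
* All randomness (sampled search, fixtures, simulations) flows through
  `numpy.random.default_rng` seeded explicitly; identical inputs and
  seeds give bit-identical outputs, which the CLI tests assert at the
  byte level.

## Problem sizes

The test suite and the acceptance script run the design oracles on
4-codon head windows (≤ 216 variants per gene, folded exhaustively), the
folding-enumeration comparison on 4–14-nt sequences, polyserial recovery
at n = 2000 (with null calibration at n = 300 over 500 replicates), and
the planted-signal analysis on 20 × 204-gene datasets — sizes chosen so
the whole validation executes in well under a minute each on one core
while still exercising every code path at the study's native 204-gene
scale. Production use with the default 33-nt head typically enumerates
10^4–10^6 variants per gene; with the built-in backend at ~2 ms per fold
that is minutes per gene, and the `vienna` backend is comparable.

## Known limitations

* The exact UTR of any particular vector must be supplied by the user;
  the shipped fixture UTR is synthetic.
* The tAI adjustment used by any specific published weight matrix cannot
  be reproduced from first principles here; load such matrices verbatim.
* The C-method guarantees nothing about codon adaptation beyond the head
  window; genes with poor downstream CAI may still express badly.
* Folding-energy maximization assumes expression is initiation-limited;
  membrane proteins, disulfide-rich proteins, or toxic products are
  outside the model.
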