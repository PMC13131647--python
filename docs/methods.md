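# Methods

## The analysis

`phosevol` tests whether the density of predicted phosphorylation sites in
the disordered C-terminal tail of a protein — SIRT6 being the motivating
case — increases with species maximum lifespan, after correcting for
phylogenetic non-independence. The pipeline is:

1. **Site prediction.** Predicted phosphosites are occurrences of the
   `[ST]P` motif: serine or threonine immediately followed by proline, the
   minimal recognition pattern of proline-directed (CMGC-family) kinases.
   A variant that also accepts proline at the −1 position exists behind a
   flag (`allow_minus1_proline`) but is off by default: the counting
   definition is strictly +1 proline. One consequence worth noting: when
   two acceptors are adjacent (e.g. a TS pair followed by proline), only
   the second can match the strict motif, so a protein can carry more
   annotated phospho positions than strict `[ST]P` matches. This is why
   the human stand-in encodes seven C-terminal phospho positions but six
   strict matches.
2. **Domain boundary.** The C-terminal domain starts at a
   reference-coordinate boundary (default residue 290 of the human
   sequence, placing the conserved-region acceptor T294 inside the
   domain). The boundary is projected onto every species through the
   alignment: a species' domain starts after the number of its own
   residues that precede the boundary column. Site counts are normalized
   to each species' own domain length (`site_density`), since tail length
   varies by tens of residues across species.
3. **Other features.** Net charge (K,R = +1; D,E = −1; histidine neutral;
   termini ignored), charged-residue fraction, and proline fraction over
   the domain (full-sequence mode available); presence of an S/T
   phosphoacceptor at the alignment column of reference residue 294
   (serine accepted by default because the motif accepts either).
   Unknown residues (X) count toward lengths, never toward tallies.
4. **Regression.** Each feature is regressed separately against log10
   maximum lifespan (years) by phylogenetic generalized least squares
   under a fixed Brownian-motion covariance, with ordinary least squares
   as the uncorrected baseline. Binary predictors are coded 0/1. A joint
   multi-predictor fit is available but is not the default analysis.

## PGLS

Under Brownian motion the expected covariance of trait values of species
i and j is proportional to C\[i,j\], the branch length shared from the
root to their most recent common ancestor. With X the design matrix
(intercept column plus predictors):

    β̂   = (XᵀC⁻¹X)⁻¹ XᵀC⁻¹ y
    σ̂²  = (y − Xβ̂)ᵀ C⁻¹ (y − Xβ̂) / (n − p)
    SEⱼ = sqrt(σ̂² [(XᵀC⁻¹X)⁻¹]ⱼⱼ),   t = β̂/SE,  two-sided p on n − p df

Implementation is by Cholesky whitening (solve L z = y with C = LLᵀ),
never by explicit inversion. No Pagel's λ or OU transformation is
estimated: C is the fixed Brownian VCV, the field's default model.
The estimator was cross-checked against an independent R route
(ape::vcv + nlme::gls with a Brownian correlation structure); both agree
to 1e-12 on a 5-taxon example frozen into the test suite.

Numerical choices: a numerically singular C gets a logged ridge of
1e-8 × mean diagonal; a design with condition number above 1e12 is
rejected as collinear; zero residual variance yields SE = 0 and the slope
is reported without a finite t. Branch-length rescaling leaves β̂, t and p
unchanged (σ̂² scales inversely), and on an ultrametric star tree PGLS
reduces to OLS exactly; both are enforced by tests at 1e-10.

## MS relative abundance

For each phosphosite, relative abundance = MS1 intensity of the
phosphopeptide ÷ intensity of the identical peptide without the
phosphorylation. "Identical" means the same peptide string, fixed
modifications included; intensities are summed over charge states before
dividing. A zero denominator (unmodified peptide undetected) yields an
explicit UNDEFINED flag, not infinity. Peptides carrying two or more
phosphosites are excluded from single-site ratios by default
(`include_multisite` reverses this). Confidence filters applied before
quantification: protein probability strictly > 0.95; localization
probability ≥ 0.80 for modified peptides ("above" vs "at least" — the
boundary cases 0.95 and 0.80 go opposite ways, and tests pin both).
FragPipe-style and generic TSV dialects are supported; missing intensity
cells are read as zero with a logged count.

## Synthetic data: what it emulates and what it does not

The generator produces the joint structure the analysis assumes:

* **Tree** — pure-birth (Yule) with rate `birth_rate` (default 1.0 per
  lineage per unit time), grown from two lineages with exponential
  waiting times, plus a final stretch at the full lineage count; expected
  root-to-tip depth is Σ_{k=2..n} 1/(bk), which the tests verify by
  Monte Carlo.
* **Lifespans** — Brownian motion on the log10 scale, root 1.2 (≈16 y),
  rate σ² = 0.05 log10-years² per unit branch. On a 128-leaf default tree
  this gives a tip standard deviation near 0.45 log10 units, matching the
  spread of real mammal panels (≈2 y shrews to ≈200 y bowhead whales).
* **Sequences** — a conserved core identical across species (no `[ST]P`
  except an optional T294-analog, present with probability
  logistic(intercept + slope × log10 lifespan)), then a tail of
  `cterm_length` = 200 residues containing K ~ Poisson(`baseline_sites` +
  `site_effect` × log10 lifespan) planted S/T-P dimers, non-overlapping
  and non-adjacent, with all other tail residues drawn from an
  S/T-free alphabet — so the scan recovers exactly the planted count
  (prolines do occur in the filler, which keeps the proline fraction
  from collapsing into a deterministic function of the site count).
  Default `site_effect` = 3.4 sites per log10 year with
  `baseline_sites` = 0.5: the least-squares slope through the reported
  real-ortholog counts (2 sites at 12 y, 6 at 122.5 y, 6 at 211 y).
* **MS tables** — log-normal unmodified intensities; modified = true
  ratio × unmodified × mean-one log-normal noise (CV `ms_noise_cv`,
  default 0.2); independent dropout at `ms_missing_rate` (default 0.05);
  optional planting of below-threshold confidence rows.

Not emulated: substitution/indel evolution of the sequences (the true
alignment is trivial by construction), clade-structured rather than
independent T294 gains, lifespan measurement error, length variation of
the C-terminal tail, chromatographic or spectral realism. Passing the
synthetic recovery tests therefore demonstrates that the statistical
machinery is correct and calibrated, not that real alignments or real MS
searches are free of their own artifacts.

## Attenuation and the stated effect sizes

In the generative model the predictor (site density) is a noisy function
of the response (lifespan): classic errors-in-variables. Under PGLS this
attenuation is aggravated, because whitening by C⁻¹ upweights contrasts
between close relatives — exactly where the Brownian lifespan difference
is tiny but the Poisson/Bernoulli sampling noise in the predictor is
undiminished. Empirically, detection power at 128 species plateaus near
85% at realistic effect sizes regardless of further increases. The
Monte-Carlo recovery checks therefore plant a deliberately strong effect
(`site_effect` = 24 sites per log10 year; T294 logistic slope 14,
intercept −21) so that they measure the pipeline's ability to detect a
real signal at ≥90% power, while the generator default stays at the
realistic 3.4. The type-I calibration runs are unaffected by this choice
(null data contain no effect): PGLS rejects at 5.0 ± 1.5% over 2,000
Brownian-null replicates while naive OLS on the same data rejects at
~50%, which is the reason phylogenetic correction is non-negotiable for
comparative claims.

## Problem sizes

Monte-Carlo suites use a fixed 64-leaf Yule tree with 2,000 null
replicates for calibration, 500 replicates for slope-recovery bias, and
200 replicates of the full 128-species pipeline for power and null
rejection; the headline demonstration panel has 150 species. These sizes
put Monte-Carlo standard errors well inside the asserted bands while the
whole suite runs in well under a minute of regression fitting.

## Known limitations

* The Brownian VCV is fixed; no λ/OU estimation means model misfit shows
  up in σ̂², not in the covariance.
* The binary T294-equivalent analysis is PGLS on a 0/1 predictor, not a
  phylogenetic logistic/threshold model; with a binary trait the Gaussian
  error model is an approximation.
* Boundary projection assumes the alignment is trustworthy around the
  boundary column; a misaligned reference region shifts every species'
  domain.
* Real-sequence counts (human 6 / guinea pig 2 / bowhead 6) can only be
  reproduced after fetching the real orthologs
  (`scripts/fetch_real_data.py`); the shipped stand-ins encode that
  layout by construction and test the machinery only.
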