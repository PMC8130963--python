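# Methods

## Strain-correlation score and its null

For a link between a gene cluster family (strain set *G*, size *g*) and a
molecular family (strain set *M*, size *m*) in a collection of *n* strains
with overlap *o* = #(G ∩ M), the raw score is

    sigma_corr = w_both*o + w_met_only*(m-o) + w_gcf_only*(g-o) + w_neither*(n-m-g+o)

with default weights (+10, −10, 0, +1). Arbitrary real weights are accepted.

Under the null hypothesis of uncorrelated strain sets the overlap is
hypergeometric (population *n*, *m* positives, sample size *g*). The null
mean and variance of the raw score are computed by **exact summation over
the overlap support** (at most min(m, g)+1 terms, via `scipy.stats.hypergeom`),
not by closed-form moment formulas: the summation is exact for arbitrary
weights and directly checkable against brute-force enumeration of all subset
pairs (the test suite does this exhaustively for n ≤ 12). Moments are cached
per (m, g, n, weights).

Numerical conventions:

* Variance is clamped to zero when the computed value is negative or below
  1e−12 of the second moment (floating-point residue, e.g. with constant
  weights).
* When the null variance is zero — the overlap is deterministic, as for a
  GCF spanning every strain, or empty families — the standardised score is
  defined as 0: such links carry no correlation evidence in either direction.
* Significance is the null probability of a raw score ≥ the observed one,
  summed generically over the support so it remains valid for weight choices
  under which the score is not monotone in the overlap; with the default
  weights it reduces to the hypergeometric upper tail P(overlap ≥ o).
* Strains observed on only one omics axis stay in the universe *n*; the
  "neither" category counts them, and removing them would silently change
  every score.

## IOKR scoring

Kernel ridge regression from spectra to fingerprint space: given training
pairs (x_i, y_i), the dual coefficients solve (K + λI)C = Y and the
prediction is ĥ(x) = k(x)ᵀC. A candidate structure with fingerprint φ(y) is
scored by ⟨ĥ(x), φ(y)⟩, which is linear in the candidate fingerprint.

**Spectrum kernel.** The Probability Product Kernel treats a spectrum as a
uniform mixture of axis-aligned 2-D Gaussians at its (m/z, intensity) peaks;
the kernel is the closed-form integral of the product of two mixture
densities, cosine-normalised by default so K(x, x) = 1. Defaults (all
configuration, exposed on `SpectrumKernelParams`):

* `sigma_mz` = 0.5 Da — order of unit-resolution fragment-mass accuracy;
* `sigma_int` = 0.5 — intensities are rescaled to unit maximum per spectrum
  before the kernel (switchable), so this is half the base peak. Rescaling
  makes the intensity width meaningful across instruments;
* `peak_match_tol` = 0.1 Da — query spectra are filtered to peaks within
  this tolerance of the pooled training peak list (a denoising step);
  a query with no surviving peaks scores 0, with a warning;
* ridge `lambda_reg` = 1e−3 — small enough to interpolate clean training
  data, large enough to keep duplicate-spectrum systems solvable.

**Fingerprints.** Binary vectors through a pluggable backend. The
file-based `PrecomputedFingerprinter` (a structure-key → bit-string table)
is what the tests and synthetic pipeline use. The optional
`RDKitFingerprinter` concatenates three families (MACCS, RDKit path,
Morgan radius-2); the concatenation-of-families design mixes curated
substructure keys with topological features, and no bit-for-bit parity with
any other toolkit is claimed. Structure identity uses the first (skeleton)
block of InChIKeys, so stereoisomers share a key; SMILES keys are verbatim.

**Aggregation.** A GCF–MF link scores the maximum over its (BGC structure,
spectrum) pairs; a BGC with several candidate structures contributes each.
Links whose GCF has no structure-annotated BGC are *undefined* and
represented as missing (NaN) in tables — never 0, which is a legitimate
score. Undefined links are excluded from the IOKR percentile and from
standardisation but remain in "all links" denominators.

**Ranking.** Candidates are ordered by descending score with ties broken by
structure key; the BGC-level rank counts only BGCs tied to *strictly*
better-ranked metabolites (ties do not count against the true structure).

## Score combination and evaluation

σ_IOKR is z-scored (population variance) over the links where it is
defined. The signed ℓ_{1/2} combination σ_sum = sgn(x)√|x| + sgn(y)√|y|
applies the coordinate signs exactly as stated — no extra penalty for the
mixed quadrants. General ℓ_p = (|x|^p + |y|^p)^{1/p} is available for p > 0;
for p < 1 it is a ranking functional, not a norm.

Per-GCF rank of a link is 1 + the number of strictly better links; in the
product order "better" means ≥ on both scores with > on at least one, so
incomparable links do not count and the product-order rank lower-bounds both
single-score ranks. Remaining ties are resolved lexicographically by
(GCF id, MF id) when tables are sorted.

Percentile enrichment uses the linear-interpolation empirical quantile of
the defined scores (a fixed, stated convention), "above" meaning strictly
greater; the "both" variant requires exceeding the per-score thresholds of
the standardised correlation and IOKR scores simultaneously. The test on the
2×2 validated × above-threshold table is a one-sided Fisher exact test
(over-representation). No multiple-testing correction is applied across the
link table.

## Synthetic data

`simulate_occurrence` plants true links by drawing each GCF strain set
Bernoulli(base_presence_prob) per strain and copying it to the MF with
per-strain flip probability `flip_prob` (detection noise: missed or
spurious metabolite observations); decoy families on both sides are drawn
independently from the same presence model. Defaults — 60 strains, 10
planted links, 50 decoy GCFs, 50 decoy MFs, presence 0.5, flip 0.05 — model
a mid-sized strain collection where roughly half the strains carry any given
family and detection noise is a few percent.

`simulate_spectra` draws binary fingerprints and produces one spectrum per
fingerprint through a fixed random linear map W from bits to the intensities
of 30 fixed m/z channels (10 Da apart from 100 Da), plus optional Gaussian
noise. Two deliberate design choices:

* the generative model is **linear-Gaussian, not a fragmentation model**:
  it gives the kernel regression a learnable spectrum→fingerprint map whose
  recovery is provable at desk scale (200 training pairs, 16 bits);
* fingerprints carry a **constant number of set bits** (n_bits/2) and are
  unique, so inner-product ranking is not trivially biased toward dense
  candidates and the true candidate is identifiable.

`simulate_linked_dataset` wires the two generators together: every GCF gets
one structure-annotated BGC and every MF one spectrum, with planted links
sharing a fingerprint, so the same links score high on both axes. All
generators are pure functions of their parameter objects (seed included),
built on numpy's seeded PCG64 generator.

What passing the synthetic tests does **not** show: real MS2 fragmentation
is not linear in fingerprint bits, real fingerprint distributions are sparse
and correlated, molecular networking produces families far larger and more
heterogeneous than the simulated singletons, and real strain-presence
matrices are phylogenetically correlated rather than i.i.d. Bernoulli. The
synthetic results validate the machinery (scores, nulls, ranking,
enrichment), not field performance.

## Problem sizes

The test and acceptance workloads use: exhaustive moment enumeration up to
12 strains; 10,000 null draws at (n=100, m=20, g=30); IOKR ranking at 200
training / 40 test pairs with 40 candidates; enrichment on a 60×60-family
link table (3,600 links). These sizes make every distributional check
exact-or-tight while a full run of the suite stays in the minutes range on a
single core.

## Known limitations

* The enrichment test is a fixed one-sided Fisher exact test; other exact
  or asymptotic 2×2 tests would give slightly different p-values.
* IOKR hyperparameters are sensible defaults, not optimised; generalised
  cross-validation on the training Gram is a natural extension.
* Upstream-tool readers (`read_bigscape_clustering`,
  `read_gnps_components`) are best-effort for the classic export layouts;
  the canonical simplified dialects are the supported interchange format.
* Genome-side parsing (GenBank, homology search against reference BGC
  libraries) is out of scope; structure annotations enter via the
  fingerprint/structure table.
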