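# Methods

## Measurement model

A confocal smFRET experiment on freely diffusing molecules is modelled at
the level of 1 ms binned photon counts in two channels. Each bin carries
Poisson background (donor and acceptor rates independent); a bin containing
a molecular transit additionally receives N ~ Poisson(burst_brightness)
photons split between the channels as acceptor ~ Binomial(N, E(r)), with

    E(r) = 1 / (1 + (r / R_eff)^6).

The inter-dye distance r is redrawn per burst from a distance model: a fixed
value, a fixed value blurred by isotropic 3-D Gaussian dye-linker motion of
per-axis width σ_link (the sampled distance is |r·e_z + g|), or a
semiflexible exterior loop (contour length L, persistence length l_p) plus
linker motion. Bursts occupy single bins and the detection factor γ is fixed
at 1: all instrument factors are absorbed into the effective Förster radius,
which is the only calibration parameter identifiable from (separation,
efficiency) data. Spectral crosstalk and direct acceptor excitation are not
generated; in real data the ruler calibration absorbs their mean effect.

## Burst analysis

Burst bins are those whose **raw** donor+acceptor total strictly exceeds a
threshold; the default rule is μ_bg + 5√μ_bg, with μ_bg the total mean
background per bin. (Thresholding raw rather than background-subtracted
totals is a convention choice; it only shifts the effective threshold by the
constant μ_bg and is exposed in the pipeline config.) Efficiencies use
expected-value background subtraction — the known or estimated mean rate per
channel — not per-bin background estimates; bins whose subtracted total is
non-positive are dropped and counted in a log message. E is not clamped to
[0, 1], so background leakage remains visible in the histogram tails.

Histograms default to 40 bins over [−0.1, 1.1] and are fitted by
least-squares with a Gaussian in the binned counts, as measured FRET
histograms conventionally are; the sample moments are logged alongside for
comparison. A fit requires at least 50 samples and at least 4 occupied bins
(a 3-parameter Gaussian is degenerate below that); narrower distributions
need finer binning. The shot-noise width is σ = √(E(1−E)/N) with N the mean
total photons per burst, and width comparisons use FWHM = 2√(2 ln 2)·σ.

## Calibration

The fit of E⁻¹ = 1 + (R/R_eff)⁶ to ruler points is a one-parameter weighted
nonlinear least squares. The dye-linker length uncertainty (10% of the
1.5 nm total, i.e. σ_R = 0.15 nm per point) is an abscissa error folded in
by the effective-variance method, σ_eff² = σ_E² + (∂E/∂R)²·σ_R², iterated
three times because ∂E/∂R depends on the fitted radius. This was preferred
to orthogonal-distance regression for transparency; the estimator class is
the single place to swap that choice. With the generator's ordinate-only
noise the resulting 1σ intervals are slightly conservative (~0.79 empirical
coverage at σ_E = 0.03 over the ten rulers).

Whether the ruler abscissa includes the 1.5 nm linker is a convention the
data alone cannot fix; the default excludes it
(`include_linker_in_abscissa = False`), and the test suite demonstrates that
including it shifts R_eff upward, as expected for a rightward-translated
curve.

Distance inversion R = R_eff(1/E − 1)^(1/6) propagates σ_E and σ_R_eff to
σ_R in quadrature at first order; it requires E strictly inside (0, 1).

## Length trend

Per condition, distance is regressed on length by weighted least squares
(weights 1/σ² when per-point σ are supplied, ordinary least squares
otherwise; which the original analysis used is not stated, so both are one
keyword apart). Parameter covariances follow the residual-scaled convention,
so noise-free input returns exact parameters with zero error. The 1σ band is
the confidence band of the fitted mean — matching the usual visual
convention — not a prediction band; `band="prediction"` switches. The
near-constancy statistic is 100·(ŷ(n_hi) − ŷ(n_lo))/ŷ(n_lo); the packaged
evaluation uses the span 550–5500 nt, a representative ten-fold factor
inside the experimental regime (the construct lengths themselves span
574–5345 nt, a 9.3-fold factor).

## Polymer models

The worm-like-chain radial end-to-end density uses the standard mean-field
interpolation

    P(r) ∝ 4π r² (1 − (r/L)²)^(−9/2) · exp(−3L / (4 l_p (1 − (r/L)²))),

normalised numerically on [0, L) (adaptive quadrature anchored at the
analytically located mode; normalisation verified to 10⁻⁶). It reproduces
the rigid-rod limit (mass concentrating at r → L for l_p ≫ L) and the
Gaussian-coil limit (rms → √(2 l_p L) within 0.4% at L = 100 l_p). A pure
Gaussian-chain density with the matching second moment sits behind the same
interface. The closed-form second moment
⟨r²⟩ = 2 l_p L − 2 l_p²(1 − e^(−L/l_p)) serves wherever the rms statistic
suffices and is cross-checked against discrete freely-rotating-chain
simulation in the tests. Sampling uses inverse-CDF interpolation on an
8193-point grid; chains with l_p > 100 L are treated as rigid (r = L).

**Contour inversion.** Converting a measured distance d to a loop contour
length solves statistic(P(·; L, l_p)) = d for L by bracketed bisection
(Brent). The matched statistic defaults to rms (closed form); mean and mode
are available via quadrature/optimisation because the literature form this
analysis descends from does not state which feature was matched. With rms
matching and l_p = 2.1 nm, d = 5–9 nm gives L ≈ 9.0–21.4 nm, i.e. roughly
16–37 nt — substantially below the 12–46 nt (and, for uncorrected
separations, 19–88 nt) ranges quoted in the source analysis, which are not
reproducible from any of the three statistics with this density; the
discrepancy is a known open point and the reason `match_statistic` is
exposed. Nucleotide counts default to rounding up (ceil): the loop must be
at least long enough to span the distance. This convention reproduces the
quoted rigid-rod endpoints 9 and 16 nt for 5 and 9 nm at 0.59 nm/nt
(the corresponding uncorrected-range endpoints 11–19 nt are not consistent
with any single rounding rule and are not asserted anywhere).

**Width prediction and rigidity inference.** A fluctuating loop's predicted
histogram is Monte-Carlo: r ~ P(r), E(r) through the calibration, binomial
photon partitioning, then the same Gaussian histogram fit applied to data.
At fixed contour length the predicted width is *not* monotone over all l_p:
a very floppy chain collapses onto the flat high-efficiency part of the
Förster curve and the histogram narrows again, so the width has a maximum at
intermediate l_p. Inference of rigidity from an observed width is therefore
restricted to the stiff branch (l_p above the width maximum, located with a
smooth moment-quadrature forward model), where width decreases
monotonically with rigidity — the regime of the "narrower width ⇒ stiffer
loop" argument. The default forward model is common-random-number
Monte-Carlo (self-consistent with how observed histograms are fitted;
recovers a generative l_p = 5 nm within a few percent); a deterministic
moment-quadrature forward is available but matches Gaussian-fit widths only
approximately for skewed efficiency distributions. An observed width at or
below the stiffest prediction returns the bracket top flagged as a lower
bound on rigidity; a width below shot noise is rejected as inconsistent.

## Synthetic-data generator: what it does and does not emulate

Defaults are the study conditions: the ten ruler lengths (10, 13, 16, 19,
20, 21, 22, 25, 28, 45 bp at 0.34 nm/bp), the eleven construct lengths
(574–5345 nt), the per-condition generative trends a = 6.8 nm,
b = 7.2×10⁻⁴ nm/nt (TM) and a = 7.2 nm, b = 7.6×10⁻⁴ nm/nt (TE), 1.2 nm
sample-to-sample scatter, and R_eff = 8.5 nm. Burst brightness (100
photons/bin), background (1.0 counts/bin/channel) and the RNA linker jitter
(σ_link = 0.3 nm) are not reported quantities; they were chosen so that, at
E ≈ 0.5, the shot-noise width is σ_E = 0.05 (a typical burst-histogram
scale) and the total histogram width lands near 1.5× the shot-noise limit,
the regime the width analysis addresses. Dye-linker motion is the only
per-burst distance jitter in the default RNA simulation; conformational
exchange between secondary structures, triplet blinking, photobleaching,
multi-bin bursts and diffusion through a realistic 3-D detection volume are
not emulated. Passing tests therefore validate the estimators under the
stated statistical model, not the absence of these instrument- and
photophysics-level effects in real data.

## Numerical choices and degenerate inputs

- Seeds: every stochastic routine takes a seed or Generator;
  pipeline child seeds derive from `numpy.random.SeedSequence(seed)`, so a
  fixed seed fixes every output bit-exactly.
- Gaussian histogram fits start from the sample moments, bound σ > 0, and
  surface optimizer diagnostics on failure; zero-width sample sets and
  sub-minimum sample counts are explicit errors.
- Calibration requires non-identical abscissae; fewer than three points
  triggers a degeneracy warning (a single point at E = 0.5 is exactly
  determined).
- Trend fits require ≥ 3 points and non-identical lengths; residual sd uses
  the n−2 denominator and refuses n < 3.
- Contour inversion brackets from L = d (the statistic is always below L)
  and doubles upward; unreachable distances raise rather than extrapolate.
- Linker correction rejects separations ≤ 1.5 nm as unphysical.
- Efficiencies of simulated calibration points are truncated to (0, 1) at
  1e−9 to keep the Förster inverse defined.

## Problem sizes

Default pipeline traces are 2×10⁵ bins (≈ 2000 bursts per sample;
the test pipeline uses 4×10⁴-bin traces), Monte-Carlo recovery checks use
500 replicate datasets, width predictions 4–6×10⁴ draws, and the replicate
trend estimates in `scripts/acceptance.py` average 200 datasets per
condition. These sizes put Monte-Carlo error well below the tolerances they
are tested against while keeping a full run in seconds.

## Known limitations

- R₀ and γ are never separated; all distances are relative to the effective
  radius scale.
- The mean-field WLC density is an interpolation, not the exact
  semiflexible-chain propagator; moments beyond the second are approximate
  at intermediate stiffness.
- The rigidity inference assumes a single homogeneous loop persistence
  length and attributes all super-shot-noise width at fixed mean to chain
  fluctuation once linker motion is accounted for; static heterogeneity
  between molecules is indistinguishable from dynamic fluctuation in this
  observable.
- Weighted trend fits treat per-point σ as independent, though
  calibration-dominated errors are correlated across samples in reality.
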