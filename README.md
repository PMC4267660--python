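# rnafret

Single-molecule FRET analysis of the 5′–3′ end-to-end separation of long
single-stranded RNA.

Folding theory predicts that the exterior loop of a long ssRNA — the loop
carrying the unpaired 5′ and 3′ ends — stays short regardless of sequence
length, so the two ends of a 500 nt and a 5000 nt messenger should sit at a
similar, small distance ("effective circularization"). `rnafret` implements
the complete measurement chain by which this is tested with single-molecule
Fluorescence Resonance Energy Transfer on freely diffusing, end-labelled
RNA, together with a seeded synthetic-data generator that reproduces the
statistical structure of such measurements. It is aimed at single-molecule
biophysicists who want a transparent, tested reference implementation of
burst-histogram FRET distance analysis and its polymer-physics
interpretation.

## The analysis

**Burst selection and efficiency histograms.** Photon counts are stored in
1 ms bins for a donor and an acceptor channel. Bins whose raw total exceeds
a background threshold (default μ_bg + 5√μ_bg) are single-molecule events;
for each such bin the transfer efficiency is

&nbsp;&nbsp;&nbsp;&nbsp;E_i = I_A^i / (I_A^i + I_D^i),

with background-subtracted counts I_A, I_D. The efficiency histogram is
fitted with a Gaussian to give the mean E and its FWHM. The minimum possible
width comes from binomial partitioning of N photons ("shot noise"),
σ = √(E(1−E)/N); the observed-to-shot-noise width ratio measures the extra
broadening from dye-linker motion and chain fluctuation.

**Calibration.** Double-stranded DNA rulers of 10–45 bp (0.34 nm/bp) with
known fluorophore separations R are measured and fitted with

&nbsp;&nbsp;&nbsp;&nbsp;E⁻¹ = 1 + (R/R_eff)⁶,

where the effective Förster radius R_eff = R₀·γ^(1/6) absorbs the detection
factor γ. The 10% uncertainty of the dye-linker length enters the
one-parameter weighted fit as an abscissa error (effective-variance method).
Mean efficiencies of the RNA samples are then inverted,
R = R_eff·(1/E − 1)^(1/6), with first-order error propagation.

**Length trend and linker correction.** Per buffer condition (TM: 5 mM
Mg²⁺; TE: Mg-free) the separations are regressed linearly on RNA length,
y = a + b·x, with 1σ confidence bands; subtracting the 1.5 nm total
dye-linker contribution converts fluorophore separations into 5′–3′
end-to-end distances. The near-constancy claim is quantified by the
fractional change of the fitted line over a ten-fold length span.

**Polymer interpretation.** End-to-end distances are converted into
exterior-loop contour lengths ℒ under a rigid rod (0.59 nm/nt, rounding up)
and under a worm-like chain with persistence length l_p (2.1 nm for free
ssRNA in Mg²⁺), using the mean-field radial end-to-end density and the
closed-form moment ⟨r²⟩ = 2·l_p·L − 2·l_p²(1 − e^(−L/l_p)). Predicted FRET
histogram widths for a fluctuating loop are compared with observed widths
to infer an effective loop rigidity.

## Worked example

```python
import rnafret as rf

# 1. calibrate against the ten dsDNA rulers (synthetic, sigma_E = 0.03)
points = rf.simulate_calibration_dataset(r_eff=8.5, noise_sd_E=0.03, seed=42)
model = rf.fit_calibration(points)
print(f"R_eff = {model.r_eff:.2f} +- {model.sigma_r_eff:.2f} nm")

# 2. a measured mean efficiency -> inter-dye distance
R, sR = rf.distance_from_efficiency(0.52, 0.02, model)
print(f"E = 0.52 -> R = {R:.2f} +- {sR:.2f} nm")

# 3. linker correction and exterior-loop contour lengths
d = rf.linker_correct(R)
rigid = rf.rigid_contour_nt(d)
wlc = rf.invert_contour_length(d, lp=2.1)
print(f"end-to-end = {d:.2f} nm")
print(f"rigid loop: {rigid.L_nt} nt; WLC loop (lp=2.1 nm): {wlc.L_nt} nt")

# 4. near-constancy of the published TM trend
fit = rf.LinearFit(a=6.8, b=7.2e-4)
print(f"10x length change moves the separation by {rf.fractional_change(fit, 550, 5500):.1f}%")
```

prints

```
R_eff = 8.42 +- 0.11 nm
E = 0.52 -> R = 8.31 +- 0.15 nm
end-to-end = 6.81 nm
rigid loop: 12 nt; WLC loop (lp=2.1 nm): 23 nt
10x length change moves the separation by 49.5%
```

The calibration recovers the generative Förster radius within its quoted
uncertainty; an efficiency slightly above one-half maps to a separation just
below R_eff; after removing the 1.5 nm linker share, a 6.8 nm end-to-end
distance needs at least 12 nt if the loop is rigid and about 23 nt if it
fluctuates with l_p = 2.1 nm; and the fitted length trend changes the
separation by less than 50% over a ten-fold span — a short, nearly
length-independent end-to-end distance.

A command-line interface mirrors the library
(`rnafret simulate | analyze | calibrate | infer | trend | contour |
reproduce`); `rnafret reproduce --seed 1 --out report/` runs the whole
synthetic study and writes a JSON report plus a measurement table.

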