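# Methods

This note documents the models, estimators, numerical choices and known
limitations of `hepaflux`.

## The measurement chain

One analyte measurement is a mass isotopomer distribution (MID): fractional
abundances of the m+0 … m+6 isotopologues of a glucose derivative fragment.
Two derivatives are monitored per sample:

* **glucose pentaacetate** (C₁₆H₂₂O₁₁) retains the C1 hydrogen → reports ¹³C
  *and* ²H mass shifts (the *combined* channel);
* **glucose aldonitrile pentaacetate** (C₁₆H₂₁NO₁₀) loses the C1 hydrogen
  during derivatization → reports ¹³C only (the *carbon_only* channel).

Because the [1-²H]galactose label sits at C1, the m+1 excess difference
between the two channels is the ²H enrichment; all other tracer-derived
species (m+2 from glycerol, m+3 from glycolytic recycling, m+6 from the
glucose tracer) are ¹³C-only and identical in both channels, so the pipeline
averages them across channels to use all measured spectra.

### Natural-abundance correction

The observed spectrum is the convolution of the tracer-labelling pattern with
the natural isotope envelope of the *entire* derivative fragment.  The
correction matrix is lower-triangular: column *j* is the envelope of a
molecule already carrying *j* tracer labels (those carbons excluded from the
natural pool), shifted by *j* and truncated at m+6.  Envelopes are built by
per-atom convolution with IUPAC abundances (¹³C 0.0107, ²H 0.000115,
¹⁵N 0.00364, ¹⁷O 0.00038, ¹⁸O 0.00205); all of C, H, N, O contribute, since
the sixteen fragment carbons alone put >15% of an unlabeled molecule's signal
into m+1 and ignoring the acetyl contribution would bias MIDA at exactly the
m+1/m+2 scale it depends on.

Correction solves `M·x ≈ y` by **nonnegative least squares** rather than
direct inversion: with measurement noise a direct inverse routinely produces
negative abundances, while NNLS is exact on noise-free data (the round-trip
error is at machine precision) and well-behaved under noise.  A 1/y-weighted
variant was evaluated and rejected: weights estimated from the noisy spectrum
correlate with the noise and bias the small corrected components by several
percent, whereas unweighted NNLS is unbiased in simulation.  The NNLS
residual norm is recorded per sample; residuals above a configurable
tolerance (default 0.02) set a quality flag but never drop data silently.

For the combined channel the matrix-column convention excludes carbons for
every labelled position, although the m+1 label may be a ²H; the error from
excluding a carbon instead of a hydrogen from a 16-C/21-H pool is below the
per-mille level.

### MIDA

Gluconeogenic hexoses are assembled from two triose phosphates.  With
precursor enrichment *p* (from [2-¹³C]glycerol), a newly synthesized molecule
is m+0/m+1/m+2 with weights (1−p)², 2p(1−p), p²; a pool containing fraction
*f* of new molecules scales that pattern by *f*.  The estimator inverts the
ratio r = E₂/E₁ → `p = 2r/(1+2r)`, then `f = E₂/p²`.  The model is exactly
identified (two excesses, two parameters); the inversion is exact to 1e-12
over p ∈ [0.02, 0.3] × f ∈ [0.05, 0.95].  Note that f as a function of E₂ at
fixed E₁ is U-shaped with vertex at E₂ = E₁/2; it is monotone increasing only
above the vertex, which is where physiological measurements lie.

m+1/m+2 for MIDA are taken from the carbon-only channel (m+1) and the
channel-averaged m+2, so the ²H label cannot contaminate the MIDA input.
*p* is estimated per analyte (blood glucose and UDP-glucose may see different
precursor pools under zonation); when the UDP-glucose m+1 excess is below the
noise floor the blood-glucose *p* is used as fallback.

## Flux closure

The shipped closure ("g6p-balance") is listed in the README.  Design points:

* **Turnovers are total appearance** (tracer included); EGP = Ra − I₆ is
  reported alongside, and both are emitted because either convention may be
  wanted downstream.
* **Glucose-cycling correction**: measured EGP underestimates G6Pase because a
  fraction c(glc) of G6Pase output is re-phosphorylated blood glucose;
  `G6Pase = EGP/(1 − c(glc))`.
* **GS = Ru − Igal**: galactose enters UDP-glucose directly, so the
  G6P-derived synthesis excludes it.  UDP-glucuronidation (the paracetamol
  sampling sink) is assumed negligible and not subtracted.
* **Glycolysis is not a model flux** — it cannot be sampled repeatedly
  in vivo — so GCK and GNG are lower bounds; this is a documented property of
  the method, not corrected for.
* **Infeasible animals are reported, never clipped**: if measured
  c(glc) + f(UDPglc) > 1 the implied phosphorylase flux is negative and the
  animal is listed with the offending value.  Near-boundary groups (high GNG
  fraction plus high direct-pathway exchange) genuinely produce such
  exclusions under measurement noise.
* Tracer isotopic purity defaults to 0.99; dilutions are purity-normalized.
* The closure is registered in a registry (`register_closure`) so an
  alternative equation set can be plugged in and cross-validated; only the
  G6P-balance closure ships, as it is fully determined by the balance
  identity and the parameter definitions.

Fluxes are per kilogram body weight per minute; molar conversion uses the
labelled tracer masses (186.11 for [U-¹³C]glucose, 181.16 for
[1-²H]galactose).

## Steady-state handling

The averaging window is fixed at 240–360 min.  A plateau diagnostic — the
relative drift (last − first)/|last| of the primary enrichment series across
the window — is attached per animal; a mono-exponential pool with τ = 60 min
drifts 1.6% (passes the 10% threshold), τ = 300 min drifts 21% (flagged).
The window is never shrunk adaptively: reproducibility of the averaging rule
beats per-animal optimisation.

The six steady-state parameters are computed from **window-averaged excess
enrichments** (ratio of means), not by averaging per-time parameter ratios.
Averaging ratios carries a Jensen bias on the noisiest (MIDA) parameters
(~+2% on f under the default noise model) which propagates to roughly −8% on
GP, the balance remainder.  The per-time parameter series are still produced
(`FluxResults.timecourses`) as diagnostics, and the generic windowed-mean
operation (`stats.average_window`) is available.

## Group statistics

Two-way ANOVA (factors shRNA and infusion plus interaction) with **type-II
sums of squares** — the conventional choice for a possibly mildly unbalanced
2×2 design — followed by Tukey HSD on the four cell means.  Only the four
contrasts of the study's marking scheme are reported: the shRNA effect within
each infusion and the infusion effect within each shRNA, at α = 0.05.
Summaries are mean ± SEM.  On synthetic cohorts with a pure infusion effect
of 3 SD (n = 7/cell) the scheme flags both infusion contrasts and neither
shRNA contrast in ≈96% of replicates.

## The synthetic experiment generator

The generator replaces the animal cohort.  It emulates:

* steady-state enrichments of both pools under the three tracers, obtained by
  **exact algebraic inversion of the flux closure** from the true fluxes, so
  that a noise-free, post-plateau dataset recovers the truth to numerical
  precision — the principal acceptance surface;
* mono-exponential approach to isotopic steady state (one well-mixed pool per
  analyte, default τ = 40 min, consistent with plateau well before 240 min);
* the sampling scheme: blood spots every 60 min (0–360), urine hourly
  (60–360) with a one-interval collection lag (glucuronide accumulates before
  voiding);
* natural-abundance convolution per derivative channel;
* multiplicative mean-one log-normal noise per isotopologue, default CV 5%.

Two reported parameters are not pinned down by the five balance fluxes and
get label-routing defaults, overridable per truth record:
`f(glc) = f(UDPglc)·G6Pase/Ra` (G6Pase output carries the G6P pool's new-F16P
fraction into blood) and `c(UDPglc) = (GP/T)·G6Pase/Ra` (UDP-glucose-derived
carbon reaches blood via GP then G6Pase).  Glycolytic recycling is modelled
phenomenologically: the m+3 excess is a fixed fraction of the m+6 excess per
pool (default 0.2), so the m+3/m+6 ratio estimator recovers the injected
fraction exactly.

The default precursor enrichment is p = 0.18.  The study the package models
reports group SEMs for the MIDA fractions of ~0.004–0.013 at n = 6–7, i.e.
per-animal CVs of 3–5%; under the 5% per-isotopologue noise model the m+2
signal (f·p²) only reaches that precision for p around 0.15–0.2, so 0.18 is
the realistic operating point of the protocol's hefty glycerol infusion
(16 mg/mL at 0.5 mL/h).

Between-animal variability jitters the free fluxes log-normally (default CV
10%) with GP closing the balance; draws with negative GP are rejected and
redrawn.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: chromatographic artefacts and spectral overlap between
fragments; drift in blood glucose concentration over the infusion;
within-animal correlation of measurement errors across time points;
G6PC-independent glucose production (AGL/GAA routes), which the flux model
folds into GP and G6Pase; and any pharmacodynamics of the G6P-transport
inhibitor beyond its effect on the chosen truth fluxes.

## Precision of the recovered fluxes

Under the default noise model with n = 7 animals, the group-mean fluxes are
recovered with median relative errors of roughly 0.7% (G6Pase), 2% (GCK), 3%
(GS), 4% (GNG) and 8–10% (GP) at study-like truths.  GP is intrinsically the
least precise: it is the remainder of the balance, so it accumulates the
absolute errors of all other fluxes while usually being the smallest of them.
Reported per-animal exclusions (infeasible parameter sets) truncate the f
distribution slightly; at default conditions they affect ~2–4% of animals.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run: 1,000 random MIDs for the
correction round trip; a 15×19 (p, f) grid for the MIDA inversion; cohorts of
2 (noise-free) and 7 (noisy) animals with 30–100 replicates for flux
recovery; 10,000 random feasible parameter draws for the conservation
identity; and 200 replicates for the contrast-scheme detection rate.  These
sizes give stable estimates of each quantity while keeping a full run in the
minutes range on a single CPU.

## Known limitations

* Only the steady-state (algebraic) problem is solved; isotopically transient
  data are out of scope.
* The closure cannot separate renal/extrahepatic from hepatic glucose
  production, or AGL/GAA-mediated glycogenolysis from PYGL flux.
* Spectral overlap between co-eluting fragments is not deconvolved; inputs
  are assumed to be clean integrated isotopologue intensities.
* With per-sample noise, the NNLS nonnegativity constraint can activate at
  near-zero components (m+4, m+5), making their corrected values slightly
  biased; the flux parameters use m+1, m+2, m+3 and m+6 only.
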