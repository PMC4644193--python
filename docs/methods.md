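# Methods

## Model

All forward models are linear time-invariant filters.  An emitting state
with decay rate Γ = 1/τ driven by a nonnegative excitation g(t) obeys
dn/dt = −Γn + g(t); its transfer function is the single pole 1/(s+Γ).
Multi-exponential emission (`MultiExpModel`) is the weighted parallel
sum F(iω) = Σ f_k/(1+iωτ_k).  Fractions are not forced to sum to one;
all phase/modulation reports normalize by |F(0)|, so only relative
weights matter.  Phases are lags and are reported positive, the plotting
convention of frequency-domain fluorometry; modulation is normalized to
1 at DC (the final algebraic form the quantity takes is
1/sqrt(1+(ωτ)²) for a single lifetime, which is what `phase_mod`
evaluates).

The three-level scheme (ground → pumped level → emitting level) is kept
in two forms.  The transfer function (`three_level_transfer`), valid
under weak pumping, is second order: gain Γ32 with poles at −Γ21 and
−(Γ31+Γ32); initial-population transients are deliberately not part of
it.  The full rate equations, including ground-state depletion, live in
the oracle (`three_level_integrate`) and are used to validate the
weak-pumping transfer function by FFT demodulation.

Instrument chains are cascades: `cascade` multiplies gains and
concatenates poles/zeros, so drive electronics, fluorophore and detector
are treated on an equal footing.  A single RC low-pass stage maps to an
equivalent lifetime 2πRC (`lifetime_from_rc`); the two second-stage RC
parameter sets used in the cascaded-low-pass demonstration are exposed
as `CIRCUIT_STAGE2_PARAMS` without curve labels, because the available
descriptions of which set belongs to which curve are mutually
inconsistent.

## Closed forms and their verification

`closed_form` holds the residue inversions of the Bromwich integral for
an impulse, a sine, a positively biased cosine g = A(1−cos ωt)/2, and a
biased square wave swinging 0→2.  Two printed variants of these
inversions circulate with sign/factor errors; the forms implemented here
are gated on two hard conditions: the zero-initial-population boundary
value n(0) = 0, and pointwise agreement with the numeric convolution
oracle.  Concretely:

* the biased-cosine inversion carries a **+cos ωt** term (the variant
  with −cos violates n(0)=0 and is kept only behind
  `literal_printed=True` for comparison);
* the square-wave inversion has transient factor 2/(1+e^{πΓ/ω}) and
  harmonic factor (4/π)Σ_{k odd ≥ 1} — equivalently (2/π) summed over
  *all* odd integers k, pairing ±k poles.  With these factors r(0) = 0
  exactly and the series matches the steady state of the exact
  piecewise-exponential solution to ~1e−10 away from the drive edges.

The square-wave series is truncated at `n_terms=200` odd harmonics by
default; the Gibbs wiggle near drive edges is accepted, with amplitude
set by the 1/(k²ω²+Γ²) tail (about 1.6e−3/Γ at the edge samples for
ω = Γ, far below plotting resolution elsewhere).

## Numeric oracle

`convolve_response` advances each pole with an exponential-integrator
recursion, y[n] = e^{−Γdt}y[n−1] + dt[(e1−e2)g[n−1] + e2 g[n]], which is
the *exact* convolution of e^{−Γt} with the linear interpolant of the
drive samples.  There is no stability constraint, so decay rates
separated by four or more decades pose no stiffness problem; the
coefficients switch to series for Γdt < 1e−4 to avoid cancellation.  Its
weights follow the superposition integral literally (impulse response
Σ f_k e^{−Γ_k t}); the DC amplitude fraction of component k is therefore
f_kτ_k, and the synthetic-acquisition layer rescales weights by 1/τ when
a DC fraction is prescribed.

Two discrete-sampling facts matter when comparing simulations to
continuous-time formulas, and tests account for both:

* a sampled rectangle's linear interpolant is the ideal rectangle
  advanced by half a sample, so closed forms are evaluated at t + dt/2
  when compared against responses to sampled square drives;
* a sampled pulse train's k-th DFT bin has magnitude
  |sin(πkM/N)/(N sin(πk/N))| and centroid phase πk(M−1)/N (pulse width M
  of N samples per period); the continuous sinc law D|sin(πkD)/(πkD)|
  and phase πkD are recovered in the N→∞ limit after the same
  half-sample correction.

`three_level_integrate` advances the full 3×3 linear system by matrix
exponentials with the drive held constant within each sample
(zero-order hold), caching the exponential per distinct drive level —
square and pulse drives need only two.  Total population is conserved to
machine precision by construction.  The zero-order hold delays the
extracted phase by half a sample (π/spc per harmonic order, 0.18° at
1024 samples per cycle), which sets the tolerance of the
transfer-function cross-checks.  A step with rate·dt > 50 is rejected
with an error naming the stiff rate.

## Harmonic demodulation

`harmonic_phases` emulates lock-in detection digitally: the trailing
n_blocks × cycles_per_block fundamental cycles of both records (trailing,
so turn-on transients at the head are excluded) are cycle-averaged per
block, FFT'd with a rectangular window on exact integer cycles, and each
harmonic order k carried by the driver yields a phase delay
arg(D_k)−arg(R_k) and a modulation ratio (|R_k|/|D_k|)/(R_0/D_0).  The
DC-bin normalization makes the modulation ratio → 1 at low frequency and
immunizes both estimates against overall gain and offset.  Records whose
sampling rate does not give integer samples per cycle are linearly
resampled onto the nearest integer-cycle grid rather than windowed.

An order is reported only when the driver bin power exceeds 1e−6 of the
fundamental bin power: phase is undefined at nulled orders (even square
harmonics, comb orders with kD integer).  Block phases are aggregated by
circular mean with deviations unwrapped around it; the reported
`phase_sd`/`mod_sd` are **standard errors of the across-block mean**
(block scatter / √n_blocks) — this is the quantity that shrinks with
more blocks and the correct inverse-variance weight when
`build_frequency_response` merges sweeps at coinciding frequencies.
Wrapping conventions: principal value (−180, 180] by default, the
arctangent sawtooth [−90, 90) on request, and an order-unwrapped variant
for multi-decade curves.

## Fitting

`fit_lifetimes` is weighted nonlinear least squares on the phase curve
(modulation can join the objective, but a two-component modulation curve
differs only subtly from a single-exponential one, so phase-only is the
default).  Parameters are log τ_k (positivity, and lifetimes spanning
four decades keep comparable step scales) and softmax logits for
fractions (nonnegativity, scale invariance).  The phase objective of a
mixture is multimodal, so the solver restarts from one deterministic
log-spaced lifetime set plus seeded log-uniform draws over the curve's
reciprocal frequency span (8 starts by default); lifetimes are bounded
two decades beyond the probed band.  The covariance is the inverse
Gauss-Newton Hessian scaled by the residual variance; Monte-Carlo
calibration in the test suite shows ~69 % coverage of nominal 68 %
intervals for the slow lifetime under 0.5° phase noise.  Results are
reported with lifetimes sorted descending; a fitted fraction below 1e−4
or a lifetime outside the probed band is flagged.

## Synthetic acquisitions

`synth` emulates the full chain so every stage is testable without
laboratory data.  The stock mixture pairs a slow emitter with
τ = 0.5 ms against a fast emitter whose real lifetime (picosecond scale)
is so far below the probed band (≤ 125 kHz, where ωτ_fast ≲ 1e−6) that
it is modelled as a zero-lag frequency-flat contribution; a finite
fast lifetime can be used instead via an ordinary second component.
Acquisitions are square waves at 10 Hz, 250 Hz and 2.5 kHz — with 50
harmonic orders these span 10 Hz to 122.5 kHz (even orders carry no
power, so order 49 is the top point) — sampled at 1024 samples per
cycle, 4 blocks of 100 cycles each after a settle allowance of 10τ.
Detector: none by default; `default_detector` provides a unit-DC-gain
single pole 100× above the band edge (≤ 0.6° of phase) for band-limiting
studies.  Noise is additive white Gaussian on the response only, seeded;
the default sd of 0.002 (unit drive amplitude) is an arbitrary choice
that produces degree-scale error bars at high harmonic orders, since no
measured noise magnitudes were available to match.  No shot noise or
detector nonlinearity is modelled.

What passing the synthetic tests does *not* show about real data:
photon-counting statistics, drive-waveform distortion from real laser
diodes, detector saturation, and digitizer timebase jitter are all
outside the noise model; the pipeline's phase accuracy on real records
is bounded by those effects, not by the numerics validated here.

## Numerical choices and degenerate inputs

* All internal frequencies are angular (rad/s); user-facing interfaces
  take Hz and convert by 2π.
* Drives must be nonnegative (populations cannot be driven negative):
  a sine spec requires bias ≥ amplitude, and `generate` rejects any
  realized waveform going negative.
* `MultiExpModel` rejects coincident lifetimes (relative tolerance
  1e−9 by default): they are not identifiable and make fitting Jacobians
  singular.
* Rectangular drives align pulse edges to sample boundaries (width
  rounded to the nearest whole sample), keeping the discrete harmonic
  laws exact.
* `fit_lifetimes` refuses curves with fewer than 2(2n−1) points or a
  frequency span too narrow for the requested number of components.
* Problem sizes in the test suite (records of ~1e5 samples, 200
  Monte-Carlo fit replicates, 20 random oracle draws) are chosen so the
  whole suite runs in well under a minute while keeping Monte-Carlo
  bands a few binomial sigma wide.

## Known limitations

* The weak-pumping transfer function and the convolution oracle are
  linear; saturation and ground-state depletion appear only in the
  three-level ODE path.
* Arbitrary drives are handled only numerically (no closed forms beyond
  the four standard ones).
* The fitter estimates a discrete number of exponential components; it
  does not attempt lifetime-distribution (maximum-entropy) inversion,
  and the three-level rates are forward-model-only.
* Circuit equivalence stops at the 2πRC mapping; no netlist handling or
  op-amp modelling.
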