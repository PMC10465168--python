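# Methods

This note documents the models, the numerical choices and what the
synthetic experiments do and do not show.  Empirical numbers quoted here
are the ones the test suite and `scripts/acceptance.py` compute.

## Opsin kinetics

ChR2(H134R) is modeled with the double two-state ("RSRS") formulation:
two independent gates with first-order relaxation

    dX/dt = (X∞(Irr) − X) / τ_X(Irr, V),   X ∈ {O, R}

where `O` is the open fraction and `R` the slow dark-light adaptation
factor.  Both steady states and the irradiance parts of the time
constants follow the pattern `a / (1 + e^b · Irr^c)`:

    O∞ = 1/(1 + e^5.45 · Irr^−0.70)
    R∞ = 1 − 0.77/(1 + e^16.33 · Irr^−3.62)
    τ_O(Irr) = 0.021/(1 + e^1.55 · Irr^0.37)          ms
    τ_R(Irr) = 10·(1 − 0.56/(1 + e^−1.82 · Irr^−0.50)
                     − 0.44/(1 + e^17.82 · Irr^−3.95)) ms
    τ_O(V) = 23.14/(1 + e^−(V+0.39)/13.19)             ms
    τ_R(V) = 99.74/(1 + e^−(V+38.69)/12.02)            ms
    τ_X(Irr, V) = [τ_X(Irr)⁻¹ + τ_X(V)⁻¹]⁻¹

Irradiance is in mW/mm², voltage in mV.  Every constant is a field of
`OpsinParams`, so a revised parameterization is a configuration change.
The current density is `i = g_ChR2 · D(V) · O · R` (mA/cm² with g_ChR2 in
S/cm², the NEURON-style mV convention absorbed into the coefficients),
with `D(V) = 1 − 1.25·e^−(V−E)/44.52` and `E_ChR2 = 0`.  `D` crosses zero
at +9.93 mV — the effective reversal — and `G = D/(V−E)` equals 0.0707 at
−68.83 mV, which is where the 14.14× and 12.89× conductance-scale factors
relative to G-normalized formulations come from.

Two consequences of this parameter set matter for interpretation:

* `O∞` half-activates only near ~2.4 W/mm² while `R∞` collapses near
  ~0.09 W/mm².  The steady product `O∞·R∞` is therefore *non-monotone*
  over roughly 0.1–0.5 W/mm²: a cell can spike in a narrow irradiance
  window and fail both below and above it.  The titration logic accounts
  for this (below).  Peak and steady photocurrents are monotone in
  irradiance over the 10⁻³–30 mW/mm² range that single-pulse protocols
  probe, which is the range the monotonicity tests assert.
* `τ_O` is short everywhere (≤ 23 ms, sub-millisecond at rest), so the
  opening gate tracks `O∞` nearly instantaneously; the photocurrent's
  temporal structure is dominated by `R`.

**Initial condition** is dark adaptation, `(O, R) = (0, 1)` — the Irr→0
steady state of the equations, appropriate for cells at rest before the
first pulse.  **Integration** is exponential Euler per gate
(`X ← X∞ + (X−X∞)e^−dt/τ`), exact for piecewise-constant inputs and
unconditionally stable for the stiff τ values at high irradiance; the
default dt is 0.025 ms.  A τ floor of 10⁻⁹ ms guards the harmonic
combination where `τ_R(Irr) → 0` at saturating light.

## Light transport

Photons launch uniformly over the fiber disk (100 µm radius) with
directions uniform in solid angle inside the NA cone (half-angle
`asin(NA/n)`, NA = 0.39); a uniform launch profile is assumed.  Transport
uses Henyey–Greenstein scattering (inverse-transform sampling), implicit
absorption weighting and Russian roulette (threshold 10⁻⁴, survival 0.1).
The tally is the MCML-style interaction-site estimator: at each collision
the fraction µ_a/µ_t of the weight is deposited in the enclosing
cylindrical voxel; fluence rate is deposited weight / (µ_a · voxel
volume), normalized by the fiber-face irradiance to give a unitless gain.
A track-length estimator would have lower variance per photon but costs
~30× more per history at 5–10 µm voxels (the mean free path is ~85 µm);
at the photon counts used here the interaction estimator resolves the
beam with <1% noise where it matters.  The grid boundary is absorbing and
escapes are recorded; energy bookkeeping (absorbed + escaped +
roulette-net = launched) closes to 10⁻¹¹ relative and is asserted at
10⁻⁶.  Refractive-index mismatch at the fiber face is ignored beyond the
NA-cone restriction.

Default optics are gray matter at 470 nm: µ_a = 0.42 mm⁻¹,
µ_s = 11.33 mm⁻¹, g = 0.88, n = 1.36.  The production grid is
r ∈ [0, 5] mm × z ∈ [−4, 6] mm at 5 µm; tests run 10–50 µm grids with
10⁵–10⁶ photons, which keeps each field under ten seconds on one core
while leaving the Beer–Lambert slope recoverable within 2%.

Fiber placement maps cell coordinates into the fiber frame for three
pitches: π/2 (fiber axis along +x, light travelling toward −x, the
position grid x ∈ [−1000, 4000] µm), 0 (axis +z, fiber below, lateral
offset x ∈ [0, 2500] µm) and π (axis −z, fiber above, same offsets).
`roll` rotates the morphology about the somato-dendritic z axis before
the transform.

## Morphologies

The generators produce stochastic binary trees with tapering diameters:
pyramidal cells (soma cylinder, thin descending axon, basal tree into −z,
apical trunk + tuft along +z) and interneurons (undifferentiated
dendrites, large lateral axonal arbor; `bistratified` and `basket`
presets).  Default parameters are calibrated so region areas fall in the
bands of reconstructed CA1 cells — soma ≈ 700 µm² (band 400–1,400),
pyramidal basal ≈ 5.9·10³, apical ≈ 1.2·10⁴, interneuron axons 2.7·10⁴
(basket) and 8.4·10⁴ (bistratified) µm² — calibration, not replication of
any particular reconstruction.  What the synthetic cells do **not**
emulate: realistic branch statistics, spines, myelin, the layer-specific
targeting of real bistratified/basket axons, or the ten fitted
conductances of data-driven CA1 models.  Passing tests therefore show the
pipeline's machinery is correct on CA1-like geometry, not that its
absolute thresholds match any measured cell.

Sections are discretized into segments of at most 20 µm (a fixed-length
rule rather than the frequency-based d-lambda rule; configurable).
Surface areas are frustum lateral areas summed per segment.  Opsin
placement is uniform over a chosen region at fixed total conductance:
`g_ChR2 = G_max / A_region` (so `Σ g·A = G_max` exactly), making the
specific conductance locally higher for smaller regions — the mechanism
behind the excitability gain from subcellular confinement.  SWC import
follows the standard type codes {1 soma, 2 axon, 3 basal, 4 apic}, with
basal/apic collapsed to `dend` for interneurons; PCA-based alignment puts
the somato-dendritic axis on z (apical +z) and the soma centroid at the
origin.

## Membrane model and solver

The simplified membrane carries leak (0.3 mS/cm², E = −70 mV), transient
Na and delayed-rectifier K with classic Hodgkin-Huxley rate functions in
a −65 mV resting frame, and per-region density scaling (defaults, S/cm²:
Na 0.30/0.12/0.03 and K 0.06/0.036/0.01 for axon/soma/dendrites); the
Na:K ratio per region is a configuration knob.  C_m = 1 µF/cm², axial
resistivity 150 Ω·cm.  Voltages start at −70 mV with a 100 ms settling
period before the pulse; the cell rests quietly (drift < 0.5 mV over the
protocol without light).

The voltage step is backward Euler on the branched tree: per-step Hines
elimination (children eliminated into parents, O(n)), with HH and opsin
gates advanced by exponential Euler using the previous voltage.  The
photocurrent's voltage dependence is linearized about the previous
voltage; its slope `g·O·R·(1.25/44.52)e^−(V−E)/44.52` is nonnegative, so
the system matrix stays diagonally dominant.  The simulation horizon is
`T_end = max(500 ms, t0 + pd + 100 ms)` so the channel-closure tail is
always integrated.  Validation: steady-state attenuation along a sealed
passive cable matches `cosh((ℓ−x)/λ)` within 2%; a passive sphere's input
impedance matches `1/(G_leak·A)` within 2%; single-compartment spike
thresholds move by <2% under 4× dt refinement.  Both kernels are
numba-compiled (cached), making a 500 ms simulation of a ~400-segment
cell ≈ 0.5 s and a ~80-segment test cell ≈ 0.1 s on one core.

## Thresholds, TAC, SoFPAN

Titration brackets the threshold with a decade scan upward from
10⁻³ mW/mm² (shifting down geometrically if even the lowest probe
spikes), then runs seven bisections and returns the final bracket
midpoint; above the 10³ mW/mm² cap the position is recorded with a
"no threshold" sentinel.  Because of the non-monotone irradiance window
noted above, a failed decade scan is retried once on half-decade
midpoints before the sentinel is declared; windows narrower than a factor
~3 can still be missed, a discretization limit of the same kind as the
position grid itself.

`TAC = (1/pd) Σ_j A_j ∫_{t0}^{T_end} i_j dt` is integrated by trapezoid;
the signed value follows the net photocurrent (inward = negative) and the
pipeline tables report its magnitude.  The SoFPAN at a fiber intensity
marks grid nodes whose threshold lies below it.  The point estimate
weights each activating node by the fraction of its discretization cell
inside the explored domain (interior 1, edges ½, corners ¼), so the
fully-activated π/2 map equals the 10×10-cell domain area of 5.5 mm²; the
lower bound counts cells with all four corners activating; the upper
bound does the same after 3×3 binary dilation of the node field (dilation
acts on nodes, not cells).  Maps for pitches 0 and π are doubled,
exploiting the mirror symmetry of their half-plane grids.  The
uniform-field approximation collapses the cell to its soma
(`I_th(x, z) = I_th^uniform / gain(x, z)`); its relative SoFPAN error is
`(uniform − MC)/MC`, reported as +∞ when MC = 0 and −100% when only the
uniform estimate vanishes.  Optimal/worst fiber depths maximize/minimize
the activation depth per z row, with mean-TAC tie-breaking (lowest TAC
wins the optimal slot — the gentlest stimulus that works) and a
deterministic fall-through to the first grid row.

## Regression, scoring, sensitivity

The Lapicque step fits `TAC₀/(1 − e^−pd/τ)` by least squares on
log-transformed values: TAC spans decades over the pulse-duration grid
and the measurement error is multiplicative, so log residuals are
homoscedastic and the asymptote is well conditioned.  The second step is
ordinary least squares of `log₁₀ I_th` on `log₁₀ G_max` and
`log₁₀ TAĈ`; adjusted R² uses the n−3 denominator.  Sentinel rows
(no threshold) are excluded from both steps.

Wilcoxon scoring runs the one-sided paired signed-rank test for every
ordered class pair, awarding 1 / 0.1 / 0.01 points for p < 0.001 / 0.01 /
0.05; zero differences are discarded (the standard convention), identical
vectors score zero by construction, and the implementation is
cross-checked against exact enumeration of all 2ⁿ sign assignments for
n ≤ 10.

The elementary-effects screen uses the radial design on scrambled Sobol
points: repetition i takes a base point from the first k coordinates and
perturbs one factor at a time toward the auxiliary coordinates.  Effects
are differences per unit step *in the unit hypercube*, which puts
physical (normal, truncated at ±4 SD so optics stay positive), angular
(uniform roll) and categorical (cell, opsin location; the auxiliary
coordinate is forced onto a different class) factors on one scale.  µ* is
the mean absolute effect, σ the effect SD (nonlinearity/interaction);
ranks sort by µ*.

## Problem sizes

The test suite and recipes run deliberately reduced configurations chosen
to exercise every code path while staying desk-scale: 10⁵-photon fields
on 10 µm grids (10⁶ for the Beer–Lambert check), reduced synthetic cells
of ~80 segments at 40 µm discretization, 5×5 fiber-position sweeps, two
to three points per pd and G_max grid, and r = 2–4 elementary-effects
repetitions.  Production-scale settings (10⁷ photons at 5 µm, 121
positions, 8×5 G_max×pd grids, r = 16) are plain configuration values on
the same functions.

## Known limitations

* The Eq-block constants were transcribed from a typographically
  collapsed source; the `a/(1+e^b·Irr^c)` reading is exposed in
  configuration precisely so a corrected parameterization drops in.
* Single-pulse excitation only: no pulse trains, bursting,
  depolarization-block characterization, synaptic input or networks.
* Homogeneous tissue, flat-tip fiber, single wavelength; no heating.
* The simplified Na/K membrane reproduces spiking and input-impedance
  gradients, not the quantitative channel repertoire of fitted CA1
  models, so absolute thresholds are indicative only.
* 2D fiber-position plane (a surface, not a volume of activation).
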