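# Methods

This note documents the models behind `musmb`, the choices made where the
design was genuinely open, and what the synthetic data do and do not
represent.

## Column model

Each SEC column is a lumped rate model with pores (LRMP): one bulk
(interstitial) phase with convection, axial dispersion and a linear
film-transfer term, and one well-mixed pore phase per species. There is no
adsorption; retention differences come entirely from the size-exclusion
distribution coefficient *K*<sub>d</sub>. A general rate model (radial
intraparticle gradients) adds nothing here because film transfer and
intraparticle diffusion cannot be distinguished from pulse experiments on
this system, at substantially higher cost.

For a fully excluded species (*K*<sub>d</sub> = 0) the pore phase holds no
mass; the implementation drops the exchange term entirely instead of
integrating a singular equation.

Discretisation: finite volume, first-order upwind convection, central
dispersion, Danckwerts (total-flux) inlet and zero-gradient outlet.
Integration: LSODA with a banded Jacobian (states interleaved as
c₀, c_p,₀, c₁, c_p,₁, …), rtol 10⁻⁶ / atol 10⁻⁹. Species are independent
and integrated separately. Defaults: 60 axial cells (a grid-refinement
test bounds the first-moment error of doubling the resolution below
0.2%); pulse mass balances close to ~10⁻⁷ relative. Negative
concentrations from solver oscillation are floored at zero for reported
chromatograms only, never inside the integrator state.

Transport parameters per zone flow: interstitial velocity
u_int = Q/(A·ε_int) (the standard interstitial convention), axial
dispersion from the Chung–Wen correlation (defined to return 0 at zero
velocity so stopped-flow zones are representable), film transfer from
Wilson–Geankoplis, molecular diffusivity from the Polson scaling when not
supplied. Water properties default to 20 °C (ρ = 998 kg/m³,
η = 1.002·10⁻³ Pa·s), configurable.

Units: configuration and public APIs use bench units (mm, µm, µL/min, mM
or g/L, s); conversion to SI happens once in the parameter dataclasses.
The model is linear, so concentration units pass through unchanged.

## Column parameter defaults

The physical columns of the reference system are 3 × 50 mm (≈353 µL)
packed with a dextran desalting resin. The packing-level parameters are
not published, so the synthetic defaults are stand-ins, chosen once and
exposed in config: ε_int = 0.38, ε_p = 0.60 (together giving the classic
ε_total ≈ 0.75 of such resins), d_p = 80 µm (midpoint of the vendor range),
*K*<sub>d</sub> = 1 for acetone and Tris (fully permeating), 0 for blue
dextran and myoglobin (fully excluded), system dead time 0 s. Tracer
simulation plus the moment-based porosity estimator recovers these values
to well under 2%.

Moment correction: whether measured retention times should be corrected
for the injection-plug width is an analysis choice; `first_moment` exposes
`injection_width_s` (subtracting half the plug width) and applies no
correction by default.

## SMB process

Four zones, one column per zone, open loop (zone-4 effluent to waste, no
recycle). Node balances: Q₁ = diluent, Q₂ = Q₁ − extract, Q₃ = Q₂ + feed,
Q₄ = Q₃ − raffinate = waste. Draw nodes split flow at equal concentration;
the feed node mixes c = (Q₂·c_out,Z2 + Q_F·c_F)/Q₃. Columns advance one
zone upstream per switch (implemented as index rotation). Because the
loop is open there is no feedback within a switching interval, so the four
columns are integrated sequentially, each taking the interpolated outlet
of its upstream neighbour as inlet — exact up to the sampling grid
(default 1 s for recorded traces, 0.5 s internally). A test verifies that
one switching interval of the process is bit-identical to chaining the
single-column solver by hand.

Triangle design: with H_i = ε_p·K_d,i, the complete-separation constraints
are m₄ < H_weak < m₂ < m₃ < H_strong < m₁. The designed point places
m₂/m₃ symmetrically inside (H_weak, H_strong), shrunk by the safety
fraction, m₁ above H_strong by the same relative margin, and then derives
zone 4 from the *fixed* raffinate flow (it feeds the ESI source at a set
rate); if the implied m₄ violates its bound the design raises rather than
silently moving the raffinate flow. Note that with a fully excluded
protein (H_weak = 0) a small raffinate draw can make zone 4 infeasible at
short switching times — the shipped experimental preset (122/44/15/30/63
µL/min, 120 s) is used directly and bypasses the design step.

Per-switch flow spikes of the physical valve are not modelled in the
fluid dynamics (they are too short to affect separation); they could only
be injected as measurement noise.

Inter-column heterogeneity: real columns are never packed identically.
`heterogeneous_columns` perturbs ε_int and ε_p per column by a seeded
uniform factor (default ±1%), which reproduces the observed pattern that
consecutive raffinate peaks differ while every fourth peak (same physical
column) is comparable. The experiment generator uses this by default.

CSS detection: the first cycle whose stream profile matches the previous
cycle within a relative L2 tolerance, default 10⁻². At the default
synthetic conditions with a 100 mM Tris feed the strict 1% criterion is
met at cycle 5; at a sensor-noise-level tolerance (0.1) the pattern
already recurs from cycle 4, matching the "settles within the first few
cycles / ~20 min" impression a conductivity trace gives by eye. Desalting
level and recovery are averaged over cycles at/after the detected CSS, so
they are independent of process duration.

The idealised synthetic columns desalt better (~99.9% at the preset) than
a real packing of this resin (~98%); packing defects and extra-column
effects that degrade single-column efficiency are deliberately not
modelled. Conclusions about absolute desalting of real hardware should
not be drawn from the defaults. Each CSS switching interval shows one
dominant Tris front cresting at the switch instant; the two-front fine
structure seen on sensitive instruments depends on single-column
efficiency and is not forced by the generator (a regression test records
at least one front per switch).

## MS detector model

Profile TOF scans on m/z 400–2600 (default grid 0.01, resolving the
±0.02 XIC window with ≥5 samples), 0.25 s accumulation. Proteins appear
as Gaussian peaks (σ = 0.05 m/z, height-normalised) at
m/z = (M + n_Na·21.98252 + z·1.00728)/z for their charge states, with
geometrically decaying sodium-adduct abundances (ratio 0.5, up to 4
adducts). The ~22 Da adduct spacing follows from Na-for-H replacement;
observed spacings of "about 23 Da" on real instruments are treated as
rounding, not as a constant. HoloMb (17566.0 Da) carries charges 7–9
(weights 0.30/0.45/0.25); apoMb (16950.5 Da) defaults to charges 7–8 so
the native spectrum shows the five observed protein peaks (which of the
six holo/apo × charge combinations is absent is a config choice). Heme is
a fixed-m/z doublet at 616.18/633.16 (default 4:1, the oxidised fraction
being unpublished) with a 3× ion yield relative to the protein (smaller
molecules ionise better). Isotope fine structure is omitted; it is
visible on real spectra but enters no computation here.

Tris: signature peak at m/z 593.23 with a limited-growth (1 − e^(−c/c_sat))
response, ceiling 23 kcps, c_sat = 0.2 mM; plus flat broadband chemical
noise (18 cps per sample at saturation) over the whole range, which lifts
the 400–500 baseline by roughly an order of magnitude at high residual
Tris — this is what destroys the cyclic pattern of the
baseline-normalised Tris signal at high feed concentrations. A 2 cps
Tris-free floor represents instrument background. Counting statistics:
seeded Poisson draws at 1 count per cps.

Ion suppression: protein signals are scaled by a log-logistic law
f(c) = 1/(1 + (c/c₅₀)^h) in the *instantaneous* Tris concentration,
fitted through the anchors (0.01 mM, 0.88) and (1 mM, 0.38), giving
c₅₀ ≈ 0.40 mM, h ≈ 0.54. f(0) = 1 by construction and f is strictly
decreasing; the empirical low-concentration enhancement bump is
representable by adding anchors but disabled by default. Holo and apo are
suppressed equally, so the apo *fraction* is suppression-invariant and
its sub-interval variability comes from counting noise alone. Because
suppression acts on the instantaneous Tris level and the Tris
breakthrough is countercyclical to the protein elution, the
Mb-weighted detection through the µSMB is substantially better than
direct infusion of the same feed — an emergent property, not an injected
one. The absolute protein response (252,050 cps per g/L) is calibrated
once so that 0.2 g/L holoMb at 0 mM Tris reconstructs to the 46.4 kcps
group-integral reference of the study system.

## Processing chain

XICs sum intensity over center ± 0.02 m/z per scan; the baseline
chromatogram uses the fixed 400–500 window. Zero-charge reconstruction
sums, for each candidate mass on the 5–20 kDa / 0.5 Da grid, the
interpolated spectrum intensity at (M + z·1.00728)/z over all charges
mapping into the 1700–2600 input range; it is verified exactly against a
naive nested-loop transform. Peak-group integrals are trapezoidal over
center ± window (default ±60 Da, capturing the adduct satellites), with
optional flank-median background subtraction — recommended (and used by
the CLI) because the reconstruction of a noisy spectrum carries a
noise-floor pedestal that would otherwise bias small peak groups. The
apoMb percentage is A_apo/(A_apo + A_holo) per switching interval;
intervals with no signal report as missing.

## Synthetic experiments

`generate_run` chains SMB sections (column states persist across feed
exchanges, MS acquisition is continuous), renders the conductivity
sensors with the instrument's linear calibrations (extract:
15.359 mM/(mS/cm) + 0.3656 mM; raffinate: 15.382 + 0.2993) and Gaussian
sensor noise (σ = 0.01 mS/cm — the true noise magnitude is unpublished;
this value is a config default), and streams MS scans into XICs, the
baseline trace and per-switch mean spectra without holding every scan in
memory. A dense scan series (exportable as mzML) is stored only on
request. All randomness derives from one run seed via seed-sequence
substreams, so bundles are bit-reproducible. Optional flow-stop events
zero the spray during the event, mimicking feed-bottle exchanges; they
are off by default. The raffinate-to-MS delay volume is zero by default
(the physical setup minimises it by omitting the raffinate conductivity
cell when coupled); a pure time lag can be configured.

Shipped plans: a stepwise Tris escalation (0/1/5/10/50/100 mM at 0.2 g/L
Mb, eleven cycles for the stability section then three per concentration),
a constant 10 mM / six-cycle run, and a stand-alone 100 mM conductivity
run. The fed myoglobin carries a constant apo fraction (default 0.08, a
typical impurity level for commercial preparations); free heme is
generated 1:1 with apoMb.

Note on the conductivity route: with the idealised columns the raffinate
Tris (~0.05 mM at 100 mM feed) sits below the sensor's calibration
intercept (0.2993 mM), so the conductivity-derived concentration
saturates at the intercept. The resulting desalting estimate (~99.6%) is
a *lower bound* that still lies within one percentage point of the
simulated truth (~99.9%) for this process — the end-to-end recovery test
asserts exactly that, and nothing stronger.

## Problem sizes

Defaults for tests and the acceptance script were chosen as sensible
study sizes: SMB runs of 2–6 cycles at 20–60 axial cells; MS rendering of
long runs at 1–4 s scan spacing and 0.02–0.1 m/z steps (single-spectrum
accuracy checks use the full 0.25 s / 0.01 resolution). The quantities
reported are cycle-averaged or anchor-based and are insensitive to these
choices at the stated tolerances.

## Known limitations

No pressure–flow coupling, valve geometry or controller dynamics; no
closed-loop or multi-column-per-zone variants; no nonlinear isotherms; no
isotope-resolved or maximum-entropy deconvolution; no physical ESI model
(suppression is an empirical law, equal for holo and apo); single
mobile-phase temperature. Passing tests demonstrate internal consistency
of the simulator + analysis chain and reproduction of the reference
system's worked numbers, not predictive accuracy for any specific piece
of hardware.
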