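# Methods

This package models the centripetal transport of microtubule organizing
centers (MTOCs) toward the chromatin mass during meiosis I spindle assembly
in mouse oocytes, in two tiers: a phenomenological random walk in a drift
field (RWD), and a mechanistic 2D microtubule–motor simulation. This note
records the models, their assumptions, the parameters that matter, the
numerical choices, and what the synthetic data can and cannot show.

## Geometry and units

The oocyte is a 2D disk of radius `r_cell = 40 µm` with a concentric
chromatin disk of radius `r_chr = 10 µm`; coordinates are cell-centred
Cartesian µm, time in seconds, forces in pN (so viscosity is pN·s/µm² and
energies pN·µm). 2D is a deliberate reduction: the only motility dataset
this pipeline is designed around is 2D over time, and all fitted constants
inherit that projection.

## Tier 1 — random walk in a drift field

Each MTOC is a point particle. Per step of `dt = 0.1 s` its speed mixes a
directed component `v_eff = 0.008 µm/s` and a Brownian component
`sqrt(4·D_eff/dt)` with `D_eff = 0.006 µm²/s`, weighted by two sigmoid
fields `phi(r) = 1/(1 + exp((r − r_half)/s))`:

    speed = phi_a·v_eff + (1 − phi_a)·(phi_r·v_eff + (1 − phi_r)·sqrt(4 D_eff/dt))

`phi_a` is measured from the chromatin edge (attraction), `phi_r` from the
cell boundary (repulsion; its directed component also points inward, so one
directed angle suffices). The heading is the circular weighted mean — the
angle of the weighted sum of unit vectors — of the centre-pointing angle
and a uniform random angle, with the same nesting of weights as the speed.
The Brownian speed uses the square root of `4·D_eff/dt` because that is
the only dimensionally consistent choice whose per-step displacement
reproduces the 2D diffusion law `⟨Δr²⟩ = 4·D·dt` and hence the msd model
used for fitting. Particles are nucleated uniformly by area in the
cytoplasmic annulus; the chromatin disk absorbs (capture time `t_c`
recorded, particle removed); the cortex reflects radially — reflection is
the minimal containment rule, as only the repulsive field is specified
physically. `simulate_rwd(capture=False, reflect=False)` runs the free
configuration used for estimator validation (below).

## Motility statistics

All measures operate on tracks downsampled to 210 s frames (matching 3.5
min video sampling): instantaneous speed `v = δL/δt`; directionality
(tortuosity) `χ = d_net/L ∈ [0, 1]`, computed per whole track and binned
by the 5 µm radial bin of the nucleation position (bin width chosen to
match the granularity of ~6 bins over the 30 µm annulus); msd with
overlapping windows on an index-lag grid up to 3/4 of the track duration
(longer lags average too few window pairs); the drift–diffusion fit
`⟨r²⟩ = 4·D_eff·δt + (v_eff·δt)²` and the anomalous fit `⟨r²⟩ = 4·D′·t^α`
(α bounded to [0, 2]), both by bounded trust-region least squares; the
saturating distance–time fit `d(t) = d_max·t^n/(T_half^n + t^n)` on the
distance from the nucleation position, whose cooperativity `n` separates
pulling (n > 1, sigmoid) from pushing (n ≤ 1, parabolic), flagged
unreliable when R² ≤ 0.7; a log-space maximum-likelihood lognormal fit of
speeds reported as linear-scale mean and variance (the convention in which
the experimental mean is 8.8·10⁻³ µm/s with variance far below mean²);
and radial density (counts per annulus area, unit total mass).

Estimator notes. Ensemble msd curves pool per-track curves by lag index
with pair-count weights, and Eq-7 constants are fitted to the ensemble
curve, not averaged over per-track fits: per-track fits on 40-frame tracks
leak variance into the `(v·δt)²` term (spurious v ≈ 10⁻³ µm/s) and bias D
low by ~35%. The D roundtrip is validated in the free configuration
because absorption at chromatin plus reflection at the cortex truncate
large displacements and depress the fitted D by ~13% in the 40 µm
geometry; the same free configuration is used for the time-step check
(fit a boundary-less random walk, require the recovered D within 10%).

## Drift-field optimization

Field shapes are fitted by brute-force scanning (r_half, s) pairs. Each
candidate is simulated (3 replicates by default, averaged), its binned
χ(r) profile and capture-time frequency distribution (10-minute bins over
[0, T]) are scored against the reference with the modified weighted RMSE

    eps = sqrt( (1/n) Σ w_i (e_i − s_i)² ),
    w_i = n_i/n_max  if |e_i − s_i| ≤ sd_i   else   w_m = 2,

which down-weights sparsely sampled reference points and penalizes
simulated values outside one standard deviation (w_m = 2 exceeds every
n_i/n_max ≤ 1). Errors are ranked per variable (average rank on ties —
order-independent) and the sum rank is minimized. Reference bins that no
replicate occupies are scored against zero with the penalty weight. The
full 600-set grid crosses attractive r_half ∈ {0,5,10,15,20,25} ×
s ∈ {0.5,1,2,4,8} with repulsive r_half ∈ {0,2,4,8} × s ∈ {0.5,1,2,4,8}
(the published scan states the count but not the axes; the grid is
configurable). Desk-scale recovery runs use a 12-set slice (six attractive
r_half × two s, repulsive fixed at the short-range optimum) with 3
replicates — problem sizes chosen to keep a scan at minutes of CPU.

Two fidelity points matter for recovery. First, candidate simulations are
degraded through the reference dataset's observation model (jittered
frame sampling plus localization noise, recorded in the reference) before
χ is binned: localization noise inflates path length and deflates χ, so
comparing noisy reference χ against noiseless simulated χ systematically
favours weaker fields. Second, one 30-track dataset is close to the
identifiability limit for neighbouring field shapes — its capture-time
histogram holds only a couple of counts per 10-minute bin — so
self-consistency recovery is scored against several independently
generated replicate datasets, averaging each candidate's error across
them before ranking (the per-dataset scoring rule is unchanged; a single
dataset remains the default for fitting one reference, as with real
data). Capture-time bin uncertainties use a half-pseudocount binomial
standard error so empty bins carry a realistic band; bins wholly inside
the chromatin disk are excluded from χ references as localization
artifacts.

## Tier 2 — microtubule–motor model

MTOCs are rigid bodies of radius 0.2 µm anchoring `n_mt` filaments
(default 20; the plausible range is 20–120) at uniformly spaced rim
positions. Filaments are polylines with fixed rest segments of 0.5 µm and
one partial tip segment; polymerization is tip-local (the terminal segment
grows/shrinks, vertices are appended or dropped as it fills or empties),
so the base never moves through re-segmentation. Dynamic instability uses
the four-parameter model: cytoplasmic `v_g = 0.178`, `v_s = 0.205` µm/s,
`f_cat = 0.075`, `f_res = 0.023` s⁻¹ (bounded regime, mean length
`v_g·v_s/(v_s·f_cat − v_g·f_res) ≈ 3.2 µm`) and a stabilized pair
`f_cat = 0.0397`, `f_res = 0.0122` s⁻¹. A filament reaching zero length
immediately regrows at its anchor, keeping the filament count constant.
Filament length is capped by the vertex budget (7.5 µm at the default 16
vertices, 11.5 at 24); the cap is several mean lengths out, and at
initialization lengths are additionally clipped at the straight-line
distance to the cortex.

Motors are minus-end-directed (dynein-like): stiffness `k_mot = 0.1
pN/nm`, unloaded speed `v_m = 2 µm/s`, attachment rate 12 s⁻¹ within
`d_attach = 0.02 µm`, basal detachment 1.5 s⁻¹ escalating with load as
`r·e^{|f|/f₀}` (Kramers), end detachment 1 s⁻¹, stall force `f₀ = 2 or 7
pN`. The force–velocity relation is piecewise linear: full speed under
assisting or zero load, linear ramp to stall under opposing load (a stated
approximation of dynein's gear-like stepping; the original piecewise curve
is not published in a reproducible form). Immobilized motors are fixed
lab-frame anchors exerting Hookean forces at their attachment abscissa;
diffusible complexes carry two independent heads (never on the same
filament), diffuse with `D_c = 20 µm²/s` when free (initially cytoplasmic,
afterwards unrestricted, as after nuclear envelope breakdown), and when
doubly bound exert equal-and-opposite spring forces that coalesce asters.

Scenarios: `uniform` (uniform immobilized motors — the self-organized
null with cortical pushing), `clustering` (complexes only), `di_gradient`
(catastrophe/rescue interpolated between cytoplasmic and stabilized
values by the optimized attractive field evaluated at the filament tip),
`motor_gradient` (anchors rejection-sampled with acceptance ∝ the
optimized field), and `hybrid` (motor gradient + complexes). Capture is a
measurement, not a dynamical event: the chromatin disk is mechanically
passive here, and an MTOC counts as captured when its centre first enters
it.

### Integration scheme

Overdamped Langevin dynamics at `dt = 0.01 s`. Per-vertex drag is the
transverse slender-body value `4πη·l/ln(2l/d)` (η = 0.05 Pa·s, segment
l = 0.5 µm, MT diameter d = 25 nm), with half shares at filament ends;
the MTOC body uses the Stokes value for its 0.2 µm radius. Thermal forces
satisfy fluctuation–dissipation (`variance 2·kBT·γ/dt` per component,
kBT = 4.1·10⁻²¹ N·m), verified against the Einstein relation for a free
MTOC. The stiff linear terms — worm-like-chain bending (κ = 2·10⁻²³ N·m²
= 20 pN·µm², discretized on unit tangents so straight chains feel exactly
zero force for any segment lengths), motor springs (anchored at the motor
anchor, or at the opposite head's current position for complexes),
cortical confinement (linearized radial spring, 50 pN/µm, on vertices
outside the cell), and the minus-end anchor springs (2000 pN/µm penalty
coupling to the rigid body) — are integrated backward-Euler through one
symmetric pentadiagonal solve per filament per axis, batched across
filaments (vectorized two-band Thomas elimination; explicit treatment
would demand dt ≈ 10⁻⁴ s). Inextensibility is enforced by projection:
two red–black relaxation sweeps distribute length corrections along the
chain (so tip compression against the cortex propagates to the minus end
and pushes the aster), then one cumulative pass from the base makes
segment lengths exact — mechanics therefore conserves contour length to
machine precision, and only polymerization changes it. MTOC bodies move
by an implicit update driven by the anchor-spring reactions evaluated
after projection plus their own thermal force. Binding uses a neighbour
list (kd-tree over segment midpoints, rebuilt every 10 steps with a 0.35
µm skin; anchors are indexed once) with exact point–segment distances at
attachment.

Known mechanical simplifications relative to a constrained-dynamics
engine: penalty coupling instead of hard constraints at the minus end
(force transmission is delayed by one step and softened by the penalty
stiffness); pushing speed against the cortex is set by the polymerization
velocity rather than load-shared across the full aster drag; no steric
exclusion between filaments; no explicit torque bookkeeping beyond what
vertex forces imply. These affect quantitative force magnitudes, not the
scenario-level contrasts the model is used for.

### Problem sizes

The full preset is 80 MTOCs for 20 min. Routine runs and tests use a
smoke preset — 10 MTOCs of 20 MTs for 120 s, motors at the reference
`N_mi = 10³`, `f₀ = 7 pN` — with MTOCs nucleated 0.5–3 µm from the
chromatin edge: over 120 s an MTOC moves well under 1 µm by diffusion, so
only nucleation within reach of ~3 µm microtubules and the gradient's
inner zone can express captures at all; farther bands make every scenario
identically zero and the contrast vacuous. At this scale the
motor-gradient scenario captures ~30% of MTOCs versus ~15% for uniform
motors over five seeds; the full-scale contrast (3% vs 32% at 20 min) is
reproducible with `full_config` at roughly an hour of CPU per scenario
batch.

## Synthetic data

`generate_pseudo_experiment` emulates the statistical structure of the
unavailable experimental tracks: 30 tracks (the real count is unknown;
published overlays show tens), fine-step RWD motion under the optimal
fields, frames jittered uniformly on [180, 240] s (emulating "3–4 min"
sampling), isotropic Gaussian localization noise of 0.2 µm (the MTOC size
scale; no published noise floor exists), clipped by re-drawing to stay in
the cell. It emits the χ(r) bins (mean, sd, count) and capture-time
frequencies (with binomial standard errors) the optimizer consumes; bins
holding a single track borrow the pooled standard deviation.
`generate_enucleated_control` draws uniform-by-area positions emulating
MTOC scatter in enucleated oocytes (mean radius (2/3)·r_cell).

What passing tests on this data do and do not show: they demonstrate the
estimators, the optimization machinery and the mechanistic engine are
self-consistent and recover known inputs under realistic sampling, noise
and geometry; they cannot validate the biological parameter values
themselves, because the generator's motility is by construction the RWD
model. Features of real data not emulated: heterogeneous per-cell
geometry, track splitting/merging and detection dropouts, anisotropic
localization error, and any pre-NEBD nuclear-envelope effects.

## Degenerate inputs and tie-breaks

χ of a zero-length path is undefined and excluded from bins; all-zero msd
curves fit to (0, 0); non-positive msd points are excluded from the
log-space anomalous fit; rank ties share the average rank; motor binding
ties resolve to the nearest eligible segment; a collapsed (zero-length)
active segment during projection falls back to the radial anchor axis.
Captured RWD particles are removed, not pinned (their tracks end at the
capturing position). Random streams derive from a single seed per run;
identical seeds give bit-identical outputs, and CLI runs record a
manifest with the config digest and seed.
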