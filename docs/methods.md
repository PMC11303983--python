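# Methods

## Model

Five state variables: two bacterial densities (cells L⁻¹) and three
concentrations (μM). Each functional group grows at the Monod rate
`g(P) = g_max P/(k_P + P)` multiplied by the inhibition factor
`h_X = 1/(1 + X/H_X)` of the opposing substrate, and dies at the constant
rate `m`. Substrate production is proportional to realized growth (`p_O`,
`p_S` μM per cell grown); both substrates are destroyed by the bilinear
oxidation term `c·O·S` and relax toward fixed background concentrations at
the first-order exchange rates `a_O`, `a_S` ("diffusivities", h⁻¹), which are
the two environmental drivers. Phosphorus is consumed in proportion to
growth (yield `y_P`) and replenished from its background at `α_P`.

Reference configuration (all shared between the groups):
`g_max = 0.1 h⁻¹`, `k_P = 0.5 μM`, `H_S = H_O = 100 μM`,
`y_P = 1.67e8 cells μM⁻¹`, `p_O = p_S = 3e-8 μM cell⁻¹`, `m = 0.04 h⁻¹`,
`α_P = 0.1 h⁻¹`, `O_b = S_b = 100 μM`, `P_b = 10 μM`, `c = 0.1 μM⁻¹ h⁻¹`.
Two unit conventions are worth stating because they are easy to get wrong:
the half-inhibition constants are concentrations (μM), so that `X/H` is
dimensionless, and the oxidation coefficient carries μM⁻¹ h⁻¹, so that
`c·O·S` is a rate of concentration change. With these values the model is
exactly invariant under the mirror swap (`N_CB`↔`N_SB`, `O`↔`S`,
`a_O`↔`a_S`); `ModelParameters.is_system_symmetric` tests the two fields
that can break it (`H_S = H_O`, `p_O = p_S`).

A consequence used throughout the tests: at any steady state with a single
dominant group, growth balances mortality, `g(P*)·h = m`. Where the
inhibitor is nearly absent (`h ≈ 1`) this pins phosphorus at
`P* = k_P·m/(g_max − m) = 1/3 μM` and hence the dominant density at
`N* = y_P·α_P·(P_b − P*)/m ≈ 4.04e9 cells L⁻¹`, independent of the drivers.

## Driver gradients and the environmental asymmetry factor

Oxygen diffusivity always spans 10⁻²–10⁰ h⁻¹ on a log₁₀-equispaced grid
(`n_steps` points; default 101, and 41 in the desk-scale reproduction runs,
81 where tipping-location resolution matters — one grid step is the location
uncertainty, 0.05 and 0.025 decades respectively). Sulfide diffusivity
traverses, in the opposite sense, a range whose log half-width about the
fixed midpoint 10⁻¹ is scaled by the environmental asymmetry factor *f*:
10^(−1−f)–10^(−1+f). Factor 1 reproduces the mirrored symmetric range,
factor 0 pins `a_S` at 10⁻¹. Spacing is logarithmic because the ranges are
specified in decades and results are read on a log driver axis. The two
directions' sequences are constructed as exact elementwise reverses of each
other, so direction-symmetry properties hold bitwise at the driver level.

The temporal mode uses a three-phase schedule: hold the anoxic-favouring
extreme, ramp stepwise to the oxic-favouring extreme, ramp back
(`n_steps_per_ramp` log-equispaced segments per ramp; defaults 50 segments,
three phases of 5e5 h — desk-scale values chosen so each ramp crosses its
tipping point quasi-statically while a full run stays in seconds). The
transient phosphorus spike at a regime shift depends mildly on ramp
granularity (0.45–0.51 μM across segment lengths 1e4–1e6 h); the default
schedule gives 0.48 μM.

## Stable-state protocol

At each gradient point the system is integrated for `step_duration`
(default 1e6 h) in chunks of `immigration_interval` (1000 h); at each chunk
start 1 cell L⁻¹ is added to both groups, implementing immigration as a
discrete impulse exactly as specified rather than as a continuous rate, and
restarting the solver so it only ever sees the smooth flow. The end-of-step
state seeds the next gradient point; the two directions are run
independently from the same initial state (1e5 cells L⁻¹ per group, 20 μM
per substrate, 10 μM phosphorus) — the long first-step equilibration
establishes the attractor appropriate to each end.

Integration uses LSODA with rtol 1e-8 and per-variable atol (1e-10): the
system is stiff (densities span ten orders of magnitude; substrate
relaxation and invasion growth differ by factors of ~10³) and the suppressed
group's density between immigration pulses falls to ~1e-9 cells L⁻¹, which
must stay resolvable for the immigration floor to mean anything. Any
component the solver drives marginally negative is floored at zero and
counted. The weighted residual `max|dx/dt|/(1+|x|)` at each step end is
recorded as a convergence diagnostic; residuals above 1e-3 are logged as
warnings but never silently altered — a large residual at the step
bracketing a tipping point is physical (a slow transition caught in
progress, which is part of the protocol's semantics).

An optional early exit ends a step once the residual stays below 1e-7 for
10 consecutive chunks. It is off by default; the reproduction script and
the heavier tests enable it, and a dedicated test shows it reproduces the
full-length protocol's recorded states to ~1e-5 relative. The gate cannot
fire during an ongoing transition because invasion keeps the residual many
orders above the threshold.

## Tipping detection and symmetry quantification

For each consecutive pair of recorded stable states the change in log₁₀
substrate concentration is computed for oxygen and sulfide and the larger
taken; the tipping step is the argmax. If no pair exceeds the no-tipping
floor (0.5 log₁₀ units — half an order of magnitude cleanly separates regime
shifts from smooth drift in every configuration studied) the response is
reported as monostable rather than raising. Exact argmax ties break toward
the pair nearest the gradient midpoint, then the lower index, and are
flagged. The location is the log₁₀ midpoint of the bracketing `a_O` pair;
the per-substrate magnitudes are the unsigned changes across that single
step. The log metric is the default (a raw-μM mode is provided) because
under multiplicative dynamics it is the scale on which a symmetric pair of
up and down shifts has equal magnitude; phosphorus and the cell densities
are deliberately excluded from detection — response symmetry is defined on
the two substrates.

Total shift magnitude sums the two substrates' magnitudes across one
tipping step; the signed magnitude asymmetry is total(oxic→anoxic) −
total(anoxic→oxic). Location shifts are reported relative to a symmetric
reference run, in decades of `a_O`. The *post-shift level* of a substrate —
the concentration it "attains" after its upward shift — is measured as the
maximum equilibrium concentration over the post-tipping branch segment
(the branch plateau), not the single first post-shift step: the first step's
value depends strongly on where the grid happens to land relative to the
tipping point (84.6 μM at resolution 41 versus a 105.9 μM plateau in the
symmetric run), while the plateau is grid-insensitive.

Scans over the sulfur bacteria's `H_O` (system asymmetry; the
cyanobacterial `H_S` stays at 100 μM) and over the environmental factor
re-run the full two-direction protocol per value, analyze each, and compare
against the symmetric reference (H_O = 100, factor = 1), which is computed
once. Per-row simulation failures are flagged, not fatal.

## What the reproduction runs show — and known limitations

With the reference configuration the package reproduces: machine-precision
response symmetry (magnitude asymmetry ~1e-12 at full protocol length);
mirror-exact trajectories between the two directions; the common ~106 μM
substrate plateau after the upward shifts, splitting into 102.5/110.9 μM
under environmental factor 0.6; monotone growth of |magnitude asymmetry| in
|H_O − 100| and |factor − 1|; same-direction tipping-location movement under
system asymmetry versus opposite-direction movement (bistability widening or
narrowing) under environmental asymmetry; and, at factor 0, an
oxic→anoxic tipping point that moves exactly three times further than the
anoxic→oxic one.

Two printed reference values are *not* reproduced by these equations and
parameters, and the corresponding checks are deliberately left failing
rather than adjusted. The anoxic-plateau phosphorus comes out at 0.334 μM
(with dominant density 4.0e9 cells L⁻¹), not 0.45 μM (1e9 cells L⁻¹): the
steady-state balance `g(P*)·h = m` forces `P* = 1/3` whenever the dominant
group's inhibitor is nearly absent, as it is on the plateau (O ≈ 0.1 μM);
0.45 μM would require ~18 μM of inhibitor there, or ~17% higher effective
mortality (for example an additional washout term on the bacteria) —
neither of which the model as written contains. Likewise the factor-0 ratio
of total shift magnitudes between directions evaluates to ~1.3 (log metric;
~1.4–1.5 in raw μM), not ~2, under the single-step magnitude definition.
The location-displacement ratio (3.0) and all substrate-level values are
insensitive to this and reproduce well.

Other limitations: tipping locations are resolved only to one grid step, and
the single-step magnitude depends mildly on grid resolution (finer grids
place the last pre-shift state closer to the fold); the temporal mode's
spike height depends on ramp granularity as noted above; the protocol is
simulation-based throughout — no root-finding continuation of the
bifurcation diagram, and no early-warning statistics. The model itself is an
idealization: two functional groups, no spatial structure, no third group or
sulfate pool, and tuned abiotic parameters; it is a laboratory for symmetry
arguments, not a calibrated model of any particular water column.
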