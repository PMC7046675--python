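# Methods

## Model and assumptions

The neuron is the planar Morris–Lecar model: instantaneous sodium activation
m∞(V), one recovery variable w (delayed-rectifier potassium activation), and
a passive leak.  Shared constants: C = 2 μF/cm², g_Na = g_K = 20 mS/cm²,
g_L = 2 mS/cm², E_Na = 50 mV, E_K = −100 mV, E_L = −70 mV, β_m = −1.2 mV,
γ_m = 18 mV, γ_w = 10 mV, φ_w = 0.15.  The half-activation of w selects the
excitability class: β_w = −13 mV (class II) or β_w = −25 mV (class III).
Everything in the package assumes this two-variable reduction — no spatial
structure, no channel noise, no temperature scaling, a single neuron.

Two readings of the recovery time constant circulate, differing in the cosh
argument: `τ_w = 1/cosh((V − β_w)/(2γ_w))` (the standard form) versus
`1/cosh((V − β_w)/γ_w)`.  Both are implemented behind
`ModelParams.tau_w_variant`.  Adjudication by the class II Hopf location:
the `factor_2` variant puts I_H at 42.80 μA/cm², the `no_factor_2` variant
at 46.39; all reference interval measurements (7.72 / 15.72 / 5.27 ms, see
below) are likewise reproduced only by `factor_2`, which is therefore the
default.  The notation cosh⁻¹ is read as the reciprocal, not the inverse
function, which would be undefined at the hyperpolarised voltages that occur.
φ_w is treated jointly with τ_w as a rate in 1/ms; only the ratio enters the
equations.

The autapse (self-synapse) adds `I_syn = −g_syn s(t − τ)(V − E_syn)` with
first-order activation kinetics `ds/dt = α Γ(V)(1 − s) − β s`,
Γ(V) = 1/(1 + exp(−k_sig (V − θ_syn))).  Defaults: E_syn = 30 mV
(excitatory), θ_syn = 10 mV (release only during a spike), α = 12 /ms,
k_sig = 10 /mV.  α is assumed to carry units of 1/ms for dimensional
consistency.  The delayed quantity is the activation s alone; the voltage in
I_syn is the instantaneous postsynaptic potential (pre- and postsynaptic
neuron are the same cell).  The tunable triple (g_syn, τ, β) spans the
studied regimes: g_syn in (0, 4] mS/cm², τ in (0, 30] ms, β in [0.01, 1] /ms
(the NMDA-receptor deactivation range ~10–100 ms corresponds to
β ~ 0.1–0.01).

## Integration

Classical fixed-step RK4 with h = 0.01 ms (configurable).  The delayed
activation s(t − τ) is read from the stored solution history with linear
interpolation, so τ need not be a grid multiple and the half-step stage times
are handled uniformly; pre-history is s ≡ 0 for t ≤ 0, so the first spike
must be evoked by a stimulus.  For τ < h the delayed lookup clamps to the
most recent sample; runs in this package always use τ ≥ h.  A convergence
test on a smooth run verifies the fourth-order error scaling (error ratio in
[10, 22] when h is halved, the wide band accommodating roundoff).  Blow-ups
are detected per step and reported with the failing time.  The autapse-free
model is the g_syn = 0 special case run through the identical code path, so
the reduction is exact to the bit.  The numerical core is numba-compiled;
logistic evaluation is overflow-safe.

Stimuli are piecewise-constant: constant, single rectangular pulse, or
periodic brief-pulse train, with half-open active windows
[start, start + duration).  The standard trigger for all autapse studies is
one 1.5 ms, 100 μA/cm² pulse at t = 50 ms (the default onset leaves visible
settling; the choice is immaterial since runs start at the solved resting
state).  Default run length for autapse studies is 1000 ms; steady-state
interval statistics use the final 300 ms.

## Spike metrics and classification

Spikes are upward crossings of 0 mV (the spikes of this model overshoot
0 mV; the 10 mV release threshold is deliberately not reused for detection)
with a 1 ms refractory guard; spike times carry grid resolution, which at
h = 0.01 ms is far below every tolerance used.  Response classes: resting
(no spikes), transient_then_rest (spikes, but none in the final settle
window, default 200 ms), repetitive (spikes persist to the end of the run).

Repetitive autapse-driven firing is labelled case-1 when the steady
interspike interval is within 15% of the delay τ (delay entrainment), and
case-2 otherwise.  Delay entrainment takes precedence deliberately: the
fraction of time the autaptic current exceeds I_H cannot discriminate the
mechanisms, because a slowly decaying autapse keeps I_syn above I_H more
than 90% of the time even in delay-entrained class III firing, where
sustained supra-Hopf current cannot drive spiking at all.  The supra-Hopf
fraction remains available as a corroborating diagnostic.

The average autaptic current is a trapezoidal time average over a stated
window.  The default window for decay-rate sweeps is two interspike
intervals of the matched β = 1 reference run (from its third spike to its
fifth), shortly after firing is established — where fast- and slow-decay
autapses differ most — and the same fixed window is used for every β so the
averages are comparable.  The window is always echoed with the value.  Under
this rule the average grows monotonically as β falls at τ = 15 ms for both
classes (≈14 μA/cm² at β = 1 up to ≈170 at β = 0.01); at τ = 4 ms for
class III the sweep shows a local dip exactly where firing ceases (spikes
inside the window re-activate the synapse), while the overall slow-vs-fast
ordering still holds.

## Bifurcation analysis

The autapse-free model is planar, so no general continuation machinery is
needed.  Equilibria are roots of the scalar current balance with
w = w∞(V), refined by Brent's method from a 400-point sign-change scan on
V ∈ [−100, 40] mV; stability comes from the analytic 2×2 Jacobian (checked
against central finite differences at 1e−6 relative).  The Hopf point is
bisected on the sign of the largest eigenvalue real part (default bracket
tolerance 1e−4 μA/cm²), verifying complex eigenvalues at the crossing.
Focus/node labels follow the eigenvalue discriminant: with the class II
preset the equilibrium is a node both at rest and at strong drive
(eigenvalues real) and a focus only in a band around I_H.

The stable limit cycle is characterised by simulation (default 500 ms, first
200 ms discarded; period = mean steady interspike interval).  The fold of
limit cycles is located by hysteresis continuation: establish the cycle at
I_app = 100, sweep downward in 2 μA/cm² steps re-seeding each 500 ms probe
from the end state of the previous one so the trajectory stays on the cycle
branch, then bisect the disappearance current to 0.01 μA/cm².  The unstable
cycle of the subcritical scenario is not tracked explicitly; its existence
is implied by the bistability between fold and Hopf, which is tested.  The
"physiological range" for the class III no-bifurcation property is fixed at
I_app ∈ [0, 200] μA/cm², twice the largest current used anywhere else.

## Scans and the firing border

Parameter-plane scans run the standard triggered experiment per cell
(default 600 ms per cell with a 200 ms settle window — long enough that
every regime observed at 1000 ms has stabilised, at desk-scale runtime; the
library default grid is 60×60, and the test suite and examples use reduced
grids of ≤ 48 cells).  Cells are independent and deterministic; re-running
any cell standalone reproduces it exactly, and per-cell integration failures
are recorded without aborting the scan.

The decay-rate firing border bisects the repetitive/non-repetitive
classification of 1000 ms triggered runs between β = 0.01 and 1 to a bracket
of 0.01, after a 9-point coarse pre-scan that guards against non-monotone
classification (the pre-scan is reported alongside the result).  For
class III at g_syn = 3 mS/cm², τ = 4 ms the computed border is β ≈ 0.36; it
is insensitive to halving the step size but strongly sensitive to the delay
(≈0.55 at τ = 3.5 ms, ≈0.26 at τ = 4.5 ms), so modest uncertainty in how the
border was originally read off translates into a few hundredths in β.

A delay ambiguity affects one fast-decay illustration (τ = 7 ms vs 15 ms are
both quoted for the same β = 1 runs).  Both values were run: each entrains
delay-locked case-1 firing with interval ≈ τ (7.8 and 15.8 ms), so the
characterisation is independent of which delay was intended; the tests
parametrise over both.

## Problem sizes and limitations

Default problem sizes: 1000 ms runs (100 000 steps) for autapse studies,
300–500 ms for limit-cycle probes, ≤ 48-cell scan grids in tests and
examples.  Known limitations: spike times are grid-resolved, not
event-located; the fold search assumes the probe length suffices for the
slow transients near the fold (500 ms leaves the reported value stable at
the 0.01 μA/cm² bracket); classification near regime borders is inherently
sensitive to run length, which is why borders are reported with their
bracket and pre-scan; and the synthetic stimulus set contains no noise,
ramps, or conductance inputs — conclusions about sharp thresholds and
entrainment should be expected to soften under noisy drive.
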