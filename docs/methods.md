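# Methods

## Model

The epidemic is a rescaled SIR model with unit recovery rate,

    s' = -k(t) s i,    i' = k(t) s i - i,    s(0) = 1 - i0,  i(0) = i0,

where the population-averaged infectiousness k(t) is itself a behavioural
variable: social distancing lowers k below its pre-epidemic level κ* (which
equals the basic reproduction number R0). Time is measured in mean
infectious periods; the defaults κ* = 4 and i0 = 3e-8 describe a
COVID-like outbreak seeded by a handful of cases in a large population.

A representative individual tracks their own probabilities ψ_s, ψ_i of
being susceptible/infectious against the population epidemic, which they
cannot influence, and maximises discounted utility

    U = ∫ f^(-t) [ -α(i) ψ_i - β (κ - κ*)² + (κ - κ*) ε(t) ] dt + U_f,

with discount base f ≥ 1 (f = 1 in all bundled scenarios: no discounting),
distancing-cost coefficient β (the unit of all costs; β = 1 throughout),
per-infection cost α(i), and a government incentive field ε(t) that taxes
or subsidises deviations of behaviour from baseline. The tail beyond the
horizon t_f is the closed-form salvage term

    U_f = -f^(-t_f) α(0) ψ_i(t_f) / (1 + ln f),

exact in the limit where the epidemic has burnt out by t_f (infections then
decay as e^-(t - t_f) at cost α(0)). Solvers verify i(t_f) ≤ 1e-8 and extend
the horizon by 50% (up to three times) when it fails.

Healthcare capacity enters through the per-infection cost

    α(i) = α0 + (α1 - α0)/2 · (tanh[(i - i_hc) σ] + 1),

a smooth step from α0 to α1 around the capacity threshold i_hc with
steepness σ (default 300 per unit infected fraction, so the step width is
~1/300 ≈ 0.003). At low thresholds the disease-free cost α(0) retains an
appreciable share of the step: (α(0)-α0)/(α1-α0) = (1 - tanh(i_hc σ))/2,
about 2.5e-3 at i_hc = 0.01 and 0.14 at i_hc = 0.003.

Three solution concepts share one optimality structure (Pontryagin costates
v_s, v_i; control rule k = max(0, κ* - f^t/2 (v_s - v_i) s i / β + ε/(2β))):

* **Nash equilibrium** — individual costates v_i' = f^(-t) α(i) + v_i,
  v_s' = (v_s - v_i) κ i, closed self-consistently with k = κ, ψ = (s, i).
* **Utilitarian optimum** — population costates gain the externality terms
  f^(-t) α'(i) i (congestion) and (v_s - v_i) k s (onward infection).
* **Government (Stackelberg) optimum** — the government chooses ε to
  maximise its own objective (parameters f_g, α_g, β_g, and the shadow cost
  of public funds γ_g on the intervention term -γ_g ε (k - κ*)), subject to
  the population playing the Nash equilibrium induced by ε. Its costates
  λ_s, λ_i are driven by the auxiliary integrand Λ and the stationary field
  is ε = i s [f^t (β_g + γ_g)(v_s - v_i) - f_g^t (λ_s - λ_i)]/(β_g + 2γ_g).

## Numerics

**Discretization.** All states, costates and controls live on one uniform
grid (default t_f = 100, n = 4001, dt = 0.025), integrated with classical
fixed-step RK4; node controls are interpolated linearly at half-steps.
Fixed stepping makes runs bit-reproducible and keeps forward and backward
passes on identical nodes, which the sweep's fixed point requires. The
scheme is 4th-order in the states for a given control path but 2nd-order
in the control coupling, so *cross-grid* comparisons of costates agree to
O(dt²) (~1e-4 relative at dt = 0.025) while *within-grid* optimality
residuals and objective refinement reach 1e-6 and better. Objectives use
trapezoidal quadrature on the same grid. Undershoot of s or i below -1e-12
is an error; smaller negative round-off is clamped to zero.

**Forward-backward sweep.** The damped Picard iteration mixes the clipped
control candidate with weight ω (default 0.1 inner, 0.05 outer); the
convergence residual is the *unrelaxed* candidate gap sup|candidate - k|
(tolerance 1e-6 κ*), which is the distance the stationarity conditions see
(the post-mixing step understates it by ω). A guard halves ω whenever the
best residual stops improving for 50 iterations.

**Acceleration and fallbacks.** Several of the fixed-point maps in this
model are not contractions:

* The *outer* government map oscillates at any practical damping; it is
  driven by windowed Anderson (type-II) extrapolation with safeguarded
  restarts, which converges the matched cost-free case in ~30 outer
  iterations where plain damping needs >1e4.
* The *coordinated threshold-tracking* optimum (steep α' acting as a stiff
  penalty) has a discrete sweep map whose instability no damping or
  acceleration cures. These problems are solved by direct transcription
  (piecewise-linear control on 60 nodes, L-BFGS-B, seeded multistart)
  followed by Newton collocation (scipy solve_bvp) on the optimality
  boundary-value problem with the control eliminated. Solutions carry
  `method="collocation"`; their `residual` then reports the fixed-step
  discretization mismatch of the projection, not a failure to solve.
* The same collocation engine backs up the inner Nash solve inside the
  government loop and, on the full six-state system, the government solve
  itself for tracking-branch policies.

**Initialization.** Sweeps start from the disease-free equilibrium k ≡ κ*,
which is exact for α = 0. The government solve starts by default from the
*decentralization ansatz*: solve the coordinated problem under the
government's own preferences, then set ε = 2β(k_g - κ*) + f^t (v_s - v_i) s i
so the individual rule reproduces k_g. For γ_g = 0 this is the optimum
itself; in general it is a warm start deep inside the well-behaved region.
ε ≡ 0 remains available (and is used by the branch scan).

**Equilibrium selection.** A strongly activity-subsidising ε supports more
than one population equilibrium (a calm one and a reckless fierce-epidemic
one); the inner solver's warm start selects the branch, and the ansatz
supplies the calm-branch behaviour path along with its field.

**The best-response audit and the nature of the equilibrium.** The
individual's problem against a frozen population has bilinear dynamics
(κ ψ_s i) and is not concave: besides the cautious consensus strategy there
is a second, "give-up" stationary strategy (little distancing, early
infection) with slightly higher utility, and the consensus is in fact a
saddle of the individual objective (a symmetric smooth bump of the control
near the epidemic onset raises utility at second order). Consequently (i)
the computed equilibrium is a *first-order* (stationary) Nash point, the
object this literature computes and compares; (ii) the Picard best-response
iteration is linearly unstable at consensus for any damping, so
`best_response` solves the individual's Pontryagin BVP by Newton
collocation, which converges to the stationary point nearest its start
(default: the consensus; pass κ* to land on the give-up branch). The audit
`verify_nash_fixed_point` therefore checks stationary self-consistency
(gap < 1e-4) and the absence of *local* profitable deviations.

**Backward ill-conditioning.** The population and government costates have
an exponentially growing backward mode in the pre-epidemic window (i ≈ 0).
Raw costate values there are ill-conditioned, but the control rule
multiplies them by s·i, which suppresses the polluted window; oracle
comparisons use the control-relevant combination (v_s - v_i) s i on the
epidemically active region.

**Branch scan.** With a healthcare threshold in the government's cost the
outer problem is non-convex with (empirically) exactly two local optima: a
"high-peak" policy and a "threshold-tracking" policy (labelled by whether
the peak stays within 2 i_hc). `branch_scan` multi-starts each α_g1 from
ε ≡ 0, the ansatz, and bidirectional continuation from neighbours, records
all distinct optima (sup-norm ε distance > 1e-2), and selects the argmax of
V; the policy switch is the α_g1 where the selected label changes. Across
the switch the optimal V varies continuously while the selected peak jumps
discontinuously.

## Oracles and validation

Everything the sweeps produce is cross-checkable by machinery that shares
no costate code: `direct_transcription_optimize` (simulate-then-quadrature
objective over a coarse control, agreement asserted on objective values at
1e-3 relative, since a 40-60-node control cannot match a 4001-node path
pointwise), `pontryagin_residual` (central finite differences of the
relevant Hamiltonian along the path, scaled into control units; < 1e-5 on
converged sweep solutions, interior nodes only, one-sided at the k = 0
bound), `verify_nash_fixed_point` (above), and the SIR final-size relation
s_∞ = s0 exp(-R0 (s0 + i0 - s_∞)) solved by bracketed root-finding for
constant-behaviour runs.

## Problem sizes used in tests and reports

The test suite runs most scenarios at dt = 0.05 (n = 2001) and the
quantitative equilibrium checks at dt = 0.025 (n = 4001), with refinement
checks against dt = 0.0125; the branch scan exercises a compact set of
α_g1 values bracketing the policy switch at dt = 0.05, t_f = 150. These
sizes are converged for every asserted tolerance (refinement moves
objectives by < 1e-6 relative) while keeping the full suite desk-scale.

## Limitations

* No reinfection, waning immunity, vaccination before t_f, demographic
  noise, or compartment heterogeneity; a single homogeneous behaviour
  variable (no selective distancing by compartment).
* The Stackelberg costate system treats the inner equilibrium's costates as
  exogenous data along the trajectory, exactly as the stationarity
  conditions are written; where the k ≥ 0 bound binds, the interior ε rule
  is still applied pointwise and the inner equilibrium re-imposes the bound.
* Global optimality of the government field is supported by multistart and
  perturbation tests, not proved; the two-local-optima structure is an
  empirical observation.
* The equilibrium concept is first-order Nash (see above); a population
  able to coordinate a jump to the give-up branch would break it, which is
  a model property, not a solver defect.
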