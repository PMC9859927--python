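# Methods

## Model and assumptions

The dynamics are a deterministic multi-group SIR system with vaccination.
Group *i* (size N_i, a population fraction) is split into six compartments
(S, I, R, SV, IV, RV). Transmission from group *j* to group *i* uses four
non-negative matrices: beta1 (unvaccinated infecting unvaccinated), beta2
(vaccinated infectors, unvaccinated susceptibles), beta3 (unvaccinated
infectors, vaccinated susceptibles) and beta4 (both vaccinated). Recovery
rates are mu1 and mu2. The container enforces that vaccination cannot be
harmful: beta1 >= beta2, beta3 >= beta4, mu1 <= mu2 elementwise, and
kappa <= 1.

Vaccination is "unvaccinated-only": doses arrive at rate U_i(t) and are
assigned at random among not-yet-vaccinated members, so susceptibles move at
rate U_i S_i / (N_i - W_i). At W_i = N_i this expression is a removable
singularity; we clamp the transfer to zero once N_i - W_i < 1e-12 N_i.
This threshold is far below solver accuracy and only exists to avoid
division blow-up in the last few ulps of a fully vaccinated group.

Assumptions inherited from the model class: no reinfection, no waning of
vaccine protection, no demography, deterministic dynamics (groups large
enough that stochastic effects do not dominate). Group sizes are treated as
fractions of a normalised population; a total different from 1 produces a
warning rather than an error because the two-group worked example
deliberately uses a total of 1 + eps.

## Simulation

`simulate` integrates the 6n ODEs with SciPy's LSODA (stiff-safe,
adaptive), restarting at every policy breakpoint so piecewise-constant
rates are seen exactly. Default tolerances rtol = 1e-9, atol = 1e-12 keep
per-group mass conservation below 1e-8 over whole trajectories. "Infinity"
is operationalised as the first time after the policy's support at which
the total infected mass falls below an extinction threshold (default
1e-10, a solver event); the model itself never fixes this constant, so it
is a package choice, small enough that the remaining future recoveries are
orders of magnitude below the 1e-6 agreement required of the final-size
cross-check. The default horizon is 200 mean infectious periods; runs that
hit it return `converged=False` and the objective warns instead of raising.
Near-critical models (reproduction number close to 1) decay slowly and may
need a longer horizon, as in `examples/homogeneous_leverage.py`.

The objective H is reported net of initially recovered individuals so that
a disease-free run scores exactly 0; the shipped examples all start with
R(0) = 0, where this is the same number as the gross definition.

## Policies and schedules

Policies are piecewise-constant in rate; smooth policies can be
approximated on a user grid, and every worked example is exactly
bang-bang, so no approximation error arises there. Supply schedules store
A as a step function and B as a piecewise-linear function with an explicit
final slope. The maximal administrable rate chi(t) equals A(t) until the
raw rate integral catches the supply cap, then min(A, B'+) with the right
derivative at kinks. Prioritised (bang-bang) policies are built by
event-walking the piecewise segments of chi and splitting them where a
group's cap is met; switch times are exact roots of linear equations, and
the cumulative total administered satisfies
sum_i W_i(t) = min(int_0^t chi, sum of caps).

The vulnerable-first swap redirects the *total* rate of a reference policy
to group 1 until eps doses have been given (the switch time is solved in
closed form inside a breakpoint interval), after which the other groups
resume their original rates and group 1 receives nothing. With eps = 0 the
redirection window has measure zero, so group 1 is simply silenced.

In the two-group example the supply cap is taken as B(t) = min(t, 1): the
cap must saturate at the large group's size for the printed policies (only
group 2 ever vaccinated under the infectious-first ordering) to be the
supply-exhausting ones. The uncapped variant max(t, 1) remains expressible
and is exercised in the schedule tests.

## Final size and the linearization

Stacking vaccinated compartments as groups n+1..2n gives a plain 2n-group
SIR with beta' the 2x2 block matrix of beta1..beta4, mu' = (mu1, mu2) and
p' = (p, kappa p). Its final size solves
S_i(inf) = S_i(0) exp(-E_i(R)), E_i = sum_k (beta'_ik/mu'_k)(R_k - R_k(0)),
iterated from the attack-size-maximal side (S = 0): the map is monotone, so
the iterates decrease to the largest root, which is the one the ODE flow
realises (verified against simulation to 1e-6 on randomized instances). A
Newton polish through `scipy.optimize.root` covers near-critical cases
where plain iteration converges only sublinearly; convergence is judged by
the fixed-point residual (< 1e-10 required, typically < 1e-13). Initial
recovered mass is subtracted inside the exponent so pre-existing immunity
is not double-counted.

Implicit differentiation of that relation with respect to the initial
susceptibles yields the per-dose gradient. With S_inf the baseline terminal
susceptibles and C_ij = beta'_ij/mu'_j,

    Q = diag(1/(1 - e^{-E})) (I - diag(S_inf) C),
    Q^T x = p',     y_i = (S_i(0)/N_i) (x_{i+n} - x_i).

Two notational choices deserve note. First, the inner sum in the
textbook-style formula for Q reuses the column index; we read it as an
independent dummy index (the only reading that makes Q a well-defined
matrix). Second, the sign of the off-diagonal term follows from the
Jacobian d(fixed point)/dR = S_inf C - I: the minus sign above is the one
validated by the finite-difference oracle (simulated dH per dose at
eps = 1e-4 agrees with y to well under 1% across randomized parameter
sets); the opposite sign disagrees by several-fold. The factor S_i(0)/N_i
converts doses to susceptibles moved, consistent with random dosing of the
unvaccinated. Q is singular when some stacked group receives no infectious
force at baseline (E_i = 0); this is raised as a named error identifying
the group, matching the seeding condition under which the linearization is
derived. Non-unique minima of y are broken toward the lowest index with a
warning; parameter sets with exact ties are measure-zero.

The knapsack-optimal policy sends the whole supply eps to argmin(y) at the
full rate cap until int A = eps. The linear prediction H0 + y.W is accurate
to ~1% of the change at eps = 0.01 in the homogeneous example; the
correction term is only known to be o(eps), and it is visibly largest near
the epidemic threshold (beta ~ 1), where the final size is most curved in
the parameters.

## Calibration and the synthetic contact fixture

Age-structured transmission is built as beta1_ij = beta Lambda_ij / N_j
from a contact matrix Lambda, with beta chosen so the next-generation
matrix R_ij = N_i beta1_ij / mu1_j has a target spectral radius (default
4). Vaccinated tiers default to halving infection and transmission
(beta2 = beta3 = 0.5 beta1, beta4 = 0.25 beta1) and kappa = 0.1 (a 90%
reduction in case fatality).

The synthetic fixture generates, deterministically per seed, a contact
matrix with the qualitative features of survey-derived age-contact data:
assortative mixing (diagonal dominance controlled by an assortativity
parameter; 1 gives fully disconnected groups), a per-capita contact budget
decreasing linearly across groups (the elderly-contact decay), seeded
multiplicative jitter, and exact reciprocity N_i Lambda_ij = N_j Lambda_ji
enforced by symmetric Sinkhorn scaling to prescribed row totals. It does
not emulate school/work/home setting structure, bimodal child-parent bands,
or country-specific population pyramids, so fixture-based results
demonstrate the method's internal consistency, not any country-specific
ranking. A loader accepts real contact/population CSVs in the same layout.
Acceptance-level checks use an 8-group fixture, enough to exercise
heterogeneous rankings while keeping the per-group finite-difference
simulations cheap.

## Crossover diagnostic

eps*(I*, p*) is the infimum of the set of group-1 sizes at which the
infectious-first policy beats the vulnerable-first swap, capped at 1. It is
estimated by simulating both policies on a 25-point log grid over
[1e-3, 1] and then bisecting (20 steps, in log space) the first bracket
where H(swap) - H(infectious-first) changes sign. The set need not be an
interval; the reported value is the infimum over the grid-resolved set. A
coarser grid (10 points, 8 bisections) is used for the monotonicity scans
to keep runtimes low; the reported crossover for the half-effective-vaccine
case is ~0.103 with either resolution.

## Numerical choices and limitations

- Feasibility checking is grid-based (refined at all breakpoints) rather
  than symbolic; for piecewise-constant policies and piecewise-linear caps
  this is exact up to the evaluation tolerance 1e-9.
- The gradient test tolerance (1% relative, supply 1e-4) balances the
  forward-difference truncation error against ODE solver accuracy.
- Randomized test instances are rescaled to next-generation spectral radii
  in [1.5, 3]: clearly supercritical epidemics burn out quickly and keep
  the final-size/ODE comparison well-conditioned. Sub- and near-critical
  models are supported but converge slowly to extinction.
- No second-order correction to the linearization is provided, and the
  small-supply optimum need not be the start of the optimal policy for
  large supplies (bifurcations are possible); both are out of scope.
- No optimizer over arbitrary policies is shipped: the package constructs
  and compares the principled policies (prioritised bang-bang, the swap,
  the knapsack optimum), which is where the theory gives guarantees.
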