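# Methods

## Model summary

The package implements a three-sided market on a line.  Patients of total
mass `dmax`, uniform on distance `d ∈ [0, dmax]` from a single specialist
provider (SP), choose a care path to maximize expected utility; a
representative population of general practitioners (GPs, uncongested,
travel-free) chooses a referral level `k`; the SP chooses a service rate
`μ`.  Complexity is handled in expectation: instead of sampling a case
complexity per patient, every patient carries the population cure
probability, so the fraction of GP visitors cured is `F(k) = ∫₀ᵏ f(x) dx`
with `f` strictly decreasing.  The default family is `f(x) = (1 − x)^p`
with `p = 1` (linear), giving `F(k) = k − k²/2`; `p` is configurable.  This
family satisfies every structural requirement (`f(0) = 1`, `f' < 0`) and
keeps all fixed points closed-form.

The SP is an M/M/1 queue.  The per-patient quality cost
`QC = β/(μ − λs) + α·μ` combines expected delay cost and inadequate-care
cost; since SP profit increases in arrivals, the SP's response is the
QC-minimizing rate `μ* = λs + √(β/α)` (first-order condition
`β/(μ − λs)² = α`).  Substituting back gives the *equilibrium* quality cost
`QC* = 2√(αβ) + α·λs` — affine in the arrival rate, which is what makes
every market regime below a linear problem.

## Equilibrium computation

At fixed `k`, each regime is the fixed point of (cutoffs → arrival rate →
quality cost → cutoffs):

* **Pre-telemedicine, full coverage.**  `d̂` solves the indifference
  equation between direct SP and GP-first with
  `λs = d̂ + (dmax − d̂)(1 − F)`; one linear equation in `d̂`.
* **Pre-telemedicine, partial coverage.**  Adds the give-up distance `d°`
  where the direct-SP utility hits zero; a 2×2 linear system.  A solution
  with `d° ≥ dmax` signals that the market is actually fully covered.
* **Post-telemedicine.**  The tele cutoff
  `d̃ = max(0, [Rs − Rt + (qs − qt)Ps]/Ct)` depends only on parameters.
  Scenario 1 (`d̂ ≤ d̃`): nobody tele-visits first and
  `λs = dmax − (dmax − d̂)F`; same linear form as full coverage.
  Scenario 2 (`d̂ > d̃`): patients beyond `d̃` mix between direct
  telemedicine and GP-first.  The model text pins this down only as a mixed
  strategy equilibrium; we operationalize it as congestion-mediated
  indifference: the tele-first mass `λ_tele` raises `λs`, hence `QC`, until
  the remote utility `Us2` equals the GP-first continuation value
  `Rg − [k(1−qg)Pg + m(k−F)]/F`.  The chain λ_tele → λs → QC → Us2 is
  affine, so `λ_tele` solves in closed form and is clamped to
  `[0, dmax − d̃]`; at a clamped boundary the strict preference direction is
  verified (no interior deviation profitable).

Cutoffs are clamped to their admissible intervals with a `clamped` flag on
the returned state; when a clamp is active the interior linear solve is
replaced by a damped fixed-point iteration (relaxation 0.5, tolerance
1e-12, at most 1e5 iterations — the map is a contraction because the
quality-cost slope `α/Ct < 1` at documented parameters).  Regime and
scenario selection is by post-solve consistency check (full tried first,
then partial; scenario 1 first, then scenario 2), not by an a-priori
threshold, because the thresholds themselves depend on `k`.

The GP's referral level maximizes profit on `k ∈ [1e-4, 1]` (the lower cap
avoids the `F(k) = 0` degeneracy in the cutoff formula) by a 2001-point
grid scan with bounded golden-section refinement (`xatol = 1e-7`).  Ties
break toward the smallest maximizer.  A profile with multiple local maxima
beyond 1e-9 triggers a logged warning and falls back to the global grid
argmax; at both study baselines all four profiles (pre/post × coverage) are
unimodal.

## Welfare accounting

Total social welfare is counted in resources: expected cure rewards minus
travel (`Ct` times the distance integral over in-person SP paths),
mistreatment (`m(k−F)` per GP visitor), GP production (`Cg·k` per GP
visitor), SP production (`Cs/μ` per SP arrival) and quality cost (`QC*` per
SP arrival).  Prices, reimbursements and the tele-reward are transfers and
net out.  Give-up patients are counted as GP visitors (they incur the GP
fee, production cost and mistreatment exposure) with reward `F·Rg`.

A transfer audit recomputes welfare as realized patient-path utilities plus
GP profit plus SP profit plus government outlays (reimbursements and
tele-rewards).  Two conventions make the identity exact: (i) delay and
inadequate-care costs are counted once, inside `QC·λs` (patient utilities
already carry them, provider profit does not); (ii) the GP's objective
internalizes the mistreatment penalty that patients also bear —
reputational and dispute costs — so the audit adds back one `m(k−F)·λg`
term; it is a single resource loss, not two.  The audit holds to 1e-9 on
random parameter draws, including mixed-strategy scenario-2 states.

Average quality cost is `φ = [λg·m(k−F) + λs·QC*] / (λg·F + λs)` — total
quality cost per cured patient.  Post-telemedicine every patient reaches
care, so the cured mass equals `dmax` exactly.

## Study conditions

The documented parameter ranges are `m ∈ [10,15]`, `Pg ∈ [10,15]`,
`Cg ∈ [4,6]`, `Ps ∈ [15,20]`, `Cs ∈ [6,8]`, `γ ∈ [2,4]`, `α ∈ [2,4]`,
`β ∈ [2,4]`, `Ct ∈ [6,8]`, with rewards `Rg=10, Rs=20, Rt=15` and
reimbursement rates `qg=0.9, qs=0.8, qt=0.85`; the experiments default to
the midpoint of every range.  The mistreatment range is grounded in a
premium deduction: annual malpractice insurance of $8,000–$47,000 spread
over a 2,300-patient GP panel implies `m` between about 3.5 and 20.5.

The market size `dmax` selects the coverage regime and is not pinned down
by any external source.  We use `dmax = 1` for the full-coverage baseline
and `dmax = 2` for the partial-coverage baseline: both are verified by the
regime detector, `dmax = 2` leaves a substantial give-up segment (mass
≈ 0.9 pre-telemedicine), and the welfare gain from telemedicine remains
positive.  The latter point is a real constraint on the model, not a
convenience: the telemedicine-induced arrival surge costs
`λs·QC* = λs(2√(αβ) + αλs)` — quadratic in `λs` — while rewards grow only
linearly, so for sufficiently large partially covered markets
(`dmax ≳ 2.8` at midpoint parameters) total welfare *falls* when
telemedicine floods the specialist.  The same mechanism caps the
sensitivity ranges: at the top of the `α` grid the welfare gain under
partial coverage turns negative, and it is also why the average quality
cost rises (rather than falls) in the tele-reward under partial coverage —
the congestion response `(QC* + αλs)·f(k)` to a referral increase
outweighs the mistreatment relief `m·k` throughout the documented box.
These are findings of the implementation, reported as computed; the
package asserts signs and orderings only, never figure-level numbers.

## Oracles

Three independent routes must agree with the analytic solves (and do, to
1e-3·dmax or better): a damped fixed-point iteration (bisection for the
scenario-2 tele mass) built straight from the primitives; a brute-force
2001-point grid over the referral level; and a finite-population simulator
in which 10,000 agents at positions `(i−0.5)·dmax/N` run sequential
(Gauss–Seidel) best-response dynamics, the SP re-optimizing after every
switch.  Sequential updating moves the aggregate one agent mass at a time,
so the dynamics settle to within one agent of the continuum fixed point;
marginal (indifferent) agents may dither, so convergence is declared when a
sweep flips at most a few agents.  Agents carry complexity in expectation,
matching the continuum model; a stochastic queue is never simulated — the
M/M/1 term enters only through its closed-form mean, as in the model.

## Limitations

* The synthetic conditions are the model's own: uniform patient density,
  a single SP, uncongested GPs, complexity in expectation.  Passing tests
  show internal consistency and faithfulness to the model, not calibration
  to any real healthcare system.
* The SP profit function is never specified beyond monotonicity in
  arrivals, so no profit level for the SP is reported — only the
  arrival-maximizing behavior it implies.
* Give-up patients' utility after an unsuccessful GP visit is not specified
  by the model text; they are treated as receiving the GP base utility with
  no specialist continuation, and as bearing mistreatment exposure.
* Figure-level numeric replication of the original numerical study is not
  attempted (axis values unprinted, baseline partially undisclosed); only
  signs, monotonicity and cross-regime orderings are asserted.
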