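# telerefer

Equilibrium analysis of telemedicine in a referral-based (gatekeeper)
healthcare system.

## The problem

In hierarchical healthcare systems, general practitioners (GPs) act as
gatekeepers: they treat the simple cases themselves and refer the complex
ones to a specialist provider (SP).  Patients, however, are free to bypass
the GP and travel to the specialist directly — and distant patients may give
up on specialist care altogether when travel is too costly.  Telemedicine
changes the game: referred patients can be treated remotely by the
specialist with the GP assisting (for a bundled-payment tele-reward), which
removes the travel barrier but funnels extra demand into an already
congested specialist.

`telerefer` solves this market as a game between three parties and answers
the comparative-statics questions: how do the GP's referral level, the
specialist's service rate, the average quality cost, and total social
welfare respond to telemedicine, to the tele-reward, and to travel costs —
under full coverage (everyone seeks care) and partial coverage (distant
patients give up)?

## The model

Patients of mass `dmax` are uniform on distance `d ∈ [0, dmax]` from a
single specialist; case complexity `x ∈ [0, 1]` enters in expectation
through a decreasing cure probability `f(x)` with `F(k) = ∫₀ᵏ f(x) dx`
(default `f(x) = 1 − x`).  The GP treats complexities up to the referral
level `k`, charging `Pg` and exposing patients to mistreatment risk
`m·[k − F(k)]`.  The specialist is an M/M/1 queue with per-patient quality
cost

```
QC(λs, μ) = β/(μ − λs) + α·μ          (delay cost + inadequate-care cost)
```

and, because specialist profit increases in arrivals, sets the service rate
minimizing QC: `β/(μ − λs)² = α`, i.e. `μ* = λs + √(β/α)` — the equilibrium
wait `√(α/β)` is independent of the arrival rate, so congestion shows up as
degraded care, not longer queues.

Patient utilities (rewards `Rs > Rt > Rg`, reimbursement rates
`qg > qt > qs`, travel cost `Ct·d`):

```
Us  = Rs − (1−qs)·Ps − QC − Ct·d                      direct in person
Us2 = Rt − (1−qt)·Ps − QC                             telemedicine (no travel)
Ug  = F·Rg − k(1−qg)Pg − m(k−F) + (1−F)·(continuation)  GP first
```

Equating adjacent options yields the cutoffs: `d̂` (direct vs GP-first),
`d°` (give-up distance, where `Us = 0`; partial coverage only), and
`d̃ = [Rs − Rt + (qs − qt)Ps]/Ct` (in-person vs telemedicine).  Because the
equilibrium quality cost is affine in the arrival rate, every regime reduces
to a small linear system; when telemedicine is attractive enough that
patients tele-visit first (`d̂ > d̃`), the mixed-strategy tele-first mass
`λ_tele` is pinned down by congestion-mediated indifference.  The GP then
picks `k` to maximize profit
`λg·[(Pg−Cg)k − m(k−F)] (+ γ per tele-assisted encounter)`, a unimodal
objective solved by grid search with golden-section refinement.

Welfare is counted in resources — cure rewards minus production, travel,
mistreatment and quality costs; prices, reimbursements and the tele-reward
are transfers and net out (an explicit audit verifies this to 1e-9).
Average quality cost `φ` is total quality cost per cured patient.

## Worked example

Compare the market with and without telemedicine at the documented baseline
(midpoint parameters, small market `dmax = 1`):

```
$ telerefer compare -o results --set dmax=1.0
param_name  param_value regime  scenario    k_pre   k_post   mu_pre  mu_post  phi_pre  phi_post  tsw_pre  tsw_post   delta_k  delta_mu  delta_phi  delta_tsw
                    NaN   full         1 0.319806 0.276973 1.806128 1.813219 7.247563  7.238599 3.903003  4.141748 -0.042834  0.007091  -0.008964   0.238744
```

Read: the market is fully covered; with telemedicine the GP lowers the
referral threshold from `k = 0.320` to `0.277` (refers more, pocketing the
tele-reward), the specialist speeds up slightly (`μ` 1.806 → 1.813), the
average quality cost per cured patient falls (7.248 → 7.239) and total
social welfare rises by 0.24.  On a large, partially covered market
(`--set dmax=2.0`) the same comparison gives a much larger welfare gain
(+0.94) — telemedicine rescues the give-up segment — but `φ` *rises*
(6.69 → 8.15): the specialist absorbs the whole market and quality degrades.

Sweeps reproduce the comparative statics, e.g.
`telerefer sweep --param gamma --grid 2:4:21 --set dmax=2.0` (referral level
falls, service rate and welfare rise in the tele-reward) and
`telerefer sweep --param Ct --grid 6:8:21 --set dmax=2.0` (costlier travel:
more gatekeeping, slower specialist, lower welfare).

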