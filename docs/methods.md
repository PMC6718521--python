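# Methods

## The model

`glucopt` models blood glucose control after oral glucose ingestion with an
8-state ODE system: glucose in the intestinal lumen (IntestG, g), absorbed
gut glucose awaiting appearance (AGutG, g), blood glucose (G, mg/dL),
insulin (I, pM), C-peptide (CP, pM), a dimensionless effective-insulin
state (X) representing insulin action at target organs, and the two
incretins, intact GIP and intact GLP-1 (pM).  Thirteen fluxes connect the
states:

- ingestion `v1` (the input), gut absorption `v6` (Michaelis–Menten in
  IntestG), appearance in blood `v7 = k7·AGutG` scaled by a volume-like
  constant `V`;
- incretin secretion `v2`, `v4` (Michaelis–Menten in IntestG) and
  first-order relaxation to basal `v3`, `v5`;
- hepatic glucose production `v8 = k8/(L8+X)` (inhibited by effective
  insulin) and insulin-dependent uptake `v9 = k9·G·X`;
- insulin/C-peptide secretion
  `v10 = k10·(G + a·GIP + b·G·GIP + c·GLP1 + d·G·GLP1)`, insulin transfer
  to target organs `v11` (Michaelis–Menten in I, feeding X after division
  by `k11`), C-peptide clearance `v12`, and effective-insulin turnover
  `v13`.

The coefficients `a`–`d` encode independent (`a`, `c`) and
glucose-cooperative (`b`, `d`) incretin actions on secretion.  A *model
structure* fixes any subset of them to zero; GLP-1 can additionally be
removed as a state, which also drops `k4`, `k5`, `L4`, and `GLP1(0)` from
the estimated quantities.  Because insulin and C-peptide share the
secretion flux `v10`, C-peptide data constrain secretion independently of
insulin clearance.

**Steady-state closure.**  Eighteen kinetic parameters and six initial
levels are estimated; `k9`, `k11`, `k12`, `k13` and the basal incretin
levels `GIP_B = GIP(0)`, `GLP1_B = GLP1(0)` are *derived* by requiring
every state derivative to vanish at the pre-ingestion state.  The closure
is exact: property tests draw 1,000 random admissible parameter sets and
verify both the zero derivative (< 1e-9 relative) and a flat 480-min
zero-ingestion trajectory (< 1e-6 relative).

**Ingestion input.**  Schedules are non-overlapping (start, grams,
duration) events with piecewise-constant flux grams/duration; "bolus"
ingestion uses a 0.5-min event (a 50-g bolus therefore flows at
100 g/min).  Integer ingestion patterns on the 5-min grid convert to one
0.5-min event per nonzero slot.

## Numerics

Three integrators share one compiled (numba) core over a padded 8-state
vector:

- fixed-step Euler — the method used for objective evaluation in pattern
  optimization (step 0.01 min during search, 0.001 min for final reported
  values);
- fixed-step classic RK4 — the default for fitting (step 0.25 min) and
  general simulation (0.05 min); at these steps it agrees with the
  adaptive reference to ~1e-4 relative;
- piecewise LSODA (SciPy) — an adaptive cross-check, integrated segment by
  segment between ingestion-event boundaries.

Fixed-step grids must align with event boundaries (all events live on the
0.5-min grid), so the integrator never steps across a flux discontinuity;
the ingestion flux is held constant within each step.  Fitting uses the
compiled RK4 rather than an adaptive solver because at this problem size
the fixed-step compiled path is two orders of magnitude faster than
SciPy's adaptive integrators, which is what makes desk-scale evolutionary
fits practical.  States are not clamped at zero by default (clamping would
mask instability); a `floor_zero` option exists for deliberately coarse
Euler experiments.  Off-grid sampling interpolates linearly; at the stored
strides the interpolation error is negligible relative to solver error.

## Fitting

The objective is the min-max-normalized residual sum of squares over all
included (condition, species) series: each residual is divided by that
series' measured range, so species with different absolute scales
contribute comparably, and excluded conditions contribute nothing.

The search runs in log-parameter space (every estimated quantity is a
positive scale):

1. **Global:** classic self-adaptive Gaussian-mutation evolutionary
   programming — each parent spawns one child with per-dimension
   log-normal step-size adaptation; survivors among the 2N pool are chosen
   by q-opponent win-count tournaments (q = 10).  One individual of the
   initial population is a data-informed guess (initial levels at the
   fasting measurements, kinetics at mid-bounds).
2. **Local:** Nelder–Mead simplex refinement of the best candidates.
3. **Polish:** a bounded trust-region least-squares pass
   (`scipy.optimize.least_squares`, TRF) on the normalized residual
   vector.  At desk scale this step supplies most of the final
   convergence; it recovers the fit quality that the original
   cluster-scale regime (40 trials × 5000 parents × 5000 generations)
   bought with brute force.  On zero-noise synthetic data the chain drives
   the RSS to ~1e-12 and trajectory recovery errors to < 0.01% of range.

Desk-scale defaults are 3 trials × 200 parents × 200 generations;
cluster-scale values remain reachable through `FitSettings`.

**Search bounds.**  Default bounds are per-parameter-class and
physiological — first-order rates in [1e-4, 1e2] /min, secretion
capacities in [1e-2, 1e3] pM/min, Michaelis constants in assay-plausible
ranges, couplings in [1e-4, 1e2] — rather than one blanket box: in 17–24
dimensions an 8-decade isotropic box leaves global search stranded in
mass-action-degenerate corners.  Initial levels are bounded by
[0.1×, 10×] the fasting measurements; X0, which is unmeasured and
dimensionless, gets [1e-2, 1e2].  A coefficient at its lower bound (1e-4)
is numerically indistinguishable from zero in the secretion flux.

## Model selection

Candidates are the 2⁴ on/off combinations of {a, b, c, d}, optionally
extended by the four GLP-1-free variants over {a, b}.  Each candidate is
scored by `AIC = N·log(RSS) + 2K` (natural log), where N is the number of
fitted data points — identical across candidates by construction — and K
counts all estimated quantities, free initial levels included (this
bookkeeping choice is recorded in the selection metadata).  RSS = 0 is
reported as −∞ with a warning.  Ties break toward smaller K, then label
order.

When GLP-1-free candidates are in the set, the GLP-1 series is dropped
from the comparison for *all* candidates, since AIC comparisons require
every model to be scored on identical data.

**Warm-started scan.**  The maximal candidate of each family
(GLP-1-including / GLP-1-free) is fit with the full budget; nested
candidates are then processed in decreasing-K order, each refined from the
best already-fitted superset projected onto its free parameters (plus the
family fit), with a second polish pass on the winner.  This is the
standard way nested AIC scans are run: it keeps every candidate within a
fraction of an AIC unit of its floor, which matters because nested
comparisons are decided by RSS ratios of order exp(2/N) ≈ 1.006.
Independent full-budget fits per candidate remain available
(`warm_start=False`).

AIC retains its intrinsic overfit probability: freeing one truly-zero
coefficient gains deviance > 2 with probability ≈ 0.16, so structure
recovery is a stochastic, majority-of-seeds property, not a per-seed
guarantee; the recovery tests assert majorities accordingly.

## Pattern optimization

The inverse problem searches integer-gram patterns
u = [u0, u5, …, u60] (5-min grid, 0–60 min) with Σu = 50 g and u0 ≥ 1 g —
a space of C(61,12) ≈ 3.2e12 compositions (the count usually quoted,
62!/(49!·13!) = C(62,13) ≈ 8.3e12, distributes the 49 free grams over 14
rather than 13 bins; the enumeration oracle follows the constraints as
stated).  The objective J(u) is the simulated peak of G or I over
[0, 480] min.

The EP loop: the initial population contains the bolus pattern, the
(1 g @ 0, 49 g @ 60) split, and random compositions; mutation performs L
random 1-g transfers between uniformly chosen slots, bracketed by
remove/restore of 1 g at slot 0 (which re-establishes u0 ≥ 1); L decays
from 20 by 1 every 25 generations; selection scores all 2N individuals by
M-opponent win-count tournaments (M = N/5) and keeps the top N; the best
pattern ever evaluated is tracked independently of survival.  Crossover is
deliberately absent.  "The source holds at least 1 g" is the default
transfer-eligibility reading; the strict "more than 1 g" variant is
available behind a flag.  Objective values are memoized per pattern within
a run, and tie-breaks in rank selection (equal win counts) order by
smaller J then insertion order, so seeded runs are exactly reproducible.

Desk-scale defaults are 100 individuals × 100 generations × 2 trials
(study-scale: 500 × 500 × 5).  On reduced instances small enough to
enumerate, the EP search attains the exhaustive minimum in every tested
seed; on the full space it reproducibly finds intermittent patterns —
mass concentrated at 0 and 60 min with small mid-interval doses — whose
simulated peaks undercut both the 50-g bolus and the 50-g 1-h-continuous
references (by ~20% in peak glucose for the bundled subjects, more in
peak insulin).

## Synthetic subjects

Three bundled fixture subjects carry the coupling structures that
selection tends to favor in healthy adults: `subjA` (GLP-1-free, a = 0),
`subjB` (b = c = 0), `subjC` (a = c = d = 0).  Their parameter values are
fixture choices tuned once for physiological behavior — fasting glucose
85–95 mg/dL, 50-g-bolus peaks ~150–190 mg/dL, insulin rising several-fold,
bolus peaks similar across doses while 2-h-continuous peaks increase with
dose, return to baseline within ~4 h.  `subjB`'s GLP-1 kinetics are
deliberately slower than its GIP kinetics (peak ~48 vs ~32 min after a
bolus): GLP-1 is secreted from distal L cells and lags GIP, and without
that temporal separation the b·G·GIP and d·G·GLP1 terms are collinear and
the generating structure would not be identifiable by any method.

The generator simulates each of the six standard conditions
({25, 50, 75} g × {bolus, 2-h continuous}), samples on a 12-point clinical
grid over 0–240 min (a design stand-in spanning the return-to-baseline
window, not a transcription of any particular study's grid), and adds
independent Gaussian noise with SD = fraction × series range (default 5%),
clipped at zero.  What passing recovery tests show is therefore recovery
under *this* measurement model: independent homoscedastic-within-series
noise, a shared grid across conditions, no assay drift, no within-subject
physiological change between conditions, and no sensor delay.  Real data
violate all of these to some degree; the tests validate the machinery,
not clinical performance.

## Problem sizes used in the test suite

Checks run at desk scale, chosen to exercise the full machinery: fits use
2 trials × 100–150 parents × 100–150 generations; selection scans warm-start
nested candidates from their supersets; optimizer oracle checks use ≤ 120
enumerable patterns; peak-ordering checks use 60 × 60 EP runs with final
objectives re-evaluated at the 0.001-min Euler step.  The study-scale
settings are exposed through the corresponding settings objects.

## Known limitations

- Point estimates only: no identifiability analysis or confidence
  intervals.
- No glucagon, free-fatty-acid, or autonomic extensions; no sensor-delay
  modeling; no multi-nutrient objectives.
- The AIC scan's warm-start strategy assumes nested candidates; disjoint
  candidate families fall back to independent fits.
- Fixed-step integrators require event boundaries on the step grid (true
  for all schedules this package constructs).
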