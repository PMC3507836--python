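# Methods

## Model and assumptions

The package analyses the growth-zone activation system

    dx_i/dtau = (eps + beta (a_i x_i)^2) * s * (1 - x_i) - x_i,
    s = l - sum_j a_j x_j,

for n >= 2 zones. The state x_i is the *active fraction* of zone i's
polarisome; a_i is that zone's share of total polarisome (sum 1); l is
total substrate in units of total polarisome, so l = 1 marks exact
sufficiency for full activation of every zone. Inactivation is first
order and sets the unit of time. The form arises exactly from the
dimensional mass-action scheme

    dA_i/dt = (k_basal + k_auto A_i^2) * S * (T_i - A_i) - k_off A_i,
    S = sigma L - sum_j A_j,

under x_i = A_i / T_i, tau = k_off t, eps = k_basal T_tot / k_off,
beta = k_auto T_tot^3 / k_off, l = sigma L / T_tot. Because autocatalysis
is quadratic in the active *amount*, the map yields a single shared beta
for arbitrary (unequal) zone totals — the a_i^2 factor absorbs them — and
`nondimensionalize` is exact and invertible. Autocatalysis must be
nonlinear in the zone's own activity: with an activation factor linear in
x_i the per-zone steady-state condition is a quadratic with exactly one
root in [0, 1], which forbids asymmetric steady states altogether (no
monopolar branch, no NETO). The quadratic term is the minimal smooth
choice that produces the observed orb/monopolar/bipolar structure; no Hill
exponent is introduced. It also makes each zone's equilibrium curve
s_i(x) = x / ((eps + beta a_i^2 x^2)(1 - x)) depend on a_i, which is what
allows disconnected islands under asymmetry — with a weight-independent
activation the full equilibrium variety is always connected.

Assumptions inherited from this reduction: the substrate diffuses fast
relative to activation (one well-mixed pool, no spatial gradients);
activation is fast relative to growth (quasi-static parameter sweep);
per-zone polarisome totals are constant within a cycle. Spatially extended
reaction–diffusion behaviour, oscillatory Cdc42 dynamics and the molecular
identity of the substrate are outside scope.

Key invariants (property-tested): the unit box [0,1]^n is forward
invariant, and s >= 0 is preserved from valid initial states; the
dynamics are equivariant under permutations of equal-weight zones; the
n = 2 system is the exact restriction of n = 3 with a_3 = 0.

## Parameters

| parameter | meaning | default / typical | notes |
| --- | --- | --- | --- |
| eps | basal activation strength | ~0.07 (wild-type-like) | > 0 required by the analysis layers; 0 allowed in the core for exact degenerate tests |
| beta | autocatalytic strength (amount-quadratic) | 20 (two equal zones) | per-zone autocatalysis is beta * a_i^2; three-zone scenarios rescale beta to match it |
| a | zone weights | (0.5, 0.5) | the bifurcation structure is in terms of beta * a_i^2 per zone |
| l | substrate/length parameter | bifurcation parameter, scanned over [0.05, 2.5] | the wild-type cycle runs l_birth -> 2 l_birth with l_birth = 1.05 |
| activity threshold | a zone counts as "active" above this fraction | 0.3, hysteresis band [0.25, 0.3] in simulation | shared by branch labelling, phenotype calls and event detection |
| rho | growth / activation time-scale ratio | 100 (floor 10) | quasi-static regime; simulated NETO converges to the continuation fold as rho grows |

The wild-type archetype is never a hard-coded constant: it is solved for
(`wt_constraint_solve`) by requiring a stable monopolar state at
l_birth = 1.05 and the monopolar fold at l* = (4/3) l_birth, i.e. NETO at
one third of a linear-growth doubling cycle; beta = 20 fixes the line
along which the one-dimensional root is taken (the pair is deliberately
non-unique). All mutant archetypes are derived from it by directional
scaling until their defining phenotype holds, with the derivation recorded
in the scenario's provenance.

## Numerical machinery

**Equilibrium enumeration** seeds damped Newton from every node of a
41-per-axis grid (21 for n = 3), dedupes at 1e-6 max-norm, filters to
residual < 1e-10 inside the box, and classifies stability from the
analytic Jacobian with eigenvalue margin 1e-8 (complex pairs handled).
An empty result raises — the compact invariant box guarantees at least
one steady state. The test suite validates enumeration against an
independent semi-analytic oracle: each zone's equilibria lie on s_i(x), so
all steady states follow from one-dimensional root finding over the shared
substrate value.

**Continuation** is pseudo-arclength with secant predictor and Newton
corrector (initial step 1e-3, bounds [1e-6, 5e-2]); a curvature limit of
0.25 rad of tangent turn per step keeps the polyline geometrically
faithful, which branch deduplication and island closure detection rely
on. Folds are bracketed by sign changes of dl along the curve and refined
by extremising l along a corrected chord; l-extrema are then classified by
a probe — at a branch point another solution persists arbitrarily close on
the outside of the extremum, at a true fold none does. This matters
because at exact symmetry the two monopolar branches form a single closed
curve that crosses both pitchforks transversally (they appear as l-extrema
along it). Branch points with l locally monotone are bracketed by the
eigenvalue test function — the antisymmetric mode J11 − J12 on an exactly
symmetric diagonal branch (honouring the symmetry; also robust for the
doubly degenerate n = 3 pitchforks), the Jacobian determinant otherwise —
and bisected to |dl| < 1e-8. Branch switching perturbs along the critical
eigenvector at small fixed l offsets, escalating the perturbation until
Newton leaves the through-branch, so the returned starts do not depend on
the nominal perturbation size.

**Diagram assembly** traces from the equilibria at l_min, switches at
branch points, then seeds additional families from enumeration at nine
interior l values plus extra probes in the gaps between detected special
points (islands are disconnected by definition and live between the folds
of the connected families; a narrow island can still straddle all probe
points — near its extinction asymmetry the island width goes to zero and
no finite seeding finds it). Curves are deduplicated geometrically and by
exact solves; each curve is split at its (exactly inserted) branch points,
and pieces whose stable runs carry different active-zone sets are split
further at stability transitions, so labels are pure: orb, monopolar_i,
bipolar(_ij), tripolar, symmetric_unstable, plus "unstable" for
off-diagonal unstable connectors and "mixed" for genuinely mixed stable
runs (e.g. the single smooth branch at strong asymmetry). Islands are
kept whole so they retain the closed flag and their two folds. Assembled
diagrams are validated against enumeration at five quantile l values
(stable-set Hausdorff distance, tolerance 1e-5); a mismatch sets an
incompleteness flag rather than raising.

**NETO length** is the largest l of the named branch's stable segment,
reported from its terminating fold; the sentinel `NO_NETO` (inf) marks
branches that persist to l_max. For strongly asymmetric cells whose
activation completes smoothly (no fold), the phenotype layer uses the
interpolated threshold crossing of the least-active zone instead.

**Cycle simulation** integrates activation plus slow growth (LSODA,
rtol 1e-8) with the division event terminal at l_div = 2 l_birth
(configurable; cdc25-like non-dividing cells just keep growing). Zone
activation events use integrator event functions on the hysteresis pair
(up at 0.30, down at 0.25); NETO and tip-switch events derive from the
persistent active-set sequence after collapsing dwell times below
max(3, 0.02 * cycle). The simulated NETO l necessarily lags the fold by
the saddle-node passage plus threshold-crossing time (~0.03 in l at
rho = 1000); what the suite asserts — and what holds — is monotone
shrinkage of that error with rho. Halving integrator tolerances moves
event times by far less than 1% of the cycle.

**Phenotype classification** is a deterministic rule table over stable
states at the window ends and the NETO fold: mixed when the orb state
spans the whole window while monopolar growth exists; premature_bipolar /
orb when no monopolar state is available at birth; otherwise NETO cycle
fraction f < 0.25 -> weak_monopolar_early_NETO, f in [0.25, 0.5] ->
WT_NETO, f > 0.5 -> delayed_NETO, none -> no_NETO_monopolar. The band
edges bracket the observed take-off window (0.3–0.4 of the cycle) around
the 1/3 design target; cells born on a vanishing orb state are followed to
whatever they land on.

## Synthetic scenarios: what they do and do not show

The bundled archetypes emulate qualitative mutant classes by directional
parameter changes (lower eps: delayed/absent NETO, tea-like; higher eps:
bipolar from birth; lower beta: late, weak activation down to orb; higher
beta: early NETO; tip-weight asymmetry: islands and tip switching; a weak
lateral zone: branching only beyond division length). They are
non-dimensional caricatures: passing tests shows the *bifurcation logic*
of competitive activation reproduces these growth-pattern classes, not
that any particular rate constant matches a real strain. Real cells add
spatial transport, fluctuating totals, and cycle-phase regulation that the
quasi-static single-pool model deliberately omits; the lognormal
parameter-noise model is a generic variability stand-in, not a measured
noise spectrum.

One structural finding is worth recording: a regime in which the bipolar
branch is stable at birth *and* the monopolar branch spans the entire
doubling window does not exist in this model (the overlap ratio peaks well
below 2 across three decades of beta). The deep-overlap archetype
therefore realises the alternating monopolar/bipolar population pattern
via residual activity at the division scar (exposed as the `x_new` /
inheritance-rule knobs, default exactly 0): a daughter born with scar
residual on both tips falls into the bipolar basin while old-end daughters
grow monopolar without NETO.

## Known limitations

* Island discovery is seeding-based; islands narrower than the probe
  spacing (immediately before their extinction) can be missed.
* Special-point locations are refined to |dl| ~ 1e-8 where the test
  function is well conditioned; the duplicate branch-point copies met
  along the closed symmetric family are located only to ~1e-3 (they are
  used for splitting, while the canonical pitchfork positions come from
  the symmetric branch's antisymmetric test function).
* Hopf bifurcations and periodic orbits are not searched for — no
  oscillations arise in this model class — and two-parameter fold-curve
  continuation is replaced by plane scanning.
* `divide` is defined for two-zone cells; three-zone runs are analysed at
  fixed parameters without lineage bookkeeping.
* Phenotype band edges (0.25/0.5) and the activity threshold 0.3 are
  reported in output metadata; conclusions that hinge on cells near a
  band edge should be checked at neighbouring thresholds.
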