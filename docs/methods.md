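# Methods

## Coordination as relative redundancy

For a system of random variables $\{X_i\}_{i\in S}$, $S=\{1,\dots,n\}$,
the total correlation

$$I(\{X_i\}) = \sum_{i\in S} H(X_i) - H(\{X_i\})$$

measures how much shorter a joint description of the system is than a
variable-by-variable one.  Normalizing by the marginal description cost
gives the relative redundancy

$$r = \frac{I(\{X_i\})}{\sum_i H(X_i)} = 1 - s,$$

with $s$ the incompressible fraction.  $r$ lies in $[0, 1-1/n)$: it is
0 for independent elements, $1-1/n$ for $n$ perfect copies, invariant
to the overall scale of individual variability, and increasing both in
the strength of dependence and in system size.  These properties make
it a dimensionless, system-independent measure of coordination:
the same scale applies to a fish school, a neural population, or a
simulation, whatever the units of the microscopic variables.

Discrete computations (`redpart.discrete`) are exact and reported in
bits.  They require the full joint table and are intended for small
systems and for validating the estimators, not for data.

## The practical Gaussian lower bound

For continuous microscopic variables the package bounds $r$ from below
(`redpart.gaussian`).  Each variate is first rank-Gaussianized: value
with average rank $k$ of $T$ maps to $\Phi^{-1}((k-\tfrac12)/T)$.  This
makes every marginal standard normal while preserving all monotone
pairwise structure, so the Gaussian mutual information computed from
the sample correlation matrix $P_S$,

$$I_G = -\tfrac12 \log\det(P_S),$$

is a lower bound on the total correlation of the underlying variables,
and every redundancy output is invariant to monotone per-variate
transforms of the raw data (pixels vs meters, speeds vs log-speeds).

Elements may own several variates (an element $i$ with $k_i$ variates
has differential entropy $h_i = \tfrac12\log[(2\pi e)^{k_i}\det K_i]$).
For such elements the numerator subtracts the within-element block
terms, $-\tfrac12[\log\det P_A - \sum_{i\in A}\log\det P_i]$, so that
dependence *between* a fish's own vx and vy never counts as
coordination and every singleton subset scores exactly zero — a
property the partitioning objective requires.

Differential entropies can be negative, so the denominator adds a
quantization offset $\alpha$ per variate (an $\alpha$-bit discretization
adds $\alpha$ bits to each marginal description):

$$r(A) \ge \frac{-\tfrac12[\log\det P_A - \sum_{i\in A}\log\det P_i]}
             {\sum_{i\in A} (h_i + k_i\,\alpha)}.$$

$\alpha$ cancels in the numerator but rescales the denominator, so it
must be held fixed across any systems being compared.  The package
default is 4 bits per variate, which keeps all terms positive for
rank-Gaussianized data with moderate within-element dependence.  In the
strongly ordered regime of constant-speed motion the (vx, vy) block of
an element approaches degeneracy and $h_i \to -\infty$; the noise sweep
therefore defaults to 8 bits per variate across its whole grid.  A
non-positive denominator raises an error instructing a larger $\alpha$
rather than silently producing an invalid bound.

Numerics: correlation matrices that fail a Cholesky factorization (or
whose smallest pivot is below $10^{-6}$) are shrunk toward the identity,
$P \leftarrow (1-\varepsilon)P + \varepsilon I$ with $\varepsilon$
escalating by decades from $10^{-8}$ to $10^{-4}$; each escalation is
logged, and a subset that is singular even after shrinkage returns a
+inf sentinel with a warning.  Fischer's inequality guarantees the
numerator is nonnegative in exact arithmetic; tiny negative rounding
residues are clipped to zero.

## Redundancy partitioning

To find the most coordinated components, elements are assigned to
components $j \in \{1,\dots,m\}$ by a row-stochastic matrix $p(j|i)$.
Component $j$ induces a Bernoulli product measure over subsets,
$p(A|j) = \prod_{i\in A} p(j|i) \prod_{i\notin A}[1-p(j|i)]$, and is
scored by its expected redundancy $E[r(A)|j] = \sum_A r(A)\,p(A|j)$;
the objective is the plain average over components,
$E[r(A)] = \tfrac1m \sum_j E[r(A)|j]$.

Maximizing average redundancy while compressing element identity as
much as possible (minimal $I(S;\hat S)$, reported in bits as the
achieved rate) yields a Blahut–Arimoto-style self-consistency
condition

$$p(j|i) \propto p(j)\, e^{\beta\,\Delta d(i,j)},\qquad
  p(j) = \sum_i p(j|i)\,p(i),$$

where $\Delta d(i,j)$ is the marginal value of element $i$ to component
$j$: the expected redundancy of the component's subset with $i$
included minus excluded, weighted by $1/p(i)$.  The element prior is
uniform, $p(i)=1/n$.  One iteration updates all rows synchronously from
the current marginals, then refreshes $p(j)$; exponentials are
stabilized by subtracting the per-row maximum of $\beta\Delta d$.  At
large $\beta$ the synchronous map can enter a two-cycle between
near-hard configurations; the solver detects this, stops, and returns
the best iterate seen.  Restarts (default 100) draw initial rows from a
symmetric Dirichlet with concentration 1, and the best-objective
solution wins.  Convergence is declared when the average redundancy
changes by less than $10^{-9}$ or the assignment matrix stabilizes;
non-convergence is logged and the best iterate returned.

Exact expectations enumerate the $2^n$ power set and are capped at
$n=15$; beyond that, $\Delta d$ is estimated by Monte Carlo: draw $K$
subsets of the other elements by independent inclusion with probability
$p(j|k)$ and average $r(B\cup\{i\}) - r(B)$ over shared samples (the
shared-sample difference has much lower variance than estimating the
two terms independently).  Draws are collapsed to unique subsets so the
redundancy function is evaluated once per distinct draw; estimates are
bit-reproducible given a seed.

### Hard-partition limit

As $\beta\to\infty$ rows become one-hot and the update reduces to
greedy reassignment.  `solve_hard` implements this directly: visit
elements in a seeded random order, move each to the component that most
improves the average-redundancy objective (ties to the lowest index,
moves accepted only above a $10^{-12}$ improvement), and stop on a full
pass with no moves.  The objective never decreases across accepted
moves.  Under the Gaussian bound each subset evaluation is one Cholesky
factorization of a principal correlation submatrix; results are cached
by element bitmask and the cache is shared across all restarts and all
values of $m$ in a scan, which makes the $m=1..10$, 50-restart scans
used in the experiments run in seconds to a couple of minutes for
systems of 10–70 variates on one core.  $m>n$ is allowed; surplus
components end empty (an empty or singleton component scores zero).

### Choosing the number of components

`component_scan` records the best average redundancy $\bar r(m)$ for
$m = 1..m_{\max}$ and the drop $\Delta(m) = \bar r(m-1) - \bar r(m)$.
Splitting weakly coupled parts is cheap (small $\Delta$); splitting a
strongly coordinated component is expensive (large $\Delta$).  The
first local minimum of $\Delta$ is the structure-count heuristic.  A
point interior to the curve is a minimum when strictly below its left
neighbor and no greater than its right one (ties, within $10^{-12}$,
resolve toward smaller $m$); the left endpoint $m=2$ counts when it
does not exceed $\Delta(3)$, since two independent groups plateau right
there; the right endpoint is never a minimum because nothing beyond it
is observed.  The heuristic is exactly that — curves can lack minima
(single cohesive groups typically do) or have several.

## Simulators

`vicsek_simulate` is the standard alignment model: constant speed
$c=0.03$, box $L=1$ with periodic boundaries, interaction radius
$d=0.2$, $\Delta t = 1$; each step an agent adopts the direction of the
vector sum of unit headings of itself and all neighbors within $d$,
plus noise uniform on $[-\eta/2, \eta/2]$.  The redundancy-vs-noise
sweep runs 500 burn-in steps and scores the Gaussian-bound redundancy
of the 2-D velocity components over the following 1000 steps (one
sample per replicate), alongside the time-averaged polarization
$\bigl|\tfrac1n\sum_i v_i/|v_i|\bigr|$.  Modes of the redundancy
distribution per noise level are KDE local maxima (Silverman
bandwidth) above 20% of the level's peak density, linked across
adjacent noise levels when within 0.05 in redundancy units; floor and
link threshold are exposed parameters.

`school_simulate` is a zone-based attraction–alignment–repulsion model
in open 2-D space used to generate cohesive polarized groups with a
controlled dependency structure.  Constant speed 1 (body lengths per
time unit), $\Delta t = 0.1$; zones: repulsion within 0.2, alignment
within 1.0, attraction only in the annulus $[1.0, 2.0)$ — attraction
confined to the annulus makes a mutually aligned pair inside the
alignment zone a true fixed point of the noiseless dynamics.  Repulsion
takes absolute priority; otherwise the desired direction blends the
alignment direction (weight 1.0) and the attraction direction (weight
0.4).  Headings relax toward the desired direction at rate 4 per time
unit with additive Gaussian angular noise of standard deviation
$\eta\sqrt{\Delta t}$ per step.  Weights were fixed by the
fixture-validity requirement — every single group of size 5, 10, or 20
at $\eta \in \{0.15, 0.2\}$ must be cohesive (no agent beyond
$5\,r_{att}$ of the centroid after burn-in) and polarized (time-averaged
polarization above 0.8) — verified over a 120-run grid.  Each
simulation records its own self-check outcome in metadata and warns on
failure.  This model is a documented stand-in chosen for behavioral
plausibility; it is not a replication of any specific published
parameterization.

`independent_groups` simulates several such groups with independent
child seeds and no cross-group forces, spatially offset; group labels
are returned as ground truth for validation but are never consumed by
the analysis, which sees only velocities.

### What the generators do and do not emulate

The generators produce the coordination structure the method is
designed to detect: strong within-group velocity dependence, exact
independence between groups, and an order parameter that responds to
noise.  They do not emulate several features of real tracked data —
measurement noise, occlusions and identity switches, fission–fusion
events, heterogeneous individuals, or within-group social substructure
(dominance networks, spatial preferences).  Passing the group-recovery
tests therefore demonstrates that the estimator-plus-partitioner
pipeline detects independence structure through velocities alone; it
does not certify performance on data with tracking artifacts, nor that
a particular biological school has no finer structure than the
partitioner reports.

### Analysis window for the group-structure experiments

A schooling group's shared heading is the slowest mode of the dynamics;
measured over long runs it decorrelates in roughly 16 time units (160
steps) at $\eta=0.2$.  Sample correlations between *independent* groups
are pure estimation noise of magnitude $\sim\sqrt{2\tau/T}$, so the
analysis window must span many decorrelation times for the dependence
structure to be identifiable.  The group-structure experiments use a
500-step burn-in followed by a 5000-step window ($\approx 30\tau$),
which brings spurious cross-group correlations down to $\approx 0.2$
while within-group correlations remain near 0.9.  With a 1000-step
window the scan outcome is dominated by seed noise.  The window length
is a property of the study conditions, not a tuning knob: all reported
experiments use the same value.

Known consequence: a group's measured redundancy still varies
considerably from seed to seed (worst for small groups), because it
depends on how far the shared heading happens to wander within the
window.  For mixed-size systems this can make a merged two-component
description score as well as the true three-group split, so the
first-minimum heuristic may report fewer components than there are
groups.  This is a genuine property of the measure on this generator
at these conditions, reported as such.

## Empirical trajectory pipeline

`read_tracks` ingests (frame, id, x, y) tables at a known frame rate,
canonicalizes order, rejects duplicate (frame, id) pairs, and
normalizes ids.  Velocities come from a 3rd-order Savitzky–Golay
smoothing derivative over a 7-frame window (30 fps defaults), computed
per maximal contiguous run; the first and last 3 frames of each run
are dropped rather than extrapolated.  `window_observations` builds
the observation matrix for a closed window of $\pm$15 s around a time
of interest ($T = 2\cdot15\cdot30+1 = 901$ samples at the defaults),
with (vx, vy) per individual as elements; individuals with any gap in
the window are excluded with a warning (no interpolation — a flag for
interpolation is deliberately not provided until its bias is
understood).  Frames are 0-based, window intervals closed, and the
y-axis is taken as recorded (no image-convention flip).  Because of the
rank transform, all downstream results are invariant to the units of
the input coordinates.

## Known limitations

- The Gaussian bound is a lower bound; it captures monotone pairwise
  structure only and is inappropriate for discrete or mixed systems.
- The exact partitioning path scales as $2^n$ and is capped at
  $n = 15$; beyond that only the Monte-Carlo and hard-partition paths
  apply.
- All solvers have local-optimality guarantees only; restarts are the
  sole globalization mechanism.
- The first-local-minimum heuristic has no significance calibration;
  plateaus and multiple minima require judgment.
- The soft-partition regime ($\beta$ of order 1–10) is exposed but not
  analyzed.
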