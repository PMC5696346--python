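# Methods

## Model

A traveler on a set of N populated locations moves from its current location
*i* to location *j* with probability

    p_ij ∝ B_ij · A_j,      B_ij = m_j / W_ji,      A_j = 1 + λ / r_j,

where `m_j` is the destination's population, `W_ji` the total population in
the circle centred at *j* with radius equal to the *j*–*i* distance, `r_j`
the order in which the traveler first visited *j* (home has rank 1), and
`A_j = 1` for never-visited locations. λ ≥ 0 — the model's single free
parameter — scales the preferential-return (memory) effect. Self-transitions
are excluded: each step is an inter-city travel step, and a "stay" is not a
move. Destination sets are global (no distance cutoff); the kernel is
defined over all N locations.

Conventions the formulas leave open, fixed here:

* **Circle boundary.** `W_ji` includes every location k with
  `d(j,k) ≤ d(j,i)`, ties compared with relative tolerance 1e-9. The
  inclusive convention guarantees `W_ji ≥ m_i + m_j` and hence `B_ij ≤ 1`,
  and resolves exact-tie geometries (equilateral triangles, lattice points of
  fractal sets) deterministically.
* **Home.** The traveler's first visited location is its home, counted once
  at t = 0 with rank 1, which reproduces the strong return-to-home bias; in
  check-in data the home is identified as the most frequently visited
  location, ties broken by earliest first visit.
* **Distance.** Planar Euclidean, in km. Tables with lon/lat columns are
  projected to km with a local equirectangular projection about the mean
  latitude; the model itself is metric-agnostic.

`W` is computed per centre by a neighbour sort plus prefix sums
(O(N² log N)) and cached; the per-origin kernel `B` is cached with a zero
diagonal.

## Simulation protocol

Each traveler receives a home (sampled proportionally to population unless
given) and a trajectory length L, then performs L multinomial steps under
p_ij, updating first-visit ranks as it explores. One seed sequence is split
per traveler, so ensembles are reproducible and trajectories are independent
given the seed.

**Trajectory lengths.** Real check-in records have heavy-tailed per-user
activity; the synthetic default is a discrete truncated power law
P(L) ∝ L^-1.5 on [10, 1000] (mean ≈ 100). Any explicit length vector or
empirical resampler can be passed instead. This default is a synthetic
stand-in, not a fitted law, and drives some observables strongly (see
*Limitations*).

**Synthetic domains.** `generate_synthetic_population(n, s, extent, seed)`
draws coordinates uniformly in a square and assigns rank-r population
`max(1, round(m_max · r^-s))` (default m_max = 10⁴, s = 1 — a Zipf rank-size
law, the standard stylized fact for city sizes), shuffled over locations.

## Observables

* **S(t)** — distinct locations visited within t steps, averaged over the
  travelers still active at t (survivor averaging, since lengths vary). The
  per-trajectory curve is nondecreasing with S(0) = 1; the survivor-averaged
  curve can dip where short trajectories drop out.
* **P(τ)** — return times: inter-visit gaps per location, pooled over all
  locations and travelers (a revisit at step t after a visit at t′ yields
  τ = t − t′). Trajectories without revisits contribute nothing.
* **f_r** — per traveler, locations ranked by visit count over the L+1
  entries; f_r averages the rank-r normalized frequency over travelers
  having at least r distinct locations.
* **Motifs** — trajectories are split at every return to home; each loop's
  simple directed graph (distinct locations as nodes, observed transitions
  as edges, multiplicities collapsed, home unlabeled) is canonicalized by
  brute-force minimization over node permutations. Loops with more than 6
  distinct nodes are lumped into an `other` bucket; that bucket is an
  aggregation artifact and is excluded when ranking "top-k motifs".
* **P(d), P(T)** — trip-distance and pairwise-flux distributions, as
  log-binned densities (base 10, 10 bins per decade by default) with bin
  masses summing to 1.

## Simplified model and theory

With uniform populations the competition kernel is flat and the walk reduces
to N abstract locations where the r-th first-visited location has weight
`1 + λN/r` (as distinct from the full model's `1 + λ/r`; both forms are kept
exactly as printed, and the factor N is not reconciled here — the simplified
walk is a separate object, not a limit of the full one). Its laws:

* `f_r ∝ λS/r + 1 − λ`: uniform at λ = 0, exact Zipf `S/r` at λ = 1,
  cutoff-like deviation for λ > 1.
* `P_new = (N − S) / (N + λN·H_S) ≈ 1/(1 + λ(ln S + C))` with
  C = Euler–Mascheroni γ_E by the harmonic-sum approximation H_S ≈ ln S + γ_E
  valid for S ≪ N. C is exposed as a parameter because the approximation
  (and the constant) is a modelling choice; the exact weight-sum form is the
  oracle it is tested against.
* S(t) integrates dS/dt = P_new(S) to the monotone implicit relation
  t(S) = (S−1)(1+λC) + λ(S ln S − S + 1), inverted with a bracketed root
  find (the root lies in [1, 1+t]; tolerance 1e-12). The continuum
  approximation overshoots at the first few steps (the simulated walk always
  explores at t = 1), so simulation cross-checks compare from t ≳ 10.
* The return-time law is represented only by its asymptotic τ^-1 decay,
  used as a fitting prediction; the exact two-term expression is out of
  scope.

**One-step population flux.** m individuals per location each move once
under the pure competition kernel: `T_ij = m·p_ij`, `p_ij ∝ m_j/W_ji`, rows
summing to m (the expectation; a multinomial sampled mode exists). On a
fractal location set of dimension D, `W_ji ∝ d_ij^D`, so
`T_ij ∝ m_i m_j / d_ij^D` — a gravity law with power-law distance
deterrence — and, because the number of pairs within d grows as d^D, the
flux distribution is `P(T) ∝ T^-2` for every D.

Two distance observables must not be conflated. The *distance-decay curve*
(mean flux per pair at distance d) scales as d^-D. The *trip-length
density* (each step weighted into its distance bin) multiplies that decay by
the pair multiplicity ∝ d^(D-1) and therefore scales as ~d^-1 in the
interior of any fractal domain; it is provided as an observable but is not a
measurement of D. Exponent fits for the decay curve use the window
[4 × cell spacing, extent/4]: below a few lattice cells the IFS approximant
is discrete, and above a fraction of the domain size W saturates at the
total population, flattening the kernel.

**Generalized-Zipf walker.** Guided by the generalized Zipf law f ∝ r^-ζ
(ζ > 1), each step draws a rank from the weights r^-ζ over the full ladder
r = 1..N; a rank within the S visited locations returns to that location
(current excluded), a larger rank explores a uniformly chosen new location,
which becomes rank S+1. The exploration probability is then the Zipf tail
mass beyond S, so `P_new ∝ S^-(ζ-1)` emerges rather than being imposed —
the defining relation of exploration-and-preferential-return dynamics with
γ = ζ − 1 — and S(t) grows sublinearly as ~t^(1/ζ).

## Fractal domains and dimension estimation

Four deterministic IFS families generate the spatial point sets: 2D Cantor
dust (4 copies, contraction 1/3, D = log4/log3 ≈ 1.262), Vicsek saltire
(5, 1/3, ≈ 1.465), Sierpinski triangle (3, 1/2, ≈ 1.585) and hexaflake
(7, 1/3, ≈ 1.771). Points are the centres of depth-d cells, so the point
count is exactly copies^depth. The Sierpinski triangle uses the
right-isosceles (grid-aligned) vertex set: the dimension is unchanged under
the affine map, and box counts at sizes 2^-k become exactly 3^k.

Box counting uses square grids anchored at the per-axis minimum of the
point set, sizes aligned with the IFS contraction (extent · scale^k,
k = 1..depth), and the least-squares slope of log(count) vs log(1/size).
A point-set approximant counted down to its own cell scale undercounts
whenever the cells are not grid-aligned (at the finest size, square boxes
the size of the hexagonal cell spacing merge neighbouring hexaflake cells,
biasing the slope from 1.77 to ~1.70); `estimate_fractal_dimension`
therefore takes the counts on the approximant refined two IFS levels below
the finest box. For the grid-aligned families the refinement leaves every
count exactly copies^k.

## λ estimation

`E(λ) = Σ_{t=1..L_max} |S_real(t) − S(t,λ)| / S_real(t)` is minimized over
a λ grid (default 0..100 step 1), with optional two-round local refinement
around the coarse minimizer. The model curves are averaged over replicate
simulations run with the observed homes and lengths, using common random
numbers — the same replicate seeds for every candidate λ — so Monte-Carlo
noise cancels when comparing candidates. L_max defaults to the 90th
percentile of the observed lengths: the S(t) tail is carried by few long
trajectories and is noisy. The same relative-L1 objective with the P(τ) pmf
or the f_r curve in place of S(t) serves as a cross-check; on synthetic data
all three pick the same grid minimizer, and recovery experiments over
λ* ∈ {5, 20, 50} (100-location Zipf domain, 300 travelers of length 100,
4 replicates, multiplicative grid) achieve median relative error ≈ 4%.

## Problem sizes

Defaults chosen for the standing test and acceptance runs: fractal depths
7/6/8/5 (Cantor/Vicsek/Sierpinski/hexaflake; 6.5k–17k points) for dimension
and flux-exponent measurements, with the flux histograms computed by a
streaming two-pass column algorithm in O(N) memory; Sierpinski depth 6
(729 points, dense kernel) for the distance-decay exponent; the simplified
walk at N = 1000, L = 1000, λ = 1 with 500 walkers for return times; and a
200-location Zipf domain with 2000 travelers at λ = 35 for the motif census.

## What the synthetic generator does and does not emulate

The generator reproduces Zipf-distributed city sizes, population-weighted
home assignment, and heavy-tailed per-user activity. It does not emulate
spatially correlated population (real cities cluster; coordinates here are
uniform), calendar time (one step = one inter-city move; synthetic
timestamps advance one day per step), intra-city movement, or the empirical
trajectory-length distribution of any particular data set. Passing tests
therefore demonstrate internal consistency of the model, its analytic laws
and its estimator on synthetic data — not agreement with any empirical
record.

## Limitations

* The top-9 motif mass of full-model ensembles is sensitive to the
  trajectory-length law: with the synthetic default (mean L ≈ 100) long
  exploration loops spread mass over many rare topologies and the top nine
  cover ≈ 0.86 of loops (≈ 0.95 counting the `other` bucket as a rank);
  check-in-like records dominated by very short trajectories concentrate
  the mass far more strongly.
* Exponent fits on finite fractal approximants are window-sensitive; the
  windows above are fixed a priori and reported with every fit.
* The estimator's objective is a Monte-Carlo quantity; with few replicates
  the refinement stage can settle on a neighbouring grid point for shallow
  objectives (λ* small).
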