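# Methods

## The continuum swarming-adhesion model

Each strain *i* is described by a free (motile) density ρᵢ(r, t) and a
bound (immobilized) density bᵢ(r, t), both normalized to the carrying
capacity ρ_max = 1:

    ∂ρᵢ/∂t = ∇·(Dᵢ m(ρ_T) ∇ρᵢ) + gᵢ ρᵢ (1 − ρ_T) − ρᵢ Σ_{j∼i} K (ρⱼ + bⱼ)
    ∂bᵢ/∂t =                                        ρᵢ Σ_{j∼i} K (ρⱼ + bⱼ)

where ρ_T = Σᵢ(ρᵢ + bᵢ) and j∼i ranges over strains whose element shares a
cross-complementary adhesin pair with strain i's element. Assumptions:

- **Irreversible adhesion.** Binding converts free cells to bound cells at
  rate K per unit partner density; bound cells never detach, do not move,
  and act as sinks for further adhesive swarmers (recruitment through the
  ρⱼ + bⱼ term). A toggle (`ModelParams.bound_growth`) lets the bound
  phase also grow logistically; it is off by default, treating bound
  clusters as passive.
- **Shared carrying capacity.** All strains compete for the same space;
  growth stops when ρ_T reaches ρ_max.
- **Mobility.** The default m = 1 is plain Fickian active diffusion. It
  reproduces the characteristic interface signature — a total-density
  peak at the adhesion zone (free cells keep streaming in and are
  ratcheted into the immobile phase, locally exceeding carrying capacity)
  with depleted troughs on the flanks. The alternative
  m = max(0, 1 − ρ_T) ("crowding") shuts motility down inside the
  saturated lawn; it freezes interpenetration after fronts merge but caps
  the density at ρ_max and therefore suppresses the peak, so it is not
  the default. Either choice leaves the dilute leading edge unchanged,
  so an isolated colony expands at the pulled-front (Fisher–KPP) speed
  2√(gD).

### Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| Dᵢ | effective swarming diffusivity | 0.1692 (= 47 µm² s⁻¹) | mm² h⁻¹ |
| gᵢ | logistic growth rate | 14 | h⁻¹ |
| K | adhesion strength (densities normalized to ρ_max) | 130 | h⁻¹ |
| ρ_max | carrying capacity | 1 | — |
| dx | grid spacing | 0.025 (1-D), 0.1 (2-D) | mm |
| extent | closed-dish domain | 40 | mm |

A competitive adhesin inhibitor (such as the EPEA peptide against Nb2) is
modelled purely as a scalar multiplier on K; no binding kinetics.
Seeding-concentration differences enter as onset delays
τ = ln(ratio)/g (`delay_from_dilution`), the time exponential growth
needs to recover the dilution.

### The active-swarming window

With the fitted parameters the front speed is 2√(gD) ≈ 3.1 mm h⁻¹, so
the model clock covers only the *active swarming* phase of an
experiment: an 18-h bench protocol includes a long pre-swarming lag
(inoculum adaptation and colony establishment) that the model does not
describe, and 18 h of *active* swarming would carry fronts ~55 mm —
beyond any dish. Two observations pin the window's order of magnitude:
imaged two-colony plates show colonies extending only a few mm beyond
the measurement region, and onset delays of well under an hour
(dilutions up to 10⁶ give τ ≤ 1 h) visibly rotate interface angles,
which requires the total window to be O(1 h). The standard two-colony
assay (`pde.interface_assay`: seeds 9 mm apart, 40-mm 1-D domain)
therefore integrates **2.5 h**: fronts meet at ≈1.2 h and the profile is
read ≈1.3 h later. This choice was fixed from the geometry argument
above, before any width was compared against published values, and is
not adjusted per run.

### Numerics

Method of lines on a regular grid; 3-point (1-D) / 5-point (2-D)
Laplacian in conservative flux form with zero-flux walls; first-order
operator splitting per step:

1. **Adhesion** via an *exact* exponential update — the per-strain total
   cᵢ = ρᵢ + bᵢ is invariant under adhesion, so each strain's sink rate
   K Σⱼ cⱼ is constant within the step and ρᵢ ← ρᵢ·exp(−rate·dt) is exact
   and unconditionally stable.
2. **Growth** by explicit Euler with dt ≤ 0.2/g.
3. **Diffusion** by explicit Euler with dt ≤ safety·dx²/(2·ndim·D),
   safety = 0.8.

Flux-form diffusion and the exact adhesion exchange conserve mass to
round-off when g = 0 (verified to < 10⁻⁶ relative drift per hour).
Halving dx changes the extracted interface width by < 0.1 %. NaNs or
significantly negative densities abort with a diagnostic naming the
violated bound. Seeds are smoothed discs (radius 1 mm, amplitude
0.1·ρ_max, tanh shoulder of 2·dx) emulating 1-µl drops; delayed seeds
are inserted into the field when t reaches their delay.

## Profile fitting and the curvature width

Measured or simulated fluorescence profiles (intensity = ρᵢ + bᵢ: a
cytoplasmic fluorophore labels free and bound cells alike; in 2-D,
averaged across a 1.5-mm band perpendicular to the 6-mm seed-axis line)
are fitted with

    f(x) = z / (1 + (k_a/x)ⁿ) + y + a·exp(−x²/b)

— a generalized Hill sigmoid for the transition plus a Gaussian anchored
at the window start that absorbs plateau slope. Note b multiplies x²
directly, so it is a *squared* length (mm²) even though it is sometimes
loosely called a standard deviation. Conventions and numerical choices:

- x runs from the start of the 6-mm window (x > 0; the Hill term is
  undefined at 0) in **mm**, and the intensity is normalized to its
  maximum. Both choices matter because the curvature below is not
  scale-invariant; they mirror how normalized profiles are plotted.
- Deterministic initialization: k_a at the mid-intensity crossing,
  n = 4, z = ±(intensity range), y = min (rising) or max (falling),
  a = 0, b = (x-range/4)²; bounded trust-region least squares (n ≤ 64).
  Identical inputs give bit-identical fits.
- The transition width w is the distance between the two maxima of
  κ = |f″|/(1 + f′²)^{3/2} flanking k_a. Curvature is evaluated
  analytically (the Hill term is computed as a logistic in log x for
  numerical stability at large n), extrema located on a 10⁴-point grid
  and polished by bounded scalar optimization. If a flank is so gradual
  that its curvature maximum lies at the window edge, the edge is used —
  the width is then window-limited, which is reported honestly rather
  than extrapolated.
- Because the Hill term depends on x/k_a rather than x − k_a, refitting
  a *translated* profile changes (k_a, n) jointly; the width is nearly
  translation-invariant for steep transitions (< 2 % for n ≳ 20) but
  only approximately so for gentle ones.

Under the standard assay this yields 282 µm (K = 130 h⁻¹) versus
1358 µm (K = 0): adhesion sharpens the transition ~5-fold, and the width
decreases monotonically as K rises through {0, 13, 130, 1300} h⁻¹,
which is the inhibitor-titration trend. A caveat recorded here
deliberately: the mean-field sink K·(ρⱼ+bⱼ) blocks interpenetration
within √(D/K) ≈ 30 µm once bound density accumulates, so the simulated
adhesive interface is sharper than typical measured ones, which reflect
incomplete microscopic blocking and lateral waviness averaged across the
measurement band; no attempt is made to inflate the simulated width to
match.

## Front-arrival geometry

Territory of seed k = points where τₖ + dist(r, seedₖ)/vₖ is minimal
(dist to the point, or to the nearest point of a polyline source — a
line source behaves as the superposition of many point sources). Equal
seeds give the exact Voronoi diagram; closed forms used as test oracles:
perpendicular bisector, hyperbola branch |r−s₁| − |r−s₂| = −vτ (shifted
toward the delayed colony), Apollonius circle for speed ratio v₁/v₂
(engulfing the slower colony), parabola for point + line. The grid
engine (default 100 µm) labels cells by argmin arrival (ties to the
lowest seed index; tie loci are measure-zero), extracts each
label-pair's interface as the zero contour of the arrival-time
difference with sub-cell linear interpolation, and clips it to where the
pair is jointly first. Memory stays O(grid) for any seed count: only the
best and second-best arrivals are tracked and per-pair grids are
recomputed on demand. Interface angles are measured as in manual
tracing: the trace is split at its vertex (nearest point to the seed
axis) and each leg gets a principal-direction least-squares line; the
angle to the seed axis decreases from 90° as arccos(vτ/d) when one seed
is delayed.

## Inverse design

1. **Regular tilings** seed tile circumcentres: triangular and square
   face-adjacency graphs are bipartite (one singlet pair alternating);
   the hexagonal face graph has odd cycles (3-chromatic) and uses three
   doublets built from two adhesin pairs.
2. **Colouring.** Faces joined by desired-hidden edges are contracted;
   the quotient map is coloured exactly with ≤ 4 colours by DSATUR-
   ordered backtracking (with a step cap against non-planar abuse), and
   colours map to the four doublets in fixed lexicographic order, so
   every visible edge separates different doublets and hidden edges join
   identical ones. A group adjacent to itself across a visible edge is
   reported as unsatisfiable-without-null-isolation.
3. **Generalized inverse Voronoi.** Every target edge is pinned as a
   union of Voronoi edges by mirrored seed pairs at spacing h, offset
   h/2, with h = clamp(min(edge length, clearance to non-incident
   edges)/2, h_min, h_max) (defaults 0.2/0.4 mm — ~2–4 predictor grid
   cells; smaller h tracks vertices more tightly at the cost of more
   seeds). Subtile seeds inherit the containing face's element, hiding
   all added edges; faces that receive no pair seeds get an interior
   representative seed. Features needing h below h_min are rejected, not
   approximated.
4. **Open interfaces.** Visible edges that dangle (an endpoint not
   incident to another visible edge, or a slit wholly inside a face)
   cannot be realized by face colouring — a slit does not subdivide the
   plane. They are realized locally instead: the flank on one side keeps
   the containing face's doublet; the other flank gets a different
   doublet as a strip of seeds at offset h/2; and a wrap of null-element
   seeds (offset 3h/2 plus caps beyond open ends and at branch vertices)
   encloses the strip, so the visible boundary terminates where null
   territory begins. The null element forms no visible interface with
   anything, which is exactly the isolation role it plays. Open ends
   therefore carry a ~h-sized gap and chains show ~h-sized notches at
   branch vertices; both are within the verifier's tolerance of two
   grid cells.
5. **Self-verification.** `verify_design` predicts the interfaces of any
   solution and reports target coverage and spurious-interface fractions
   at 2-grid-cell tolerance; all design tests pass through it, so the
   pipeline is validated end to end rather than stage by stage.
6. **Triangular lattice.** With seeding restricted to triangle centres,
   targets (subsets of lattice edges) are solved by the same
   contraction + quotient-colouring route on the dual graph — provably
   sufficient whenever the instance is satisfiable, since a quotient of
   a planar graph by connected parts is planar. A row-sequential greedy
   (non-horizontal interfaces row by row, then horizontal constraints)
   is provided as an alternative strategy; it can fail on satisfiable
   instances and may use more elements (e.g. 3 instead of 2 on the
   all-edges target). Unsatisfiable targets — a target edge interior to
   a hidden-connected region — are reported explicitly, never silently
   approximated. Realizable random fixtures are generated as region
   boundaries (nearest-of-m-sources partitions), because a uniformly
   random edge subset is almost never the cut set of any colouring.

## Point-pattern statistics

The multicomponent pair correlation g_ab(r) counts, per type-a cell,
type-b cells in annuli r..r+dr, normalized by the annulus area clipped to
the observation window and by the global type-b intensity, then averaged
over a-cells. Edge correction uses *exact* circle–rectangle intersection
areas (closed-form inclusion–exclusion of quadrant integrals); no border
points are discarded. A periodic (torus) mode serves as the convergence
reference. The clustering excursion is summarized by fitting
amplitude·EMG(r; µ, σ, λ) + 1 — the baseline fixed at 1, the large-r
limit of g — and reporting the variance σ² + 1/λ². "No meaningful fit"
is declared when the fitted excursion peak is below twice the residual
RMS, which is the expected outcome for non-clustered (CSR-like)
patterns. Whether to fit g or g − 1 is a convention; the baseline-1
choice is this package's documented decision.

## What the synthetic fixtures do and do not show

The generators emulate the *structure* of the experimental inputs —
shared-parent Thomas clusters for adhesive interfaces (cross-type
clustering at the cluster scale σ), CSR for non-adhesive controls,
noisy Hill profiles, Voronoi/lattice/glyph targets, two-colony layouts
at 9-mm spacing — under ideal conditions: no segmentation error, no
illumination gradients, no biological replicate variance, perfectly
straight target edges. Passing tests therefore demonstrate correctness
of the algorithms and estimators on clean data, and directional effects
(clustered > CSR variance; adhesive sharper than non-adhesive), but not
quantitative agreement with any particular microscope's numbers;
confocal-derived magnitudes (EMG variances of a few µm²) depend on the
imaging data and are deliberately not asserted.

## Known limitations

- The continuum model is mean-field: no discrete cell runs, no cluster
  micro-structure, no mechanical jamming, no nutrient field, no 3-D
  layer structure. The adhesive interface it produces is sharper than
  measured ones (see above).
- The mapping from inhibitor concentration or induction level to K is
  not modelled; K is the knob.
- The front-arrival predictor is first-arrival only: no refraction or
  post-contact front interaction; curved interfaces arise only through
  delays and speed ratios.
- GIVP output is not seed-count-optimal, and curved target edges are out
  of scope (straight-edge patterns only).
- The four-colouring is exact backtracking: desk-scale maps (hundreds of
  faces) solve in milliseconds, but the step cap may trigger on large
  adversarial non-planar graphs.
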