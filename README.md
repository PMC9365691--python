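# swarmpat

Engineering multicellular interface patterns with a 4-bit synthetic
cell–cell adhesion logic.

Swarming *E. coli* strains displaying heterophilic synthetic adhesins —
nanobody/antigen pairs Nb2·Ag2 and Nb3·Ag3 — form a macroscopically
visible, low-mobility interface wherever two expanding colonies carrying
*cross-complementary* adhesins meet. The set of adhesins seeded at one
position (an **element**) can be the null element (no adhesin), one of
four **singlets**, or one of four non-self-interacting **doublets**; with
four adhesins (4 bits) there are 16 elements, 9 of practical use. On the
doublet subset, a visible interface forms **iff the two elements differ**,
which turns interface patterning into a map-colouring problem: since
equal-speed swarm fronts meet on the Voronoi tessellation of their seed
points, the four-colour theorem guarantees that four doublets suffice to
realize *any* planar tessellation, and the null element isolates the ends
of open interfaces.

The package provides:

- **`swarmpat.adhesion`** — the combinatorial adhesin calculus
  (complementarity, element census, visible/hidden interface predicate).
- **`swarmpat.pde`** — a continuum reaction–diffusion–adhesion model: per
  strain *i*, a free density ρᵢ and an immobilized bound density bᵢ with

  ∂ρᵢ/∂t = Dᵢ∇²ρᵢ + gᵢρᵢ(1 − ρ_T/ρ_max) − ρᵢ Σ_{j∼i} K(ρⱼ + bⱼ),
  ∂bᵢ/∂t = ρᵢ Σ_{j∼i} K(ρⱼ + bⱼ),

  with irreversible adhesion of strength *K*, no-flux boundaries, and the
  fitted parameters D = 47 µm² s⁻¹, g = 14 h⁻¹, K = 130 h⁻¹. Isolated
  colonies expand as Fisher–KPP pulled fronts at speed 2√(gD).
- **`swarmpat.fronts`** — the fast geometric predictor: territories by
  first front arrival (delay + distance/speed), giving exact Voronoi
  diagrams, hyperbolae (delays), Apollonius circles (speed ratios) and
  point–line parabolae, with visible/hidden flags from the adhesion logic.
- **`swarmpat.design`** — inverse design: regular tilings, hidden-edge
  contraction + exact DSATUR four-colouring, a generalized inverse
  Voronoi construction (mirrored seed pairs), null-element isolation of
  open interface ends, a triangular-lattice-constrained solver and a
  16-segment display generator.
- **`swarmpat.stats`** — the quantification statistics: the
  Hill+Gaussian profile model f(x) = z/(1+(k_a/x)ⁿ) + y + a·e^(−x²/b),
  the interface width w as the distance between the two maxima of the
  curvature κ = |f″|/(1+f′²)^{3/2}, the multicomponent pair-correlation
  function g(r) with exact circle–rectangle edge correction, and the
  exponentially modified Gaussian (EMG) clustering-width summary
  σ² + 1/λ².
- **`swarmpat.fixtures`** / **`swarmpat.cli`** — deterministic synthetic
  fixtures (Voronoi/lattice/glyph patterns, Thomas and CSR point
  patterns, noisy profiles) and a `swarmpat` command line
  (`simulate`, `predict`, `design`, `analyze`, `fixtures`).

## Worked example

```python
import numpy as np
from swarmpat import adhesion, design, fixtures, pde, stats

census = adhesion.enumerate_elements(adhesion.default_library())
print(f"elements: {len(census.all)} total, {len(census.practical)} practical "
      f"({len(census.singlets)} singlets, {len(census.doublets)} doublets)")

x, intensity, _ = pde.interface_assay(K=130.0)
fit = stats.fit_profile(x, intensity)
print(f"adhesive interface width: {fit.w * 1000:.0f} um (Hill n = {fit.n:.0f})")

x, intensity, _ = pde.interface_assay(K=0.0)
print(f"non-adhesive control width: {stats.fit_profile(x, intensity).w * 1000:.0f} um")

tess, _ = fixtures.random_voronoi_tessellation(50, seed=1)
cmap = design.colour_tiles(tess)
print(f"50-tile Voronoi pattern coloured with "
      f"{len({str(e) for e in cmap.values()})} doublet elements")

pat = design.segment_display_pattern("U")
sol = design.solve_pattern(pat)
v = design.verify_design(sol, pat)
print(f"'U' glyph: {len(sol.seeds)} seeds, "
      f"{v['coverage']:.0%} of the target interface reproduced, "
      f"{v['spurious']:.1%} spurious")
```

prints

```
elements: 16 total, 9 practical (4 singlets, 4 doublets)
adhesive interface width: 282 um (Hill n = 64)
non-adhesive control width: 1358 um
50-tile Voronoi pattern coloured with 4 doublet elements
'U' glyph: 192 seeds, 100% of the target interface reproduced, 0.3% spurious
```

The two widths come from the standard interface assay: complementary
(resp. non-interacting) colonies seeded 9 mm apart, integrated through
2.5 h of active swarming, one strain's normalized free+bound profile read
along a 6-mm line through the seeds, fitted with the Hill+Gaussian model,
and the width taken between the two curvature maxima. Adhesion sharpens
the transition several-fold and produces the characteristic total-density
peak at the interface with troughs on either side; without adhesins the
two strains interpenetrate into a gradual transition. The glyph example
runs the full inverse-design pipeline and then *checks itself* by
predicting the resulting interfaces with the front-arrival model.

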