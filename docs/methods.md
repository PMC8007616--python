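# Methods

## The model

The spine plasma membrane is a closed, oriented triangle mesh with vertex
positions `x_k` (um). Vertices follow the overdamped gradient flow

    dx_k/dt = zeta * ( F_mem(x_k) + F_actin(x_k) )

with mobility `zeta` (um^2 s^-1 pN^-1). `F_mem = -dE_mem/dx_k` is the exact
analytic gradient of the discrete membrane energy

    E_mem = P*V + sigma*A + 2*kappa * sum_v (c1+c2)_v^2 A_v ,

the sum of a pressure-volume penalty, a surface-tension area penalty, and a
Helfrich bending term written with the total curvature `c1+c2`. With
positive `P` and `sigma`, the free surface shrinks until bending and the
fixed boundary sets stop it; the resting spine is the constrained minimizer
of `E_mem`.

A note on the bending convention, because it is decisive. Writing the
bending term with the *mean* curvature `(c1+c2)/2` instead (an energy four
times softer, `8*pi*kappa` on a sphere rather than `32*pi*kappa`) leaves
the constrained problem without a minimum anywhere near spine scale: the
membrane necks down to a tube of radius ~`sqrt(kappa/2 sigma)` ~ 0.08 um
and the "resting shape" becomes whatever transient one stops at. With the
total-curvature convention the minimum exists and sits at a resting volume
of ~0.078 um^3 for the default geometry — the scale a mushroom spine head
should have with these parameters. The package therefore uses the
total-curvature form everywhere (energy, force, reported bending term).

The actin polymerization force emanates from discrete foci `f_i` (the
nucleation sites of fast-treadmilling F-actin patches near the membrane):

    F_actin(f_i, x_k) = alpha * phi(n_f) / d(f_i, x_k) * unit(x_k - f_i) ,
    phi(n_f) = n_fil / (n_vertices0 * n_f) .

The `1/d` decay models G-actin depletion as the membrane moves away from a
focus; `phi` divides a fixed filament budget (`n_fil`) among foci and mesh
vertices, which makes the *total* applied force independent of both the
mesh resolution and the focus count. Below `d_min = delta_s/2` the
magnitude is clamped at its `d_min` value (the printed force law has an
unaddressed 1/d singularity).

## Discretization

* Integral quantities: divergence-theorem volume, summed triangle areas.
* Curvature: cotangent mean-curvature vector with Meyer mixed Voronoi
  areas and the standard obtuse-triangle fallback (obtuse corner takes
  half the triangle area, the others a quarter).
* Gradients: all three energy terms are differentiated analytically
  (hand-written reverse mode through the cotangents and mixed areas).
  Finite differences are used only as a test oracle (relative error
  < 1e-4; in practice ~1e-9). A fused numba kernel reproduces the numpy
  reference to machine precision and provides the production path.
* Constraints: the PSD disc (the spherical cap above `h_PSD`, projected to
  that plane) and the neck cap (below `h_neck`) are fixed; their vertices
  are excluded from the dynamics and protected from remeshing. On the
  initial sphere the cap boundaries coincide with the tabulated PSD and
  neck radii.

## Time stepping and remeshing

One reported step is `dt = 1/8 s` of classical RK4, internally divided
into `n_substeps = 6` equal RK4 substeps: the bending term makes the
semi-discrete system stiff at `delta_s = 0.03` um, and 6 is the smallest
substep count for which the energy decreases monotonically in the
constrained-sphere test (4 is visibly unstable). Substepping changes only
the integration accuracy, not the model.

After each reported step the mesh is re-isotropized (3 iterations of the
incremental split / collapse / flip / tangential-relax loop with edge
bounds 4/5 and 4/3 of `delta_s`). Tangential relaxation moves free
vertices toward their neighbour centroid restricted to the tangent plane,
so shape (volume) drift per call stays below 0.5% (fixtures measure
~1e-4). Collapses obey the manifold link condition; protected vertices are
never moved or removed. Lagrangian tension probes rebind to the nearest
surviving vertex after every call.

## Resting shape

From the constrained icosphere the energy is minimized by a FIRE
quasi-dynamic descent (remeshing interleaved), run in 2000-iteration
chunks until the enclosed volume changes by < 5e-5 um^3 per chunk, then
settled for 50 steps of the production dynamics. The sharp PSD-rim crease
keeps a residual per-step flutter of ~2-6e-4 um (1-2% of an edge length)
that does not decay even at twice the stability-mandated substep count —
it is genuine slow dynamics of the discrete crease, not integrator error —
so "stationary" here means: at the volume plateau, with that flutter as
the quoted convergence level. Typical outcome with default parameters:
~1175 vertices (recorded as `n_vertices0`), volume ~0.078 um^3 after the
settle phase, area ~1.0 um^2.

## Tension probes

The tracking points are the vertices of a coarse isotropic mesh built once
on the resting shape at edge length `2*delta_s`; each rides on its nearest
fine-mesh vertex. The tension force at probe j is the sigma-weighted area
gradient of that coarse mesh, `-d(sigma*A_track)/dx_j`, and its norm is
the reported scalar. Summed over probes this approximates
`sigma * int 2|H| dA`, which is resolution-independent; reading the
gradient on the fine mesh instead would shrink all values by ~4x and is
not what a probe at 2*delta_s spacing measures.

## Scenarios

* **LTP expansion**: resting shape plus one near-PSD focus (a resting
  vertex nearest the PSD rim, scaled by 0.99 toward the origin) or `n_f`
  evenly spread foci (farthest-point selection on a coarsened copy of the
  0.99-scaled resting shape, restricted to the head). `t*` is the first
  time the tension norm of the max-tension-at-v* probe (determined
  self-consistently) reaches 2.5x its resting baseline; `v*` is the volume
  then. The probe-nearest-the-focus reading is also exposed, but the
  near-PSD focus sits at the PSD rim whose adjacent probe has a
  crease-inflated baseline, making that reading degenerate here.
* **Expanded shape**: the single-focus run continued until the volume
  reaches 2.7x resting (cap 240 s), actin then switched off. The factor
  follows from the published stabilization arithmetic (final volume and
  percent reduction imply the start), not from a fitted time.
* **Omega profile**: at the max-tension free probe, the nearest vertex is
  driven one bulb diameter (default 0.125 um) toward the spine centre and
  its 1-2-ring is arranged on the bulb sphere, leaving a pore of diameter
  `delta_s`; two protected remesh+project rounds refine the bulb; the
  region is then released. The construction removes approximately the bulb
  volume. The depth metric is the maximal inward excursion near the bulb
  axis relative to the median of a surrounding annulus, measured inside a
  ball around the apex. Without actin the profile heals quickly (within a
  few seconds — once its features fall below mesh scale, isotropic
  remeshing absorbs them), comfortably inside the published 30-s bound;
  with a tip focus the membrane area recovers above its starting value
  while the spine grows, and an adjacent focus gives smaller growth.
* **Stabilization**: per step the PSD capture radius grows by
  `delta_psd * dt` and every free vertex inside it with
  `|z - h_PSD| <= 0.001` um is snapped to `h_PSD` and fixed permanently;
  the PSD area is the summed area of triangles whose three vertices are
  captured. At this package's fidelity the relaxed membrane approaches the
  PSD plane from below with a gap of a few nanometres that only grows
  during relaxation, so the 1-nm capture slab collects nothing and the
  rule is inert (the tolerance is exposed as
  `ModelParams.psd_capture_tol`; larger values activate the mechanism and
  make the PSD grow asymmetrically toward the bulge, at the price of
  departing from the printed value).

## What the defaults represent

All physical defaults are the reference parameter set of the study this
model family comes from: `P=75 pN/um^2`, `sigma=15 pN/um`,
`kappa=0.18 pN um`, `alpha=3.8 pN`, `zeta=0.004`, `n_fil=70`,
`delta_s=0.03 um`, `dt=1/8 s`, sphere radius 0.4 um, neck radius
0.0796 um at height -0.392 um, PSD radius 0.1744 um at height 0.36 um,
`delta_PSD = delta_s/60 um/s`. There is no randomness anywhere in the core
dynamics; runs are bit-reproducible. The only randomized option
(`random_head` foci placement for robustness sweeps) takes an explicit
seed.

## Known quantitative deviations

Checked against the published single-focus study (tolerances 15% relative,
0.25 absolute skewness, 10 points on percentages):

* The probe-tension scale runs ~0.5x the published values (totals ~115 pN
  at rest vs 210.7). The smooth-surface part of the sum is
  discretization-independent; the shortfall is rougher discrete curvature
  at probe scale in the original implementation (a different remesher).
  Fractions below 0.6 pN are correspondingly high here.
* The 2.5-fold tension crossing arrives early (t* = 42 s vs 89.5 s, with
  v* = 0.113 vs 0.197 um^3): the lower, smoother baseline makes the
  fold criterion easier to reach, so the leading probe crosses well
  before the published time and volume.
* The skewness of the probe-tension distribution at the crossing is 0.79
  vs the published 1.08 (just outside the 0.25 band); the multi-foci
  skewness values land inside it, but the strict decreasing ordering and
  the near-PSD vs middle/neck total orderings do not hold at the earlier
  crossing (the published near-PSD vs near-neck margin is itself
  sub-percent).
* The stabilization capture rule collects nothing at the printed 1-nm
  tolerance (see above), so the PSD-area increase reads 0 and stabilized
  and unstabilized relaxation coincide; both 7-minute volume-reduction
  percentages still land near the published ones (~57-59% vs 60.56 /
  52.99).

None of these were compensated by parameter changes; the printed parameter
set is used as-is.

## Problem sizes

Default runs use the ~2,500-vertex icosphere (which coarsens to ~1,180
vertices on the resting shape at `delta_s`), ~380 tension probes, 1,300
steps for a full LTP expansion and 3,360 steps per 7-minute relaxation.

## Limitations

Self-intersection is not detected; the continuous actin force has no
filament-level dynamics (no treadmilling, branching, severing, capping);
no lipid dynamics, spontaneous curvature, or area-difference elasticity;
no receptor trafficking. The omega-profile pore geometry is one concrete
realization of an under-specified construction and its healing time is
mesh-maintenance dominated.
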