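# Methods

## Model overview

`densecon` estimates synaptic connectivity in a brain region from
structural overlap, under three assumptions:

1. **Registration precision sets the resolution.**  All fields are
   voxelized at the inter-animal variability of the reference frame
   (50 µm by default).  Below that scale positions are meaningless, so
   bouton/target proximity within a voxel carries no information.
2. **Independent, uniform synapse formation within a voxel.**  Every
   postsynaptic target site (PST) in a voxel is equally likely to receive
   any bouton in that voxel, and voxels are independent.  This yields the
   capture probability p_j = PST_j / PST_all, the per-voxel law
   Binomial(B_i, p_j), and — because B_i is O(10–100) while p_j is
   O(10⁻³) in dense tissue — its Poisson limit with rate
   Ĩ_ij = B_i · p_j.
3. **The average model is representative.**  Somata are placed from
   measured density fields; each is dressed with a reconstruction of its
   assigned type registered to the same column and within one voxel of
   the same depth, so location-specific morphology is preserved at grid
   resolution.

The pair connection probability is p_ij = 1 − exp(−I_ij) with
I_ij = Σ_x Ĩ_ij(x); the per-voxel product of zero-synapse probabilities
equals the exponential of the summed innervation identically, and the
suite asserts the two forms agree to 1e−12.

## Coordinate and partition conventions

Coordinates are micrometers, right-handed, with depth increasing along
each column's unit axis from the pia.  Voxel and laminar-zone intervals
are half-open, so in-bounds space is partitioned without double counting;
a point on a zone boundary belongs to the deeper zone.  Curved pia/white
matter surfaces are abstracted as per-column depth intervals along the
local axis — a height-field view that preserves every quantity the
innervation equations consume (depth, laminar zone) without mesh
geometry.  Equidistant column ties resolve to the smallest column id.

The local vertical axis at a point is the inverse-distance-weighted mean
of the k nearest column axes (k = 3 by default, configurable), normalized
to unit length; a point on a column axis returns that axis exactly.  The
interpolation kernel is a design choice — only "interpolate from the
nearest column axes" is anatomically constrained.

## Morphologies

SWC v1 is the on-disk format (codes 1/2/3/4 → soma/axon/basal/apical);
the reader rejects unknown codes, negative radii, orphan parents and
cyclic links, naming the offending line.  Lengths sum Euclidean
parent–child segments by the child's label.  Surface areas use the
frustum lateral area π·(r_parent + r_child)·length per segment, i.e.,
trapezoidal integration of the diameter; a single-node soma is scored as
a sphere (4πr²) and its area is assigned to the voxel containing the
node, while multi-node somata are clipped like branches.  The soma
position is the unweighted centroid of soma nodes — deterministic and
translation-equivariant.

Segment-to-voxel clipping is exact: each segment is split at its
axis-aligned face crossings by parametric intersection, with radii
linearly interpolated at the split points.  A dense-resampling oracle is
kept in the tests only.  Pieces leaving the grid are dropped with a
logged warning (long axons legitimately exit the modeled volume).

## Assembly

Per voxel, the soma count is density × voxel volume rounded half-up
(the rounding convention is not otherwise constrained; half-up is
documented here and fixed), positions uniform within the voxel.  Cell
types are drawn from the (column, inside/septum) frequency table,
restricted to the soma's excitatory class and the type's occupancy flag.

Dendrite selection filters the library by type, column, and registered
depth within one grid spacing, then picks uniformly.  The chosen
reconstruction is translated to the soma and rotated about the local
vertical axis: by a uniform random azimuth for ordinary types (the
maximal-entropy choice consistent with preserving vertical orientation),
or, for polar types, by the angle aligning the reconstruction's
soma-to-column-center bearing with the new soma's bearing, so projections
toward the column center are retained.

Axon selection applies only the type and column criteria — deliberately
no depth criterion — and axons are **never** transformed: moving them
would destroy location-specific projection patterns (e.g., axons confined
to their home column would start innervating septa).  Long-range types
(somata outside the region) are up-scaled by duplicating the registered
axons round-robin over a seed-shuffled order until the prescribed
per-column count is met; round-robin keeps per-morphology multiplicities
within one of each other, and an independent-uniform mode exists for
comparison.

Randomness fans out from one seed into child streams keyed by (stage,
neuron id), so results are independent of iteration order and exactly
reproducible.

## Surface-PST fitting

Spine (length) densities λ are measurable; surface densities α are fitted
from the balance requirement that total boutons match total PSTs.  Both
sides are collapsed to depth profiles per presynaptic excitatory class
and the nonnegative least-squares problem is solved for α tied by
(pre class, post cell type, label).  A 1D profile cannot identify a full
pre-type × post-type × label tensor, hence the tying; it requires λ to
agree across pre types within a class (checked, with a clear error
otherwise), and collinear area profiles raise a rank error naming the
groups.  Nonnegativity reflects that α is a physical count per area.

## Statistics

Autapse entries (i = j) are computed but excluded from all ensemble
averages by default (flag-reversible); the underlying model is silent on
self-innervation.  The population synapse-count law n_AB is the
elementwise mean of the per-pair Poisson mass functions, evaluated to the
largest per-pair 1 − 1e−9 quantile, so its mean equals ⟨I_ab⟩ exactly.
The reported "synapses per connection" range is the 99 % cumulative range
of n_AB conditioned on n > 0.  Convergence SDs are across postsynaptic
neurons.

Motif classes are found by exhaustive S₃ orbit enumeration of the 64
edge configurations (no graph library: six permutations, exact).  The
canonical numbering sorts by connected-pair count descending, then by
smallest representative; published pictogram orderings are graphical and
a mapping to them is not guaranteed.  Population spectra sample triplets
by rejection under the constraint that no two triplets share more than
one neuron (equivalently, no reused neuron pair), with a feasibility
bound n(n−1)/6 reported on infeasible requests; means and SDs are taken
across repeats.  The uniform null sets all six edge probabilities to the
population mean; since the null is deterministic, z-scores use the
across-repeat SD of the observed spectrum.

## Synthetic data

The fixture generator emulates the seven input kinds at toy scale:
parallel cylindrical columns in a row, three laminar zones, uniform
in-column soma densities of 8·10³ mm⁻³ (one soma per 50 µm voxel, with
thinned deterministic patterns in septa and for inhibitory cells),
parametric-random labeled tree morphologies with linear taper and
optional polar bias, spine densities of ~1 µm⁻¹, surface densities of
~0.3–0.4 µm⁻², and bouton densities of ~0.1–0.35 µm⁻¹ — magnitudes
typical of cortical neuropil.  Default problem sizes (a few hundred
neurons, 8×8×4–8 grids) keep the full pipeline in seconds; these are the
package's chosen test scales, stated here so results are interpretable.

What the generator does **not** emulate: realistic branching statistics,
layer-specific dendrite targeting, realistic cell-type proportions, or
the ~10⁵-fold larger competing target pool of real tissue.  Passing tests
therefore demonstrate correctness of the geometry, bookkeeping and
probability calculus — not anatomical realism; toy-scale connection
probabilities are much higher than in full-scale models because few
neurons compete per voxel.

The ground-truth path places ≤ 10 neurons directly (identity transforms)
and recomputes every output with dense brute force: Liang–Barsky slab
clipping per segment–voxel pair, dense array field arithmetic, explicit
64-term motif products.  The oracle shares only I/O containers with the
production path.  For fit validation the generator constructs bouton
depth profiles that exactly balance the PSTs under known α\*, giving an
exact recovery target through the production collapsing and solving code.

## Numerical choices and limitations

- Sub-segment intervals shorter than 1e−12 of a segment are merged to
  avoid zero-length slivers; voxel assignment of a piece uses its
  midpoint.
- PST_j is validated against PST_all per voxel (relative tolerance
  1e−9); no floor is applied to PST_all, so a lone neuron in an edge
  voxel legitimately has p_j = 1.
- Poisson is the default synapse-count law; an exact-binomial mode is
  retained for validating the approximation.
- The fit, and hence α, inherits the identifiability of the depth
  profiles; strongly correlated area profiles (e.g., apical vs basal of
  a single deep type) cannot be separated by design.
- Innervation below voxel resolution, synapse placement on specific
  branches, and motifs of order ≥ 4 are out of scope.
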