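# Methods

This note documents the models, conventions and numerical choices behind
`atlasdai`, and what its synthetic fixtures do and do not demonstrate.

## Spatial reference systems

An SRS is described by a code (`INCF:NNNN` for community-registered spaces,
`LOCAL:NNNN` for user-derived ones — a separate namespace because this
library has no central code-issuing authority), a unique name, family,
version, species, free-text origin description, exactly three axes, a region
of validity, and provenance (author, `derived_from`).

Axis orientations use a controlled vocabulary of six anatomical direction
terms (`left-to-right`, `posterior-to-anterior`, `dorsal-to-ventral` and
their reverses; arrow-style spellings are normalized on input). Each term
maps to a signed unit vector in a canonical interior frame
(left-to-right = +x, posterior-to-anterior = +y, ventral-to-dorsal = +z);
the three axes of one SRS must be mutually orthogonal in that frame. The
free-text marker `complex` accommodates curved or derived axes (developing
brain): such SRSs are storable and listable, but any transformation fitting
over them is refused with an explicit error, since a straight-axis fit
would silently misrepresent them.

Units are restricted to `mm`, `um` and `voxel`; a voxel axis must declare
its physical pitch (`voxel_size_mm`) so voxel-space SRSs remain usable in
cross-SRS work. Registries persist authoritatively as WaxML, with JSON and
CSV convenience dumps; all round-trips are exact (string fields verbatim,
floats via shortest round-trip decimals).

The seven-SRS mouse fixture reproduces the published registry rows (codes,
names, families, versions, species, prose descriptions). Numeric origins
and extents for those atlases are not published in tabular form, so the
fixture's extents (0–10 mm boxes; −5 to 5 mm for the stereotaxic space) and
its inter-atlas affines are synthetic placeholders, clearly non-anatomical,
deterministic for a fixed seed. Conclusions from tests on this fixture
concern infrastructure behavior (resolution, routing, round-trips), not
real anatomy.

## Transformations

**Affine.** Homogeneous matrices, `(dim+1)²`, last row pinned to
`(0,…,0,1)`. Fitting is linear least squares on `dim+1` or more pairs; the
source configuration must be affinely independent (checked by the rank of
the homogeneous design matrix). The fit is exact to round-off when the
pairs are consistent with one affine map.

**Thin-plate spline.** Kernel `U(r) = r² ln r` in 2D with `U(0)=0` and
`U(r) = −r` in 3D — standard polyharmonic choices; the published method
names thin-plate splines without fixing a kernel normalization, so these
are documented conventions of this package. The interpolation system

```
| K + λI  P | |W|   |Y|
| Pᵀ      0 | |A| = |0|
```

with `P = [1, x]` enforces the side conditions `Σw = 0` and `Σw·p = 0` per
output dimension, removing the kernel's affine null space; they are
verified to 1e-9 after every fit. `λ = 0` (the default) interpolates every
landmark exactly; `λ > 0` trades fidelity for smoothness via the kernel
diagonal. Duplicate source landmarks make the system singular and are
rejected up front.

**Inversion.** Affine inverses are exact matrix inverses. A TPS inverse is
a new TPS fitted on swapped (target, source) pairs and tagged
`approximate` — root-finding per point would be exact but orders of
magnitude slower and stateless; the refit gives a reusable closed-form
object whose error is *measured* rather than hidden: `inverse_consistency`
draws `n` uniform points (default `n=1000`, `seed=0`, region = the source
extents) and reports mean/max/RMS of the round-trip error in target units.
These statistics ride along on transformation records and service
responses.

**Out-of-extent inputs** transform with a per-point `out_of_validity` flag
instead of an error: refusing would break near-boundary queries, and the
flag preserves the information for the caller. Coordinates are double
precision throughout; comparisons use absolute tolerance 1e-9 unless a
statement says otherwise.

**Planar lifts.** 2D in-plane transforms from slice registration embed into
the 3D graph as `(x, y, z) ↦ (T(x, y), z·s + c)`, keeping per-slice
registrations usable for 3D POI routing. This is a design choice of this
package: per-slice plate mappings are otherwise stored row-by-row in the
Slice table.

## Chain resolution

The transformation registry is a directed multigraph over SRS codes.
Forward and inverse are independent edges; the resolver never auto-inverts
an edge whose inverse was not registered (an unregistered inverse may not
exist or may be unvalidated). Optimality is fewest steps, because every
step accumulates registration error. Ties are broken deterministically:
paths whose interior visits a WHS-family SRS win first (WHS is the
designated go-between), then the highest interior WHS version, then the
lexicographically smallest sequence of transformation codes. Among parallel
edges for one SRS pair, the highest version string wins, then the smallest
code. The resolver is therefore a pure function of the graph contents,
independent of insertion order — property-tested against an exhaustive
breadth-first-search oracle on seeded random multigraphs.

Error-weighted (consistency-weighted) routing is deliberately out of scope;
the consistency metadata needed for it is already attached to each edge.

## WaxML

The dialect preserves the published structure — GML 3.2.1-style
Point/MultiPoint with a mandatory `srsName` attribute (simple-features
profile), per-kind response documents for SRS descriptions, transformation
lists, chain responses (TransformPOI request templates with blank
coordinate slots and order indices), capabilities, process descriptions,
structure/image responses and exception reports — without claiming byte
compatibility with the original schema files, which are no longer
retrievable. Element and attribute names are this package's documented
choices. One project namespace (`urn:waxml:1.0`) plus the standard GML
namespace. Encoding is deterministic: fixed element/attribute order and
shortest round-trip decimal float formatting, so equal payloads produce
byte-identical documents and `decode ∘ encode` is the identity on every
document kind. `srsName` accepts either a registry code or a name; the
service layer emits names, and decoders resolve both.

## Atlas hubs

Hubs are in-process objects — the contract is the request/response
semantics, not the transport; a thin HTTP layer could map URLs onto
`parse_wps_request` verbatim. The WPS dialect: case-insensitive keys,
`DataInputs` as `;`-separated `key=value` pairs, coordinates as decimal
strings. The asynchronous WPS clauses (`storeExecuteResponse`, `status`,
`lineage`) are parsed and explicitly rejected as unsupported. Service-level
failures are returned as structured ExceptionReport documents, never raised
across the front door.

A hub's offered process list derives from its configuration (transformation
hosting, label volumes, image/annotation stores), so capabilities,
describability and executability are consistent by construction — asserted
as an invariant in tests. Structure lookup uses a nearest-voxel containment
test with an optional vicinity radius (default 0 = exact voxel, overridable
per request) measured in world units. Image/annotation queries intersect
the ball of the given radius with stored extent boxes; radius 0 means
containment; results are title-sorted for determinism.

The central mediator harvests hub transformations into one graph and
rewrites queries per hub, transforming the POI into each hub's SRS
automatically. `GetObjectsByPOI` is implemented as a live fan-out (each
offered POI method is actually invoked and only non-empty responders are
listed) rather than a precomputed index: on federation scales of a handful
of hubs, correctness-by-invocation beats cache invalidation complexity.
Federated queries degrade gracefully: a failing hub contributes a warning
entry, not a query failure.

## Registration workflow

Image coordinates are pixel centers, origin at the top-left pixel, x
rightward (columns), y downward (rows), 0-based; plate coordinates are in
the plate SRS's units. Tie-points are supplied as files — the workflow is
fully scriptable, with no interactive alignment GUI — and the affine stage
uses only the tie-points. The two stages: least-squares affine over all
pairs, then a TPS fitted on the affine-mapped image points so the composite
interpolates every tie-point exactly at `λ = 0`. The registered inverse is
the swapped-refit TPS inverse composed with the exact affine inverse;
inverse-consistency statistics are computed over the tie-point bounding box
with a seeded sample and stored on the result.

Warping resamples by inverse mapping with bilinear interpolation and a
configurable constant background fill (default 0) — the published pipeline
does not state its warping engine's interpolation order or boundary policy,
so this is a documented convention. Bilinear inverse mapping makes
integer-pixel translations exact array shifts (histogram-conserving on the
interior), a property the tests pin down.

`derive_srs` publishes a collection as a `LOCAL:` SRS named after the
collection: X/Y extents are the union of the slices' tie-point extents in
pixels (voxel units with the declared pixel pitch), Z is the slice index.
Per-slice affine placements go into the Slice table; one representative
forward/inverse pair (the first slice's composite, lifted to 3D) is
registered in the chain graph so the new SRS is immediately chain-reachable.
Re-invocation with additional registered slices updates the extents and
Slice rows in place under the same code.

## Synthetic fixtures

Phantom atlases are pairwise-disjoint ellipsoids (disjointness guaranteed
by bounding-box rejection sampling) in a label volume indexed `[x, y, z]`
with world = voxel coordinates, so structure membership has a closed-form
point-in-ellipsoid oracle fully independent of the voxel data. Intensity
plates add Gaussian-smoothed structure contrast over a linear gradient so
registration has texture to work with. Default problem sizes — volumes of
24³–48³ voxels, 2–3 structures, 25–36 tie-points, warps of ~2.5 px peak
displacement on 48-pixel plates, 100–500-case randomized suites — are small
enough to regenerate everything at test time while leaving each property
several orders of magnitude of headroom at its stated tolerance.

Known warps come in two families: seeded near-identity affines, and
sinusoidal displacement fields sampled at a control grid and interpolated
by TPS, so the true transform maps each returned tie-point exactly and
magnitude 0 degenerates to the identity. All generators are pure functions
of their parameters including the seed.

What passing tests do *not* show: phantoms are noise-free, high-contrast
and smoothly warped, so registration accuracy here is an upper bound —
real histology brings staining variability, tears and tie-point placement
error; the registry fixture's geometry is invented, so numeric
transformation outputs on it have no anatomical meaning; and the in-process
hubs exercise the service semantics, not network transport, authentication
or live third-party atlas APIs.

## Known limitations

- TPS inversion is approximate by design; strongly folded warps (Jacobian
  sign changes) are not detected beyond the consistency score.
- `derive_srs` registers one representative 3D transform per collection;
  per-slice variation is preserved in the Slice table but not yet consulted
  during chain execution.
- No diffeomorphic volume registration, error-weighted routing, catalog
  harvesting, storage backends or gene-expression encodings — these sit
  outside the infrastructure core this package implements.
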