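# atlasdai

A digital atlasing infrastructure for rodent brain data: a registry of brain
**spatial reference systems** (SRSs), **coordinate transformations** between
them (affine and thin-plate-spline, with inverse-consistency scoring and
graph-based chain resolution), the **WaxML** XML dialect for exchanging atlas
information, **WPS-style atlas hub services** with a federating central
mediator, and a scriptable **2D slice-to-atlas registration workflow** —
all exercisable offline on synthetic phantom atlases.

## Who this is for

Neuroinformatics developers and researchers who need to move coordinates and
point-of-interest (POI) queries between independently developed mouse brain
atlases — e.g. "what structure sits at this point, according to each atlas?"
or "which image collections cover this location?" — and to bring their own
2D image collections into a shared spatial framework.

## The model

**Spatial reference systems.** Borrowing from geodesy (EPSG-style
registries), every brain coordinate system is registered with a code
(`INCF:0001`), a unique name (`Mouse_WHS_0.9`), three oriented axes with
controlled anatomical direction terms, units, valid extents, and a region of
validity. No single space is mandated; the Waxholm Space (WHS) serves as the
common *go-between*, like WGS84 in geodesy.

**Transformations and chains.** Registered transformations form a directed
multigraph over SRSs (forward and inverse mappings are independent edges).
Affine maps are fit by least squares from landmark pairs. Non-rigid mappings
use the thin-plate spline

$$ f(x) = A\,[1, x]^T + \sum_i w_i\, U(\lVert x - p_i \rVert), $$

with kernel $U(r) = r^2 \log r$ in 2D and $U(r) = -r$ in 3D, under the side
conditions $\sum_i w_i = 0$ and $\sum_i w_i p_i = 0$ per output dimension.
At zero regularization the spline interpolates every landmark exactly. A
TPS inverse is refit on swapped pairs; its quality is quantified by
**inverse consistency**, the distribution of $\lVert T^{-1}(T(p)) - p
\rVert$ over a seeded uniform sample, and attached to transformation
records. Chains between SRSs lacking a direct mapping are resolved with
fewest steps (each step accumulates mapping error), tie-broken toward WHS
intermediates.

**Services.** Hubs publish their SRSs, transformations and POI queries
behind self-describing WPS-style requests (GetCapabilities, DescribeProcess,
Execute with `key=value;...` DataInputs). The central mediator resolves
chains across hubs (GetTransformationChain), discovers which (hub, method)
pairs would answer non-empty at a POI (GetObjectsByPOI), and unions per-hub
responses with provenance. Responses are WaxML: GML Point/MultiPoint
geometry with a mandatory `srsName`, plus per-kind response documents.

**Registration workflow.** A manifest records an uploaded image collection
(checksums, thumbnails, provenance). Each slice is aligned to its atlas
plate from user tie-points by a least-squares affine stage followed by a TPS
correction, warped by inverse-mapping bilinear resampling, and the
collection is published as a new `LOCAL:` SRS with forward/inverse
transformations into the chain graph.

## Worked example

Resolving coordinates from the Allen gene-expression space (AGEA) to the
Paxinos & Franklin stereotaxic space — no direct mapping exists, so the
resolver routes through Waxholm Space 0.9 across two hubs
(`examples/03_chain_resolution.py`):

```
2 steps, hubs ('ABA', 'UCSD'), intermediate ('INCF:0001',)
AGEA [1. 2. 3.] -> INCF:0200 [1.80489211 2.32352346 2.57987114]
```

The two steps are served by different atlas hubs and returned as WaxML
TransformPOI request templates with the coordinates left blank; executing
them in order carries the POI from AGEA into Paxinos coordinates.

Registering a synthetically warped phantom slice back onto its plate from
true tie-point correspondences (`examples/05_registration_workflow.py`):

```
landmark residual: 7.815970093361102e-14
dense-grid RMS error: 0.0011 px (0.04% of the 2.59 px max displacement)
inverse consistency RMS: 0.0682 px
derived SRS LOCAL:0001 (UserStack); reachable from WHS in 2 steps
```

The affine+TPS composite hits every tie-point to machine precision, deviates
from the known ground-truth warp by well under 1% of its peak displacement
across the slice interior, and the derived SRS immediately participates in
federation-wide chain resolution.

The other examples cover the SRS registry (`01`), transform fitting and
consistency scoring (`02`), and federated hub queries (`04`). A thin CLI
wraps the same calls: `dai srs list`, `dai chain resolve --from ... --to
...`, `dai transform fit`, `dai waxml validate`, `dai fixtures make`.

## Layout

- `src/atlasdai/` — the library (`srs_registry`, `transforms`,
  `chain_resolver`, `waxml`, `atlas_hub`, `registration`,
  `synthetic_atlas`, `cli`)
- `examples/` — one narrative script per capability
- `tests/` — pytest suite, including the acceptance properties
- `docs/methods.md` — models, conventions, parameter choices, limitations
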