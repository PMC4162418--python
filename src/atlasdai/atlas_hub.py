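"""Atlas hubs, the central mediator, and the WPS request dialect.

An *atlas hub* publishes spatial reference systems, coordinate
transformations and point-of-interest (POI) query functions behind a
self-describing WPS-style interface (GetCapabilities / DescribeProcess /
Execute with key-value-pair encoding).  The *central hub* mediates across
registered hubs: it resolves transformation chains so a POI expressed in any
known SRS can be routed to any hub, fans POI queries out to every hub
(rewriting the coordinates per hub), and unions the responses with hub
provenance.

Hubs here are in-process objects; the contract is the request/response
semantics, not the transport.  Service-level failures are returned as
structured ExceptionReport documents by :meth:`AtlasHub.handle`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from urllib.parse import parse_qsl, unquote

import numpy as np

from . import waxml
from .chain_resolver import Chain, TransformationGraph
from .errors import (
    DAIError,
    MalformedDataInputs,
    MissingIdentifier,
    MissingService,
    NoPathFound,
    NoSegmentation,
    SRSMismatch,
    UnknownProcess,
    UnknownSRS,
    UnsupportedAsync,
)
from .objects import ObjectRecord, ProcessDescription, ProcessInput, \
    StructureHit
from .srs_registry import Registry
from .transforms import (
    ConsistencyStats,
    PointSet,
    TransformationRecord,
    apply_transform,
)

__all__ = [
    "WpsRequest", "parse_wps_request", "LabelVolume", "AtlasHub",
    "CentralHub", "FederatedResult",
]

#: POI-based query methods a hub may offer (beyond the core set)
POI_METHODS = ("GetStructureNamesByPOI", "Get2DImagesByPOI",
               "GetAnnotationsByPOI")

_ASYNC_KEYS = ("storeexecuteresponse", "status", "lineage")


# ---------------------------------------------------------------------------
# WPS request parsing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WpsRequest:
    """A parsed WPS-style key-value-pair request."""

    service: str
    version: str
    request_kind: str  # GetCapabilities | DescribeProcess | Execute
    identifier: str | None = None
    response_form: str | None = None
    data_inputs: tuple[tuple[str, str], ...] = ()
    extra: tuple[tuple[str, str], ...] = ()

    def input(self, key: str, default=None):
        for k, v in self.data_inputs:
            if k.lower() == key.lower():
                return v
        return default


_KINDS = {"getcapabilities": "GetCapabilities",
          "describeprocess": "DescribeProcess",
          "execute": "Execute"}


def parse_wps_request(query_string: str) -> WpsRequest:
    """Parse a WPS key-value-pair query string.

    Keys are case-insensitive; ``DataInputs`` is a ";"-separated list of
    ``key=value`` pairs.  Asynchronous execution clauses
    (``storeExecuteResponse``, ``status``, ``lineage``) are recognized and
    explicitly rejected as unsupported.  Unknown top-level keys are
    preserved in ``extra``.
    """
    qs = query_string.split("?", 1)[-1]
    pairs = parse_qsl(qs, keep_blank_values=True)
    by_key: dict[str, str] = {}
    extra = []
    for k, v in pairs:
        lk = k.lower()
        if lk in _ASYNC_KEYS and v.lower() in ("true", "1"):
            raise UnsupportedAsync(
                f"asynchronous WPS clause {k!r} is not supported")
        if lk in ("service", "version", "request", "identifier",
                  "responseform", "datainputs") or lk in _ASYNC_KEYS:
            by_key[lk] = v
        else:
            extra.append((k, v))
    service = by_key.get("service")
    if not service:
        raise MissingService("request lacks the mandatory Service parameter")
    if service.upper() != "WPS":
        raise MissingService(f"service token must be 'WPS', got {service!r}")
    kind_raw = by_key.get("request", "")
    kind = _KINDS.get(kind_raw.lower())
    if kind is None:
        raise MalformedDataInputs(
            f"unknown Request kind {kind_raw!r}; expected one of "
            f"{sorted(_KINDS.values())}")
    identifier = by_key.get("identifier")
    if kind in ("DescribeProcess", "Execute") and not identifier:
        raise MissingIdentifier(f"{kind} requires an Identifier")
    data_inputs = []
    raw = by_key.get("datainputs", "")
    if raw:
        for tok in raw.split(";"):
            if not tok:
                continue
            if "=" not in tok:
                raise MalformedDataInputs(
                    f"DataInputs token {tok!r} is not key=value")
            k, v = tok.split("=", 1)
            if not k:
                raise MalformedDataInputs("empty DataInputs key")
            data_inputs.append((unquote(k), unquote(v)))
    return WpsRequest(service="WPS", version=by_key.get("version", "1.0.0"),
                      request_kind=kind, identifier=identifier,
                      response_form=by_key.get("responseform"),
                      data_inputs=tuple(data_inputs), extra=tuple(extra))


# ---------------------------------------------------------------------------
# object stores
# ---------------------------------------------------------------------------

@dataclass
class LabelVolume:
    """A segmentation volume hosted by a hub, indexed ``labels[x, y, z]``.

    Coordinates are voxel units unless a ``world_from_voxel`` affine is
    given.  ``structures`` maps label value to (name, vocabulary_ref).
    """

    labels: np.ndarray
    structures: dict[int, tuple[str, str | None]]
    world_from_voxel: object | None = None

    def _to_voxel(self, point: np.ndarray) -> np.ndarray:
        if self.world_from_voxel is None:
            return point
        from .transforms import invert_transform
        return invert_transform(self.world_from_voxel)(
            point[None])[0]

    def lookup(self, point, radius: float = 0.0) -> list[StructureHit]:
        """Structures whose labelled voxels contain the point (or lie within
        ``radius`` of it, in world units); sorted by label value."""
        p = self._to_voxel(np.asarray(point, dtype=float))
        shape = self.labels.shape
        hits: set[int] = set()
        if radius <= 0:
            idx = np.round(p).astype(int)
            if np.all(idx >= 0) and np.all(idx < shape):
                lab = int(self.labels[tuple(idx)])
                if lab > 0:
                    hits.add(lab)
        else:
            r = float(radius)
            lo = np.maximum(np.floor(p - r), 0).astype(int)
            hi = np.minimum(np.ceil(p + r), np.asarray(shape) - 1).astype(int)
            for ix in range(lo[0], hi[0] + 1):
                for iy in range(lo[1], hi[1] + 1):
                    for iz in range(lo[2], hi[2] + 1):
                        if np.linalg.norm(np.array([ix, iy, iz]) - p) <= r:
                            lab = int(self.labels[ix, iy, iz])
                            if lab > 0:
                                hits.add(lab)
        out = []
        for lab in sorted(hits):
            name, vocab = self.structures.get(lab, (f"label_{lab}", None))
            out.append(StructureHit(structure_name=name, label=lab,
                                    vocabulary_ref=vocab))
        return out


# ---------------------------------------------------------------------------
# hubs
# ---------------------------------------------------------------------------

_PD_POI_INPUTS = (
    ProcessInput("srsName", "srs-name"),
    ProcessInput("x", "coordinate"),
    ProcessInput("y", "coordinate"),
    ProcessInput("z", "coordinate", required=False),
)


@dataclass
class FederatedResult:
    """Union of per-hub responses with provenance and partial failures."""

    records: list[tuple[str, object]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


class AtlasHub:
    """An in-process atlas hub: SRSs, transformations and POI stores."""

    def __init__(self, name: str, registry: Registry,
                 hosted_srs=(), central: "CentralHub | None" = None):
        self.name = name
        self.registry = registry
        self.hosted_srs = {registry.resolve_code(s) for s in hosted_srs}
        self.central = central
        self.transformations: dict[str, TransformationRecord] = {}
        self.label_volumes: dict[str, LabelVolume] = {}
        self.image_stores: dict[str, list[ObjectRecord]] = {}
        self.annotation_stores: dict[str, list[ObjectRecord]] = {}

    # -- configuration -------------------------------------------------------

    def add_transformation(self, rec: TransformationRecord) -> str:
        rec = TransformationRecord(
            code=rec.code, source_srs=rec.source_srs,
            target_srs=rec.target_srs, hub=self.name, method=rec.method,
            version=rec.version, inverse_code=rec.inverse_code,
            consistency=rec.consistency)
        self.transformations[rec.code] = rec
        self.hosted_srs |= {self.registry.resolve_code(rec.source_srs),
                            self.registry.resolve_code(rec.target_srs)}
        if self.central is not None:
            self.central.graph.add_transformation(rec)
        return rec.code

    def add_label_volume(self, srs: str, volume: LabelVolume) -> None:
        code = self.registry.resolve_code(srs)
        self.label_volumes[code] = volume
        self.hosted_srs.add(code)

    def add_image_store(self, srs: str, records) -> None:
        code = self.registry.resolve_code(srs)
        self.image_stores.setdefault(code, []).extend(records)
        self.hosted_srs.add(code)

    def add_annotation_store(self, srs: str, records) -> None:
        code = self.registry.resolve_code(srs)
        self.annotation_stores.setdefault(code, []).extend(records)
        self.hosted_srs.add(code)

    # -- capability model ----------------------------------------------------

    @property
    def processes(self) -> list[str]:
        out = ["ListSRSs", "DescribeSRS"]
        if self.transformations:
            out += ["ListTransformations", "TransformPOI"]
        if self.label_volumes:
            out.append("GetStructureNamesByPOI")
        if self.image_stores:
            out.append("Get2DImagesByPOI")
        if self.annotation_stores:
            out.append("GetAnnotationsByPOI")
        return out

    def get_capabilities(self) -> str:
        """Capabilities document: one Process entry per offered process."""
        return waxml.encode_capabilities(self.name, self.processes)

    def describe_process(self, identifier: str) -> ProcessDescription:
        if identifier not in self.processes:
            raise UnknownProcess(
                f"hub {self.name!r} does not offer {identifier!r}")
        if identifier == "ListSRSs":
            return ProcessDescription(identifier, (
                ProcessInput("species", "filter", required=False),
                ProcessInput("family", "filter", required=False)),
                output_kind="SRSDescriptionList")
        if identifier == "DescribeSRS":
            return ProcessDescription(identifier, (
                ProcessInput("srsName", "srs-name"),),
                output_kind="SRSDescription")
        if identifier == "ListTransformations":
            return ProcessDescription(identifier, (),
                                      output_kind="TransformationList")
        if identifier == "TransformPOI":
            return ProcessDescription(identifier, (
                ProcessInput("inputSrsName", "srs-name"),
                ProcessInput("outputSrsName", "srs-name"),
                ProcessInput("x", "coordinate"),
                ProcessInput("y", "coordinate"),
                ProcessInput("z", "coordinate", required=False)),
                output_kind="POI")
        if identifier == "GetTransformationChain":
            return ProcessDescription(identifier, (
                ProcessInput("inputSrsName", "srs-name"),
                ProcessInput("outputSrsName", "srs-name")),
                output_kind="ChainResponse")
        if identifier == "GetObjectsByPOI":
            return ProcessDescription(identifier, _PD_POI_INPUTS,
                                      output_kind="ObjectMethodList")
        if identifier == "GetStructureNamesByPOI":
            return ProcessDescription(identifier, _PD_POI_INPUTS + (
                ProcessInput("radius", "radius", required=False),),
                output_kind="StructureResponse")
        return ProcessDescription(identifier, _PD_POI_INPUTS + (
            ProcessInput("radius", "radius", required=False),),
            output_kind="ImageResponse")

    # -- core processes ------------------------------------------------------

    def list_srs(self, species=None, family=None):
        hosted = [self.registry.get_srs(c) for c in sorted(self.hosted_srs)]
        return [d for d in hosted
                if (species is None or d.species == species)
                and (family is None or d.srs_family == family)]

    def list_transformations(self) -> list[TransformationRecord]:
        return sorted(self.transformations.values(), key=lambda r: r.code)

    def transform_poi(self, ps: PointSet, target_srs: str
                      ) -> tuple[PointSet, list[ConsistencyStats | None]]:
        """Transform a POI (array) into the target SRS.

        Uses a directly hosted transformation when one exists; otherwise
        auto-resolves a chain through the central mediator.  Returns the
        transformed points plus per-step inverse-consistency metadata.
        """
        src = self._code_of(ps.srs_name)
        dst = self._code_of(target_srs)
        if src == dst:
            out = PointSet(srs_name=dst, points=ps.points,
                           out_of_validity_flags=ps.out_of_validity_flags)
            zero = ConsistencyStats(n_samples=1, seed=0, mean_error=0.0,
                                    max_error=0.0, rms_error=0.0)
            return out, [zero]
        tagged = PointSet(srs_name=src, points=ps.points,
                          out_of_validity_flags=ps.out_of_validity_flags)
        direct = [r for r in self.list_transformations()
                  if self.registry.resolve_code(r.source_srs) == src
                  and self.registry.resolve_code(r.target_srs) == dst]
        if direct:
            rec = direct[0]
            out = apply_transform(rec, tagged, registry=self.registry)
            out = PointSet(srs_name=dst, points=out.points,
                           out_of_validity_flags=out.out_of_validity_flags)
            return out, [rec.consistency]
        if self.central is None:
            raise NoPathFound(
                f"hub {self.name!r} has no direct transformation "
                f"{src} -> {dst} and no central mediator")
        chain = self.central.graph.resolve_chain(src, dst)
        out = self.central.graph.execute_chain(chain, tagged)
        return out, self.central.graph.chain_consistency(chain)

    def _code_of(self, srs: str) -> str:
        try:
            return self.registry.resolve_code(srs)
        except DAIError:
            raise UnknownSRS(f"SRS {srs!r} is not registered anywhere in "
                             "the federation")

    # -- POI queries ---------------------------------------------------------

    def _route_points(self, ps: PointSet, hosted_codes) -> tuple[str,
                                                                 PointSet]:
        """Bring a POI into one of the hub's hosted SRSs (chain if needed)."""
        src = self._code_of(ps.srs_name)
        if src in hosted_codes:
            return src, PointSet(srs_name=src, points=ps.points,
                                 out_of_validity_flags=ps.out_of_validity_flags)
        for code in sorted(hosted_codes):
            try:
                out, _ = self.transform_poi(ps, code)
                return code, out
            except (NoPathFound, UnknownSRS):
                continue
        raise NoPathFound(
            f"POI in {ps.srs_name!r} cannot be routed to any SRS hosted by "
            f"hub {self.name!r}")

    def get_structure_names_by_poi(self, ps: PointSet,
                                   radius: float = 0.0
                                   ) -> list[StructureHit]:
        """Names of structures containing the POI voxel (plus any within the
        vicinity radius); the POI is transformed to the segmentation's SRS
        first when needed."""
        if not self.label_volumes:
            raise NoSegmentation(
                f"hub {self.name!r} hosts no segmentation volume")
        code, local = self._route_points(ps, set(self.label_volumes))
        vol = self.label_volumes[code]
        hits: dict[int, StructureHit] = {}
        for p in local.points:
            for h in vol.lookup(p, radius=radius):
                hits[h.label] = h
        return [hits[k] for k in sorted(hits)]

    @staticmethod
    def _box_hit(extent, point: np.ndarray, radius: float) -> bool:
        lo = np.array([e[0] for e in extent])
        hi = np.array([e[1] for e in extent])
        d = min(len(point), len(lo))
        clamped = np.clip(point[:d], lo[:d], hi[:d])
        return bool(np.linalg.norm(clamped - point[:d]) <= radius)

    def _store_query(self, stores, ps: PointSet,
                     radius: float) -> list[ObjectRecord]:
        if not stores:
            return []
        try:
            code, local = self._route_points(ps, set(stores))
        except NoPathFound:
            return []
        recs = [r for r in stores[code]
                if any(self._box_hit(r.extent, p, radius)
                       for p in local.points)]
        return sorted(recs, key=lambda r: (r.title, r.extent))

    def get_2d_images_by_poi(self, ps: PointSet,
                             radius: float = 0.0) -> list[ObjectRecord]:
        """Image records whose extent intersects the ball of the given
        radius about the POI (radius 0 = containment); deterministic
        order."""
        return self._store_query(self.image_stores, ps, radius)

    def get_annotations_by_poi(self, ps: PointSet,
                               radius: float = 0.0) -> list[ObjectRecord]:
        return self._store_query(self.annotation_stores, ps, radius)

    def invoke_poi_method(self, method: str, ps: PointSet,
                          radius: float = 0.0):
        if method not in self.processes or method not in POI_METHODS:
            raise UnknownProcess(
                f"hub {self.name!r} does not offer POI method {method!r}")
        if method == "GetStructureNamesByPOI":
            return self.get_structure_names_by_poi(ps, radius=radius)
        if method == "Get2DImagesByPOI":
            return self.get_2d_images_by_poi(ps, radius=radius)
        return self.get_annotations_by_poi(ps, radius=radius)

    # -- WPS front door ------------------------------------------------------

    def handle(self, query_string: str) -> str:
        """Answer a WPS key-value request with a WaxML document.

        Service-level errors come back as ExceptionReport documents rather
        than raised exceptions, mirroring WPS practice.
        """
        try:
            req = parse_wps_request(query_string)
            return self._dispatch(req)
        except DAIError as exc:
            return waxml.encode_exception_report(exc)

    def _dispatch(self, req: WpsRequest) -> str:
        if req.request_kind == "GetCapabilities":
            return self.get_capabilities()
        if req.request_kind == "DescribeProcess":
            return waxml.encode_process_description(
                self.describe_process(req.identifier))
        return self._execute(req)

    def _poi_from_inputs(self, req: WpsRequest) -> PointSet:
        srs = req.input("srsName") or req.input("inputSrsName")
        if not srs:
            raise MalformedDataInputs("POI request requires srsName")
        coords = [req.input("x"), req.input("y")]
        if req.input("z") not in (None, ""):
            coords.append(req.input("z"))
        try:
            vals = [float(c) for c in coords]
        except (TypeError, ValueError):
            raise MalformedDataInputs(
                f"bad POI coordinates {coords!r}")
        return PointSet(srs_name=srs, points=np.array([vals]))

    def _execute(self, req: WpsRequest) -> str:
        ident = req.identifier
        if ident not in self.processes:
            raise UnknownProcess(
                f"hub {self.name!r} does not offer {ident!r}")
        if ident == "ListSRSs":
            descs = self.list_srs(species=req.input("species"),
                                  family=req.input("family"))
            reg = Registry()
            for d in descs:
                reg.register_srs(d)
            return waxml.encode_registry(reg)
        if ident == "DescribeSRS":
            name = req.input("srsName")
            if not name:
                raise MalformedDataInputs("DescribeSRS requires srsName")
            return waxml.encode_srs(self.registry.get_srs(name))
        if ident == "ListTransformations":
            return waxml.encode_transformation_list(
                self.list_transformations())
        if ident == "TransformPOI":
            ps = self._poi_from_inputs(req)
            out, _ = self.transform_poi(ps, req.input("outputSrsName"))
            named = PointSet(
                srs_name=self.registry.get_srs(out.srs_name).name,
                points=out.points,
                out_of_validity_flags=out.out_of_validity_flags)
            return waxml.encode_poi(named)
        radius = float(req.input("radius", 0.0) or 0.0)
        ps = self._poi_from_inputs(req)
        if ident == "GetStructureNamesByPOI":
            hits = self.get_structure_names_by_poi(ps, radius=radius)
            return waxml.encode_structure_response(hits, srs_name=ps.srs_name,
                                                   hub=self.name)
        if ident in ("Get2DImagesByPOI", "GetAnnotationsByPOI"):
            recs = self.invoke_poi_method(ident, ps, radius=radius)
            return waxml.encode_image_response(recs, hub=self.name)
        raise UnknownProcess(ident)


class CentralHub(AtlasHub):
    """The central mediator: federation-wide chaining and query fan-out."""

    def __init__(self, registry: Registry, name: str = "central"):
        super().__init__(name, registry)
        self.graph = TransformationGraph(registry=registry)
        self.central = self
        self.hubs: dict[str, AtlasHub] = {}

    def register_hub(self, hub: AtlasHub) -> None:
        """Harvest a hub's transformations into the central graph."""
        self.hubs[hub.name] = hub
        hub.central = self
        self.hosted_srs |= hub.hosted_srs
        for rec in hub.list_transformations():
            if rec.code not in self.graph._by_code:
                self.graph.add_transformation(rec)

    @property
    def processes(self) -> list[str]:
        out = super().processes
        if self.graph.list_transformations() and \
                "TransformPOI" not in out:
            out = (out[:2] + ["ListTransformations", "TransformPOI"]
                   + out[2:])
        return out + ["GetTransformationChain", "GetObjectsByPOI"]

    def list_transformations(self) -> list[TransformationRecord]:
        merged = {r.code: r for r in self.graph.list_transformations()}
        merged.update(self.transformations)
        return sorted(merged.values(), key=lambda r: r.code)

    def get_transformation_chain(self, input_srs: str,
                                 output_srs: str) -> Chain:
        return self.graph.resolve_chain(self._code_of(input_srs),
                                        self._code_of(output_srs))

    def transform_poi(self, ps: PointSet, target_srs: str):
        src = self._code_of(ps.srs_name)
        dst = self._code_of(target_srs)
        tagged = PointSet(srs_name=src, points=ps.points,
                          out_of_validity_flags=ps.out_of_validity_flags)
        chain = self.graph.resolve_chain(src, dst)
        out = self.graph.execute_chain(chain, tagged)
        stats = self.graph.chain_consistency(chain)
        if not stats:
            stats = [ConsistencyStats(n_samples=1, seed=0, mean_error=0.0,
                                      max_error=0.0, rms_error=0.0)]
        return out, stats

    def get_objects_by_poi(self, ps: PointSet, radius: float = 0.0
                           ) -> list[tuple[str, str]]:
        """The (hub, POI method) pairs that would answer non-empty at ps.

        Implemented as a live fan-out: each registered hub's offered POI
        methods are invoked with the (auto-transformed) POI and only those
        returning at least one object are listed.  Hubs unreachable from the
        POI's SRS simply contribute nothing.
        """
        out = []
        for hub_name in sorted(self.hubs):
            hub = self.hubs[hub_name]
            for method in POI_METHODS:
                if method not in hub.processes:
                    continue
                try:
                    result = hub.invoke_poi_method(method, ps, radius=radius)
                except (NoPathFound, NoSegmentation, UnknownSRS):
                    continue
                if result:
                    out.append((hub_name, method))
        return out

    def federated_query(self, method: str, ps: PointSet,
                        radius: float = 0.0) -> FederatedResult:
        """Fan a POI method out to all hubs and union the responses.

        The initial query is rewritten per hub (the POI is transformed into
        each hub's SRS automatically); each returned object is tagged with
        its hub of origin.  A failing hub yields a warning entry instead of
        failing the whole query.
        """
        if method not in POI_METHODS:
            raise UnknownProcess(f"{method!r} is not a POI query method")
        result = FederatedResult()
        for hub_name in sorted(self.hubs):
            hub = self.hubs[hub_name]
            if method not in hub.processes:
                continue
            try:
                for rec in hub.invoke_poi_method(method, ps, radius=radius):
                    result.records.append((hub_name, rec))
            except DAIError as exc:
                result.warnings.append(f"{hub_name}: {exc}")
        return result

    def _execute(self, req: WpsRequest) -> str:
        if req.identifier == "GetTransformationChain":
            chain = self.get_transformation_chain(
                req.input("inputSrsName"), req.input("outputSrsName"))
            return waxml.encode_chain_response(chain)
        if req.identifier == "GetObjectsByPOI":
            ps = self._poi_from_inputs(req)
            pairs = self.get_objects_by_poi(
                ps, radius=float(req.input("radius", 0.0) or 0.0))
            return waxml.encode_capabilities(
                self.name, [f"{h}:{m}" for h, m in pairs])
        return super()._execute(req)
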