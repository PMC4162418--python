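"""WaxML: the XML dialect for atlas information exchange.

WaxML is a GML application dialect: points of interest are encoded with GML
``Point``/``MultiPoint`` constructs (simple-features profile) carrying a
mandatory ``srsName`` attribute, while SRS descriptions, transformation
lists, chain responses, service capabilities, process descriptions and
POI-query responses use elements in the WaxML namespace.

The original schema files of the prototype infrastructure are no longer
available; this module defines a documented dialect that preserves the
published structure (mandatory ``srsName``, per-document-kind response types,
GML geometry) without claiming byte compatibility with the historical XSDs.

Encoding is deterministic: fixed element/attribute order and shortest
round-trip decimal formatting for floats, so equal inputs produce
byte-identical documents.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from lxml import etree

from .chain_resolver import Chain, ChainStep
from .errors import (
    BadCoordinateCount,
    DAIError,
    MalformedXML,
    MissingSRSName,
    ValidationError,
)
from .objects import ObjectRecord, ProcessDescription, ProcessInput, \
    StructureHit
from .srs_registry import (
    AxisSpec,
    FiducialRecord,
    Registry,
    SliceRecord,
    SRSDescription,
    StructureRecord,
    Violation,
)
from .transforms import (
    ConsistencyStats,
    PointSet,
    TransformationRecord,
    transform_from_payload,
)

__all__ = [
    "WAX_NS", "GML_NS",
    "encode_poi", "decode_poi",
    "encode_srs", "decode_srs",
    "encode_transformation_list", "decode_transformation_list",
    "encode_chain_response", "decode_chain_response",
    "encode_capabilities", "decode_capabilities",
    "encode_process_description", "decode_process_description",
    "encode_structure_response", "decode_structure_response",
    "encode_image_response", "decode_image_response",
    "encode_exception_report", "decode_exception_report",
    "encode_registry", "decode_registry",
    "validate_document",
]

WAX_NS = "urn:waxml:1.0"
GML_NS = "http://www.opengis.net/gml/3.2"
_NSMAP = {"wax": WAX_NS, "gml": GML_NS}


def _wax(tag: str) -> str:
    return f"{{{WAX_NS}}}{tag}"


def _gml(tag: str) -> str:
    return f"{{{GML_NS}}}{tag}"


def _fmt(v: float) -> str:
    """Shortest decimal that round-trips the double exactly."""
    return repr(float(v))


def _serialize(root) -> str:
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def _parse(xml: str | bytes):
    try:
        if isinstance(xml, str):
            xml = xml.encode()
        return etree.fromstring(xml)
    except etree.XMLSyntaxError as exc:
        raise MalformedXML(str(exc)) from exc


def _text(parent, tag: str, value: str) -> None:
    el = etree.SubElement(parent, _wax(tag))
    el.text = value


def _child_text(el, tag: str, default=None):
    c = el.find(_wax(tag))
    if c is None:
        return default
    return c.text or ""


# ---------------------------------------------------------------------------
# points of interest (GML Point / MultiPoint)
# ---------------------------------------------------------------------------

def encode_poi(ps: PointSet) -> str:
    """Encode a PointSet as a WaxML POI document.

    A single point uses the GML ``Point`` construct; an array of points uses
    ``MultiPoint`` with one ``pointMember`` each, order preserved.  The SRS
    name is mandatory on every geometry element.
    """
    if not ps.srs_name:
        raise MissingSRSName("PointSet has no srs_name")
    root = etree.Element(_wax("POI"), nsmap=_NSMAP)
    flags = ps.out_of_validity_flags
    if len(ps) == 1:
        _point_elem(root, ps.points[0], ps.srs_name,
                    bool(flags[0]) if flags is not None else False)
    else:
        mp = etree.SubElement(root, _gml("MultiPoint"),
                              srsName=ps.srs_name)
        for i, p in enumerate(ps.points):
            member = etree.SubElement(mp, _gml("pointMember"))
            _point_elem(member, p, ps.srs_name,
                        bool(flags[i]) if flags is not None else False)
    return _serialize(root)


def _point_elem(parent, coords, srs_name: str, out_of_validity: bool):
    attrs = {"srsName": srs_name}
    if out_of_validity:
        attrs[_wax("outOfValidity")] = "true"
    pt = etree.SubElement(parent, _gml("Point"), attrib=attrs)
    pos = etree.SubElement(pt, _gml("pos"))
    pos.text = " ".join(_fmt(c) for c in coords)


def decode_poi(xml: str | bytes) -> PointSet:
    """Decode a WaxML POI document back into a PointSet."""
    root = _parse(xml)
    points = root.findall(f".//{_gml('Point')}")
    if not points:
        raise MalformedXML("document contains no gml:Point")
    mp = root.find(f".//{_gml('MultiPoint')}")
    srs_name = None
    if mp is not None:
        srs_name = mp.get("srsName")
    coords, flags = [], []
    for pt in points:
        name = pt.get("srsName") or srs_name
        if not name:
            raise MissingSRSName("Point lacks the mandatory srsName "
                                 "attribute")
        srs_name = srs_name or name
        pos = pt.find(_gml("pos"))
        if pos is None or not (pos.text or "").strip():
            raise BadCoordinateCount("Point has no gml:pos coordinates")
        vals = [float(t) for t in pos.text.split()]
        if len(vals) not in (2, 3):
            raise BadCoordinateCount(
                f"expected 2 or 3 coordinates, got {len(vals)}")
        if coords and len(vals) != len(coords[0]):
            raise BadCoordinateCount(
                "inconsistent coordinate counts within MultiPoint")
        coords.append(vals)
        flags.append(pt.get(_wax("outOfValidity")) == "true")
    flag_arr = np.array(flags) if any(flags) else None
    return PointSet(srs_name=srs_name, points=np.array(coords),
                    out_of_validity_flags=flag_arr)


# ---------------------------------------------------------------------------
# SRS descriptions
# ---------------------------------------------------------------------------

_SRS_KNOWN = {"SrsFamily", "Version", "Species", "Description",
              "OriginDescription", "RegionOfValidity", "Author",
              "DerivedFrom", "ReferenceImplementation", "Orientation"}


def encode_srs(desc: SRSDescription) -> str:
    root = etree.Element(_wax("SRSDescription"), nsmap=_NSMAP,
                         code=desc.code, name=desc.name)
    _srs_children(root, desc)
    return _serialize(root)


def _srs_children(root, desc: SRSDescription) -> None:
    _text(root, "SrsFamily", desc.srs_family)
    _text(root, "Version", desc.version)
    _text(root, "Species", desc.species)
    _text(root, "Description", desc.description)
    _text(root, "OriginDescription", desc.origin_description)
    _text(root, "RegionOfValidity", desc.region_of_validity)
    _text(root, "Author", desc.author)
    if desc.derived_from is not None:
        _text(root, "DerivedFrom", desc.derived_from)
    if desc.reference_implementation is not None:
        _text(root, "ReferenceImplementation",
              desc.reference_implementation)
    orient = etree.SubElement(root, _wax("Orientation"))
    for a in desc.axes:
        attrs = {"label": a.axis_label, "direction": a.anatomical_direction,
                 "unit": a.unit, "extentMin": _fmt(a.extent_min),
                 "extentMax": _fmt(a.extent_max)}
        if a.voxel_size_mm is not None:
            attrs["voxelSizeMm"] = _fmt(a.voxel_size_mm)
        etree.SubElement(orient, _wax("Axis"), **attrs)


def decode_srs(xml: str | bytes, strict: bool = False) -> SRSDescription:
    """Decode an SRS description document.

    In strict mode unknown child elements raise :class:`ValidationError`;
    in lax mode (default) they are ignored, so newer dialect revisions stay
    readable.
    """
    root = _parse(xml)
    if root.tag != _wax("SRSDescription"):
        raise MalformedXML(f"expected wax:SRSDescription, got {root.tag}")
    return _decode_srs_elem(root, strict=strict)


def _decode_srs_elem(root, strict: bool = False) -> SRSDescription:
    if strict:
        unknown = [etree.QName(c).localname for c in root
                   if isinstance(c.tag, str)
                   and etree.QName(c).localname not in _SRS_KNOWN]
        if unknown:
            raise ValidationError([Violation(
                "document", f"unknown element(s): {unknown}")])
    axes = []
    orient = root.find(_wax("Orientation"))
    if orient is not None:
        for ax in orient.findall(_wax("Axis")):
            vs = ax.get("voxelSizeMm")
            axes.append(AxisSpec(
                axis_label=ax.get("label"),
                anatomical_direction=ax.get("direction"),
                unit=ax.get("unit"),
                extent_min=float(ax.get("extentMin")),
                extent_max=float(ax.get("extentMax")),
                voxel_size_mm=float(vs) if vs is not None else None))
    return SRSDescription(
        code=root.get("code"), name=root.get("name"),
        srs_family=_child_text(root, "SrsFamily", ""),
        version=_child_text(root, "Version", ""),
        species=_child_text(root, "Species", ""),
        description=_child_text(root, "Description", ""),
        origin_description=_child_text(root, "OriginDescription", ""),
        axes=tuple(axes),
        region_of_validity=_child_text(root, "RegionOfValidity",
                                       "whole brain"),
        author=_child_text(root, "Author", ""),
        derived_from=_child_text(root, "DerivedFrom"),
        reference_implementation=_child_text(root,
                                             "ReferenceImplementation"))


# ---------------------------------------------------------------------------
# transformation payloads and lists
# ---------------------------------------------------------------------------

def _matrix_text(rows) -> str:
    return "; ".join(" ".join(_fmt(v) for v in row) for row in rows)


def _matrix_from_text(text: str):
    return [[float(v) for v in row.split()]
            for row in text.split(";") if row.strip()]


def _payload_elem(parent, payload: dict) -> None:
    el = etree.SubElement(parent, _wax("Method"), type=payload["type"])
    _fill_payload(el, payload)


def _fill_payload(el, payload: dict) -> None:
    kind = payload["type"]
    if kind == "affine":
        m = etree.SubElement(el, _wax("Matrix"))
        m.text = _matrix_text(payload["matrix"])
    elif kind == "tps":
        for tag, key in (("ControlPoints", "control_points"),
                         ("Weights", "weights"),
                         ("AffinePart", "affine_part")):
            c = etree.SubElement(el, _wax(tag))
            c.text = _matrix_text(payload[key])
        lam = etree.SubElement(el, _wax("Lambda"))
        lam.text = _fmt(payload["lambda"])
        if payload.get("approximate"):
            el.set("approximate", "true")
    elif kind == "composite":
        for step in payload["steps"]:
            s = etree.SubElement(el, _wax("Step"), type=step["type"])
            _fill_payload(s, step)
    elif kind == "lifted_planar":
        el.set("zScale", _fmt(payload["z_scale"]))
        el.set("zOffset", _fmt(payload["z_offset"]))
        s = etree.SubElement(el, _wax("Planar"),
                             type=payload["planar"]["type"])
        _fill_payload(s, payload["planar"])
    else:  # pragma: no cover
        raise MalformedXML(f"unknown method type {kind!r}")


def _payload_from_elem(el) -> dict:
    kind = el.get("type")
    if kind == "affine":
        return {"type": "affine",
                "matrix": _matrix_from_text(el.find(_wax("Matrix")).text)}
    if kind == "tps":
        return {
            "type": "tps",
            "control_points": _matrix_from_text(
                el.find(_wax("ControlPoints")).text),
            "weights": _matrix_from_text(el.find(_wax("Weights")).text),
            "affine_part": _matrix_from_text(
                el.find(_wax("AffinePart")).text),
            "lambda": float(el.find(_wax("Lambda")).text),
            "approximate": el.get("approximate") == "true"}
    if kind == "composite":
        return {"type": "composite",
                "steps": [_payload_from_elem(s)
                          for s in el.findall(_wax("Step"))]}
    if kind == "lifted_planar":
        return {"type": "lifted_planar",
                "planar": _payload_from_elem(el.find(_wax("Planar"))),
                "z_scale": float(el.get("zScale")),
                "z_offset": float(el.get("zOffset"))}
    raise MalformedXML(f"unknown method type {kind!r}")


def encode_transformation_list(records) -> str:
    root = etree.Element(_wax("TransformationList"), nsmap=_NSMAP)
    for r in records:
        attrs = {"code": r.code, "hub": r.hub, "inputSrs": r.source_srs,
                 "outputSrs": r.target_srs, "version": r.version}
        if r.inverse_code is not None:
            attrs["inverseCode"] = r.inverse_code
        el = etree.SubElement(root, _wax("Transformation"), **attrs)
        _payload_elem(el, r.method.to_payload())
        if r.consistency is not None:
            c = r.consistency
            etree.SubElement(
                el, _wax("ConsistencyStats"), nSamples=str(c.n_samples),
                seed=str(c.seed), meanError=_fmt(c.mean_error),
                maxError=_fmt(c.max_error), rmsError=_fmt(c.rms_error))
    return _serialize(root)


def decode_transformation_list(xml: str | bytes):
    root = _parse(xml)
    if root.tag != _wax("TransformationList"):
        raise MalformedXML("expected wax:TransformationList")
    out = []
    for el in root.findall(_wax("Transformation")):
        stats = None
        c = el.find(_wax("ConsistencyStats"))
        if c is not None:
            stats = ConsistencyStats(
                n_samples=int(c.get("nSamples")), seed=int(c.get("seed")),
                mean_error=float(c.get("meanError")),
                max_error=float(c.get("maxError")),
                rms_error=float(c.get("rmsError")))
        method = transform_from_payload(
            _payload_from_elem(el.find(_wax("Method"))))
        out.append(TransformationRecord(
            code=el.get("code"), source_srs=el.get("inputSrs"),
            target_srs=el.get("outputSrs"), hub=el.get("hub"),
            method=method, version=el.get("version"),
            inverse_code=el.get("inverseCode"), consistency=stats))
    return out


# ---------------------------------------------------------------------------
# chain responses
# ---------------------------------------------------------------------------

def _request_template(step: ChainStep) -> str:
    """KVP TransformPOI request with blank coordinate slots."""
    return ("Service=WPS&version=1.0.0&Request=Execute"
            "&Identifier=TransformPOI&DataInputs="
            f"transformationCode={step.transformation_code};"
            f"inputSrsName={step.source_srs};"
            f"outputSrsName={step.target_srs};x=;y=;z=")


def encode_chain_response(chain: Chain) -> str:
    """Encode a resolved chain as an ordered list of TransformPOI request
    templates (coordinates left blank), one per step with its serving hub."""
    root = etree.Element(_wax("ChainResponse"), nsmap=_NSMAP,
                         inputSrs=chain.input_srs,
                         outputSrs=chain.output_srs)
    for step in chain.steps:
        el = etree.SubElement(
            root, _wax("TransformPOITemplate"), order=str(step.order),
            hub=step.hub, code=step.transformation_code,
            inputSrs=step.source_srs, outputSrs=step.target_srs)
        tmpl = etree.SubElement(el, _wax("RequestTemplate"))
        tmpl.text = _request_template(step)
    return _serialize(root)


def decode_chain_response(xml: str | bytes) -> Chain:
    root = _parse(xml)
    if root.tag != _wax("ChainResponse"):
        raise MalformedXML("expected wax:ChainResponse")
    steps = []
    for el in root.findall(_wax("TransformPOITemplate")):
        steps.append(ChainStep(
            order=int(el.get("order")), hub=el.get("hub"),
            transformation_code=el.get("code"),
            source_srs=el.get("inputSrs"), target_srs=el.get("outputSrs")))
    steps.sort(key=lambda s: s.order)
    return Chain(input_srs=root.get("inputSrs"),
                 output_srs=root.get("outputSrs"), steps=tuple(steps))


# ---------------------------------------------------------------------------
# capabilities / process descriptions
# ---------------------------------------------------------------------------

def encode_capabilities(hub_name: str, processes) -> str:
    root = etree.Element(_wax("Capabilities"), nsmap=_NSMAP, hub=hub_name,
                         service="WPS", version="1.0.0")
    for p in processes:
        ident = p.identifier if isinstance(p, ProcessDescription) else str(p)
        etree.SubElement(root, _wax("Process"), identifier=ident)
    return _serialize(root)


def decode_capabilities(xml: str | bytes):
    root = _parse(xml)
    if root.tag != _wax("Capabilities"):
        raise MalformedXML("expected wax:Capabilities")
    return (root.get("hub"),
            [p.get("identifier") for p in root.findall(_wax("Process"))])


def encode_process_description(pd: ProcessDescription) -> str:
    root = etree.Element(_wax("ProcessDescription"), nsmap=_NSMAP,
                         identifier=pd.identifier, outputKind=pd.output_kind)
    for inp in pd.inputs:
        etree.SubElement(root, _wax("Input"), name=inp.name,
                         type=inp.semantic_type,
                         required="true" if inp.required else "false")
    return _serialize(root)


def decode_process_description(xml: str | bytes) -> ProcessDescription:
    root = _parse(xml)
    if root.tag != _wax("ProcessDescription"):
        raise MalformedXML("expected wax:ProcessDescription")
    inputs = tuple(ProcessInput(name=i.get("name"),
                                semantic_type=i.get("type"),
                                required=i.get("required") == "true")
                   for i in root.findall(_wax("Input")))
    return ProcessDescription(identifier=root.get("identifier"),
                              inputs=inputs,
                              output_kind=root.get("outputKind"))


# ---------------------------------------------------------------------------
# POI-query responses
# ---------------------------------------------------------------------------

def encode_structure_response(hits, srs_name: str = "",
                              hub: str = "") -> str:
    root = etree.Element(_wax("StructureResponse"), nsmap=_NSMAP)
    if srs_name:
        root.set("srsName", srs_name)
    if hub:
        root.set("hub", hub)
    for h in hits:
        attrs = {"name": h.structure_name, "label": str(h.label)}
        if h.vocabulary_ref is not None:
            attrs["vocabularyRef"] = h.vocabulary_ref
        etree.SubElement(root, _wax("Structure"), **attrs)
    return _serialize(root)


def decode_structure_response(xml: str | bytes):
    root = _parse(xml)
    if root.tag != _wax("StructureResponse"):
        raise MalformedXML("expected wax:StructureResponse")
    return [StructureHit(structure_name=el.get("name"),
                         label=int(el.get("label")),
                         vocabulary_ref=el.get("vocabularyRef"))
            for el in root.findall(_wax("Structure"))]


def encode_image_response(records, hub: str = "") -> str:
    root = etree.Element(_wax("ImageResponse"), nsmap=_NSMAP)
    if hub:
        root.set("hub", hub)
    for r in records:
        el = etree.SubElement(root, _wax("ObjectRecord"),
                              kind=r.object_kind, srsName=r.srs_name,
                              title=r.title, modality=r.modality,
                              provenance=r.provenance)
        ext = etree.SubElement(el, _wax("Extent"))
        ext.text = _matrix_text(r.extent)
    return _serialize(root)


def decode_image_response(xml: str | bytes):
    root = _parse(xml)
    if root.tag != _wax("ImageResponse"):
        raise MalformedXML("expected wax:ImageResponse")
    out = []
    for el in root.findall(_wax("ObjectRecord")):
        extent = tuple(tuple(row) for row in
                       _matrix_from_text(el.find(_wax("Extent")).text))
        out.append(ObjectRecord(
            object_kind=el.get("kind"), srs_name=el.get("srsName"),
            extent=extent, title=el.get("title"),
            modality=el.get("modality"), provenance=el.get("provenance")))
    return out


def encode_exception_report(error: Exception) -> str:
    root = etree.Element(_wax("ExceptionReport"), nsmap=_NSMAP)
    code = getattr(error, "code", type(error).__name__)
    el = etree.SubElement(root, _wax("Exception"), exceptionCode=code)
    el.text = str(error)
    return _serialize(root)


def decode_exception_report(xml: str | bytes):
    root = _parse(xml)
    if root.tag != _wax("ExceptionReport"):
        raise MalformedXML("expected wax:ExceptionReport")
    el = root.find(_wax("Exception"))
    return el.get("exceptionCode"), (el.text or "")


# ---------------------------------------------------------------------------
# registry documents
# ---------------------------------------------------------------------------

def encode_registry(reg: Registry) -> str:
    """Authoritative WaxML dump of a full SRS registry and its tables."""
    root = etree.Element(_wax("Registry"), nsmap=_NSMAP)
    for desc in reg.list_srs():
        el = etree.SubElement(root, _wax("SRSDescription"), code=desc.code,
                              name=desc.name)
        _srs_children(el, desc)
    for s in reg.structures:
        attrs = {"srsCode": s.srs_code, "name": s.structure_name}
        if s.vocabulary_ref is not None:
            attrs["vocabularyRef"] = s.vocabulary_ref
        if s.geometry_ref is not None:
            attrs["geometryRef"] = str(s.geometry_ref)
            attrs["geometryRefKind"] = ("label"
                                        if isinstance(s.geometry_ref, int)
                                        else "polygon")
        etree.SubElement(root, _wax("Structure"), **attrs)
    for f in reg.fiducials:
        el = etree.SubElement(root, _wax("Fiducial"), srsCode=f.srs_code,
                              name=f.fiducial_name)
        el.text = " ".join(_fmt(c) for c in f.point)
    for s in reg.slices:
        el = etree.SubElement(root, _wax("Slice"), srsCode=s.srs_code,
                              index=str(s.slice_index), plane=s.plane)
        el.text = " ".join(_fmt(v) for v in s.in_plane_to_3d)
    return _serialize(root)


def decode_registry(xml: str | bytes) -> Registry:
    root = _parse(xml)
    if root.tag != _wax("Registry"):
        raise MalformedXML("expected wax:Registry")
    reg = Registry()
    for el in root.findall(_wax("SRSDescription")):
        reg.register_srs(_decode_srs_elem(el))
    for el in root.findall(_wax("Structure")):
        geom = el.get("geometryRef")
        if geom is not None and el.get("geometryRefKind") == "label":
            geom = int(geom)
        reg.add_structure(StructureRecord(
            srs_code=el.get("srsCode"), structure_name=el.get("name"),
            vocabulary_ref=el.get("vocabularyRef"), geometry_ref=geom))
    for el in root.findall(_wax("Fiducial")):
        reg.add_fiducial(FiducialRecord(
            srs_code=el.get("srsCode"), fiducial_name=el.get("name"),
            point=tuple(float(v) for v in el.text.split())))
    for el in root.findall(_wax("Slice")):
        reg.add_slice(SliceRecord(
            srs_code=el.get("srsCode"), slice_index=int(el.get("index")),
            plane=el.get("plane"),
            in_plane_to_3d=tuple(float(v) for v in el.text.split())))
    return reg


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_document(xml: str | bytes) -> list[str]:
    """Check well-formedness and the mandatory-srsName rule.

    Returns a list of problem strings (empty = valid).  Every GML Point and
    MultiPoint element must carry a non-empty ``srsName`` attribute.
    """
    problems: list[str] = []
    try:
        root = _parse(xml)
    except MalformedXML as exc:
        return [f"not well-formed: {exc}"]
    for el in root.iter():
        if el.tag in (_gml("Point"), _gml("MultiPoint")):
            if not el.get("srsName"):
                problems.append(
                    f"{etree.QName(el).localname} element without srsName")
    return problems
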