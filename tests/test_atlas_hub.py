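"""WPS request parsing and hub/central-mediator service semantics."""

import numpy as np
import pytest

from atlasdai import (
    AtlasHub,
    CentralHub,
    LabelVolume,
    PointSet,
    make_object_store,
    make_phantom_atlas,
    make_table1_registry,
    parse_wps_request,
    register_phantom,
    waxml,
)
from atlasdai.atlas_hub import POI_METHODS
from atlasdai.errors import (
    MalformedDataInputs,
    MissingIdentifier,
    MissingService,
    NoSegmentation,
    UnknownProcess,
    UnknownSRS,
    UnsupportedAsync,
)


@pytest.fixture()
def federation():
    """Central + two data hubs over the seven-SRS fixture and a phantom."""
    reg, graph = make_table1_registry()
    phantom = make_phantom_atlas(seed=11, shape=(24, 24, 16),
                                 n_structures=2, min_radius=3.0)
    register_phantom(reg, phantom)
    central = CentralHub(reg)
    for rec in graph.list_transformations():
        central.graph.add_transformation(rec)

    whs_hub = AtlasHub("WHS", reg, hosted_srs=["INCF:0001"])
    whs_hub.add_image_store("INCF:0001", make_object_store(
        seed=2, n_images=5, srs_name="Mouse_WHS_0.9",
        extents=[[0.0, 10.0]] * 3))

    ph_hub = AtlasHub("PH", reg)
    ph_hub.add_label_volume(phantom.srs_code, LabelVolume(
        labels=phantom.labels,
        structures={s.label: (s.name, "phantom-vocabulary")
                    for s in phantom.structures}))
    central.register_hub(whs_hub)
    central.register_hub(ph_hub)
    return reg, central, whs_hub, ph_hub, phantom


class TestParseWpsRequest:
    def test_execute_transform_poi_grammar(self):
        req = parse_wps_request(
            "Service=WPS&version=1.0.0&Request=Execute"
            "&Identifier=TransformPOI"
            "&DataInputs=srsName=Mouse_WHS_1.0;x=1;y=2;z=3")
        assert req.request_kind == "Execute"
        assert req.identifier == "TransformPOI"
        assert len(req.data_inputs) == 4
        assert req.input("SRSNAME") == "Mouse_WHS_1.0"  # case-insensitive

    def test_missing_service_rejected(self):
        with pytest.raises(MissingService):
            parse_wps_request("Request=Execute&Identifier=TransformPOI")

    def test_get_capabilities_needs_no_identifier(self):
        req = parse_wps_request(
            "Service=WPS&version=1.0.0&Request=GetCapabilities")
        assert req.request_kind == "GetCapabilities"
        assert req.identifier is None

    def test_execute_without_identifier_rejected(self):
        with pytest.raises(MissingIdentifier):
            parse_wps_request("Service=WPS&Request=Execute")

    def test_malformed_data_inputs_rejected(self):
        with pytest.raises(MalformedDataInputs):
            parse_wps_request("Service=WPS&Request=Execute&Identifier=X"
                              "&DataInputs=justakeywithnovalue")

    def test_async_clauses_parsed_and_rejected(self):
        with pytest.raises(UnsupportedAsync):
            parse_wps_request("Service=WPS&Request=Execute&Identifier=X"
                              "&storeExecuteResponse=true")

    def test_unknown_keys_preserved(self):
        req = parse_wps_request(
            "Service=WPS&Request=GetCapabilities&Vendor=acme")
        assert ("Vendor", "acme") in req.extra


class TestCapabilities:
    def test_one_entry_per_offered_process(self, federation):
        _, _, whs_hub, _, _ = federation
        hub_name, procs = waxml.decode_capabilities(
            whs_hub.get_capabilities())
        assert hub_name == "WHS"
        assert procs == whs_hub.processes
        assert "Get2DImagesByPOI" in procs

    def test_every_listed_identifier_is_describable(self, federation):
        _, central, whs_hub, ph_hub, _ = federation
        for hub in (central, whs_hub, ph_hub):
            for ident in hub.processes:
                pd = hub.describe_process(ident)
                assert pd.identifier == ident

    def test_central_lists_chain_and_object_discovery(self, federation):
        _, central, _, _, _ = federation
        assert "GetTransformationChain" in central.processes
        assert "GetObjectsByPOI" in central.processes

    def test_unknown_process_not_describable(self, federation):
        _, _, whs_hub, _, _ = federation
        with pytest.raises(UnknownProcess):
            whs_hub.describe_process("GetCoffeeByPOI")

    def test_transform_poi_description_names_srs_inputs(self, federation):
        _, central, _, _, _ = federation
        pd = central.describe_process("TransformPOI")
        names = [i.name for i in pd.inputs]
        assert "inputSrsName" in names and "outputSrsName" in names
        assert "x" in names and "y" in names
        assert waxml.decode_process_description(
            waxml.encode_process_description(pd)) == pd


class TestTransformPOI:
    def test_same_srs_is_identity_with_zero_consistency(self, federation):
        _, central, _, _, _ = federation
        ps = PointSet(srs_name="Mouse_WHS_0.9",
                      points=np.array([[1.0, 2.0, 3.0]]))
        out, stats = central.transform_poi(ps, "INCF:0001")
        assert np.array_equal(out.points, ps.points)
        assert all(s.mean_error == 0.0 for s in stats if s)

    def test_cross_hub_request_routes_through_figure_chain(self, federation):
        _, central, _, _, _ = federation
        ps = PointSet(srs_name="Mouse_AGEA_1.0",
                      points=np.array([[1.0, 2.0, 3.0]]))
        out, stats = central.transform_poi(ps, "Mouse_Paxinos_1.0")
        chain = central.get_transformation_chain("Mouse_AGEA_1.0",
                                                 "Mouse_Paxinos_1.0")
        assert len(stats) == len(chain) == 2
        expected = central.graph.execute_chain(chain, PointSet(
            srs_name="INCF:0102", points=ps.points))
        assert np.abs(out.points - expected.points).max() <= 1e-12

    def test_unregistered_target_srs_rejected(self, federation):
        _, central, _, _, _ = federation
        ps = PointSet(srs_name="Mouse_WHS_0.9",
                      points=np.array([[0.0, 0.0, 0.0]]))
        with pytest.raises(UnknownSRS):
            central.transform_poi(ps, "INCF:9999")


class TestStructureLookup:
    def test_poi_at_phantom_center_names_that_structure(self, federation):
        _, _, _, ph_hub, phantom = federation
        s0 = phantom.structures[0]
        ps = PointSet(srs_name=phantom.srs_code,
                      points=np.array([s0.center]))
        hits = ph_hub.get_structure_names_by_poi(ps)
        assert [h.structure_name for h in hits] == [s0.name]

    def test_background_poi_with_zero_radius_is_empty(self, federation):
        _, _, _, ph_hub, phantom = federation
        # a corner voxel is background by construction (radii < shape/2)
        ps = PointSet(srs_name=phantom.srs_code,
                      points=np.array([[0.0, 0.0, 0.0]]))
        assert ph_hub.get_structure_names_by_poi(ps) == []

    def test_exhaustive_grid_matches_label_volume_scan(self, federation):
        _, _, _, ph_hub, phantom = federation
        nx, ny, nz = phantom.shape
        step = 2
        mismatches = 0
        for ix in range(0, nx, step):
            for iy in range(0, ny, step):
                for iz in range(0, nz, step):
                    ps = PointSet(srs_name=phantom.srs_code,
                                  points=np.array(
                                      [[float(ix), float(iy), float(iz)]]))
                    hits = ph_hub.get_structure_names_by_poi(ps)
                    expected = int(phantom.labels[ix, iy, iz])
                    got = hits[0].label if hits else 0
                    mismatches += (got != expected)
        assert mismatches == 0

    def test_vicinity_radius_expands_hits(self, federation):
        _, _, _, ph_hub, phantom = federation
        s0 = phantom.structures[0]
        edge = np.array(s0.center)
        edge[0] += s0.radii[0] + 1.5  # just outside along x
        ps = PointSet(srs_name=phantom.srs_code, points=edge[None])
        assert ph_hub.get_structure_names_by_poi(ps, radius=0) == []
        hits = ph_hub.get_structure_names_by_poi(ps, radius=3.0)
        assert s0.name in [h.structure_name for h in hits]

    def test_hub_without_segmentation_refuses(self, federation):
        _, _, whs_hub, _, phantom = federation
        ps = PointSet(srs_name="Mouse_WHS_0.9",
                      points=np.array([[1.0, 1.0, 1.0]]))
        with pytest.raises(NoSegmentation):
            whs_hub.get_structure_names_by_poi(ps)


class TestImageQueries:
    def test_results_equal_linear_scan_oracle(self):
        rng = np.random.default_rng(5)
        reg, _ = make_table1_registry()
        hub = AtlasHub("H", reg, hosted_srs=["INCF:0001"])
        store = make_object_store(seed=8, n_images=20,
                                  srs_name="Mouse_WHS_0.9",
                                  extents=[[0.0, 10.0]] * 3)
        hub.add_image_store("INCF:0001", store)
        for _ in range(30):
            p = rng.uniform(0, 10, 3)
            radius = float(rng.choice([0.0, 0.5, 2.0]))
            ps = PointSet(srs_name="INCF:0001", points=p[None])
            got = hub.get_2d_images_by_poi(ps, radius=radius)
            expected = []
            for r in store:  # independent linear scan
                lo = np.array([e[0] for e in r.extent])
                hi = np.array([e[1] for e in r.extent])
                d = np.linalg.norm(np.clip(p, lo, hi) - p)
                if d <= radius:
                    expected.append(r)
            assert sorted(got, key=lambda r: r.title) == \
                sorted(expected, key=lambda r: r.title)

    def test_containing_box_is_returned_and_empty_store_is_empty(self):
        reg, _ = make_table1_registry()
        hub = AtlasHub("H", reg, hosted_srs=["INCF:0001"])
        ps = PointSet(srs_name="INCF:0001",
                      points=np.array([[5.0, 5.0, 5.0]]))
        assert hub.get_2d_images_by_poi(ps) == []
        from atlasdai.objects import ObjectRecord
        rec = ObjectRecord("image2d", "Mouse_WHS_0.9",
                           ((4.0, 6.0), (4.0, 6.0), (4.0, 6.0)), title="hit")
        hub.add_image_store("INCF:0001", [rec])
        assert hub.get_2d_images_by_poi(ps) == [rec]


class TestCentralDiscovery:
    def test_no_data_near_poi_yields_empty_list(self, federation):
        reg, central, _, _, phantom = federation
        # POI in a WHS corner away from any store box and phantom structure
        ps = PointSet(srs_name="Mouse_WHS_0.9",
                      points=np.array([[0.01, 0.01, 0.01]]))
        pairs = central.get_objects_by_poi(ps)
        for hub_name, method in pairs:
            got = central.hubs[hub_name].invoke_poi_method(method, ps)
            assert got  # listed pairs really are non-empty

    def test_sound_and_complete_against_exhaustive_invocation(
            self, federation):
        reg, central, _, _, phantom = federation
        rng = np.random.default_rng(17)
        for _ in range(20):
            ps = PointSet(srs_name="Mouse_WHS_0.9",
                          points=rng.uniform(0, 10, (1, 3)))
            listed = set(central.get_objects_by_poi(ps))
            for hub_name, hub in central.hubs.items():
                for method in POI_METHODS:
                    if method not in hub.processes:
                        continue
                    try:
                        result = hub.invoke_poi_method(method, ps)
                    except Exception:
                        result = []
                    assert ((hub_name, method) in listed) == bool(result)

    def test_adding_an_image_adds_exactly_one_pair(self, federation):
        reg, central, whs_hub, _, _ = federation
        ps = PointSet(srs_name="Mouse_WHS_0.9",
                      points=np.array([[9.9, 9.9, 9.9]]))
        before = set(central.get_objects_by_poi(ps))
        from atlasdai.objects import ObjectRecord
        whs_hub.add_image_store("INCF:0001", [ObjectRecord(
            "image2d", "Mouse_WHS_0.9",
            ((9.8, 10.0), (9.8, 10.0), (9.8, 10.0)), title="corner")])
        after = set(central.get_objects_by_poi(ps))
        assert after - before == {("WHS", "Get2DImagesByPOI")}


class TestFederatedQuery:
    def test_union_is_provenance_tagged_multiset_union(self, federation):
        reg, central, _, _, _ = federation
        rng = np.random.default_rng(23)
        for _ in range(10):
            ps = PointSet(srs_name="Mouse_WHS_0.9",
                          points=rng.uniform(0, 10, (1, 3)))
            fed = central.federated_query("Get2DImagesByPOI", ps, radius=1.0)
            expected = []
            for hub_name in sorted(central.hubs):
                hub = central.hubs[hub_name]
                if "Get2DImagesByPOI" not in hub.processes:
                    continue
                for rec in hub.get_2d_images_by_poi(ps, radius=1.0):
                    expected.append((hub_name, rec))
            assert fed.records == expected

    def test_partial_failure_yields_warning_not_error(self, federation):
        reg, central, whs_hub, _, _ = federation

        class ExplodingHub(AtlasHub):
            @property
            def processes(self):
                return super().processes + ["Get2DImagesByPOI"]

            def get_2d_images_by_poi(self, ps, radius=0.0):
                from atlasdai.errors import NoPathFound
                raise NoPathFound("backend down")

        bad = ExplodingHub("BAD", reg)
        central.register_hub(bad)
        ps = PointSet(srs_name="Mouse_WHS_0.9",
                      points=np.array([[5.0, 5.0, 5.0]]))
        fed = central.federated_query("Get2DImagesByPOI", ps, radius=5.0)
        assert any(w.startswith("BAD:") for w in fed.warnings)
        assert all(h != "BAD" for h, _ in fed.records)
        assert fed.records  # healthy hubs still answered


class TestSRSInvariance:
    def test_affine_related_srs_give_identical_structure_lookup(
            self, federation):
        """A POI expressed in two SRSs linked by an exact affine yields the
        same structures."""
        reg, central, _, ph_hub, phantom = federation
        from atlasdai import AffineTransform, TransformationRecord
        A = AffineTransform.translation([10.0, 0.0, 0.0])
        central.graph.add_transformation(TransformationRecord(
            code="T:WHS10-PH", source_srs="INCF:0002",
            target_srs=phantom.srs_code, hub="PH", method=A))
        s0 = phantom.structures[0]
        native = PointSet(srs_name=phantom.srs_code,
                          points=np.array([s0.center]))
        shifted = PointSet(srs_name="INCF:0002",
                           points=np.array([s0.center]) - [10.0, 0.0, 0.0])
        assert ph_hub.get_structure_names_by_poi(native) == \
            ph_hub.get_structure_names_by_poi(shifted)


class TestWpsFrontDoor:
    def test_all_responses_are_reparsable_waxml(self, federation):
        _, central, whs_hub, _, _ = federation
        queries = [
            "Service=WPS&version=1.0.0&Request=GetCapabilities",
            "Service=WPS&Request=DescribeProcess&Identifier=TransformPOI",
            ("Service=WPS&Request=Execute&Identifier=TransformPOI"
             "&DataInputs=inputSrsName=Mouse_AGEA_1.0;"
             "outputSrsName=Mouse_Paxinos_1.0;x=1;y=2;z=3"),
            ("Service=WPS&Request=Execute&Identifier=GetTransformationChain"
             "&DataInputs=inputSrsName=Mouse_AGEA_1.0;"
             "outputSrsName=Mouse_Paxinos_1.0"),
            "Service=WPS&Request=Execute&Identifier=DescribeSRS"
            "&DataInputs=srsName=Mouse_WHS_0.9",
        ]
        for q in queries:
            assert waxml.validate_document(central.handle(q)) == []

    def test_errors_become_exception_reports(self, federation):
        _, central, _, _, _ = federation
        xml = central.handle("Request=Execute&Identifier=TransformPOI")
        code, _ = waxml.decode_exception_report(xml)
        assert code == "MissingService"
        xml = central.handle("Service=WPS&Request=Execute"
                             "&Identifier=GetCoffeeByPOI&DataInputs=x=1")
        code, _ = waxml.decode_exception_report(xml)
        assert code == "UnknownProcess"
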