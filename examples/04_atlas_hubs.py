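"""Query federated atlas hubs with WPS-style point-of-interest requests.

Two hubs are stood up over a shared registry: one hosts a phantom
segmentation volume, the other a store of 2D image records in WHS
coordinates.  The central mediator resolves chains so a POI expressed in any
known SRS reaches every hub, discovers which (hub, method) pairs would
answer non-empty, and unions per-hub responses with provenance.
"""

import numpy as np

from atlasdai import (
    AtlasHub, CentralHub, LabelVolume, PointSet,
    make_object_store, make_phantom_atlas, make_table1_registry,
    register_phantom,
)

registry, graph = make_table1_registry()
phantom = make_phantom_atlas(seed=11, shape=(24, 24, 16), n_structures=2,
                             min_radius=3.0)
register_phantom(registry, phantom)

central = CentralHub(registry)
for rec in graph.list_transformations():
    central.graph.add_transformation(rec)

structure_hub = AtlasHub("PH", registry)
structure_hub.add_label_volume(phantom.srs_code, LabelVolume(
    labels=phantom.labels,
    structures={s.label: (s.name, "phantom-vocabulary")
                for s in phantom.structures}))

image_hub = AtlasHub("WHS", registry, hosted_srs=["INCF:0001"])
image_hub.add_image_store("INCF:0001", make_object_store(
    seed=2, n_images=5, srs_name="Mouse_WHS_0.9", extents=[[0, 10]] * 3))

central.register_hub(structure_hub)
central.register_hub(image_hub)

print("central capabilities:", central.processes)

# structure lookup at a phantom ellipsoid's centre
s0 = phantom.structures[0]
poi = PointSet(srs_name=phantom.srs_code, points=np.array([s0.center]))
print("structures at centre:",
      [h.structure_name for h
       in structure_hub.get_structure_names_by_poi(poi)])
# exactly the structure whose ellipsoid contains the point

# which (hub, method) pairs would answer non-empty near a WHS point?
whs_poi = PointSet(srs_name="Mouse_WHS_0.9",
                   points=np.array([[5.0, 5.0, 5.0]]))
print("non-empty methods:", central.get_objects_by_poi(whs_poi, radius=2.0))

# federated image query: per-hub results, provenance-tagged
fed = central.federated_query("Get2DImagesByPOI", whs_poi, radius=2.0)
for hub_name, rec in fed.records:
    print(f"  [{hub_name}] {rec.title} ({rec.modality})")
print("warnings:", fed.warnings)

# the raw WPS front door returns WaxML text
print(central.handle(
    "Service=WPS&version=1.0.0&Request=Execute&Identifier=TransformPOI"
    "&DataInputs=inputSrsName=Mouse_AGEA_1.0;"
    "outputSrsName=Mouse_Paxinos_1.0;x=1;y=2;z=3"))
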