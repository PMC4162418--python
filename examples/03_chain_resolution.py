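"""Resolve and execute a multi-hub transformation chain.

No direct mapping exists between the Allen gene-expression space (AGEA) and
the Paxinos & Franklin stereotaxic space, so the resolver routes through the
go-between Waxholm Space 0.9: step 1 served by the ABA hub, step 2 by the
UCSD hub.  The chain is rendered as a WaxML document of TransformPOI request
templates with the coordinates left blank, ready for a client to fill in.
"""

import numpy as np

from atlasdai import PointSet, make_table1_registry, waxml

registry, graph = make_table1_registry()

chain = graph.resolve_chain("Mouse_AGEA_1.0", "Mouse_Paxinos_1.0")
print(f"{len(chain)} steps, hubs {chain.hubs}, "
      f"intermediate {chain.intermediate_srs}")
# 2 steps through INCF:0001 (Mouse_WHS_0.9): the fewest-steps route,
# preferred because every extra step accumulates mapping error

poi = PointSet(srs_name="INCF:0102", points=np.array([[1.0, 2.0, 3.0]]))
out = graph.execute_chain(chain, poi)
print("AGEA", poi.points[0], "->", out.srs_name, out.points[0])

print("\nChain as a WaxML response (request templates, coordinates blank):")
print(waxml.encode_chain_response(chain))
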