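"""Small built-in reference tables used by worked examples and checks."""
from __future__ import annotations

import pandas as pd

#: STRING-style interaction scores around NPPA (atrial natriuretic
#: peptide): one physical edge to its receptor NPR3 and five weaker
#: text-mining associations with cardiac remodeling genes.  Used by the
#: worked subnetwork example: with a 0.7 score floor on the physical
#: channel, exactly the NPPA-NPR3 edge survives.
_NPPA_EDGES = [
    ("NPPA", "NPR3", "physical", 0.89),
    ("NPPA", "ATP2A2", "textmining", 0.58),
    ("NPPA", "ADM", "textmining", 0.55),
    ("NPPA", "TBX18", "textmining", 0.48),
    ("NPPA", "PITX2", "textmining", 0.46),
    ("NPPA", "POSTN", "textmining", 0.41),
]


def nppa_reference_edges() -> pd.DataFrame:
    """The six reference NPPA interaction edges as an edge-list frame."""
    return pd.DataFrame(
        _NPPA_EDGES, columns=["protein_a", "protein_b", "channel", "score"]
    )
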