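"""Small published summary datasets bundled for examples and checks.

These are aggregate counts from the Czech alien-flora study of introduction
pathways (Pysek, Jarosik & Pergl 2011, PLoS ONE 6:e24890); the underlying
species-level database is not public, but the published pathway x status
table is sufficient input for the contingency machinery.
"""

from __future__ import annotations

import pandas as pd

from .core_data import PATHWAYS, STATUSES

__all__ = ["czech_pathway_status_counts"]


def czech_pathway_status_counts() -> pd.DataFrame:
    """Observed pathway x invasion-status counts for the Czech alien flora.

    1,007 neophyte species; multi-label pathway membership makes the grand
    total 1,389 assignments.
    """
    data = {
        "release": (51, 23, 19),
        "escape": (444, 109, 46),
        "contaminant": (367, 53, 23),
        "stowaway": (204, 37, 13),
    }
    return pd.DataFrame(
        [data[p] for p in PATHWAYS], index=list(PATHWAYS), columns=list(STATUSES)
    )
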