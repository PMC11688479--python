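"""phytoscreen: a phytochemical screening cascade.

Compound-table ingestion and ADME admission filtering, molecular
fingerprints with Tanimoto similarity, chemical-space clustering with
per-cluster representative selection, gene-set intersection and PPI hub
ranking by maximal clique centrality, hypergeometric over-representation
analysis, a fingerprint-based inhibitor-classification benchmark harness,
and molecular-dynamics trajectory analytics — all driven by seeded
synthetic-data generators so the full pipeline is testable offline.
"""

from importlib import resources

import pandas as pd

__version__ = "0.1.0"

__all__ = ["load_reference_library", "__version__"]


def load_reference_library() -> pd.DataFrame:
    """Load the bundled 18-compound lotus-leaf reference library.

    Returns a DataFrame with columns ``id, name, smiles, V1, V2, V3,
    cluster, is_representative``: the published chemical-space clustering
    of the 18 orally bioavailable, drug-like lotus-leaf compounds (three
    chemotype clusters — steroid/triterpene, flavonoid, aporphine
    alkaloid — each with a flagged representative).
    """
    with resources.files("phytoscreen.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    df["is_representative"] = df["is_representative"].astype(str).str.upper() == "TRUE"
    return df
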