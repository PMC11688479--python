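import pytest

import phytoscreen
from phytoscreen import chemlib, fingerprints


@pytest.fixture(scope="session")
def reference_df():
    """The bundled 18-compound lotus-leaf library with printed clustering."""
    return phytoscreen.load_reference_library()


@pytest.fixture(scope="session")
def reference_compounds(reference_df):
    recs = [
        chemlib.CompoundRecord(id=r.id, name=r.name, smiles=r.smiles)
        for r in reference_df.itertuples()
    ]
    return chemlib.canonicalize_and_dedup(recs).compounds


@pytest.fixture(scope="session")
def reference_morgan_fps(reference_compounds):
    """Radius-2, 2048-bit Morgan fingerprints keyed by compound id."""
    return {
        r.id: fingerprints.compute_fingerprint(
            r, "morgan", fingerprints.CLUSTERING_MORGAN
        )
        for r in reference_compounds
    }
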