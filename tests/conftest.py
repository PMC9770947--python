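import numpy as np
import pandas as pd
import pytest


def make_prsm_frame(rows):
    """Minimal PrSM frame from (spectrum_id, accession, mass, e_value) tuples
    or dicts; decoy status derived from the accession prefix."""
    recs = []
    for r in rows:
        if isinstance(r, dict):
            rec = dict(r)
        else:
            sid, acc, mass, ev = r
            rec = {"spectrum_id": sid, "protein_accession": acc,
                   "precursor_mass": mass, "e_value": ev}
        rec.setdefault("is_decoy", rec["protein_accession"].startswith("DECOY_"))
        rec.setdefault("proteoform", "PEPTIDEK")
        rec.setdefault("condition", "A")
        rec.setdefault("replicate", 1)
        rec.setdefault("fraction", 1)
        rec.setdefault("intensity", 1000.0)
        recs.append(rec)
    return pd.DataFrame(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_scored_frame(rng):
    """Random target/decoy collection for FDR oracle checks."""
    def _make(n, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return pd.DataFrame({
            "spectrum_id": [f"S{i:04d}" for i in range(n)],
            "protein_accession": ["X"] * n,
            "e_value": 10.0 ** r.uniform(-10, 1, size=n),
            "is_decoy": r.random(n) < 0.4,
        })
    return _make
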