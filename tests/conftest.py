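import numpy as np
import pandas as pd
import pytest

from tumorevo.filtering import CohortVariantTable


def make_samples(ids, phases=None, purity=None):
    phases = phases or {s: "post" for s in ids}
    purity = purity or {s: 0.8 for s in ids}
    return pd.DataFrame(
        {"phase": [phases[s] for s in ids], "purity": [purity[s] for s in ids]},
        index=pd.Index(list(ids), name="sample_id"),
    )


def make_table(rows, sample_ids=None, phases=None, purity=None, callers=("c1", "c2", "c3")):
    """Build a cohort table from compact row dicts; missing caller flags
    default to all-PASS for rows with alt reads."""
    records = []
    for r in rows:
        rec = {
            "chrom": "chr1",
            "pos": 100,
            "ref": "A",
            "alt": "T",
            "gene": "GENE0",
            "impact": "MODERATE",
        }
        rec.update(r)
        for c in callers:
            rec.setdefault(f"pass_{c}", rec["alt_count"] > 0)
        records.append(rec)
    obs = pd.DataFrame(records)
    ids = sample_ids or sorted(obs["sample_id"].unique())
    return CohortVariantTable(
        observations=obs,
        samples=make_samples(ids, phases, purity),
        callers=tuple(callers),
    )


@pytest.fixture
def toy_table():
    """Six observations over three samples, mixed quality."""
    rows = [
        {"sample_id": "s1", "variant_id": "v1", "alt_count": 20, "ref_count": 80},
        {"sample_id": "s2", "variant_id": "v1", "alt_count": 3, "ref_count": 97,
         "pass_c1": False, "pass_c2": False, "pass_c3": False},
        {"sample_id": "s3", "variant_id": "v1", "alt_count": 30, "ref_count": 70},
        {"sample_id": "s1", "variant_id": "v2", "alt_count": 40, "ref_count": 60,
         "pass_c2": False, "impact": "LOW"},
        {"sample_id": "s2", "variant_id": "v2", "alt_count": 0, "ref_count": 100},
        {"sample_id": "s3", "variant_id": "v3", "alt_count": 4, "ref_count": 96},
    ]
    return make_table(rows, sample_ids=["s1", "s2", "s3"])


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
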