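import pandas as pd
import pytest

from protmr.sumstats import SumStats, TraitMeta

DEFAULTS = {
    "chrom": "1",
    "effect_allele": "A",
    "other_allele": "G",
    "eaf": 0.3,
    "beta": 0.1,
    "se": 0.02,
    "pval": 1e-9,
}


def build_sumstats(rows, trait_id="prot", trait_type="continuous", n=10_000, n_cases=None):
    """Assemble a SumStats from partial row dicts, filling sane defaults."""
    full = []
    for i, row in enumerate(rows):
        r = dict(DEFAULTS, snp_id=f"rs{i + 1}", pos=1_000_000 + 1000 * i)
        r.update(row)
        full.append(r)
    meta = TraitMeta(trait_id=trait_id, trait_type=trait_type, n=n, n_cases=n_cases)
    return SumStats(meta=meta, df=pd.DataFrame(full))


@pytest.fixture
def make_sumstats():
    return build_sumstats
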