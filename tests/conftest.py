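import numpy as np
import pandas as pd
import pytest

from hybridkaryo.synthetic import ChromosomeSpec, TruthSpec


@pytest.fixture
def small_spec() -> TruthSpec:
    """Two chromosomes per subgenome, 10 genes each, desk-scale lengths."""
    return TruthSpec(
        seed=42,
        chromosomes=[
            ChromosomeSpec("sc01", "Scer", 50_000, 2),
            ChromosomeSpec("sc02", "Scer", 50_000, 2),
            ChromosomeSpec("se01", "Seub", 50_000, 2),
            ChromosomeSpec("se02", "Seub", 50_000, 2),
        ],
        genes_per_chromosome=10,
        gene_length=2_000,
    )


def make_records(
    chrom="sc01",
    subgenome="Scer",
    ad_ref=(25,),
    ad_alt=(25,),
    pos=None,
    left=10,
    right=10,
):
    """Hand-build a variant frame with the pipeline's column layout."""
    n = len(ad_ref)
    ad_ref = np.asarray(ad_ref)
    ad_alt = np.asarray(ad_alt)
    return pd.DataFrame(
        {
            "CHROM": chrom,
            "SUBGENOME": subgenome,
            "POS": np.arange(1, n + 1) * 100 if pos is None else np.asarray(pos),
            "REF": "A",
            "ALT": "C",
            "DP": ad_ref + ad_alt,
            "AD_REF": ad_ref,
            "AD_ALT": ad_alt,
            "LEFT_FLANK": np.full(n, left),
            "RIGHT_FLANK": np.full(n, right),
        }
    )
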