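"""Generate the three hybrid karyotype archetypes and summarise their
synthetic sequencing signals.

Builds an allotetraploid, an allotriploid and an allodiploid truth
configuration (25x per-copy depth, ~200:1 Scer:Seub heterozygosity
asymmetry, S. eubayanus mitochondria in the polyploids, S. cerevisiae
in the diploid), simulates coverage, SNPs and mitochondrial depth for
each, and writes a per-hybrid summary table plus the truth configs to
results/.
"""

import json
from pathlib import Path

import pandas as pd

from hybridkaryo import io, synthetic

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name, (spec, dna) in synthetic.hybrid_archetypes(seed=SEED).items():
        ref = synthetic.generate_reference(spec)
        track = synthetic.simulate_coverage(ref, spec)
        variants = synthetic.simulate_variants(ref, spec)
        m_sc, m_se = synthetic.simulate_mito(ref, spec)
        io.write_truth_json(spec, RESULTS / f"truth_{name}.json")
        share = (variants["SUBGENOME"] == "Seub").mean()
        rows.append(
            {
                "hybrid": name,
                "dna_content_n": dna,
                "n_chromosomes": len(ref.chromosomes),
                "n_genes": len(ref.genes),
                "n_snp_records": len(variants),
                "seub_snp_share": round(float(share), 4),
                "mean_depth_scer_mito": round(m_sc, 2),
                "mean_depth_seub_mito": round(m_se, 2),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "simulated_hybrids.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(
        "\nNote the minority share of SNPs on the Seub subgenome in every "
        "hybrid — the het-density asymmetry leaves the S. eubayanus side "
        "nearly devoid of variants."
    )


if __name__ == "__main__":
    main()
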