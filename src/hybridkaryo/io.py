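"""Plain-text readers and writers for the pipeline's table formats.

Conventions: gene and mask annotations are BED (0-based half-open);
depth tracks are the ``samtools depth`` dialect (chrom, 1-based pos,
depth); variants are a VCF-like TSV with explicit allele-depth and
flank-support columns; the simulator's truth is a JSON mirror of its
TruthSpec.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import (
    VARIANT_COLUMNS,
    CoverageTrack,
    Gene,
    ReferenceModel,
    TruthSpec,
)


def write_reference_tsv(ref: ReferenceModel, path: str | Path) -> None:
    pd.DataFrame(ref.chromosomes, columns=["name", "subgenome", "length"]).to_csv(
        path, sep="\t", index=False
    )


def read_reference_tsv(path: str | Path, mito: dict | None = None) -> ReferenceModel:
    df = pd.read_csv(path, sep="\t")
    return ReferenceModel(
        chromosomes=list(df.itertuples(index=False, name=None)),
        genes=[],
        mito_contigs=mito or {"Scer": ("Scer_mito", 80_000), "Seub": ("Seub_mito", 70_000)},
    )


def write_genes_bed(ref: ReferenceModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in ref.genes:
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\n")


def read_genes_bed(path: str | Path) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
            genes.append(Gene(name, chrom, int(start), int(end)))
    return genes


def read_mask_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.rstrip("\n").split("\t")[:3]
            out.append((chrom, int(start), int(end)))
    return out


def write_depth_tsv(track: CoverageTrack, path: str | Path) -> None:
    """samtools-depth dialect: chrom <TAB> 1-based pos <TAB> depth."""
    with open(path, "w") as fh:
        for chrom in track.chromosomes():
            d = track[chrom]
            block = pd.DataFrame(
                {"chrom": chrom, "pos": np.arange(1, len(d) + 1), "depth": d}
            )
            block.to_csv(fh, sep="\t", index=False, header=False)


def read_depth_tsv(path: str | Path, lengths: dict[str, int]) -> CoverageTrack:
    """Read a samtools-depth TSV; absent positions default to depth 0."""
    df = pd.read_csv(path, sep="\t", names=["chrom", "pos", "depth"])
    depths = {c: np.zeros(n, dtype=np.int64) for c, n in lengths.items()}
    for chrom, grp in df.groupby("chrom"):
        if chrom not in depths:
            raise KeyError(f"depth track chromosome {chrom!r} not in reference")
        depths[chrom][grp["pos"].to_numpy() - 1] = grp["depth"].to_numpy()
    return CoverageTrack(depths)


def write_variants_tsv(variants: pd.DataFrame, path: str | Path) -> None:
    variants[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_json(spec: TruthSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(spec.to_dict(), fh, indent=1, sort_keys=True)


def read_truth_json(path: str | Path) -> TruthSpec:
    with open(path) as fh:
        return TruthSpec.from_dict(json.load(fh))


def write_mito_json(mean_scer: float, mean_seub: float, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"mean_depth_scer": mean_scer, "mean_depth_seub": mean_seub}, fh, indent=1
        )


def read_mito_json(path: str | Path) -> tuple[float, float]:
    with open(path) as fh:
        d = json.load(fh)
    return float(d["mean_depth_scer"]), float(d["mean_depth_seub"])
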