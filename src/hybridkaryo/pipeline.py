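"""End-to-end orchestration: simulate → karyotype → corroborate → report.

A single declarative config drives the whole run. In simulation mode a
TruthSpec block generates the dataset and the report additionally
contains a truth-vs-called confusion table; in real-input mode the same
stages run on depth/gene/variant/mito files of the documented shapes.
Reports are deterministic for a fixed config (no timestamps), so two
runs with the same seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__, io, karyotype, mito, synthetic, zygosity


class ConfigError(ValueError):
    """Pipeline configuration failed validation (exit code 2 in the CLI)."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one of ``truth`` (simulation mode) or the input-path trio
    ``reference/genes/depth`` (+ optional variants/mito/mask) must be
    supplied; ``dna_content_n`` is always required for karyotyping.
    """

    out_dir: Path
    dna_content_n: float
    truth: synthetic.TruthSpec | None = None
    reference_path: Path | None = None
    genes_path: Path | None = None
    depth_path: Path | None = None
    variants_path: Path | None = None
    mito_path: Path | None = None
    mask_path: Path | None = None
    min_flank: int = zygosity.DEFAULT_MIN_FLANK
    het_band: tuple[float, float] = zygosity.DEFAULT_HET_BAND
    hom_min: float = zygosity.DEFAULT_HOM_MIN
    min_snps: int = zygosity.DEFAULT_MIN_SNPS
    mito_min_ratio: float = mito.DEFAULT_MIN_RATIO
    extra: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        if "dna_content_n" not in d:
            raise ConfigError("config is missing required field 'dna_content_n'")
        if "out_dir" not in d:
            raise ConfigError("config is missing required field 'out_dir'")
        truth = None
        if "truth" in d:
            truth = synthetic.TruthSpec.from_dict(d["truth"])
        else:
            for key in ("reference_path", "genes_path", "depth_path"):
                if key not in d:
                    raise ConfigError(
                        f"config needs a 'truth' block or input paths; missing {key!r}"
                    )
        kwargs = {
            k: d[k]
            for k in (
                "min_flank",
                "hom_min",
                "min_snps",
                "mito_min_ratio",
            )
            if k in d
        }
        if "het_band" in d:
            kwargs["het_band"] = tuple(d["het_band"])
        paths = {
            k: Path(d[k])
            for k in (
                "reference_path",
                "genes_path",
                "depth_path",
                "variants_path",
                "mito_path",
                "mask_path",
            )
            if k in d
        }
        return cls(
            out_dir=Path(d["out_dir"]),
            dna_content_n=float(d["dna_content_n"]),
            truth=truth,
            **paths,
            **kwargs,
        )


class StageError(RuntimeError):
    """Computation failed inside a named pipeline stage."""

    def __init__(self, stage: str, source: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {source}: {cause}")
        self.stage = stage


def _stage(stage: str, source: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except (ConfigError, StageError):
        raise
    except Exception as exc:  # surface stage + provenance, per contract
        raise StageError(stage, source, exc) from exc


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns a dict with the in-memory results (karyotype frame, zygosity
    summary, chimera calls, mito call, confusion table in simulation
    mode) alongside the written file paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.truth is not None

    if sim:
        source = f"TruthSpec(seed={config.truth.seed})"
        ref = _stage("reference", source, synthetic.generate_reference, config.truth)
        track = _stage("coverage", source, synthetic.simulate_coverage, ref, config.truth)
        variants = _stage("variants", source, synthetic.simulate_variants, ref, config.truth)
        mito_depths = _stage("mito", source, synthetic.simulate_mito, ref, config.truth)
        mask = None
        io.write_truth_json(config.truth, out / "truth.json")
    else:
        source = str(config.depth_path)
        ref = _stage("reference", source, io.read_reference_tsv, config.reference_path)
        ref.genes = _stage("reference", source, io.read_genes_bed, config.genes_path)
        lengths = {name: ln for name, _, ln in ref.chromosomes}
        track = _stage("coverage", source, io.read_depth_tsv, config.depth_path, lengths)
        variants = (
            _stage("variants", source, io.read_variants_tsv, config.variants_path)
            if config.variants_path
            else None
        )
        mito_depths = (
            _stage("mito", source, io.read_mito_json, config.mito_path)
            if config.mito_path
            else None
        )
        mask = (
            _stage("mask", source, io.read_mask_bed, config.mask_path)
            if config.mask_path
            else None
        )

    # --- karyotype from coverage -----------------------------------------
    table, dropped = _stage(
        "gene_coverage", source, karyotype.gene_median_coverage, track, ref, mask
    )
    table = _stage("normalize", source, karyotype.normalize_gene_coverage, table)
    factor = karyotype.ploidy_factor(config.dna_content_n)
    kary = _stage(
        "karyotype",
        source,
        karyotype.estimate_chromosome_copies,
        table,
        factor,
        [(name, sub) for name, sub, _ in ref.chromosomes],
    )
    kary.to_csv(out / "karyotype.tsv", sep="\t", index=False)
    (out / "karyotype.json").write_text(
        json.dumps(
            {
                r["chromosome"]: {
                    "subgenome": r["subgenome"],
                    "integer_copies": int(r["integer_copies"]),
                    "raw_copies": None if pd.isna(r["raw_copies"]) else r["raw_copies"],
                    "uncertain": bool(r["uncertain"]),
                }
                for _, r in kary.iterrows()
            },
            indent=1,
            sort_keys=True,
        )
    )

    # --- zygosity corroboration + chimeras --------------------------------
    zsummary = chimeras = None
    qc: dict[str, Any] = {"genes_dropped_masked": len(dropped)}
    if variants is not None and len(variants):
        n_in = len(variants)
        filtered = _stage(
            "snp_filter", source, zygosity.filter_variants, variants, config.min_flank
        )
        calls = _stage(
            "zygosity",
            source,
            zygosity.classify_zygosity,
            filtered,
            config.het_band,
            config.hom_min,
        )
        zsummary = _stage(
            "zygosity", source, zygosity.summarize_by_chromosome, calls, config.min_snps
        )
        zsummary.to_csv(out / "zygosity_summary.tsv", sep="\t", index=False)
        qc.update(
            snps_in=n_in,
            snps_after_flank_filter=len(filtered),
            snps_ambiguous=int((calls["CALL"] == zygosity.AMBIGUOUS).sum()),
        )
        chimeras = []
        for chrom in calls["CHROM"].unique():
            chimeras.extend(
                _stage(
                    "chimera",
                    source,
                    zygosity.detect_chimera,
                    calls.loc[calls["CHROM"] == chrom],
                )
            )
        with open(out / "chimeras.bed", "w") as fh:
            for seg in chimeras:
                fh.write(
                    f"{seg.chromosome}\t{seg.start - 1}\t{seg.end}\t{seg.state}"
                    f"\t{seg.n_snps}\t{'' if seg.breakpoint is None else seg.breakpoint}\n"
                )

    # --- mitochondrial inheritance ----------------------------------------
    mito_call = None
    if mito_depths is not None:
        d_sc, d_se = mito_depths
        mito_call = mito.mito_inheritance(
            mito.MitoDepths(d_sc, d_se, min_ratio=config.mito_min_ratio)
        )
        (out / "mito_call.json").write_text(
            json.dumps(
                {
                    "mean_depth_scer": d_sc,
                    "mean_depth_seub": d_se,
                    "origin": mito_call,
                },
                indent=1,
            )
        )

    # --- truth-vs-called confusion table (simulation mode) -----------------
    confusion = None
    if sim:
        truth_copies = {c.name: c.true_copies for c in config.truth.chromosomes}
        confusion = pd.crosstab(
            kary["chromosome"].map(truth_copies).rename("true_copies"),
            kary["integer_copies"].rename("called_copies"),
        )
        confusion.to_csv(out / "confusion.tsv", sep="\t")

    manifest = {
        "version": __version__,
        "mode": "simulation" if sim else "real-input",
        "dna_content_n": config.dna_content_n,
        "ploidy_factor": factor.factor,
        "seed": config.truth.seed if sim else None,
        "parameters": {
            "min_flank": config.min_flank,
            "het_band": list(config.het_band),
            "hom_min": config.hom_min,
            "min_snps": config.min_snps,
            "mito_min_ratio": config.mito_min_ratio,
        },
        "qc": qc,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return {
        "karyotype": kary,
        "gene_coverage": table,
        "zygosity_summary": zsummary,
        "chimeras": chimeras,
        "mito_call": mito_call,
        "confusion": confusion,
        "manifest": manifest,
        "out_dir": out,
    }
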