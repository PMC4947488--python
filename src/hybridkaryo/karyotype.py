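"""Chromosome and gene copy-number estimation from read coverage.

The estimator follows the median-of-medians recipe used for karyotyping
sequenced hybrids: take the median per-base depth of every annotated
gene, normalize by the sample-wide median over all genes, take the
median of normalized values per chromosome, and rescale by a ploidy
factor calibrated against flow-cytometry DNA content (content in haploid
units divided by 2, so a diploid gets factor 1, a triploid 1.5, a
tetraploid 2). Medians are interpolated (mean of the two central order
statistics for even counts) — for a mixed 2/1-copy triploid with
balanced gene counts this puts the normalization denominator exactly
between the two depth levels, which is what lets the 1.5x factor return
integer copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import CoverageTrack, ReferenceModel

log = logging.getLogger(__name__)

#: |raw_copies - nearest integer| beyond which a call is flagged uncertain
#: (surfaces chimeric / mosaic chromosomes without suppressing the call).
UNCERTAIN_MARGIN = 0.35

GENE_COVERAGE_COLUMNS = ["gene_id", "chromosome", "subgenome", "median_depth", "normalized"]


class CoverageInputError(ValueError):
    """Genes, masks and depth tracks that cannot be reconciled."""


@dataclass(frozen=True)
class PloidyFactor:
    """Flow-cytometry calibration: factor = DNA content (in n) / 2."""

    dna_content_n: float
    factor: float


def ploidy_factor(dna_content_n: float) -> PloidyFactor:
    """Ploidy-specific factor from flow-cytometry DNA content.

    A 2n genome maps to 1, 3n to 1.5, 4n to 2: normalized coverage is on
    a "half the genome" scale because normalization divides by the
    sample median, so absolute copies need the content/2 rescale.
    """
    if dna_content_n <= 0:
        raise ValueError(f"DNA content must be positive, got {dna_content_n}")
    return PloidyFactor(dna_content_n=float(dna_content_n), factor=dna_content_n / 2.0)


def _mask_lookup(mask: list[tuple[str, int, int]] | None) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in mask or []:
        out.setdefault(chrom, []).append((start, end))
    return out


def gene_median_coverage(
    track: CoverageTrack,
    ref: ReferenceModel,
    mask: list[tuple[str, int, int]] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Interpolated median per-base depth of every gene, mask-aware.

    ``mask`` holds excluded intervals (chrom, start, end) in 0-based
    half-open coordinates, e.g. repeat annotations; masked bases do not
    contribute to a gene's median. Genes left with zero unmasked bases
    are dropped and returned in the second element.

    Returns ``(table, dropped_gene_ids)`` where the table has one row per
    surviving gene with its ``median_depth`` filled (``normalized`` NaN
    until :func:`normalize_gene_coverage`).
    """
    masked = _mask_lookup(mask)
    rows = []
    dropped: list[str] = []
    for g in ref.genes:
        if g.chromosome not in track:
            raise CoverageInputError(
                f"gene {g.gene_id} lies on {g.chromosome}, absent from the depth track"
            )
        depths = track[g.chromosome][g.start : g.end]
        keep = np.ones(g.end - g.start, dtype=bool)
        for m_start, m_end in masked.get(g.chromosome, []):
            lo = max(m_start, g.start) - g.start
            hi = min(m_end, g.end) - g.start
            if hi > lo:
                keep[lo:hi] = False
        if not keep.any():
            log.info("gene %s fully masked; dropped", g.gene_id)
            dropped.append(g.gene_id)
            continue
        rows.append(
            (
                g.gene_id,
                g.chromosome,
                ref.subgenome_of(g.chromosome),
                float(np.median(depths[keep])),
                np.nan,
            )
        )
    if not rows:
        raise CoverageInputError("every gene was masked out; no coverage table")
    return pd.DataFrame(rows, columns=GENE_COVERAGE_COLUMNS), dropped


def normalize_gene_coverage(table: pd.DataFrame) -> pd.DataFrame:
    """Divide gene medians by the sample-wide median over all genes.

    Scale-invariant by construction: rescaling every depth by a constant
    leaves the normalized column unchanged.
    """
    sample_median = float(np.median(table["median_depth"]))
    if sample_median <= 0:
        raise CoverageInputError(
            f"sample-wide median gene coverage is {sample_median}; cannot normalize"
        )
    out = table.copy()
    out["normalized"] = out["median_depth"] / sample_median
    return out


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def estimate_chromosome_copies(
    table: pd.DataFrame,
    factor: PloidyFactor,
    all_chromosomes: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-chromosome integer copy calls (the karyotype table).

    chromosome_median is the interpolated median of normalized gene
    coverage over the chromosome's genes; raw_copies multiplies by the
    ploidy factor; integer_copies rounds half away from zero. Calls
    whose raw value sits further than ``UNCERTAIN_MARGIN`` from the
    nearest integer are flagged ``uncertain`` (a chimeric or mosaic
    chromosome signature) but still reported.

    ``all_chromosomes`` (name, subgenome pairs, e.g. from the reference)
    lets chromosomes with zero surviving genes be reported as uncallable
    instead of silently vanishing.
    """
    if table["normalized"].isna().any():
        raise CoverageInputError("table is not normalized; run normalize_gene_coverage")
    rows = []
    for (chrom, sub), grp in table.groupby(["chromosome", "subgenome"], sort=False):
        med = float(np.median(grp["normalized"]))
        raw = med * factor.factor
        call = int(_round_half_away(np.array([raw]))[0])
        rows.append(
            {
                "chromosome": chrom,
                "subgenome": sub,
                "chromosome_median": med,
                "raw_copies": raw,
                "integer_copies": call,
                "n_genes": len(grp),
                "uncertain": bool(abs(raw - call) > UNCERTAIN_MARGIN),
                "callable": True,
            }
        )
    seen = {r["chromosome"] for r in rows}
    for name, sub in all_chromosomes or []:
        if name not in seen:
            rows.append(
                {
                    "chromosome": name,
                    "subgenome": sub,
                    "chromosome_median": np.nan,
                    "raw_copies": np.nan,
                    "integer_copies": -1,
                    "n_genes": 0,
                    "uncertain": True,
                    "callable": False,
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["subgenome", "chromosome"], ignore_index=True)


def gene_copy_numbers(
    table: pd.DataFrame,
    factor: PloidyFactor,
    target_genes: list[str],
    karyotype: pd.DataFrame | None = None,
    dropped_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Copy-number calls for individual genes (e.g. aroma-gene targets).

    Gene copy = normalized coverage x ploidy factor, rounded as for
    chromosomes. When a karyotype table is supplied, the gene's
    chromosome call is attached and a ``concordant`` flag compares the
    two. Genes dropped at the masking stage come back flagged
    uncallable; genes never annotated raise ``KeyError``.
    """
    dropped = set(dropped_genes or [])
    by_gene = table.set_index("gene_id")
    chrom_call = (
        karyotype.set_index("chromosome")["integer_copies"] if karyotype is not None else None
    )
    rows = []
    for gid in target_genes:
        if gid in dropped:
            rows.append(
                {
                    "gene_id": gid,
                    "chromosome": None,
                    "raw_copies": np.nan,
                    "integer_copies": -1,
                    "chromosome_copies": -1,
                    "concordant": False,
                    "callable": False,
                }
            )
            continue
        if gid not in by_gene.index:
            raise KeyError(f"unknown gene_id {gid!r}")
        rec = by_gene.loc[gid]
        raw = float(rec["normalized"]) * factor.factor
        call = int(_round_half_away(np.array([raw]))[0])
        ccall = int(chrom_call[rec["chromosome"]]) if chrom_call is not None else -1
        rows.append(
            {
                "gene_id": gid,
                "chromosome": rec["chromosome"],
                "raw_copies": raw,
                "integer_copies": call,
                "chromosome_copies": ccall,
                "concordant": (call == ccall) if chrom_call is not None else False,
                "callable": True,
            }
        )
    return pd.DataFrame(rows)
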