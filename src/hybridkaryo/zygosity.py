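"""SNP filtering, zygosity classification, and chimera detection.

SNP records carry allele depths plus flank-read support (reads whose
alignment extends strictly left / right of the site). Records failing
the flank filter are discarded; the rest are classified from the alt
allele fraction: heterozygous when both alleles appear in roughly equal
proportions, homozygous when essentially all reads carry the non-
reference allele, ambiguous otherwise. Per-chromosome zygosity then
corroborates copy number independently of coverage — heterozygous SNPs
require two homologs, so an almost-all-het chromosome must be >= 2
copies and an all-hom one is consistent with a single copy — and a
windowed segmentation flags chimeric chromosomes whose zygosity switches
state along their length (loss-of-heterozygosity breakpoints).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ReferenceModel

DEFAULT_MIN_FLANK = 5
DEFAULT_HET_BAND = (0.25, 0.75)
DEFAULT_HOM_MIN = 0.90
DEFAULT_MIN_SNPS = 20

HET, HOM, AMBIGUOUS = "heterozygous", "homozygous", "ambiguous"


class VariantInputError(ValueError):
    pass


def filter_variants(records: pd.DataFrame, min_flank: int = DEFAULT_MIN_FLANK) -> pd.DataFrame:
    """Keep records with at least ``min_flank`` reads on each flank.

    Records with fewer than five left- and right-aligning reads are
    poorly supported call artefacts; the default drops them. Survivors
    are monotonically non-increasing in ``min_flank``.
    """
    if min_flank < 0:
        raise ValueError(f"min_flank must be >= 0, got {min_flank}")
    keep = (records["LEFT_FLANK"] >= min_flank) & (records["RIGHT_FLANK"] >= min_flank)
    return records.loc[keep].reset_index(drop=True)


def classify_zygosity(
    records: pd.DataFrame,
    het_band: tuple[float, float] = DEFAULT_HET_BAND,
    hom_min: float = DEFAULT_HOM_MIN,
) -> pd.DataFrame:
    """Call het/hom/ambiguous from the alt allele fraction.

    "Equal proportions" is operationalised as alt fraction within
    ``het_band`` and "only the non-reference allele" as >= ``hom_min``;
    the gap is an explicit ambiguous class, excluded from summaries but
    tallied. Every record gets exactly one label.
    """
    total = records["AD_REF"] + records["AD_ALT"]
    if (total <= 0).any():
        bad = records.loc[total <= 0]
        raise VariantInputError(
            f"{len(bad)} record(s) with zero allele depth cannot be classified"
        )
    out = records.copy()
    frac = records["AD_ALT"] / total
    lo, hi = het_band
    out["ALT_FRAC"] = frac
    out["CALL"] = np.select(
        [(frac >= lo) & (frac <= hi), frac >= hom_min], [HET, HOM], default=AMBIGUOUS
    )
    return out


def summarize_by_chromosome(
    calls: pd.DataFrame, min_snps: int = DEFAULT_MIN_SNPS
) -> pd.DataFrame:
    """Per-chromosome zygosity tallies and copy-number corroboration.

    A chromosome dominated by heterozygous SNPs (het fraction >= 0.8
    among unambiguous calls) is corroborated as carrying >= 2 copies;
    one with essentially none (<= 0.05) as a single copy; anything in
    between — or with fewer than ``min_snps`` informative records — is
    indeterminate (possible chimera or low support).
    """
    rows = []
    for (chrom, sub), grp in calls.groupby(["CHROM", "SUBGENOME"], sort=False):
        n_het = int((grp["CALL"] == HET).sum())
        n_hom = int((grp["CALL"] == HOM).sum())
        n_amb = int((grp["CALL"] == AMBIGUOUS).sum())
        informative = n_het + n_hom
        het_fraction = n_het / informative if informative else np.nan
        if informative < min_snps:
            corroborated = "indeterminate"
        elif het_fraction >= 0.8:
            corroborated = ">=2"
        elif het_fraction <= 0.05:
            corroborated = "1"
        else:
            corroborated = "indeterminate"
        rows.append(
            {
                "chromosome": chrom,
                "subgenome": sub,
                "n_het": n_het,
                "n_hom": n_hom,
                "n_ambiguous": n_amb,
                "het_fraction": het_fraction,
                "corroborated_copies": corroborated,
            }
        )
    return pd.DataFrame(rows)


def subgenome_snp_fraction(calls: pd.DataFrame) -> dict[str, float]:
    """Share of SNP records per subgenome (sums to 1 over those present)."""
    if calls.empty:
        raise VariantInputError("no SNP records; cannot summarize subgenome shares")
    counts = calls["SUBGENOME"].value_counts()
    return (counts / counts.sum()).to_dict()


@dataclass(frozen=True)
class HeterozygosityRatio:
    ratio: float  # Scer density / Seub density; math.inf when undefined
    density_scer: float  # het SNPs per bp over >= 2-copy Scer chromosomes
    density_seub: float
    undefined: bool  # denominator density was zero (or no eligible sequence)


def heterozygosity_ratio(
    calls: pd.DataFrame,
    ref: ReferenceModel,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> HeterozygosityRatio:
    """Scer:Seub per-bp heterozygous-SNP density ratio.

    Densities are computed only over chromosomes corroborated as >= 2
    copies: heterozygous sites are unobservable on single-copy
    chromosomes, so including their length would bias the ratio
    downward. A zero (or unmeasurable) Seub density yields an infinite
    sentinel with ``undefined=True``, never an exception.
    """
    subs = {s for _, s, _ in ref.chromosomes}
    for needed in ("Scer", "Seub"):
        if needed not in subs:
            raise VariantInputError(f"reference has no {needed} chromosomes")
    summary = summarize_by_chromosome(calls, min_snps=min_snps)
    eligible = set(summary.loc[summary["corroborated_copies"] == ">=2", "chromosome"])
    dens = {}
    for sub in ("Scer", "Seub"):
        length = sum(
            ln for name, s, ln in ref.chromosomes if s == sub and name in eligible
        )
        n_het = int(
            (
                (calls["CALL"] == HET)
                & (calls["SUBGENOME"] == sub)
                & calls["CHROM"].isin(eligible)
            ).sum()
        )
        dens[sub] = n_het / length if length else 0.0
    if dens["Seub"] == 0.0:
        return HeterozygosityRatio(math.inf, dens["Scer"], dens["Seub"], True)
    return HeterozygosityRatio(
        dens["Scer"] / dens["Seub"], dens["Scer"], dens["Seub"], False
    )


@dataclass(frozen=True)
class ChimeraSegment:
    chromosome: str
    start: int  # 1-based position of the segment's first SNP
    end: int  # 1-based position of its last SNP
    state: str  # "het" | "hom"
    n_snps: int
    n_windows: int
    breakpoint: float | None  # midpoint to the next segment; None on the last


def detect_chimera(
    calls: pd.DataFrame,
    window_snps: int = 25,
    min_segment_windows: int = 3,
) -> list[ChimeraSegment]:
    """Windowed majority-vote segmentation of one chromosome's zygosity.

    Unambiguous calls are cut, in position order, into consecutive
    windows of ``window_snps`` sites (a trailing remainder shorter than
    a full window is ignored); each window is labelled het- or
    hom-dominant by majority, and runs of same-label windows are merged
    into segments. A chimera is reported iff at least two segments each
    span ``min_segment_windows`` windows and adjacent such segments
    disagree in state; the breakpoint estimate is the midpoint between
    the last SNP of one segment and the first SNP of the next. Fewer
    than two windows of data is a no-call (empty list), not an error.
    """
    chroms = calls["CHROM"].unique()
    if len(chroms) != 1:
        raise VariantInputError(
            f"detect_chimera expects one chromosome, got {sorted(map(str, chroms))}"
        )
    chrom = str(chroms[0])
    informative = calls.loc[calls["CALL"].isin([HET, HOM])].sort_values("POS")
    n_windows = len(informative) // window_snps
    if n_windows < 2:
        return []
    is_het = (informative["CALL"] == HET).to_numpy()[: n_windows * window_snps]
    pos = informative["POS"].to_numpy()[: n_windows * window_snps]
    win_frac = is_het.reshape(n_windows, window_snps).mean(axis=1)
    labels = np.where(win_frac >= 0.5, "het", "hom")

    # merge consecutive same-label windows into candidate segments
    segments: list[dict] = []
    for w, lab in enumerate(labels):
        if segments and segments[-1]["state"] == lab:
            segments[-1]["windows"].append(w)
        else:
            segments.append({"state": lab, "windows": [w]})

    stable = [s for s in segments if len(s["windows"]) >= min_segment_windows]
    if len(stable) < 2 or all(
        a["state"] == b["state"] for a, b in zip(stable, stable[1:])
    ):
        return []

    out: list[ChimeraSegment] = []
    for i, s in enumerate(stable):
        first_w, last_w = s["windows"][0], s["windows"][-1]
        seg_pos = pos[first_w * window_snps : (last_w + 1) * window_snps]
        if i + 1 < len(stable):
            next_first = pos[stable[i + 1]["windows"][0] * window_snps]
            breakpoint = (float(seg_pos[-1]) + float(next_first)) / 2.0
        else:
            breakpoint = None
        out.append(
            ChimeraSegment(
                chromosome=chrom,
                start=int(seg_pos[0]),
                end=int(seg_pos[-1]),
                state=str(s["state"]),
                n_snps=len(seg_pos),
                n_windows=len(s["windows"]),
                breakpoint=breakpoint,
            )
        )
    return out
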