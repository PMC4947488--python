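"""Synthetic hybrid-genome dataset generator with known ground truth.

Emulates the sequencing signals of an interspecific *S. cerevisiae* ×
*S. eubayanus* hybrid at desk scale: a concatenated two-parent reference
(chromosomes tagged ``Scer``/``Seub``), copy-number-proportional per-base
read depth with negative-binomial overdispersion, SNP records whose
zygosity follows chromosome copy number (heterozygous sites require two
homologs), an asymmetric heterozygosity density between the subgenomes,
optional chimeric chromosomes with a zygosity breakpoint, and
uniparentally inherited mitochondrial coverage.

Every stochastic quantity is driven by :class:`TruthSpec.seed` through
per-operation, per-chromosome seed sequences, so outputs are reproducible
bit-for-bit and independent of call order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

SUBGENOMES = ("Scer", "Seub")
Subgenome = Literal["Scer", "Seub"]
Regime = Literal["het", "hom"]

# seed-stream tags: keep each simulation stage statistically independent
_TAG_COVERAGE = 1
_TAG_VARIANTS = 2
_TAG_MITO = 3

#: per-read error rate used for homozygous-site allele draws; makes the
#: alt fraction land near 0.99 instead of exactly 1 so classification
#: bands are actually exercised.
HOM_ALT_PROB = 0.99

#: probability that a read covering a SNP starts strictly left of it
#: (150 bp read geometry; only a read starting exactly on the site fails).
FLANK_PROB = 149.0 / 150.0

READ_LENGTH = 150


class SpecError(ValueError):
    """A TruthSpec violates its invariants."""


@dataclass(frozen=True)
class ChromosomeSpec:
    """One simulated chromosome: name, parental subgenome, size, truth."""

    name: str
    subgenome: Subgenome
    length: int
    true_copies: int


@dataclass(frozen=True)
class ChimeraSpec:
    """A zygosity breakpoint on one chromosome.

    Left/right regimes give the SNP zygosity on each side of the
    breakpoint, modelling e.g. a partially lost homolog (het → hom).
    """

    chromosome: str
    breakpoint: int
    left_regime: Regime
    right_regime: Regime


@dataclass
class TruthSpec:
    """Complete ground-truth configuration for one synthetic hybrid.

    Parameters
    ----------
    seed
        Root seed; all randomness derives from it.
    chromosomes
        Nuclear chromosomes with their true copy numbers.
    per_copy_depth
        Mean read depth contributed by a single chromosome copy
        (reads/base).
    dispersion
        Negative-binomial size parameter ``r`` (variance = mu + mu^2/r).
        ``None`` selects ``r = mu`` so that variance = 2 x mean, a
        standard mild overdispersion for short-read depth.
    het_snp_density, hom_snp_density
        Expected heterozygosity-capable / fixed-difference sites per bp,
        keyed by subgenome. Defaults encode a ~200:1 Scer:Seub
        heterozygosity asymmetry.
    chimera_specs
        Zygosity breakpoints overriding the copy-number-derived regime.
    mito_origin, mito_depth, mito_background
        Which parent's mitochondrial genome was retained, its mean
        coverage, and the trace background on the other parent's
        (models index-hopping noise so callers must use a ratio).
    """

    seed: int
    chromosomes: list[ChromosomeSpec]
    per_copy_depth: float = 25.0
    dispersion: float | None = None
    genes_per_chromosome: int = 25
    gene_length: int = 2000
    het_snp_density: dict[str, float] = field(
        default_factory=lambda: {"Scer": 2e-3, "Seub": 1e-5}
    )
    hom_snp_density: dict[str, float] = field(
        default_factory=lambda: {"Scer": 5e-5, "Seub": 5e-5}
    )
    chimera_specs: list[ChimeraSpec] = field(default_factory=list)
    mito_origin: Subgenome = "Seub"
    mito_depth: float = 100.0
    mito_background: float = 0.2

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.chromosomes:
            raise SpecError("TruthSpec needs at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise SpecError("chromosome names must be unique")
        for c in self.chromosomes:
            if c.subgenome not in SUBGENOMES:
                raise SpecError(f"unknown subgenome {c.subgenome!r} on {c.name}")
            if c.length <= 0:
                raise SpecError(f"chromosome {c.name} has non-positive length")
            if c.true_copies < 0:
                raise SpecError(f"chromosome {c.name} has negative copy number")
        if self.per_copy_depth < 0:
            raise SpecError("per_copy_depth must be >= 0")
        if self.dispersion is not None and self.dispersion <= 0:
            raise SpecError("dispersion must be > 0")
        for dens in (self.het_snp_density, self.hom_snp_density):
            if any(v < 0 for v in dens.values()):
                raise SpecError("SNP densities must be >= 0")
        by_name = {c.name: c for c in self.chromosomes}
        for ch in self.chimera_specs:
            if ch.chromosome not in by_name:
                raise SpecError(f"chimera on unknown chromosome {ch.chromosome!r}")
            if not 0 < ch.breakpoint < by_name[ch.chromosome].length:
                raise SpecError(
                    f"chimera breakpoint {ch.breakpoint} outside {ch.chromosome}"
                )
            if ch.left_regime not in ("het", "hom") or ch.right_regime not in (
                "het",
                "hom",
            ):
                raise SpecError("chimera regimes must be 'het' or 'hom'")
        if self.mito_origin not in SUBGENOMES:
            raise SpecError(f"mito_origin must be one of {SUBGENOMES}")
        if self.mito_depth < 0 or self.mito_background < 0:
            raise SpecError("mitochondrial depths must be >= 0")
        if self.genes_per_chromosome < 1 or self.gene_length < 1:
            raise SpecError("gene layout parameters must be positive")

    def chromosome(self, name: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TruthSpec":
        d = dict(d)
        d["chromosomes"] = [ChromosomeSpec(**c) for c in d["chromosomes"]]
        d["chimera_specs"] = [ChimeraSpec(**c) for c in d.get("chimera_specs", [])]
        return cls(**d)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chromosome: str
    start: int  # 0-based, half-open
    end: int


@dataclass
class ReferenceModel:
    """Concatenated two-parent reference: chromosome table + gene annotation."""

    chromosomes: list[tuple[str, str, int]]  # (name, subgenome, length)
    genes: list[Gene]
    mito_contigs: dict[str, tuple[str, int]]  # subgenome -> (contig name, length)

    @property
    def chromosome_names(self) -> list[str]:
        return [name for name, _, _ in self.chromosomes]

    def subgenome_of(self, chrom: str) -> str:
        for name, sub, _ in self.chromosomes:
            if name == chrom:
                return sub
        raise KeyError(chrom)

    def length_of(self, chrom: str) -> int:
        for name, _, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def genes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.gene_id, g.chromosome, g.start, g.end) for g in self.genes],
            columns=["gene_id", "chromosome", "start", "end"],
        )


class CoverageTrack:
    """Per-base read depth per chromosome (0-based internal indexing)."""

    def __init__(self, depths: dict[str, np.ndarray]):
        self.depths = {c: np.asarray(d) for c, d in depths.items()}

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.depths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.depths

    def chromosomes(self) -> list[str]:
        return list(self.depths)

    def mean_depth(self, chrom: str) -> float:
        return float(np.mean(self.depths[chrom]))

    def __eq__(self, other) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        return set(self.depths) == set(other.depths) and all(
            np.array_equal(self.depths[c], other.depths[c]) for c in self.depths
        )


VARIANT_COLUMNS = [
    "CHROM",
    "SUBGENOME",
    "POS",
    "REF",
    "ALT",
    "DP",
    "AD_REF",
    "AD_ALT",
    "LEFT_FLANK",
    "RIGHT_FLANK",
]


def _rng(spec: TruthSpec, tag: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, tag, index]))


def generate_reference(spec: TruthSpec) -> ReferenceModel:
    """Lay out the concatenated reference implied by a TruthSpec.

    Genes are evenly spaced and non-overlapping: each chromosome is cut
    into ``genes_per_chromosome`` equal slots and one gene is centred in
    each slot. Deterministic for a given spec.
    """
    spec.validate()
    genes: list[Gene] = []
    for c in spec.chromosomes:
        genic = spec.genes_per_chromosome * spec.gene_length
        if genic > c.length:
            raise SpecError(
                f"chromosome {c.name}: {genic} bp of genes cannot fit in "
                f"{c.length} bp"
            )
        slot = c.length // spec.genes_per_chromosome
        offset = (slot - spec.gene_length) // 2
        for i in range(spec.genes_per_chromosome):
            start = i * slot + offset
            genes.append(
                Gene(f"{c.name}_g{i + 1:03d}", c.name, start, start + spec.gene_length)
            )
    mito = {"Scer": ("Scer_mito", 80_000), "Seub": ("Seub_mito", 70_000)}
    return ReferenceModel(
        chromosomes=[(c.name, c.subgenome, c.length) for c in spec.chromosomes],
        genes=genes,
        mito_contigs=mito,
    )


def _nb_depths(
    rng: np.random.Generator, mean: float, dispersion: float | None, size: int
) -> np.ndarray:
    """Negative-binomial depth draws with mean ``mean``; Poisson-like as r grows."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    r = mean if dispersion is None else dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_coverage(ref: ReferenceModel, spec: TruthSpec) -> CoverageTrack:
    """Draw per-base depth: NB(mean = copies x per_copy_depth) i.i.d. per base."""
    depths: dict[str, np.ndarray] = {}
    for idx, (name, _sub, length) in enumerate(ref.chromosomes):
        try:
            c = spec.chromosome(name)
        except KeyError:
            raise SpecError(f"no copy-number truth for chromosome {name!r}") from None
        rng = _rng(spec, _TAG_COVERAGE, idx)
        depths[name] = _nb_depths(
            rng, c.true_copies * spec.per_copy_depth, spec.dispersion, length
        )
    return CoverageTrack(depths)


_BASES = np.array(list("ACGT"))


def _alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref = rng.integers(0, 4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref], _BASES[alt]


def simulate_variants(ref: ReferenceModel, spec: TruthSpec) -> pd.DataFrame:
    """Emit SNP records whose zygosity tracks chromosome copy number.

    Heterozygosity-capable sites (per-subgenome density) become
    heterozygous records (alt reads ~ Binomial(DP, 0.5)) on chromosomes
    with >= 2 copies and homozygous records on single-copy chromosomes;
    fixed-difference sites are homozygous everywhere. A chimera spec
    overrides the regime on each side of its breakpoint. Chromosomes with
    zero copies yield no records. Flank-read support is drawn directly
    from local depth with 150 bp read geometry.
    """
    chimera_by_chrom = {c.chromosome: c for c in spec.chimera_specs}
    frames: list[pd.DataFrame] = []
    for idx, (name, sub, length) in enumerate(ref.chromosomes):
        c = spec.chromosome(name)
        if c.true_copies == 0:
            continue
        rng = _rng(spec, _TAG_VARIANTS, idx)
        mean_depth = c.true_copies * spec.per_copy_depth

        n_het = rng.poisson(spec.het_snp_density.get(sub, 0.0) * length)
        n_hom = rng.poisson(spec.hom_snp_density.get(sub, 0.0) * length)
        pos_het = rng.integers(0, length, size=n_het)
        pos_hom = rng.integers(0, length, size=n_hom)

        base_regime = "het" if c.true_copies >= 2 else "hom"
        if name in chimera_by_chrom:
            ch = chimera_by_chrom[name]
            regimes_het = np.where(
                pos_het < ch.breakpoint, ch.left_regime, ch.right_regime
            )
        else:
            regimes_het = np.full(n_het, base_regime, dtype=object)

        pos = np.concatenate([pos_het, pos_hom])
        regimes = np.concatenate([regimes_het, np.full(n_hom, "hom", dtype=object)])
        order = np.argsort(pos, kind="stable")
        pos, regimes = pos[order], regimes[order]

        dp = _nb_depths(rng, mean_depth, spec.dispersion, len(pos))
        keep = dp > 0
        pos, regimes, dp = pos[keep], regimes[keep], dp[keep]

        p_alt = np.where(regimes == "het", 0.5, HOM_ALT_PROB)
        ad_alt = rng.binomial(dp, p_alt)
        left = rng.binomial(dp, FLANK_PROB)
        right = rng.binomial(dp, FLANK_PROB)
        ref_b, alt_b = _alleles(rng, len(pos))

        frames.append(
            pd.DataFrame(
                {
                    "CHROM": name,
                    "SUBGENOME": sub,
                    "POS": pos + 1,  # 1-based output convention
                    "REF": ref_b,
                    "ALT": alt_b,
                    "DP": dp,
                    "AD_REF": dp - ad_alt,
                    "AD_ALT": ad_alt,
                    "LEFT_FLANK": left,
                    "RIGHT_FLANK": right,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    return pd.concat(frames, ignore_index=True)[VARIANT_COLUMNS]


def simulate_mito(ref: ReferenceModel, spec: TruthSpec) -> tuple[float, float]:
    """Mean mitochondrial depth on (Scer mito, Seub mito).

    The retained parent's contig gets NB coverage at ``mito_depth``; the
    other gets Poisson background at ``mito_background``.
    """
    means = {}
    for i, sub in enumerate(SUBGENOMES):
        rng = _rng(spec, _TAG_MITO, i)
        _, length = ref.mito_contigs[sub]
        if sub == spec.mito_origin:
            d = _nb_depths(rng, spec.mito_depth, spec.dispersion, length)
        else:
            d = rng.poisson(spec.mito_background, size=length)
        means[sub] = float(np.mean(d))
    return means["Scer"], means["Seub"]


def hybrid_archetypes(
    seed: int = 0,
    per_copy_depth: float = 25.0,
    chrom_length: int = 100_000,
    genes_per_chromosome: int = 25,
    gene_length: int = 2000,
) -> dict[str, tuple[TruthSpec, float]]:
    """The three de novo lager-hybrid karyotype archetypes.

    Returns ``{name: (TruthSpec, flow-cytometry DNA content in n)}`` for
    an allotetraploid (both subgenomes duplicated, one Seub chromosome
    reduced to a single copy), an allotriploid (Scer duplicated except
    one chromosome, Seub single-copy) and an allodiploid (one chromosome
    set from each parent, one Scer chromosome lost outright) — 33
    chromosomes in total. The allotriploid layout balances gene counts
    between the 2-copy and 1-copy classes so the sample-wide median of
    normalized gene coverage sits midway between the two depth levels,
    which is what makes the 1.5x ploidy factor resolve integer copies.
    """

    def chroms(prefix: str, sub: str, n: int, copies: list[int]) -> list[ChromosomeSpec]:
        return [
            ChromosomeSpec(f"{prefix}{i + 1:02d}", sub, chrom_length, copies[i])
            for i in range(n)
        ]

    common = dict(
        per_copy_depth=per_copy_depth,
        genes_per_chromosome=genes_per_chromosome,
        gene_length=gene_length,
    )
    tetra = TruthSpec(
        seed=seed,
        chromosomes=chroms("sc", "Scer", 6, [2] * 6)
        + chroms("se", "Seub", 5, [2, 2, 2, 2, 1]),
        mito_origin="Seub",
        **common,
    )
    tri = TruthSpec(
        seed=seed,
        chromosomes=chroms("sc", "Scer", 6, [2, 2, 2, 2, 2, 1])
        + chroms("se", "Seub", 4, [1] * 4),
        mito_origin="Seub",
        **common,
    )
    di = TruthSpec(
        seed=seed,
        chromosomes=chroms("sc", "Scer", 7, [1, 1, 1, 1, 1, 1, 0])
        + chroms("se", "Seub", 5, [1] * 5),
        mito_origin="Scer",
        **common,
    )
    return {
        "allotetraploid": (tetra, 4.0),
        "allotriploid": (tri, 3.0),
        "allodiploid": (di, 2.0),
    }
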