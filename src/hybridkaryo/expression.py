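"""qPCR quantification and expression–phenotype statistics.

Covers the downstream quantitative toolbox: Pfaffl efficiency-corrected
relative copy-number ratios (with standard-curve efficiency calibration
E = 10^(-1/m)), extraction of per-strain maximum transcription signals
across fermentation time points, ordinary-least-squares fits of aroma
compound concentrations on the two parental orthologues' maximum
transcription (Y = beta_Sc*X_Sc + beta_Se*X_Se + beta_0, with ANOVA
F-test and per-coefficient t-tests; coefficients with p > 0.05 are
marked NS), the Pearson correlation between standardized transcription
levels and gene copy number, and per-compound z-score matrices for
aroma heat maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

NS_ALPHA = 0.05


class ExpressionInputError(ValueError):
    pass


@dataclass(frozen=True)
class QpcrAssay:
    """Efficiencies and ΔC_T (control − sample) for target and reference."""

    E_target: float
    E_reference: float
    dCT_target: float
    dCT_reference: float

    def __post_init__(self) -> None:
        if self.E_target <= 1 or self.E_reference <= 1:
            raise ValueError("amplification efficiencies must be > 1")


def amplification_efficiency(slope_m: float) -> float:
    """E = 10^(−1/m) from the slope of the C_T-vs-log10(dilution) line.

    A perfectly doubling assay has m = −1/log10(2) ≈ −3.32; slopes must
    be negative (more template ⇒ earlier threshold cycle).
    """
    if slope_m >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope_m}")
    return 10.0 ** (-1.0 / slope_m)


def pfaffl_ratio(a: QpcrAssay) -> float:
    """Efficiency-corrected relative ratio: E_t^ΔCT_t / E_r^ΔCT_r."""
    return (a.E_target**a.dCT_target) / (a.E_reference**a.dCT_reference)


def max_transcription(
    profile: pd.DataFrame,
    expected_timepoints: list[str] | None = None,
) -> pd.DataFrame:
    """Per (strain, gene) maximum normalized signal over time points.

    Expects columns ``strain, gene, timepoint, signal``. Pairs missing
    some of ``expected_timepoints`` still use whatever is available but
    come back with ``complete=False``.
    """
    if profile.empty:
        raise ExpressionInputError("empty transcription profile")
    rows = []
    for (strain, gene), grp in profile.groupby(["strain", "gene"], sort=False):
        complete = (
            set(expected_timepoints).issubset(set(grp["timepoint"]))
            if expected_timepoints
            else True
        )
        rows.append(
            {
                "strain": strain,
                "gene": gene,
                "max_signal": float(grp["signal"].max()),
                "n_timepoints": len(grp),
                "complete": complete,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of one aroma compound on one gene's two orthologues."""

    beta_sc: float
    beta_se: float
    beta_0: float
    p_sc: float
    p_se: float
    p_0: float
    adj_r_squared: float
    f_pvalue: float
    conf_int: dict[str, tuple[float, float]]  # 95 % CIs keyed sc/se/intercept

    def significance(self, alpha: float = NS_ALPHA) -> dict[str, str]:
        """Table-style marks: the coefficient value, or "NS" when p > alpha."""
        return {
            name: ("NS" if p > alpha else f"{beta:.3g}")
            for name, beta, p in [
                ("beta_sc", self.beta_sc, self.p_sc),
                ("beta_se", self.beta_se, self.p_se),
            ]
        }


def fit_expression_aroma(
    y: np.ndarray | pd.Series,
    x_sc: np.ndarray | pd.Series,
    x_se: np.ndarray | pd.Series,
) -> RegressionFit:
    """Y = beta_Sc·X_Sc + beta_Se·X_Se + beta_0, by OLS with ANOVA.

    Predictors are the per-strain maximum transcription levels of the
    two parental orthologues (raw scale); Y the compound concentration.
    Needs >= 4 observations (three parameters plus one residual degree
    of freedom) and a full-rank design.
    """
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.asarray(x_sc, float), np.asarray(x_se, float)])
    if len(y) < 4:
        raise ExpressionInputError(f"need >= 4 strains, got {len(y)}")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ExpressionInputError("collinear predictors: design matrix is rank-deficient")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionFit(
        beta_sc=float(fit.params[1]),
        beta_se=float(fit.params[2]),
        beta_0=float(fit.params[0]),
        p_sc=float(fit.pvalues[1]),
        p_se=float(fit.pvalues[2]),
        p_0=float(fit.pvalues[0]),
        adj_r_squared=float(fit.rsquared_adj),
        f_pvalue=float(fit.f_pvalue),
        conf_int={
            "intercept": (float(ci[0, 0]), float(ci[0, 1])),
            "sc": (float(ci[1, 0]), float(ci[1, 1])),
            "se": (float(ci[2, 0]), float(ci[2, 1])),
        },
    )


def copy_expression_correlation(
    signals: pd.DataFrame, copies: pd.DataFrame
) -> tuple[float, float]:
    """Pearson r between standardized transcription and gene copy number.

    ``signals`` has columns ``strain, gene, signal`` (one average or
    maximum level per pair); ``copies`` has ``strain, gene, copies``.
    Each gene's signals are standardized to zero mean / unit variance
    across strains before pooling, so genes with different absolute
    signal scales contribute comparably. Returns (r, two-sided p).
    """
    merged = signals.merge(copies, on=["strain", "gene"], how="inner")
    if len(merged) < 3:
        raise ExpressionInputError("need >= 3 pooled (strain, gene) pairs")

    def _standardize(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ExpressionInputError(
                "zero variance in a gene's signals; correlation undefined"
            )
        return (x - x.mean()) / sd

    z = merged.groupby("gene", sort=False)["signal"].transform(_standardize)
    if merged["copies"].std(ddof=1) == 0:
        raise ExpressionInputError("zero variance in copy numbers; correlation undefined")
    r, p = scipy.stats.pearsonr(z, merged["copies"])
    return float(r), float(p)


def zscore_matrix(aromas: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-compound z-scores across strains: z = (x − μ)/σ.

    ``aromas`` has columns ``strain, compound, concentration``. σ uses
    the sample (n−1) denominator. Compounds with zero spread get all-
    zero z-scores and are returned in the flagged list. Output is a
    strain × compound matrix.
    """
    wide = aromas.pivot(index="strain", columns="compound", values="concentration")
    if len(wide) < 2:
        raise ExpressionInputError("z-scores need >= 2 strains per compound")
    flagged: list[str] = []
    out = {}
    for compound in wide.columns:
        x = wide[compound].astype(float)
        sd = x.std(ddof=1)
        # constant columns can yield sd ~ 1e-16 from accumulated rounding
        if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, abs(float(x.mean()))):
            flagged.append(str(compound))
            out[compound] = x * 0.0
        else:
            out[compound] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=wide.index), flagged
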