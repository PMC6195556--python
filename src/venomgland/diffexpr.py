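"""Consensus differential expression with negative-binomial GLMs.

The design crosses each transcript with a set of contrasts: one continuous
contrast for body size (SVL) and one pairwise contrast per unordered pair
of observed levels of each discrete factor (sex, subspecies, mitochondrial
lineage, nuclear lineage).  On the published eight-individual design this
yields 17 contrasts.

Each (transcript, contrast) is tested twice from the same log-link NB fit:
a Wald test on the contrast coefficient and a likelihood-ratio test against
the intercept-only model.  The two flavors emulate the common practice of
requiring agreement between two independent count-model engines; a result
is consensus-significant only when both FDR-adjusted tests clear alpha.

Per-gene dispersions are moment-estimated on normalized counts and shrunk
toward a parametric mean-dispersion trend; that pooling is what keeps both
tests near their nominal size with only a handful of libraries.  Wald
statistics are referred to the standard normal and deviance differences to
chi-square with one degree of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metadata import validate_factor_table

ALPHA = 0.05
DISCRETE_FACTORS = ("sex", "subspecies", "mtdna_lineage", "nontoxin_lineage")
DISPERSION_SHRINKAGE = 0.15  # weight on the per-gene estimate
MIN_DISPERSION = 1e-6


@dataclass(frozen=True)
class Contrast:
    factor: str
    kind: str  # "pairwise" | "continuous"
    level_a: Optional[str] = None
    level_b: Optional[str] = None

    @property
    def name(self) -> str:
        if self.kind == "continuous":
            return self.factor
        return f"{self.factor}:{self.level_a}_vs_{self.level_b}"


def enumerate_contrasts(factor_table: pd.DataFrame) -> List[Contrast]:
    """One continuous contrast for SVL plus every unordered level pair of
    each discrete factor with data.  Factors with fewer than two observed
    levels contribute nothing (with a warning)."""
    table = validate_factor_table(factor_table)
    if table.empty:
        raise ValueError("factor table is empty")
    contrasts: List[Contrast] = [Contrast(factor="svl_cm", kind="continuous")]
    for fac in DISCRETE_FACTORS:
        levels = sorted(table[fac].astype(str).unique())
        if len(levels) < 2:
            warnings.warn(f"factor {fac} has <2 observed levels; skipped")
            continue
        for a, b in combinations(levels, 2):
            contrasts.append(
                Contrast(factor=fac, kind="pairwise", level_a=a, level_b=b)
            )
    return contrasts


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (geometric-mean reference);
    falls back to relative totals when too few all-positive genes exist."""
    x = counts.to_numpy(dtype=float)
    pos = (x > 0).all(axis=1)
    if pos.sum() >= 5:
        logx = np.log(x[pos])
        ref = logx.mean(axis=1)
        sf = np.exp(np.median(logx - ref[:, None], axis=0))
    else:
        totals = x.sum(axis=0)
        sf = totals / np.exp(np.log(totals[totals > 0]).mean())
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns)


def estimate_dispersions(
    counts: pd.DataFrame,
    sf: pd.Series,
    design: Optional[np.ndarray] = None,
    shrinkage: float = DISPERSION_SHRINKAGE,
) -> pd.Series:
    """Per-gene NB dispersions shrunk toward a parametric trend.

    The raw per-gene estimate is moment-based on the residual variance of
    normalized counts around the fitted design (so genuinely differential
    genes do not inflate their own dispersion):
    ``alpha = (resid_var - mean) / mean^2``.  The trend
    ``alpha(mu) = a0 + a1/mu`` is fit by least squares to binned medians
    (robust to differential-expression outliers); the final value is a
    log-space weighted average of gene and trend estimates.
    """
    norm = counts.div(sf, axis=1).to_numpy(dtype=float)
    n_genes, n = norm.shape
    if design is None:
        design = np.ones((n, 1))
    p = design.shape[1]
    hat = design @ np.linalg.pinv(design)
    resid = norm - norm @ hat.T
    dof = max(n - p, 1)
    var = (resid**2).sum(axis=1) / dof
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mu) / np.where(mu > 0, mu**2, np.nan)
    raw = np.where(np.isfinite(raw), raw, 0.0)
    ok = (mu > 0) & (raw > 0)
    if ok.sum() >= 10:
        # plain least squares: with design-aware residuals the raw
        # estimates have no DE outliers, and the mean-like fit keeps the
        # trend unbiased (a median fit under-shoots the skewed moment
        # estimator and makes the tests anticonservative)
        A = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(A, raw[ok], rcond=None)
        a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
        if a0 == 0.0 and a1 == 0.0:
            a0 = max(float(np.median(raw[ok])), MIN_DISPERSION)
    else:
        med = np.median(raw[ok]) if ok.any() else 0.1
        a0, a1 = max(med, MIN_DISPERSION), 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        trend = a0 + a1 / np.where(mu > 0, mu, np.nan)
    trend = np.where(np.isfinite(trend), trend, a0)
    trend = np.maximum(trend, MIN_DISPERSION)
    gene = np.maximum(raw, MIN_DISPERSION)
    alpha = np.exp(
        shrinkage * np.log(gene) + (1.0 - shrinkage) * np.log(trend)
    )
    return pd.Series(np.maximum(alpha, MIN_DISPERSION), index=counts.index)


@dataclass
class GeneFit:
    log2fc: float
    p_wald: float
    p_lrt: float
    converged: bool = True


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    alpha: float,
    offset: Optional[np.ndarray] = None,
):
    """Log-link negative-binomial GLM fit (IRLS via statsmodels)."""
    fam = sm.families.NegativeBinomial(alpha=max(alpha, MIN_DISPERSION))
    model = sm.GLM(y, X, family=fam, offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=100)


def test_contrast_gene(
    y: np.ndarray,
    X: np.ndarray,
    alpha_disp: float,
    offset: Optional[np.ndarray] = None,
) -> GeneFit:
    """Wald and LRT p-values for the last design column of one gene.

    The Wald statistic (coefficient over its standard error) is referred to
    the standard normal; the LRT refers the deviance difference against the
    intercept-only model to chi-square with one degree of freedom.
    """
    n, p = X.shape
    if y.sum() == 0:
        return GeneFit(log2fc=0.0, p_wald=1.0, p_lrt=1.0)
    try:
        full = fit_nb_glm(y, X, alpha_disp, offset)
        red = fit_nb_glm(y, X[:, :-1], alpha_disp, offset)
    except Exception:
        return GeneFit(log2fc=np.nan, p_wald=np.nan, p_lrt=np.nan, converged=False)
    beta = full.params[-1]
    se = full.bse[-1]
    if not np.isfinite(se) or se == 0:
        warnings.warn("zero standard error; Wald p set to 1")
        p_wald = 1.0
    else:
        p_wald = float(2.0 * stats.norm.sf(abs(beta / se)))
    dev_diff = max(red.deviance - full.deviance, 0.0)
    p_lrt = float(stats.chi2.sf(dev_diff, 1))
    return GeneFit(
        log2fc=float(beta / np.log(2.0)), p_wald=p_wald, p_lrt=p_lrt
    )


def adjust_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaN-safe; NaN stays NaN)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _design_for(contrast: Contrast, table: pd.DataFrame):
    """Sample subset and design matrix for one contrast; the tested term is
    the last column."""
    if contrast.kind == "continuous":
        inds = list(table.index)
        x = table["svl_cm"].astype(float).to_numpy()
        x = x - x.mean()
        X = np.column_stack([np.ones(len(inds)), x])
        return inds, X
    vals = table[contrast.factor].astype(str)
    mask = vals.isin([contrast.level_a, contrast.level_b])
    sub = table[mask]
    if sub[contrast.factor].astype(str).nunique() < 2:
        raise ValueError(f"contrast {contrast.name} has <2 observed levels")
    inds = list(sub.index)
    ind_b = (sub[contrast.factor].astype(str) == contrast.level_b).to_numpy()
    X = np.column_stack([np.ones(len(inds)), ind_b.astype(float)])
    return inds, X


def run_de(
    counts: pd.DataFrame,
    factor_table: pd.DataFrame,
    contrasts: Optional[Sequence[Contrast]] = None,
    alpha: float = ALPHA,
    shrinkage: float = DISPERSION_SHRINKAGE,
    fdr_scope: str = "per-contrast",
) -> pd.DataFrame:
    """Run the dual NB-GLM test for every transcript x contrast.

    ``counts`` holds (expected) read counts, transcripts x individuals.
    Returns a tidy frame with columns transcript_id, contrast, log2fc,
    p_wald, p_lrt, q_wald, q_lrt, consensus_significant.  FDR is applied
    within contrast by default (``fdr_scope='global'`` pools everything).
    """
    table = validate_factor_table(factor_table)
    if set(counts.columns) - set(table.index):
        raise ValueError("count columns not present in factor table")
    if contrasts is None:
        contrasts = enumerate_contrasts(table.loc[counts.columns])
    rows = []
    for contrast in contrasts:
        inds, X = _design_for(contrast, table.loc[counts.columns])
        sub = counts[inds]
        sf = size_factors(sub)
        offset = np.log(sf.to_numpy())
        disp = estimate_dispersions(sub, sf, design=X, shrinkage=shrinkage)
        for tid in sub.index:
            y = sub.loc[tid].to_numpy(dtype=float)
            fit = test_contrast_gene(y, X, float(disp[tid]), offset)
            rows.append(
                {
                    "transcript_id": tid,
                    "contrast": contrast.name,
                    "log2fc": fit.log2fc,
                    "p_wald": fit.p_wald,
                    "p_lrt": fit.p_lrt,
                }
            )
    res = pd.DataFrame(rows)
    if fdr_scope == "global":
        res["q_wald"] = adjust_fdr(res["p_wald"])
        res["q_lrt"] = adjust_fdr(res["p_lrt"])
    else:
        res["q_wald"] = np.nan
        res["q_lrt"] = np.nan
        for _, idx in res.groupby("contrast").groups.items():
            res.loc[idx, "q_wald"] = adjust_fdr(res.loc[idx, "p_wald"])
            res.loc[idx, "q_lrt"] = adjust_fdr(res.loc[idx, "p_lrt"])
    res["consensus_significant"] = (res["q_wald"] <= alpha) & (
        res["q_lrt"] <= alpha
    )
    return res


def consensus_summary(results: pd.DataFrame) -> Dict[str, float]:
    """Counts and shares of consensus-significant results."""
    n_transcripts = results["transcript_id"].nunique()
    n_contrasts = results["contrast"].nunique()
    n_comparisons = len(results)
    sig = results[results["consensus_significant"]]
    n_sig_comparisons = len(sig)
    n_sig_transcripts = sig["transcript_id"].nunique()
    return {
        "n_transcripts": int(n_transcripts),
        "n_contrasts": int(n_contrasts),
        "n_comparisons": int(n_comparisons),
        "n_significant_comparisons": int(n_sig_comparisons),
        "n_significant_transcripts": int(n_sig_transcripts),
    }
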