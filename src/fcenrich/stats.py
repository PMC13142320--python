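"""Multiple-testing control, meta-analysis, profile similarity and reliability.

Reference atlases are mutually correlated, so a Bonferroni-style correction
over M atlases would be far too strict.  Instead the effective number of
tests M_eff is estimated from the eigenvalues of the Pearson correlation
matrix of the score columns (Nyholt's estimator) and plugged into a Sidak
correction, p_Meff = 1 - (1 - p)^M_eff.

Cross-dataset evidence is combined with sample-size-weighted Stouffer
z-scores; reproducibility of atlas profiles uses Spearman correlations and
ICC(3,1); test-retest reliability of scores uses ICC(2,k) and the
within-subject coefficient of variation (WCV) with a permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import FcEnrichError

P_CLIP = 1e-15  # Stouffer quantile guard


def effective_tests(score_matrix, method: str = "nyholt", labels=None) -> float:
    """Effective number of independent tests among correlated score columns.

    Parameters
    ----------
    score_matrix
        Observations x tests (e.g. subjects x atlases) real matrix.
    method
        "nyholt" (default): M_eff = 1 + (M-1) * (1 - Var(lambda)/M) with
        Var(lambda) the sample variance of the correlation-matrix eigenvalues.
        "li-ji": sum over eigenvalues of [lambda >= 1] + (lambda - floor(lambda)).
    """
    x = np.asarray(score_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise FcEnrichError("need an observations x tests matrix with >= 2 tests")
    if x.shape[0] < 3:
        raise FcEnrichError("need >= 3 observations")
    sd = x.std(axis=0)
    if np.any(sd == 0.0):
        j = int(np.flatnonzero(sd == 0.0)[0])
        name = labels[j] if labels is not None else f"column {j}"
        raise FcEnrichError(f"constant score column: {name}")
    corr = np.corrcoef(x, rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    m = corr.shape[0]
    if method == "nyholt":
        meff = 1.0 + (m - 1.0) * (1.0 - np.var(lam, ddof=1) / m)
    elif method == "li-ji":
        al = np.abs(lam)
        meff = float(np.sum((al >= 1.0) + (al - np.floor(al))))
    else:
        raise FcEnrichError(f"unknown M_eff method {method!r}")
    return float(np.clip(meff, 1.0, m))


def sidak_adjust(p: float, m_eff: float) -> float:
    """Sidak correction with a (possibly fractional) effective test count."""
    if not 0.0 <= p <= 1.0:
        raise FcEnrichError("p must lie in [0, 1]")
    if m_eff < 1.0:
        raise FcEnrichError("m_eff must be >= 1")
    if m_eff == 1.0:
        return float(p)  # exact identity, no rounding through the power
    return float(np.clip(1.0 - (1.0 - p) ** m_eff, 0.0, 1.0))


def stouffer_meta(p_values, weights) -> float:
    """Weighted Stouffer combination of one-sided p-values.

    z_i is the upper standard-normal quantile of 1 - p_i; the combined
    Z = sum(w_i z_i) / sqrt(sum(w_i^2)) is converted back to an upper-tail p.
    Weights are typically dataset sample sizes.
    """
    p = np.asarray(p_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape != w.shape or p.ndim != 1 or p.size == 0:
        raise FcEnrichError("p_values and weights must be equal-length 1-D sequences")
    if np.any(w <= 0.0):
        raise FcEnrichError("weights must be positive")
    p = np.clip(p, P_CLIP, 1.0 - P_CLIP)
    z = sps.norm.isf(p)
    combined = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    return float(sps.norm.sf(combined))


def profile_similarity(a: pd.Series, b: pd.Series) -> float:
    """Spearman rank correlation between two atlas profiles.

    Profiles are pandas Series indexed by atlas label (values are robust
    z-scores or raw scores for one cohort/modality/direction).
    """
    if len(a) < 3:
        raise FcEnrichError("profiles need >= 3 atlases")
    if sorted(a.index) != sorted(b.index):
        raise FcEnrichError("profile atlas labels do not match")
    b = b.reindex(a.index)
    rho, _ = sps.spearmanr(a.to_numpy(dtype=float), b.to_numpy(dtype=float))
    return float(rho)


def _anova_mean_squares(x: np.ndarray):
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ms_r = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_c = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ms_e = np.sum(resid**2) / ((n - 1) * (k - 1))
    return ms_r, ms_c, ms_e


def _check_table(scores, min_rows: int, min_cols: int) -> np.ndarray:
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[0] < min_rows or x.shape[1] < min_cols:
        raise FcEnrichError(f"need a complete table of >= {min_rows} x {min_cols} scores")
    if not np.all(np.isfinite(x)):
        raise FcEnrichError("score table must be complete (no missing values)")
    return x


def icc2k(scores) -> float:
    """ICC(2,k): two-way random effects, average measures, absolute agreement.

    Rows are subjects, columns are runs/sessions.
    """
    x = _check_table(scores, 3, 2)
    n, _ = x.shape
    ms_r, ms_c, ms_e = _anova_mean_squares(x)
    return float((ms_r - ms_e) / (ms_r + (ms_c - ms_e) / n))


def icc31(scores) -> float:
    """ICC(3,1): two-way mixed effects, single measure, consistency.

    Used for profile reproducibility with atlases as targets (rows) and
    datasets as raters (columns).
    """
    x = _check_table(scores, 3, 2)
    _, k = x.shape
    ms_r, _, ms_e = _anova_mean_squares(x)
    return float((ms_r - ms_e) / (ms_r + (k - 1) * ms_e))


def profile_icc(profiles) -> float:
    """ICC(3,1) of an atlases x datasets profile matrix."""
    return icc31(profiles)


def wcv(scores) -> float:
    """Within-subject coefficient of variation across runs.

    Root mean square of per-subject CVs (sample SD over |mean|).  Scale
    invariant: multiplying all scores by a constant leaves it unchanged.
    """
    x = _check_table(scores, 1, 2)
    means = x.mean(axis=1)
    small = np.flatnonzero(np.abs(means) <= 1e-12)
    if small.size:
        raise FcEnrichError(f"near-zero across-run mean for subject index {int(small[0])}")
    cv = x.std(axis=1, ddof=1) / np.abs(means)
    return float(np.sqrt(np.mean(cv**2)))


def wcv_permutation_p(scores, n_perm: int = 1000, seed=None) -> float:
    """Permutation p-value for the WCV.

    Null: scores are exchangeable across subjects within each run column, so
    any subject-specific consistency is destroyed.  p is the add-one fraction
    of permuted WCVs at or below the observed one (small WCV = high
    within-subject consistency).
    """
    x = _check_table(scores, 2, 2)
    rng = np.random.default_rng(seed)
    observed = wcv(x)
    count = 0
    perm = x.copy()
    for _ in range(n_perm):
        for j in range(x.shape[1]):
            perm[:, j] = rng.permutation(x[:, j])
        if wcv(perm) <= observed:
            count += 1
    return (1.0 + count) / (1.0 + n_perm)


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    icc_form: str
    wcv: float
    wcv_p: float


def reliability(scores, n_perm: int = 1000, seed=None) -> ReliabilityResult:
    """Test-retest reliability summary of a subjects x runs score table."""
    return ReliabilityResult(
        icc=icc2k(scores),
        icc_form="ICC(2,k)",
        wcv=wcv(scores),
        wcv_p=wcv_permutation_p(scores, n_perm=n_perm, seed=seed),
    )
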