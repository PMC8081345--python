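"""Group-level and behavioral statistics.

These are the cross-individual analyses that sit on top of the state
labeling: robust standardization of state topographies, PCA with a
channel-shuffle permutation test for consistent state groups, a sliding
modulation index to verify that labels track PAC strength, the
trait-correlation suite (partial Pearson correlations with Bonferroni
control plus a post-hoc multiple-correlation regression), and the pooled
two-proportion z test used to compare rejection counts between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm

from .core import MultichannelSeries
from .envelopes import wavelet_envelope, wavelet_phase


def modified_zscore(values: np.ndarray) -> np.ndarray:
    """Robust z-score: 0.6745 * (x - median) / MAD.

    The factor 0.6745 makes the score comparable to an ordinary z-score for
    Gaussian data (it is the ratio of the MAD to the SD of a normal).
    """
    x = np.asarray(values, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ValueError("median absolute deviation is zero (constant input)")
    return 0.6745 * (x - med) / mad


@dataclass
class PCAPermutationResult:
    explained_variance: np.ndarray
    explained_ratio: np.ndarray
    components: np.ndarray            # eigenvectors, rows
    pvalues: np.ndarray               # per-component, Bonferroni-corrected
    significant: np.ndarray           # boolean mask
    cumulative_significant_ratio: float


def state_group_pca(
    state_vectors: np.ndarray,
    n_perm: int = 200,
    alpha: float = 0.05,
    robust: bool = True,
    seed: int = 0,
) -> PCAPermutationResult:
    """PCA of per-state channel vectors with a channel-shuffle permutation test.

    Rows are state topographies (one vector per state and individual); each
    row is first converted to modified Z-scores when ``robust``.  The null
    for each component's explained variance is built by independently
    permuting every row across channels, which destroys the shared spatial
    structure while preserving row marginals.  Per-component one-sided
    p-values are Bonferroni-corrected across all components.
    """
    rows = np.asarray(state_vectors, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 rows")
    if n_perm < 20:
        raise ValueError("n_perm too small for a meaningful permutation test")
    if robust:
        rows = np.vstack([modified_zscore(r) for r in rows])
    n_comp = min(rows.shape)

    def _variances(data: np.ndarray) -> np.ndarray:
        centered = data - data.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        var = s**2 / (data.shape[0] - 1)
        out = np.zeros(n_comp)
        out[: var.size] = var[:n_comp]
        return out

    observed = _variances(rows)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_comp)
    for _ in range(n_perm):
        shuffled = np.vstack([rng.permutation(r) for r in rows])
        exceed += _variances(shuffled) >= observed
    # plain empirical p (no add-one): a Bonferroni correction across all
    # components must remain attainable at a few hundred permutations
    raw_p = exceed / n_perm
    pvalues = np.minimum(raw_p * n_comp, 1.0)
    significant = pvalues < alpha
    total = observed.sum()
    ratio = observed / total if total > 0 else np.zeros_like(observed)
    centered = rows - rows.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return PCAPermutationResult(
        explained_variance=observed,
        explained_ratio=ratio,
        components=vt[:n_comp],
        pvalues=pvalues,
        significant=significant,
        cumulative_significant_ratio=float(ratio[significant].sum()),
    )


def modulation_index_course(
    x: MultichannelSeries,
    f_slow: float,
    f_fast: float,
    window: float | None = None,
) -> tuple[np.ndarray, float]:
    """Sliding mean-vector modulation index of a single-channel signal.

    MI(t) = | mean over the window of A_fast(s) * exp(i phi_slow(s)) |,
    evaluated at every sample (hop of one sample).  The window defaults to
    one slow-oscillation period, 1/f_slow.  Returns (mi, t0) where t0 is
    the time of the first window's center.
    """
    if x.n_channels != 1:
        raise ValueError("modulation index operates on a single channel")
    if window is None:
        window = 1.0 / f_slow
    amp = wavelet_envelope(x, f_fast)
    ph = wavelet_phase(x, f_slow)
    # align the two differently trimmed series on their common support
    t_start = max(amp.t0, ph.t0)
    t_end = min(amp.times[-1], ph.times[-1])
    a = amp.data[0][(amp.times >= t_start - 1e-9) & (amp.times <= t_end + 1e-9)]
    p = ph.data[0][(ph.times >= t_start - 1e-9) & (ph.times <= t_end + 1e-9)]
    n = min(a.size, p.size)
    a, p = a[:n], p[:n]
    w = int(round(window * x.sample_rate))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    if w > n:
        raise ValueError("window exceeds the usable series length")
    phasor = a * np.exp(1j * p)
    csum = np.concatenate(([0.0 + 0.0j], np.cumsum(phasor)))
    mi = np.abs(csum[w:] - csum[:-w]) / w
    t0 = t_start + (w - 1) / (2.0 * x.sample_rate)
    return mi, t0


def fdr_bh(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg rejection mask at FDR level q."""
    return sm.stats.multipletests(np.asarray(pvalues), alpha=q, method="fdr_bh")[0]


def partial_pearson(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of x and y with covariates partialled out.

    Both variables are residualized on the covariates (with intercept); the
    p-value uses the t distribution with n - n_cov - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.column_stack([np.ones(x.size), np.asarray(covariates, dtype=float)])
    if np.linalg.cond(Z) > 1e10:
        raise ValueError(
            f"collinear covariates (condition number {np.linalg.cond(Z):.3g})"
        )
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = x.size - (Z.shape[1] - 1) - 2
    if df <= 0:
        raise ValueError("not enough observations for the partial correlation")
    t = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
    p = 2.0 * sstats.t.sf(abs(t), df)
    return r, float(p)


def trait_correlation_suite(
    table: pd.DataFrame,
    stat_columns: list[str],
    trait_columns: list[str],
) -> pd.DataFrame:
    """All pairwise partial correlations between dynamics statistics and
    trait subscores, Bonferroni-corrected over the full grid.

    For each (statistic, trait) pair the remaining statistics are partialled
    out of both variables.  Returns a tidy frame with r, raw p and the
    Bonferroni-corrected p (factor = number of pairs).
    """
    n = len(table)
    if n <= len(stat_columns) + 2:
        raise ValueError("need more individuals than statistics plus two")
    n_pairs = len(stat_columns) * len(trait_columns)
    records = []
    for sc in stat_columns:
        others = [c for c in stat_columns if c != sc]
        cov = table[others].to_numpy()
        for tc in trait_columns:
            r, p = partial_pearson(table[sc].to_numpy(), table[tc].to_numpy(), cov)
            records.append(
                {
                    "statistic": sc,
                    "trait": tc,
                    "r": r,
                    "p": p,
                    "p_bonferroni": min(p * n_pairs, 1.0),
                }
            )
    return pd.DataFrame.from_records(records)


def posthoc_regression(
    table: pd.DataFrame, trait: str, predictors: list[str]
) -> dict:
    """Post-hoc multiple-correlation test via a linear regression model.

    Regresses the trait on the chosen predictors; reports the F statistic
    with its (k, n - k - 1) degrees of freedom, the multiple correlation
    coefficient, and factor loadings (the Pearson correlations between the
    fitted linear sum and each predictor).
    """
    y = table[trait].to_numpy(dtype=float)
    X = sm.add_constant(table[predictors].to_numpy(dtype=float))
    if np.linalg.cond(X) > 1e10:
        raise ValueError("collinear predictors in the post-hoc regression")
    fit = sm.OLS(y, X).fit()
    fitted = fit.fittedvalues
    loadings = {
        p: float(np.corrcoef(fitted, table[p].to_numpy(dtype=float))[0, 1])
        for p in predictors
    }
    return {
        "F": float(fit.fvalue),
        "df": (int(fit.df_model), int(fit.df_resid)),
        "p": float(fit.f_pvalue),
        "multiple_r": float(np.sqrt(fit.rsquared)),
        "loadings": loadings,
    }


def two_proportion_z(
    successes_a: int, n_a: int, successes_b: int, n_b: int
) -> tuple[float, float]:
    """Pooled-variance z test for the difference of two proportions."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= successes_a <= n_a and 0 <= successes_b <= n_b):
        raise ValueError("successes must lie in [0, n]")
    pa, pb = successes_a / n_a, successes_b / n_b
    pool = (successes_a + successes_b) / (n_a + n_b)
    se = np.sqrt(pool * (1.0 - pool) * (1.0 / n_a + 1.0 / n_b))
    if se == 0:
        return 0.0, 1.0
    z = (pa - pb) / se
    return float(z), float(2.0 * sstats.norm.sf(abs(z)))
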