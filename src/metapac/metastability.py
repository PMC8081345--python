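"""LDA projection, attracting statistic, and FT-surrogate testing.

After clustering, each labeled state should behave like a weakly attracting
zero-dimensional state if the chosen envelope depth d matches the dimension
of the underlying dynamics.  The labeled samples are projected by Fisher
discriminant analysis onto at most two axes; on a shared histogram grid the
per-state maximum bin count E_k measures how tightly state k concentrates,
and E = min_k E_k is the test statistic.  The null — that the final
envelopes are just linearly correlated Gaussian noise — is represented by
multivariate Fourier-transform surrogates, which preserve every channel's
amplitude spectrum and all cross-spectra while destroying any nonlinear
structure.  Each surrogate is re-clustered at the same K, projected with
the same fitted weights and binned with the same geometry; H0 is rejected
when E exceeds the surrogate distribution at the 0.05 level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .core import MultichannelSeries, StateLabeling
from .labeling import kmeans_deterministic


@dataclass
class ProjectionModel:
    """Fitted Fisher-LDA projection plus shared histogram geometry."""

    weights: np.ndarray          # channels x m
    m: int
    bin_width: np.ndarray        # per-axis width
    bin_anchor: np.ndarray       # per-axis origin
    E_k: np.ndarray | None = None
    E: int | None = None

    def project(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.weights


@dataclass
class SurrogateVerdict:
    """Outcome of the one-sided FT-surrogate test on E."""

    E_observed: int
    E_surrogates: np.ndarray
    p: float
    reject: bool
    alpha: float = 0.05
    n_redrawn: int = 0


def _fisher_directions(points: np.ndarray, labels: np.ndarray, K: int, m: int) -> np.ndarray:
    """Leading m generalized eigenvectors of the between/within scatter pair."""
    n, n_ch = points.shape
    overall_mean = points.mean(axis=0)
    Sw = np.zeros((n_ch, n_ch))
    Sb = np.zeros((n_ch, n_ch))
    for k in range(1, K + 1):
        cls = points[labels == k]
        if cls.shape[0] < 2:
            raise ValueError(f"state {k} has fewer than 2 samples; LDA undefined")
        mu = cls.mean(axis=0)
        centered = cls - mu
        Sw += centered.T @ centered
        dm = (mu - overall_mean)[:, None]
        Sb += cls.shape[0] * (dm @ dm.T)
    # ridge-regularize a (near-)singular within-class scatter
    if np.linalg.cond(Sw) > 1e10:
        Sw = Sw + (1e-8 * np.trace(Sw) / n_ch) * np.eye(n_ch)
    eigvals, eigvecs = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(eigvals)[::-1][:m]
    W = eigvecs[:, order]
    # deterministic sign: first nonzero coordinate of each axis positive
    for j in range(W.shape[1]):
        nz = np.flatnonzero(W[:, j])
        if nz.size and W[nz[0], j] < 0:
            W[:, j] = -W[:, j]
    return W


def _freedman_diaconis_width(values: np.ndarray) -> float:
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    n = values.size
    if iqr > 0:
        return 2.0 * iqr / n ** (1.0 / 3.0)
    span = np.ptp(values)
    return span / np.sqrt(n) if span > 0 else 1.0


def lda_project(
    points: np.ndarray, labeling: StateLabeling
) -> tuple[ProjectionModel, np.ndarray]:
    """Fit the supervised projection and the shared histogram geometry.

    The target dimension is m = min(2, K - 1): a plane when K > 2,
    otherwise a single axis.  The bin geometry (Freedman-Diaconis width per
    axis, anchored at the pooled minimum) is frozen here so surrogate data
    are binned identically.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] != labeling.n_samples:
        raise ValueError("points and labeling must cover the same samples")
    K = labeling.K
    if K < 2:
        raise ValueError("need at least two states for LDA")
    m = min(2, K - 1)
    W = _fisher_directions(points, labeling.labels, K, m)
    projected = points @ W
    width = np.array([_freedman_diaconis_width(projected[:, j]) for j in range(m)])
    anchor = projected.min(axis=0)
    model = ProjectionModel(weights=W, m=m, bin_width=width, bin_anchor=anchor)
    Ek, E = attracting_statistic(projected, labeling, model)
    model.E_k, model.E = Ek, E
    return model, projected


def attracting_statistic(
    projected: np.ndarray, labeling: StateLabeling, model: ProjectionModel
) -> tuple[np.ndarray, int]:
    """Per-state maxima of histogram bin counts E_k and E = min_k E_k.

    All states share the bin geometry frozen in ``model``; the integer grid
    extends outward automatically for points beyond the original range.
    """
    projected = np.atleast_2d(np.asarray(projected, dtype=float))
    if projected.shape[1] != model.m:
        raise ValueError("projected dimension does not match the model")
    idx = np.floor((projected - model.bin_anchor) / model.bin_width).astype(np.int64)
    E_k = np.zeros(labeling.K, dtype=int)
    for k in range(1, labeling.K + 1):
        mask = labeling.state_mask(k)
        if not np.any(mask):
            raise ValueError(f"state {k} has no samples")
        _, counts = np.unique(idx[mask], axis=0, return_counts=True)
        E_k[k - 1] = int(counts.max())
    return E_k, int(E_k.min())


def ft_surrogate_multivariate(
    series: MultichannelSeries, seed: int | np.random.Generator = 0
) -> MultichannelSeries:
    """Multivariate Fourier-transform surrogate.

    One random phase sequence is added to the Fourier phases of every
    channel (conjugate-symmetrically), so per-channel amplitude spectra and
    all cross-spectra are preserved exactly while temporal structure beyond
    second order is destroyed.
    """
    n = series.n_samples
    if n < 8:
        raise ValueError("need at least 8 samples for an FT surrogate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spectrum = np.fft.rfft(series.data, axis=1)
    n_bins = spectrum.shape[1]
    phases = np.zeros(n_bins)
    # bins strictly between DC and Nyquist get a shared random phase
    hi = n_bins - 1 if n % 2 == 0 else n_bins
    phases[1:hi] = rng.uniform(0.0, 2.0 * np.pi, size=hi - 1)
    rotated = spectrum * np.exp(1j * phases)[np.newaxis, :]
    return series.copy_with(np.fft.irfft(rotated, n=n, axis=1))


def metastability_test(
    A0: MultichannelSeries,
    labeling: StateLabeling,
    projection: ProjectionModel,
    n_surrogates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> SurrogateVerdict:
    """One-sided FT-surrogate test of the attracting statistic E.

    Every surrogate is re-clustered at the original K and projected/binned
    with the original fitted geometry.  The p-value uses the add-one
    permutation convention, so p is never exactly zero.  A surrogate whose
    clustering degenerates (an empty state) is redrawn; the redraw count is
    recorded on the verdict.
    """
    if projection.E is None:
        raise ValueError("projection must carry the observed statistic E")
    rng = np.random.default_rng(seed)
    E_obs = int(projection.E)
    E_surr = np.empty(n_surrogates, dtype=int)
    redrawn = 0
    filled = 0
    while filled < n_surrogates:
        surr = ft_surrogate_multivariate(A0, rng)
        try:
            lab = kmeans_deterministic(surr.data.T, labeling.K)
            proj = projection.project(surr.data.T)
            _, E_prime = attracting_statistic(proj, lab, projection)
        except ValueError:
            redrawn += 1
            if redrawn > 10 * n_surrogates:
                raise RuntimeError("surrogate clustering degenerated persistently")
            continue
        E_surr[filled] = E_prime
        filled += 1
    p = (1.0 + np.sum(E_surr >= E_obs)) / (1.0 + n_surrogates)
    return SurrogateVerdict(
        E_observed=E_obs,
        E_surrogates=E_surr,
        p=float(p),
        reject=bool(p < alpha),
        alpha=alpha,
        n_redrawn=redrawn,
    )
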