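"""Model fitting: phase patterns, PPC connectivity, fluctuation covariance
and fluctuation level from labeled phase dynamics.

Workflow, given labeled slow-band phases theta(t) with states mu = 1..K:

1. ``state_phase_stats`` — per state, the circular mean of every pairwise
   phase difference yields a synchrony index R_ij^mu (how reliably i and j
   are locked while in state mu) and a mean difference psi_ij^mu.
2. ``reconstruct_patterns`` — the relative phase pattern theta^mu of each
   state is rebuilt from {psi_ij^mu} by a greedy chain that always hops to
   the channel most reliably locked (by the state-averaged index R-bar) to
   the current one; the visiting order is computed once and shared across
   states, and the first visited channel anchors the global rotation.
3. ``ppc_from_patterns`` — embedding the patterns as fixed directions of a
   Kuramoto-Sakaguchi network gives the coupling matrix C = P P+ with
   P_ij = exp(i theta_i^j); C is the orthogonal projector onto the span of
   the pattern phasors.
4. ``fluctuation_covariance`` / ``estimate_fluctuation_level`` — node pairs
   whose relative phase is conserved across patterns fluctuate together
   (Sigma), and the scalar noise level D is chosen on a grid so that
   simulated dwell-time statistics match the observed ones in RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MultichannelSeries, StateLabeling, wrap_phase
from .envelopes import wavelet_phase
from .simulator import PPCModel, overlap_labels, simulate_pac

D_GRID_DEFAULT = np.round(np.arange(0.0, 1.0 + 1e-9, 0.02), 2)


@dataclass
class PhasePatternSet:
    """Per-state synchrony structure and reconstructed phase patterns."""

    R: np.ndarray                  # K x N x N synchrony indices in [0, 1]
    psi: np.ndarray                # K x N x N mean phase differences
    R_bar: np.ndarray              # N x N state-averaged index
    patterns: np.ndarray | None = None   # K x N relative phases

    @property
    def K(self) -> int:
        return self.R.shape[0]

    @property
    def n_channels(self) -> int:
        return self.R.shape[1]


@dataclass
class DwellStats:
    """Per-state maximum, median and minimum dwell time in seconds.

    ``table`` is 3 x K with rows (max, median, min).
    """

    table: np.ndarray
    K: int


def extract_phases(
    csd_series: MultichannelSeries, f1: float, n_cycles: float = 3.0
) -> MultichannelSeries:
    """Instantaneous slow-band phases of source signals (Morlet argument)."""
    return wavelet_phase(csd_series, f1, n_cycles=n_cycles)


def state_phase_stats(
    theta: MultichannelSeries | np.ndarray, labeling: StateLabeling
) -> PhasePatternSet:
    """Circular statistics of pairwise phase differences per state.

    For each state mu, R_ij^mu exp(i psi_ij^mu) is the time average of
    exp(i (theta_i - theta_j)) over the samples labeled mu.
    """
    data = theta.data if isinstance(theta, MultichannelSeries) else np.asarray(theta)
    if data.shape[1] != labeling.n_samples:
        raise ValueError("phases and labeling must cover the same samples")
    n = data.shape[0]
    K = labeling.K
    z = np.exp(1j * data)
    R = np.empty((K, n, n))
    psi = np.empty((K, n, n))
    for mu in range(1, K + 1):
        mask = labeling.state_mask(mu)
        count = int(mask.sum())
        if count == 0:
            raise ValueError(f"state {mu} never visited")
        zs = z[:, mask]
        mean_phasor = (zs @ zs.conj().T) / count
        R[mu - 1] = np.abs(mean_phasor)
        psi[mu - 1] = np.angle(mean_phasor)
    return PhasePatternSet(R=R, psi=psi, R_bar=R.mean(axis=0))


def reconstruct_patterns(stats: PhasePatternSet) -> PhasePatternSet:
    """Rebuild each state's relative phase pattern from mean differences.

    The chain of channel visits is derived once from the state-averaged
    synchrony index: the most reliable pair seeds the chain and each hop
    goes to the unvisited channel with the highest index from the current
    one (ties toward the lowest channel index).  Along the chain,
    theta_j^mu = theta_i^mu - psi_ij^mu, with the seed channel fixed at 0,
    so patterns are determined up to a global rotation.
    """
    if not np.all(np.isfinite(stats.R_bar)):
        raise ValueError("state-averaged synchrony index contains non-finite values")
    n = stats.n_channels
    if n < 2:
        raise ValueError("need at least two channels")
    work = stats.R_bar.copy()
    # seed pair: argmax over the strict lower triangle (i > j)
    tri = np.tril(np.ones((n, n), dtype=bool), k=-1)
    masked = np.where(tri, work, -np.inf)
    i_star, j_star = np.unravel_index(int(np.argmax(masked)), (n, n))

    patterns = np.zeros((stats.K, n))
    patterns[:, i_star] = 0.0
    patterns[:, j_star] = -stats.psi[:, i_star, j_star]
    work[:, i_star] = 0.0
    for _ in range(n - 2):
        work[:, j_star] = 0.0
        i_star = j_star
        j_star = int(np.argmax(work[i_star]))
        patterns[:, j_star] = patterns[:, i_star] - stats.psi[:, i_star, j_star]
    stats.patterns = wrap_phase(patterns)
    return stats


def ppc_from_patterns(patterns: np.ndarray) -> np.ndarray:
    """Coupling matrix embedding the patterns as fixed network directions.

    C = P P+ with P the N x K matrix of unit phasors (one column per
    pattern) and P+ its Moore-Penrose inverse; C is the orthogonal
    projector onto the pattern span, so C p^mu = p^mu for every pattern.
    """
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    K, n = patterns.shape
    if K > n:
        raise ValueError("more patterns than channels")
    P = np.exp(1j * patterns.T)          # N x K
    return P @ np.linalg.pinv(P)


def fluctuation_covariance(patterns: np.ndarray) -> np.ndarray:
    """Fluctuation covariance from the cross-pattern difference structure.

    Sigma_ij = (1/K) |sum_mu exp(i (theta_i^mu - theta_j^mu))| is near 1
    where the relative phase of (i, j) is conserved across patterns and
    near 0 where it varies; the matrix is then projected to the nearest
    symmetric positive semidefinite matrix by eigenvalue clipping.
    """
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    K = patterns.shape[0]
    P = np.exp(1j * patterns.T)          # N x K
    raw = np.abs(P @ P.conj().T) / K
    sym = (raw + raw.T) / 2.0
    w, V = np.linalg.eigh(sym)
    return (V * np.clip(w, 0.0, None)) @ V.T


def _interior_runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode, dropping the truncated first and last runs."""
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    values = labels[starts]
    return values[1:-1], (ends - starts)[1:-1]


def dwell_statistics(
    labeling: StateLabeling, dt: float, strict: bool = True
) -> DwellStats:
    """Per-state max/median/min dwell time between transitions, in seconds.

    The first and last runs are uncertain intervals (truncated by the
    recording edges) and are excluded.  With ``strict`` a state lacking any
    interior run is an error; otherwise its statistics fall back to the
    edge-inclusive runs, or to zero if the state is never visited (the
    lenient convention used inside the fluctuation-level grid search, where
    low noise levels legitimately produce single-state trajectories).
    """
    values, lengths = _interior_runs(labeling.labels)
    if strict and values.size < 1:
        raise ValueError("need at least 3 runs in the label sequence")
    table = np.zeros((3, labeling.K))
    for k in range(1, labeling.K + 1):
        runs = lengths[values == k]
        if runs.size == 0:
            if strict:
                raise ValueError(f"state {k} has no interior dwell interval")
            # fall back to all runs of that state, edges included
            all_vals, all_lens = _all_runs(labeling.labels)
            runs = all_lens[all_vals == k]
            if runs.size == 0:
                continue
        table[:, k - 1] = (
            runs.max() * dt,
            float(np.median(runs)) * dt,
            runs.min() * dt,
        )
    return DwellStats(table=table, K=labeling.K)


def _all_runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return labels[starts], ends - starts


def estimate_fluctuation_level(
    model: PPCModel,
    patterns: np.ndarray,
    target: DwellStats,
    grid: np.ndarray = D_GRID_DEFAULT,
    reps: int = 100,
    duration: float = 180.0,
    dt: float = 0.2,
    burn_in: float = 120.0,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Grid search of the fluctuation level by dwell-time RMSE matching.

    For each candidate D the phase-only system is simulated ``reps`` times
    (coarse step ``dt`` for efficiency, an initial ``burn_in`` discarded so
    dwell statistics describe the attractor regime rather than the locking
    transient), trajectories are labeled by their overlaps with the
    patterns, and the 3K dwell statistics are compared with the target by
    RMSE; the mean RMSE curve over repetitions is minimized.  Returns
    (D_hat, mean RMSE per grid value).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    K = patterns.shape[0]
    if target.table.shape != (3, K):
        raise ValueError("target dwell table does not match the pattern count")
    rmse = np.zeros((reps, grid.size))
    rng = np.random.default_rng(seed)
    for rep in range(reps):
        for g, D in enumerate(grid):
            sim_model = PPCModel(
                C_delta=model.C_delta,
                omega=model.omega,
                C_alphadelta=model.C_alphadelta,
                k_delta=model.k_delta,
                k_alphadelta=model.k_alphadelta,
                Sigma=model.Sigma,
                D=float(D),
            )
            sim = simulate_pac(
                sim_model,
                duration=duration,
                dt=dt,
                seed=int(rng.integers(2**31 - 1)),
                with_amplitudes=False,
                burn_in=burn_in,
            )
            _, lab = overlap_labels(sim.phases, patterns)
            stats = dwell_statistics(lab, dt=dt, strict=False)
            rmse[rep, g] = np.sqrt(np.mean((stats.table - target.table) ** 2))
    mean_rmse = rmse.mean(axis=0)
    return float(grid[int(np.argmin(mean_rmse))]), mean_rmse
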