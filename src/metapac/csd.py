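"""Spherical-spline current source density and the scalp observation map.

Scalp potentials mix the contributions of underlying sources by volume
conduction; the surface Laplacian (current source density, CSD) sharpens
the spatial resolution before phase estimation.  Electrodes live on the
unit sphere, and the spline kernels are Legendre series over the cosine of
the inter-electrode angle:

    g(x) = 1/(4*pi) * sum_n (2n+1) / (n(n+1))^m     * P_n(x)
    h(x) = 1/(4*pi) * sum_n (2n+1) / (n(n+1))^(m-1) * P_n(x)

with spline order m (default 4) and the series truncated at 50 terms.  Per
sample, the mean-subtracted potentials are interpolated by the regularized
spline system and the Laplacian matrix H maps the spline coefficients to
CSD values.  The observation operator h = G H^{-1} maps CSD back to scalp
space (up to the spatial mean), which lets simulated source amplitudes be
compared with scalp-level signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.polynomial import legendre

from .core import MultichannelSeries

DEFAULT_LAMBDA = 1e-5


@dataclass
class Montage:
    """Electrode names and unit-sphere coordinates plus spline settings."""

    channel_names: list[str]
    coords: np.ndarray                # N x 3, unit norm
    m_spline: int = 4
    n_legendre: int = 50
    lam: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be N x 3")
        if len(self.channel_names) != self.coords.shape[0]:
            raise ValueError("one name per coordinate row required")
        norms = np.linalg.norm(self.coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("coordinates must lie on the unit sphere")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, (x, y, z) in zip(self.channel_names, self.coords):
                fh.write(f"{name}\t{x:.10f}\t{y:.10f}\t{z:.10f}\n")

    @classmethod
    def load(cls, path: str | Path, **kwargs) -> "Montage":
        names, rows = [], []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
        return cls(channel_names=names, coords=np.asarray(rows), **kwargs)


# outer-ring and ground positions absent from the 63-channel cap
_EXCLUDED_1010 = {
    "AFz", "F9", "F10", "FT9", "FT10", "TP9", "TP10", "P9", "P10", "O9", "O10",
}


def standard_montage_1010(**kwargs) -> Montage:
    """63-channel 10/10 montage on the unit sphere (via the mne templates)."""
    import mne

    template = mne.channels.make_standard_montage("easycap-M1")
    pos = template.get_positions()["ch_pos"]
    names = [c for c in template.ch_names if c not in _EXCLUDED_1010]
    coords = np.array([pos[c] for c in names])
    coords /= np.linalg.norm(coords, axis=1, keepdims=True)
    return Montage(channel_names=names, coords=coords, **kwargs)


def octahedral_montage(**kwargs) -> Montage:
    """Six electrodes at the octahedron vertices; a small symmetric test cap."""
    coords = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    names = ["px", "mx", "py", "my", "pz", "mz"]
    return Montage(channel_names=names, coords=coords, **kwargs)


def _legendre_series(cosang: np.ndarray, order: int, n_terms: int) -> np.ndarray:
    coefs = np.zeros(n_terms + 1)
    n = np.arange(1, n_terms + 1)
    coefs[1:] = (2 * n + 1) / (n * (n + 1.0)) ** order
    return legendre.legval(cosang, coefs) / (4.0 * np.pi)


def build_spline_matrices(montage: Montage) -> tuple[np.ndarray, np.ndarray]:
    """Spherical-spline potential matrix G and surface-Laplacian matrix H."""
    cosang = np.clip(montage.coords @ montage.coords.T, -1.0, 1.0)
    if np.any(cosang[~np.eye(montage.n_channels, dtype=bool)] > 1.0 - 1e-12):
        raise ValueError("coincident electrodes in montage")
    G = _legendre_series(cosang, montage.m_spline, montage.n_legendre)
    H = _legendre_series(cosang, montage.m_spline - 1, montage.n_legendre)
    return G, H


def _spline_coefficients(
    x: np.ndarray, G: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the regularized spline system with the sum-to-zero constraint.

    Returns (c, c0) where x' ~= G c + c0 and sum(c) = 0, per sample
    (columns of x).
    """
    n = G.shape[0]
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + lam * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    rhs = np.vstack([x, np.zeros(x.shape[1])])
    sol = np.linalg.solve(A, rhs)
    return sol[:n], sol[n]


def csd_transform(x: MultichannelSeries, montage: Montage) -> MultichannelSeries:
    """Current source density of a scalp series.

    Per sample the channel mean is subtracted, the smoothed spherical spline
    is fitted, and the Laplacian matrix maps the coefficients to CSD.
    """
    if x.n_channels != montage.n_channels:
        raise ValueError("montage does not match the number of channels")
    G, H = build_spline_matrices(montage)
    centered = x.data - x.data.mean(axis=0, keepdims=True)
    c, _ = _spline_coefficients(centered, G, montage.lam)
    return x.copy_with(H @ c)


def observe_scalp(csd_series: MultichannelSeries, montage: Montage) -> MultichannelSeries:
    """Map CSD signals back to scalp space with the operator G H^{-1}."""
    if csd_series.n_channels != montage.n_channels:
        raise ValueError("montage does not match the number of channels")
    G, H = build_spline_matrices(montage)
    if np.linalg.cond(H) > 1e12:
        projected = np.linalg.pinv(H) @ csd_series.data
    else:
        projected = np.linalg.solve(H, csd_series.data)
    return csd_series.copy_with(G @ projected)
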