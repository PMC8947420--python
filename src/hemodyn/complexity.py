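"""Wavelet entropy and statistical complexity of flow-velocity signals.

An m-level discrete wavelet transform splits a signal into detail bands
j = 1 (finest) .. m.  The band energies E_j — sums of squared detail
coefficients — normalized to the total detail energy give a probability
vector p = {p_j}.  From p:

* Shannon entropy            H = -sum p_j ln p_j, normalized by ln m;
* disequilibrium             Q = Q0 * D(p, uniform), with D Euclidean
  (Q0 = m/(m-1)) or the Wootters statistical distance
  (Q0 = 1/arccos(sqrt(1/m)));
* statistical complexity     C = H_norm * Q  (Lopez-Ruiz form).

C vanishes both at perfect order (point-mass p) and full randomness
(uniform p); the (H_norm, C) pair locates a signal on the
complexity-entropy plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .errors import DecompositionError, DistributionError, ParameterError
from .signals import UniformSignal

#: margin kept above the deepest level so every band has >= 4 coefficients
_AUTO_LEVEL_MARGIN = 2


@dataclass
class WaveletEnergyDistribution:
    """Per-level detail energies and their normalized distribution."""

    wavelet_name: str
    energies: np.ndarray  # E_j, j = 1 (finest) .. m
    p: np.ndarray  # relative energies, sums to 1
    approx_energy: float
    include_approx: bool = False

    @property
    def m(self) -> int:
        """Number of bins in the probability vector."""
        return int(self.p.size)

    def total_energy(self) -> float:
        return float(self.energies.sum() + self.approx_energy)


def auto_levels(length: int) -> int:
    """Default decomposition depth: floor(log2 n) - 2, at least 2."""
    if length < 8:
        raise DecompositionError(f"signal of length {length} is too short")
    return max(2, int(np.floor(np.log2(length))) - _AUTO_LEVEL_MARGIN)


def wavelet_energy(
    signal: UniformSignal | np.ndarray,
    wavelet_name: str = "db4",
    m: int | None = None,
    include_approx: bool = False,
    detrend: bool = True,
) -> WaveletEnergyDistribution:
    """Energy per wavelet detail level and the relative-energy distribution.

    Uses the periodized transform so orthogonal wavelets conserve energy
    exactly on dyadic lengths.  The mean is removed first (a DC offset is
    not signal structure); the approximation band is excluded from the
    distribution by default because slow trend energy would otherwise
    dominate every p_j.
    """
    x = signal.values if isinstance(signal, UniformSignal) else np.asarray(signal, float)
    wavelet = pywt.Wavelet(wavelet_name)
    if m is None:
        # cap by the wavelet's own maximum useful depth (filter support)
        m = max(2, min(auto_levels(x.size), pywt.dwt_max_level(x.size, wavelet.dec_len)))
    if m < 2:
        raise ParameterError("need at least 2 decomposition levels")
    if 2**m > x.size:
        raise DecompositionError(f"{m} levels is too deep for length {x.size}")
    if detrend:
        x = x - x.mean()
    coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=m)
    # coeffs[0]: approximation at level m; coeffs[i]: detail at level m - i + 1
    energies = np.empty(m)
    for i in range(1, m + 1):
        level = m - i + 1
        energies[level - 1] = float(np.sum(coeffs[i] ** 2))
    approx = float(np.sum(coeffs[0] ** 2))
    if include_approx:
        full = np.concatenate((energies, [approx]))
        total = full.sum()
        if total <= 0:
            raise DistributionError("signal has zero energy")
        p = full / total
    else:
        total = energies.sum()
        if total <= 0:
            raise DistributionError("signal has zero detail energy")
        p = energies / total
    return WaveletEnergyDistribution(
        wavelet_name=wavelet_name,
        energies=energies,
        p=p,
        approx_energy=approx,
        include_approx=include_approx,
    )


def _check_distribution(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise DistributionError("p must be a vector of at least 2 probabilities")
    if np.any(p < -1e-12):
        raise DistributionError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise DistributionError(f"probabilities sum to {p.sum()}, not 1")
    return np.clip(p, 0.0, None)


def shannon_entropy(p: np.ndarray) -> tuple[float, float]:
    """Shannon entropy of a distribution, in nats, raw and normalized.

    Returns ``(H, H / ln m)`` with the 0 ln 0 := 0 convention.
    """
    p = _check_distribution(p)
    nz = p[p > 0]
    h = float(-np.sum(nz * np.log(nz)))
    return h, h / np.log(p.size)


def disequilibrium(p: np.ndarray, kind: str = "euclidean") -> float:
    """Normalized distance between p and the uniform distribution.

    Euclidean: Q = [m/(m-1)] * sum (p_j - 1/m)^2, which is 1 for a point
    mass.  Wootters: Q = arccos(sum sqrt(p_j / m)) / arccos(sqrt(1/m)).
    """
    p = _check_distribution(p)
    m = p.size
    u = 1.0 / m
    if kind == "euclidean":
        q0 = m / (m - 1.0)
        return float(q0 * np.sum((p - u) ** 2))
    if kind == "wootters":
        q0 = 1.0 / np.arccos(np.sqrt(u))
        inner = float(np.clip(np.sum(np.sqrt(p * u)), -1.0, 1.0))
        return float(q0 * np.arccos(inner))
    raise ParameterError(f"unknown distance kind {kind!r}")


def statistical_complexity(h_norm: float, q: float) -> float:
    """Lopez-Ruiz statistical complexity C = H_norm * Q."""
    if not (0.0 <= h_norm <= 1.0 + 1e-12):
        raise ParameterError(f"normalized entropy {h_norm} outside [0, 1]")
    if not (0.0 <= q <= 1.0 + 1e-12):
        raise ParameterError(f"disequilibrium {q} outside [0, 1]")
    return float(h_norm * q)


@dataclass
class ComplexityPoint:
    """Entropy/complexity summary of one signal."""

    H: float
    H_norm: float
    Q: float
    C: float
    m: int
    wavelet_name: str
    distance_kind: str
    p: np.ndarray

    def plane_coords(self) -> tuple[float, float]:
        """(abscissa, ordinate) on the complexity-entropy plane."""
        return self.H_norm, self.C


def complexity_entropy_point(
    signal: UniformSignal | np.ndarray,
    wavelet_name: str = "db4",
    m: int | None = None,
    distance_kind: str = "euclidean",
    include_approx: bool = False,
    normalized_entropy_in_product: bool = True,
) -> ComplexityPoint:
    """Wavelet energy -> entropy -> disequilibrium -> complexity, composed.

    By default the entropy entering the complexity product is the
    normalized one (the plane abscissa lives in [0, 1]); set
    ``normalized_entropy_in_product=False`` for the raw-H variant.
    """
    dist = wavelet_energy(
        signal, wavelet_name=wavelet_name, m=m, include_approx=include_approx
    )
    h, h_norm = shannon_entropy(dist.p)
    q = disequilibrium(dist.p, kind=distance_kind)
    c = statistical_complexity(h_norm, q) if normalized_entropy_in_product else h * q
    return ComplexityPoint(
        H=h,
        H_norm=h_norm,
        Q=q,
        C=c,
        m=dist.p.size,
        wavelet_name=wavelet_name,
        distance_kind=distance_kind,
        p=dist.p,
    )
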