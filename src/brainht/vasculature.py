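"""Stochastic bifurcating vascular trees and the impairment parameter ζ.

The flow-impairment factor ζ that scales tumour perfusion is given a
biophysical reading: two tree-like networks of the same depth — one with
the tight geometric regularity of healthy vasculature, one with the wide
radius/length dispersion of tumour vessels — are driven by the same
pressure difference, and ζ is the ratio of the flows they carry, i.e. the
inverse ratio of their total Hagen–Poiseuille resistances.  Because vessel
resistance goes as 1/r⁴, mean-one perturbations of the radii *raise* the
expected resistance (convexity), so disorganised networks systematically
carry less flow and ζ falls below 1.

Each network has N arterial levels (level k holds 2^k vessels) branching
down to the capillaries at level N−1, mirrored by N venous levels merging
back up.  Backbone geometry follows a Murray-type cube-root branching law
from the capillary dimensions outward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkSpec",
    "VesselNetwork",
    "NetworkStatistics",
    "NORMAL_SPEC",
    "TUMOUR_SPEC",
    "vessel_resistance",
    "build_network",
    "total_resistance",
    "total_resistance_oracle",
    "estimate_zeta",
]


def vessel_resistance(radius: float, length: float, mu: float) -> float:
    """Hagen–Poiseuille resistance Z = 8μl/(πr⁴) [Pa s m⁻³]."""
    if radius <= 0 or length <= 0 or mu <= 0:
        raise ValueError("radius, length and viscosity must be positive")
    return 8.0 * mu * length / (np.pi * radius**4)


@dataclass(frozen=True)
class NetworkSpec:
    """Recipe for sampling a vascular tree.

    ``radius_cv``/``length_cv`` are coefficients of variation of the
    multiplicative log-normal perturbation (mean 1) applied per vessel to
    the deterministic backbone.  ``scaling_exponent`` e sets the branching
    law r_k = 2^e · r_{k+1} (e = 1/3 is Murray's law).
    """

    n_levels: int = 6             #: arterial levels N (venous mirrored)
    capillary_radius: float = 5e-6   #: [m]
    capillary_length: float = 75e-6  #: [m]
    radius_cv: float = 0.08
    length_cv: float = 0.08
    scaling_exponent: float = 1.0 / 3.0
    mu: float = 3e-3              #: blood dynamic viscosity [Pa s]


#: Tight geometric dispersion of a functional (healthy) vasculature
#: (≈ 3–5% relative spread of the total resistance at N = 6).
NORMAL_SPEC = NetworkSpec(radius_cv=0.05, length_cv=0.05)
#: Wide dispersion of a disorganised tumour vasculature (≈ 20–25% relative
#: spread of the total resistance at N = 6; because resistance is convex in
#: the radius, the wider spread also raises the mean, pushing ζ below 1).
TUMOUR_SPEC = NetworkSpec(radius_cv=0.25, length_cv=0.25)


@dataclass(frozen=True)
class VesselNetwork:
    """A sampled bifurcating tree: per-level radius and length arrays.

    ``radii[k]`` and ``lengths[k]`` hold the 2^k vessels of arterial level
    k (k < N) or the 2^(2N−1−k) vessels of venous level k (k ≥ N).
    """

    n_levels: int
    radii: tuple[np.ndarray, ...] = field(repr=False)
    lengths: tuple[np.ndarray, ...] = field(repr=False)
    mu: float = 3e-3

    def level_size(self, k: int) -> int:
        N = self.n_levels
        return 2**k if k < N else 2 ** (2 * N - 1 - k)

    def check_structure(self) -> None:
        if len(self.radii) != 2 * self.n_levels:
            raise ValueError("network must have 2N vessel levels")
        for k, (r, l) in enumerate(zip(self.radii, self.lengths)):
            if len(r) != self.level_size(k) or len(l) != self.level_size(k):
                raise ValueError(f"level {k} has wrong vessel count")
            if np.any(r <= 0) or np.any(l <= 0):
                raise ValueError(f"level {k} has non-positive geometry")

    def resistances(self, k: int) -> np.ndarray:
        """Per-vessel Hagen–Poiseuille resistances at level k."""
        return 8.0 * self.mu * self.lengths[k] / (np.pi * self.radii[k] ** 4)


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one log-normal multipliers with coefficient of variation cv."""
    if cv == 0.0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def build_network(
    spec: NetworkSpec, seed: int | None = None, rng: np.random.Generator | None = None
) -> VesselNetwork:
    """Sample a vascular tree from a :class:`NetworkSpec`.

    The deterministic backbone applies the branching law recursively from
    the capillary level outward (level-k backbone radius
    2^(e·(N−1−k))·r_cap, same for lengths) and is mirrored for the venous
    half; every vessel then receives independent mean-one log-normal
    perturbations of its radius and length.
    """
    if spec.n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {spec.n_levels}")
    if spec.radius_cv < 0 or spec.length_cv < 0:
        raise ValueError("variability coefficients must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    N = spec.n_levels
    radii: list[np.ndarray] = []
    lengths: list[np.ndarray] = []
    for k in range(2 * N):
        mirror = k if k < N else 2 * N - 1 - k  # venous mirrors arterial
        scale = 2.0 ** (spec.scaling_exponent * (N - 1 - mirror))
        n_vessels = 2**mirror
        r_back = scale * spec.capillary_radius
        l_back = scale * spec.capillary_length
        radii.append(r_back * _lognormal_factors(rng, spec.radius_cv, n_vessels))
        lengths.append(l_back * _lognormal_factors(rng, spec.length_cv, n_vessels))
    net = VesselNetwork(
        n_levels=N, radii=tuple(radii), lengths=tuple(lengths), mu=spec.mu
    )
    net.check_structure()
    return net


def total_resistance(network: VesselNetwork) -> float:
    """Total network resistance Z_tot [Pa s m⁻³] under equal flow splitting.

    Direct evaluation of the level sums
    Z_tot = Σ_{k<N} Σ_j Z_k^(j)/2^(2k) + Σ_{k≥N} Σ_j Z_k^(j)/2^(4N−2−2k):
    each vessel at arterial level k carries a fraction 1/2^k of the inflow
    and is traversed by the same fraction of the root-to-root paths, hence
    the squared weight.
    """
    network.check_structure()
    N = network.n_levels
    total = 0.0
    for k in range(2 * N):
        weight = 2.0 ** (-2 * k) if k < N else 2.0 ** (-(4 * N - 2 - 2 * k))
        total += float(np.sum(network.resistances(k))) * weight
    return total


def total_resistance_oracle(network: VesselNetwork) -> float:
    """Brute-force Z_tot = ΔP/Q₀ by explicit flow and path bookkeeping.

    Leaf (capillary) flows of Q₀/2^(N−1) are propagated to the root by
    summing daughter flows at every arterial junction (and symmetrically on
    the venous side), asserting exact flow conservation.  Every
    capillary-indexed root-to-root path is then walked, accumulating its
    pressure drop Σ Z·Q, and the path average divided by Q₀ is returned.
    Combinatorial, so refuses networks deeper than N = 8.
    """
    network.check_structure()
    N = network.n_levels
    if N > 8:
        raise ValueError("oracle limited to N <= 8 (combinatorial cost)")
    n_paths = 2 ** (N - 1)
    Q0 = 1.0

    # Bottom-up flow propagation on the arterial side.
    flows: dict[int, np.ndarray] = {}
    flows[N - 1] = np.full(n_paths, Q0 / n_paths)
    for k in range(N - 2, -1, -1):
        children = flows[k + 1]
        flows[k] = children[0::2] + children[1::2]
    assert np.isclose(flows[0][0], Q0, rtol=0, atol=1e-15 * Q0)
    # Venous side: level k >= N vessel j collects capillaries j*2^(k-N)...
    for k in range(N, 2 * N):
        if k == N:
            flows[k] = flows[N - 1].copy()
        else:
            prev = flows[k - 1]
            flows[k] = prev[0::2] + prev[1::2]
    # Flow conservation at every junction (exact by construction, asserted
    # to document the invariant).
    for k in range(N - 1):
        assert np.allclose(flows[k], flows[k + 1][0::2] + flows[k + 1][1::2])

    drops = np.zeros(n_paths)
    for path in range(n_paths):
        for k in range(N):  # arterial: vessel index = path >> (N-1-k)
            j = path >> (N - 1 - k)
            drops[path] += network.resistances(k)[j] * flows[k][j]
        for k in range(N, 2 * N):  # venous: vessel index = path >> (k-N)
            j = path >> (k - N)
            drops[path] += network.resistances(k)[j] * flows[k][j]
    return float(np.mean(drops)) / Q0


@dataclass(frozen=True)
class NetworkStatistics:
    """Monte-Carlo samples of total resistances and the derived ζ ratios."""

    z_normal: np.ndarray = field(repr=False)
    z_tumour: np.ndarray = field(repr=False)
    zeta: np.ndarray = field(repr=False)

    @property
    def zeta_mean(self) -> float:
        return float(np.mean(self.zeta))

    @property
    def zeta_sd(self) -> float:
        return float(np.std(self.zeta, ddof=1)) if len(self.zeta) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "n_samples": int(len(self.zeta)),
            "z_normal_mean": float(np.mean(self.z_normal)),
            "z_normal_sd": float(np.std(self.z_normal, ddof=1)),
            "z_tumour_mean": float(np.mean(self.z_tumour)),
            "z_tumour_sd": float(np.std(self.z_tumour, ddof=1)),
            "zeta_mean": self.zeta_mean,
            "zeta_sd": self.zeta_sd,
            "zeta_frac_below_1": float(np.mean(self.zeta < 1.0)),
        }


def estimate_zeta(
    normal_spec: NetworkSpec = NORMAL_SPEC,
    tumour_spec: NetworkSpec = TUMOUR_SPEC,
    n_samples: int = 500,
    seed: int | None = None,
) -> NetworkStatistics:
    """Monte-Carlo distribution of ζ = Z_tot(normal)/Z_tot(tumour).

    Draws ``n_samples`` paired normal/tumour networks (pairing by index:
    the i-th ζ sample is the ratio of the i-th normal to the i-th tumour
    resistance) under the same pressure difference; viscosity cancels in
    the ratio when equal across populations.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    z_nor = np.empty(n_samples)
    z_tum = np.empty(n_samples)
    for i in range(n_samples):
        z_nor[i] = total_resistance(build_network(normal_spec, rng=rng))
        z_tum[i] = total_resistance(build_network(tumour_spec, rng=rng))
    return NetworkStatistics(z_normal=z_nor, z_tumour=z_tum, zeta=z_nor / z_tum)
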