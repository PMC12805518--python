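"""Equilibrium measurements on particle configurations and time series.

Provides the virial pressure, the three temperature estimators (kinetic,
mean dressed theta, mean inverse bare theta), shell-normalized radial
distribution functions, block-averaged means with standard errors, and the
partition-of-unity diagnostic for the kernel field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import local_density as ld
from .local_density import KernelConfig

__all__ = [
    "virial_pressure",
    "temperatures",
    "rdf",
    "RDFHistogram",
    "block_stats",
    "thermo_summary",
    "partition_unity_check",
]


def virial_pressure(system, virial_pair_sum: float) -> float:
    """Virial pressure ``P = (1/3V) [sum p^2/m + sum_pairs r_ij . f^C_ij]``.

    Only conservative forces enter the configurational term; the dissipative
    and random channels average to zero and are excluded by construction.
    ``virial_pair_sum`` is the pair sum returned by the force evaluation for
    the same frame.
    """
    kinetic = float((system.momenta**2).sum() / system.mass)
    return (kinetic + virial_pair_sum) / (3.0 * system.volume)


def temperatures(system) -> tuple[float, float, float]:
    """Return ``(T_kin, <theta>, <1/theta~>)`` for the current frame.

    At equilibrium all three are estimators of the same temperature:
    ``<theta> = T`` and ``<1/theta~> = 1/T``.
    """
    T_kin = system.kinetic_temperature()
    if system.theta is None or system.theta_bare is None:
        raise ValueError("per-particle temperatures not refreshed; run a step first")
    return T_kin, float(system.theta.mean()), float((1.0 / system.theta_bare).mean())


@dataclass
class RDFHistogram:
    """Shell-normalized pair histogram averaged over frames."""

    edges: np.ndarray      # bin edges [reduced length]
    g: np.ndarray          # g(r) per bin
    counts: np.ndarray     # raw pair counts per bin
    n_frames: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def rdf(
    frames,
    box: float,
    bin_width: float = 0.02,
    r_max: float | None = None,
) -> RDFHistogram:
    """Radial distribution function from one or more position frames.

    ``frames`` is an (N, 3) array or a sequence of them (same N and box).
    Normalization uses ideal-gas shell counts at the frame number density, so
    ``g -> 1`` at large r for a homogeneous fluid.
    """
    if isinstance(frames, np.ndarray) and frames.ndim == 2:
        frames = [frames]
    frames = [np.asarray(f, dtype=float) for f in frames]
    N = frames[0].shape[0]
    if r_max is None:
        r_max = box / 2.0
    if r_max > box / 2.0:
        raise ValueError(f"r_max={r_max} exceeds half the box edge {box / 2.0}")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    counts = np.zeros(edges.size - 1)
    for pos in frames:
        pos = np.mod(pos, box)
        tree = cKDTree(pos, boxsize=box)
        pairs = tree.query_pairs(r_max, output_type="ndarray")
        if pairs.size:
            delta = pos[pairs[:, 0]] - pos[pairs[:, 1]]
            delta -= box * np.round(delta / box)
            r = np.sqrt((delta**2).sum(axis=1))
            counts += np.histogram(r, bins=edges)[0]
    rho = N / box**3
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = 0.5 * N * rho * shell * len(frames)
    g = counts / ideal
    return RDFHistogram(edges=edges, g=g, counts=counts, n_frames=len(frames))


def block_stats(values, n_blocks: int = 10) -> tuple[float, float]:
    """Mean and block-averaged standard error of a time series."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < n_blocks:
        return float(values.mean()), float(values.std(ddof=1) / np.sqrt(max(n - 1, 1)))
    usable = n - n % n_blocks
    blocks = values[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(values.mean()), float(blocks.std(ddof=1) / np.sqrt(n_blocks))


def thermo_summary(series, n_blocks: int = 10) -> dict:
    """Block means and standard errors of the sampled thermodynamic columns."""
    out = {}
    for col in ("T_kin", "theta_mean", "inv_theta_bare_mean", "n_mean", "P"):
        mean, err = block_stats(series[col].to_numpy(), n_blocks)
        out[col] = {"mean": mean, "stderr": err}
    out["drift_max_abs"] = float(np.abs(series["drift"].to_numpy()).max())
    return out


def partition_unity_check(
    positions: np.ndarray,
    box: float,
    probes: np.ndarray,
    cfg: KernelConfig,
) -> tuple[float, int]:
    """Worst deviation of ``sum_i phi_i(r)`` from 1 over the probe points.

    The kernel-ratio field is a partition of unity by construction wherever
    at least one kernel covers the probe; the deviation measures only
    round-off.  Returns ``(max |sum phi - 1|, number of uncovered probes)``;
    uncovered probes (farther than R_cut from every particle) are excluded.
    """
    positions = np.asarray(positions, dtype=float)
    probes = np.atleast_2d(np.asarray(probes, dtype=float))
    max_dev = 0.0
    n_undefined = 0
    for probe in probes:
        delta = probe - positions
        delta -= box * np.round(delta / box)
        r = np.sqrt((delta**2).sum(axis=1))
        w = ld.kernel_w(r, cfg)
        denom = w.sum()
        if denom == 0.0:
            n_undefined += 1
            continue
        max_dev = max(max_dev, abs(float((w / denom).sum()) - 1.0))
    return max_dev, n_undefined
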