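"""Synthetic data generators with known ground truth.

Every downstream estimator in this package (permeation counting,
collective-diffusion permeability, occupancy free-energy profiles,
dipole correlations, membrane potential) is validated against data
produced here, where the governing parameters are known exactly.

The central generator, :func:`simulate_pore`, runs overdamped-Langevin
(Brownian) point particles in a periodic box containing an impermeable
membrane slab pierced by a cylindrical pore. Inside the pore an imposed
free-energy profile U(z) acts on the axial coordinate only; the two
reservoirs are force-free. The stationary density is therefore the
Boltzmann distribution of U, and the particle diffusion coefficient is
an input — exactly the two properties the estimators under test
consume. Real MD water (hydrogen bonding, single-file effects,
electrostatics) is *not* emulated; see docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .trajio import AtomMeta, Trajectory
from .units import kt

__all__ = [
    "PoreSimConfig",
    "GroundTruth",
    "simulate_pore",
    "generate_collective_series",
    "generate_dipole_pair",
    "generate_charge_slab",
    "parallel_plate_delta_v",
]


@dataclass
class PoreSimConfig:
    """Parameters of the Brownian pore simulation.

    Units: Å, ns, kcal/mol. ``n_frames`` recorded frames are taken every
    ``stride`` integration steps of length ``dt``, so the simulated span
    is ``n_frames * stride * dt`` ns per channel.
    """

    n_particles: int
    box: tuple[float, float, float]
    pore_radius: float
    pore_z_bounds: tuple[float, float]
    profile_z: np.ndarray = None
    profile_U: np.ndarray = None
    diffusion_coefficient: float = 100.0  # Å²/ns, order of bulk TIP3P water
    dt: float = 1e-3  # ns
    n_frames: int = 1000
    stride: int = 1
    seed: int = 0
    n_channels: int = 1
    temperature: float = 310.15

    def __post_init__(self):
        z_lo, z_hi = self.pore_z_bounds
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if z_hi <= z_lo:
            raise ValueError("pore_z_bounds must be ordered (z_lo < z_hi)")
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion_coefficient must be positive")
        if self.pore_radius <= 0:
            raise ValueError("pore_radius must be positive")
        if self.n_particles < 1 or self.n_frames < 1 or self.stride < 1:
            raise ValueError("n_particles, n_frames, stride must be >= 1")
        if self.profile_z is None:
            # flat profile over the pore by default
            self.profile_z = np.linspace(z_lo, z_hi, 61)
            self.profile_U = np.zeros_like(self.profile_z)
        self.profile_z = np.asarray(self.profile_z, dtype=float)
        self.profile_U = np.asarray(self.profile_U, dtype=float)
        if self.profile_z[0] > z_lo or self.profile_z[-1] < z_hi:
            raise ValueError("imposed profile grid must cover pore_z_bounds")
        # reject dt too large for the profile: the deterministic drift per
        # step must stay below the profile grid spacing
        beta = 1.0 / kt(self.temperature)
        grad = np.gradient(self.profile_U, self.profile_z)
        max_drift = beta * self.diffusion_coefficient * np.max(np.abs(grad)) * self.dt
        spacing = np.min(np.diff(self.profile_z))
        if max_drift > spacing:
            raise ValueError(
                f"dt={self.dt} ns too large for profile curvature: max drift "
                f"per step {max_drift:.3g} Å exceeds grid spacing {spacing:.3g} Å"
            )


@dataclass
class GroundTruth:
    """The known truth of a generated dataset; never consumed by estimators."""

    true_profile_z: np.ndarray = None
    true_profile_U: np.ndarray = None
    true_D: float | None = None  # Å²/ns
    true_Dn: float | None = None  # ns⁻¹
    true_event_rate: float | None = None  # events/ns
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "true_profile_z": None
            if self.true_profile_z is None
            else np.asarray(self.true_profile_z).tolist(),
            "true_profile_U": None
            if self.true_profile_U is None
            else np.asarray(self.true_profile_U).tolist(),
            "true_D": self.true_D,
            "true_Dn": self.true_Dn,
            "true_event_rate": self.true_event_rate,
            "extras": self.extras,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _boltzmann_z_sampler(config: PoreSimConfig, rng: np.random.Generator, n: int):
    """Sample initial z from the stationary density of the accessible volume.

    The density is uniform in the reservoirs and ∝ exp(-U(z)/kT) times the
    pore cross-section inside the membrane slab.
    """
    lz = config.box[2]
    z_lo, z_hi = config.pore_z_bounds
    area_box = config.box[0] * config.box[1]
    area_pore = np.pi * config.pore_radius**2
    grid = np.linspace(0.0, lz, 2001)
    beta = 1.0 / kt(config.temperature)
    weight = np.full_like(grid, area_box)
    in_pore = (grid >= z_lo) & (grid <= z_hi)
    u = np.interp(grid[in_pore], config.profile_z, config.profile_U)
    weight[in_pore] = area_pore * np.exp(-beta * u)
    cdf = np.cumsum(weight)
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, grid)


def simulate_pore(config: PoreSimConfig) -> tuple[list[Trajectory], GroundTruth]:
    """Brownian dynamics of point particles around a cylindrical pore.

    Update per axis: ``x += -βD·∂U·dt + sqrt(2·D·dt)·ξ`` with U acting on
    z only and only inside the pore cylinder. The membrane annulus
    (pore z-range, lateral distance > pore_radius) is impenetrable: a
    particle inside the pore reflects off the radial wall, and a move
    from a reservoir into the annulus is rejected. All three box axes
    are periodic, so z-flux through the pore is possible.

    Returns one :class:`Trajectory` per channel (independent replicate
    pores differing only in the random stream) and the ground truth.
    Initial positions are drawn from the stationary (Boltzmann) density.
    """
    d = config.diffusion_coefficient
    beta = 1.0 / kt(config.temperature)
    box = np.asarray(config.box, dtype=float)
    z_lo, z_hi = config.pore_z_bounds
    cx, cy = box[0] / 2.0, box[1] / 2.0
    r2_pore = config.pore_radius**2
    sigma = np.sqrt(2.0 * d * config.dt)
    grad_grid = np.gradient(config.profile_U, config.profile_z)

    atoms = [
        AtomMeta(name="OW", residue_name="SOL", residue_id=i + 1)
        for i in range(config.n_particles)
    ]
    times = np.arange(config.n_frames) * config.dt * config.stride

    def lateral_r2(pos):
        dx = pos[:, 0] - cx
        dy = pos[:, 1] - cy
        dx -= box[0] * np.round(dx / box[0])
        dy -= box[1] * np.round(dy / box[1])
        return dx * dx + dy * dy

    channels = []
    for ch in range(config.n_channels):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, ch]))
        n = config.n_particles
        pos = np.empty((n, 3))
        pos[:, 2] = _boltzmann_z_sampler(config, rng, n)
        in_slab = (pos[:, 2] >= z_lo) & (pos[:, 2] <= z_hi)
        # lateral placement: uniform in box, but uniform in the pore disk
        # for particles starting inside the membrane slab
        pos[:, 0] = rng.random(n) * box[0]
        pos[:, 1] = rng.random(n) * box[1]
        k = int(np.sum(in_slab))
        if k:
            rr = config.pore_radius * np.sqrt(rng.random(k))
            th = 2 * np.pi * rng.random(k)
            pos[in_slab, 0] = cx + rr * np.cos(th)
            pos[in_slab, 1] = cy + rr * np.sin(th)

        coords = np.empty((config.n_frames, n, 3))
        coords[0] = pos
        total_steps = (config.n_frames - 1) * config.stride
        frame = 1
        for step in range(total_steps):
            noise = rng.standard_normal((n, 3)) * sigma
            in_pore = ((pos[:, 2] >= z_lo) & (pos[:, 2] <= z_hi)) & (
                lateral_r2(pos) <= r2_pore
            )
            drift = np.zeros(n)
            if np.any(in_pore):
                g = np.interp(pos[in_pore, 2], config.profile_z, grad_grid)
                drift[in_pore] = -beta * d * g * config.dt
            new = pos + noise
            new[:, 2] += drift
            new %= box  # periodic wrap, all axes

            new_in_slab = (new[:, 2] >= z_lo) & (new[:, 2] <= z_hi)
            new_r2 = lateral_r2(new)
            blocked = new_in_slab & (new_r2 > r2_pore)
            if np.any(blocked):
                # particles that were inside the pore reflect off the wall
                refl = blocked & in_pore
                if np.any(refl):
                    dx = new[refl, 0] - cx
                    dy = new[refl, 1] - cy
                    dx -= box[0] * np.round(dx / box[0])
                    dy -= box[1] * np.round(dy / box[1])
                    r = np.sqrt(new_r2[refl])
                    scale = (2.0 * config.pore_radius - r) / r
                    # fold back inside; clamp pathological overshoots
                    scale = np.clip(scale, 0.0, 1.0)
                    new[refl, 0] = (cx + dx * scale) % box[0]
                    new[refl, 1] = (cy + dy * scale) % box[1]
                # moves from a reservoir into the membrane annulus: reject
                rej = blocked & ~in_pore
                if np.any(rej):
                    new[rej] = pos[rej]
            pos = new
            if (step + 1) % config.stride == 0:
                coords[frame] = pos
                frame += 1

        channels.append(
            Trajectory(coordinates=coords, box=box.copy(), times=times.copy(), atoms=atoms)
        )

    truth = GroundTruth(
        true_profile_z=config.profile_z.copy(),
        true_profile_U=config.profile_U.copy(),
        true_D=d,
        extras={"seed": config.seed, "n_channels": config.n_channels},
    )
    return channels, truth


def write_dataset(channels, truth: GroundTruth, directory) -> None:
    """Write each channel as GRO+XTC plus a ground-truth JSON sidecar.

    Files: ``channel_<k>.gro``, ``channel_<k>.xtc`` and
    ``ground_truth.json`` under ``directory``, so synthetic data flows
    through the same readers as real MD output.
    """
    import pathlib

    from .trajio import write_gro_xtc

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, traj in enumerate(channels):
        write_gro_xtc(
            traj, directory / f"channel_{k}.gro", directory / f"channel_{k}.xtc"
        )
    truth.to_json(directory / "ground_truth.json")


def generate_collective_series(
    Dn: float, n_frames: int, dt: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Brownian path n(t) with ⟨n(t)²⟩ = 2·Dn·t.

    Direct generator for the collective permeation coordinate, used to
    validate the permeability estimator against a known Dn (ns⁻¹).
    Returns (times ns, n).
    """
    if Dn < 0:
        raise ValueError("Dn must be >= 0")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal(n_frames - 1) * np.sqrt(2.0 * Dn * dt)
    n = np.concatenate([[0.0], np.cumsum(steps)])
    return np.arange(n_frames) * dt, n


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate normal with Spearman rho ``rho_s``."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def generate_dipole_pair(
    rho_target: float, n_frames: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two angle-vs-time series (degrees) with a controlled Spearman rho.

    A Gaussian copula with Pearson correlation 2·sin(π·rho/6) yields the
    requested Spearman correlation; the normal marginals are mapped
    monotonically onto [0°, 180°], which leaves ranks (and hence the
    Spearman coefficient) untouched. rho_target=1 gives identical rank
    order.
    """
    if abs(rho_target) > 1:
        raise ValueError("|rho_target| must be <= 1")
    rng = np.random.default_rng(seed)
    r = spearman_to_pearson(rho_target)
    z1 = rng.standard_normal(n_frames)
    z2 = r * z1 + np.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n_frames)
    return 180.0 * norm.cdf(z1), 180.0 * norm.cdf(z2)


def generate_charge_slab(
    sigma: float, separation: float, z_grid: np.ndarray, center: float | None = None
) -> np.ndarray:
    """Charge-density profile of two opposite uniform sheets.

    ``sigma`` (e/Å²) is deposited as +sigma at ``center − separation/2``
    and −sigma at ``center + separation/2``, each smeared over one bin of
    the ``z_grid`` edges (e/Å³). Total charge is zero by construction.
    """
    z_grid = np.asarray(z_grid, dtype=float)
    centers = 0.5 * (z_grid[:-1] + z_grid[1:])
    widths = np.diff(z_grid)
    if center is None:
        center = 0.5 * (z_grid[0] + z_grid[-1])
    lo, hi = center - separation / 2.0, center + separation / 2.0
    if lo < z_grid[0] or hi > z_grid[-1]:
        raise ValueError("grid must cover both sheets")
    rho = np.zeros_like(centers)
    i_lo = np.argmin(np.abs(centers - lo))
    i_hi = np.argmin(np.abs(centers - hi))
    rho[i_lo] += sigma / widths[i_lo]
    rho[i_hi] -= sigma / widths[i_hi]
    return rho


def parallel_plate_delta_v(sigma: float, separation: float) -> float:
    """Analytic potential difference σ·d/ε0 of a parallel-plate pair, in mV."""
    from .units import E_CHARGE, EPS0

    sigma_si = sigma * E_CHARGE / 1e-20  # e/Å² → C/m²
    return sigma_si * (separation * 1e-10) / EPS0 * 1e3
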