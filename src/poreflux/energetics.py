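"""Occupancy free-energy profiles and binding-energy → KD conversion.

The potential of mean force along the pore axis is obtained from the
time-averaged water density in 0.5 Å slices of the cylinder:

    G(z) = −kT · ln(ρ(z) / ρ_bulk)

with ρ_bulk measured in a user-designated bulk region. Slices that were
never occupied carry no information and are masked, never set to ±∞;
operations that would consume a masked slice fail loudly instead of
propagating NaN.

Dissociation constants follow K_D = exp(ΔG/RT) in molar (1 M standard
state). Note the sign: a favourable (negative) binding free energy gives
K_D < 1 M. With R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and T = 310.15 K this
maps −9.22 kcal/mol to ≈318 nM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .permeation import PoreGeometry, _lateral_inside, _wrapped_z
from .trajio import Selection, Trajectory
from .units import DEFAULT_TEMPERATURE, R_KCAL_MOL_K, kt

__all__ = [
    "FreeEnergyProfile",
    "BindingSeries",
    "KdSummary",
    "occupancy_profile",
    "gibbs_profile",
    "barrier",
    "kd_from_dg",
    "summarize_binding",
    "read_binding_series",
]


@dataclass
class FreeEnergyProfile:
    """Per-slice Gibbs free energy along z (kcal/mol).

    ``G`` is NaN where ``undefined`` is True (zero occupancy).
    """

    z_edges: np.ndarray
    G: np.ndarray
    rho_bulk: float
    T: float
    undefined: np.ndarray

    def __post_init__(self):
        self.z_edges = np.asarray(self.z_edges, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.undefined = np.asarray(self.undefined, dtype=bool)
        if len(self.z_edges) != len(self.G) + 1:
            raise ValueError("z_edges must have len(G)+1 entries")
        if self.undefined.shape != self.G.shape:
            raise ValueError("undefined mask must match G")
        if np.any(np.isinf(self.G)):
            raise ValueError("G must never be ±inf; mask undefined slices")

    @property
    def z_mid(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"z": self.z_mid, "G_kcal_mol": self.G, "undefined": self.undefined}
        )


@dataclass
class BindingSeries:
    """Binding free energy sampled along a trajectory (kcal/mol per time)."""

    times: np.ndarray
    dG: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.dG = np.asarray(self.dG, dtype=float)
        if self.times.shape != self.dG.shape or self.times.size == 0:
            raise ValueError("times and dG must be equal-length and non-empty")
        if not np.all(np.isfinite(self.dG)):
            raise ValueError("dG must be finite")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be increasing")


@dataclass
class KdSummary:
    """Binding-energy summary with the matching dissociation constants.

    ``Kd_mean`` is Kd(mean dG), not the mean of per-frame Kd values.
    All Kd values are molar.
    """

    dG_mean: float
    dG_min: float
    dG_max: float
    Kd_mean: float
    Kd_min: float
    Kd_max: float
    T: float
    R: float = R_KCAL_MOL_K


def occupancy_profile(
    trajectory: Trajectory,
    selection: Selection,
    geometry: PoreGeometry,
    slice_width: float = 0.5,
    bulk_region="outside_cylinder",
):
    """Time-averaged number density ρ(z) in cylinder slices, plus ρ_bulk.

    ``bulk_region`` designates where the bulk reference density is
    measured:

    - ``"outside_cylinder"`` (default): everything not in the cylinder;
    - ``"reservoir"``: the z-slabs outside the pore z-range (the right
      choice when an impermeable membrane surrounds the pore);
    - a ``(z_lo, z_hi)`` tuple: an explicit z-slab.

    Returns ``(z_edges, rho, rho_bulk)`` with densities in counts/Å³.
    """
    if len(selection) == 0:
        raise ValueError("selection is empty")
    idx = selection.indices
    z = _wrapped_z(trajectory, idx)
    lateral = _lateral_inside(trajectory, idx, geometry)
    in_cyl = lateral & (z >= geometry.z_lo) & (z <= geometry.z_hi)

    n_slices = int(round(geometry.L / slice_width))
    z_edges = geometry.z_lo + slice_width * np.arange(n_slices + 1)
    slice_vol = np.pi * geometry.radius**2 * slice_width

    counts = np.zeros(n_slices)
    for t in range(trajectory.n_frames):
        zz = z[t][in_cyl[t]]
        h, _ = np.histogram(zz, bins=z_edges)
        counts += h
    rho = counts / (trajectory.n_frames * slice_vol)

    box = trajectory.box
    box_vol = float(np.mean(np.prod(box, axis=1)))
    area = float(np.mean(box[:, 0] * box[:, 1]))
    lz = float(np.mean(box[:, 2]))
    cyl_vol = np.pi * geometry.radius**2 * geometry.L

    if bulk_region == "outside_cylinder":
        n_bulk = np.mean(np.sum(~in_cyl, axis=1))
        rho_bulk = n_bulk / (box_vol - cyl_vol)
    elif bulk_region == "reservoir":
        in_res = (z < geometry.z_lo) | (z > geometry.z_hi)
        n_bulk = np.mean(np.sum(in_res, axis=1))
        rho_bulk = n_bulk / (area * (lz - geometry.L))
    else:
        b_lo, b_hi = bulk_region
        if b_hi <= b_lo:
            raise ValueError("bulk slab must be ordered (z_lo, z_hi)")
        in_slab = (z >= b_lo) & (z <= b_hi)
        n_bulk = np.mean(np.sum(in_slab, axis=1))
        rho_bulk = n_bulk / (area * (b_hi - b_lo))
    return z_edges, rho, float(rho_bulk)


def gibbs_profile(
    rho: np.ndarray,
    rho_bulk: float,
    T: float = DEFAULT_TEMPERATURE,
    z_edges: np.ndarray | None = None,
) -> FreeEnergyProfile:
    """G(z) = −kT·ln(ρ(z)/ρ_bulk); zero-occupancy slices are masked."""
    if rho_bulk <= 0:
        raise ValueError(f"rho_bulk must be positive, got {rho_bulk}")
    rho = np.asarray(rho, dtype=float)
    if z_edges is None:
        z_edges = np.arange(len(rho) + 1, dtype=float)
    undefined = rho <= 0
    g = np.full(rho.shape, np.nan)
    g[~undefined] = -kt(T) * np.log(rho[~undefined] / rho_bulk)
    return FreeEnergyProfile(
        z_edges=z_edges, G=g, rho_bulk=rho_bulk, T=T, undefined=undefined
    )


def barrier(
    profile: FreeEnergyProfile,
    section: tuple[float, float] | None = None,
    require_defined: bool = False,
):
    """Highest barrier ΔG_max (kcal/mol) and its slice-midpoint position.

    The barrier is relative to the bulk zero level. Ties break toward
    the smallest z. A fully masked section is an error; with
    ``require_defined`` any masked slice inside the section is.
    """
    z = profile.z_mid
    if section is None:
        in_sec = np.ones(len(z), dtype=bool)
    else:
        s_lo, s_hi = section
        in_sec = (z >= s_lo) & (z <= s_hi)
        if not np.any(in_sec):
            raise ValueError(f"section {section} outside profile support")
    masked = profile.undefined & in_sec
    if require_defined and np.any(masked):
        raise ValueError(
            "undefined (zero-occupancy) slices inside the section at z = "
            + ", ".join(f"{v:.2f}" for v in z[masked])
        )
    ok = in_sec & ~profile.undefined
    if not np.any(ok):
        raise ValueError("section fully masked: no defined slices")
    g = np.where(ok, profile.G, -np.inf)
    i = int(np.argmax(g))  # argmax returns the first (smallest z) maximum
    return float(profile.G[i]), float(z[i])


def kd_from_dg(dG, T: float = DEFAULT_TEMPERATURE):
    """Dissociation constant (molar) from binding free energy (kcal/mol).

    K_D = exp(ΔG / (R·T)) with a 1 M standard state; a negative
    (favourable) ΔG gives K_D < 1 M. Accepts scalars or arrays.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    return np.exp(np.asarray(dG, dtype=float) / (R_KCAL_MOL_K * T))


def summarize_binding(series: BindingSeries, T: float = DEFAULT_TEMPERATURE) -> KdSummary:
    """Mean/min/max of a ΔG series and their dissociation constants."""
    dg_mean = float(np.mean(series.dG))
    dg_min = float(np.min(series.dG))
    dg_max = float(np.max(series.dG))
    return KdSummary(
        dG_mean=dg_mean,
        dG_min=dg_min,
        dG_max=dg_max,
        Kd_mean=float(kd_from_dg(dg_mean, T)),
        Kd_min=float(kd_from_dg(dg_min, T)),
        Kd_max=float(kd_from_dg(dg_max, T)),
        T=T,
    )


def read_binding_series(path) -> BindingSeries:
    """Read a two-column CSV (time_ns, dG_kcal_mol) into a BindingSeries."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("binding series CSV needs two columns (time, dG)")
    return BindingSeries(times=df.iloc[:, 0].to_numpy(), dG=df.iloc[:, 1].to_numpy())
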