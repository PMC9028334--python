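"""Geometric and electrostatic trajectory observables.

Hydrogen bonds, minimum group distances, a simplified pore-radius
profile, radial distribution functions, dipole moments and their
z-angles, and the membrane-potential profile from Poisson double
integration. All pairwise distances use the orthorhombic minimum-image
convention.

The pore-radius profile is a slice-wise inscribed-radius approximation
(lateral distance to the pore axis minus the atom's van der Waals
radius, minimised per slice), not a sphere-propagation algorithm; every
output labels it "simplified".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .permeation import PoreGeometry
from .trajio import Selection, Trajectory, minimum_image
from .units import E_CHARGE, EA_TO_DEBYE, EPS0

logger = logging.getLogger(__name__)

__all__ = [
    "HBondCriterion",
    "RdfResult",
    "DipoleSeries",
    "PotentialProfile",
    "hydrogen_bonds",
    "min_distance",
    "pore_radius_profile",
    "rdf",
    "dipole_moment",
    "membrane_potential",
    "potential_from_density",
    "bond_vector_angle",
]


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond definition.

    A bond requires donor–acceptor distance ≤ ``max_da_distance`` (Å)
    and H–D–A angle ≤ ``max_hda_angle`` (degrees). Defaults are the
    common 3.5 Å / 30° geometric criterion. ``max_dh_distance`` bounds
    the covalent D–H search used to attach hydrogens to donors.
    """

    max_da_distance: float = 3.5
    max_hda_angle: float = 30.0
    max_dh_distance: float = 1.25

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be positive")
        if not 0 < self.max_hda_angle < 180:
            raise ValueError("max_hda_angle must be in (0, 180)")


@dataclass
class RdfResult:
    """Radial distribution function g(r) between two groups."""

    r_edges: np.ndarray
    g: np.ndarray
    reference_label: str
    target_label: str
    n_frames: int

    @property
    def r_mid(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])


@dataclass
class DipoleSeries:
    """Per-frame dipole vector (Debye) and its angle to the z-axis."""

    times: np.ndarray
    vector: np.ndarray  # (frames, 3) Debye
    angle_to_z: np.ndarray  # degrees in [0, 180]
    reference: str = "center of geometry"

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vector, axis=1)


@dataclass
class PotentialProfile:
    """Charge density (e/Å³) and electrostatic potential (mV) along z."""

    z_edges: np.ndarray
    charge_density: np.ndarray
    potential: np.ndarray  # at z_edges, potential[0] = 0
    total_charge: float = 0.0

    @property
    def z_mid(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])


def _pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image distance matrix between coordinate sets a and b."""
    d = a[:, None, :] - b[None, :, :]
    d = minimum_image(d, box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def hydrogen_bonds(
    trajectory: Trajectory,
    donors: Selection,
    acceptors: Selection,
    criterion: HBondCriterion | None = None,
):
    """Geometric hydrogen bonds per frame.

    Donor hydrogens are resolved from the topology: atoms whose name
    starts with "H", in the same residue as the donor heavy atom and
    within ``max_dh_distance`` of it in the first frame. Donors without
    any attached hydrogen are excluded with a warning.

    Returns ``(counts, pairs)``: per-frame count of bonded (donor,
    acceptor) pairs (a pair counts once however many hydrogens satisfy
    the angle), and the per-frame list of such pairs.
    """
    crit = criterion or HBondCriterion()
    if len(donors) == 0 or len(acceptors) == 0:
        raise ValueError("donor and acceptor selections must be non-empty")

    coords0 = trajectory.coordinates[0]
    box0 = trajectory.box[0]
    hydrogens = [
        i
        for i, a in enumerate(trajectory.atoms)
        if a.name.upper().startswith("H")
    ]
    dh_pairs: list[tuple[int, int]] = []
    for d in donors.indices:
        res = trajectory.atoms[d].residue_id
        cand = [h for h in hydrogens if trajectory.atoms[h].residue_id == res]
        attached = [
            h
            for h in cand
            if np.linalg.norm(minimum_image(coords0[h] - coords0[d], box0))
            <= crit.max_dh_distance
        ]
        if not attached:
            logger.warning("donor atom %d has no attached hydrogen; excluded", d)
            continue
        dh_pairs.extend((int(d), int(h)) for h in attached)
    if not dh_pairs:
        raise ValueError("no donor has a resolvable hydrogen")

    d_idx = np.array([p[0] for p in dh_pairs])
    h_idx = np.array([p[1] for p in dh_pairs])
    a_idx = acceptors.indices
    cos_max = np.cos(np.deg2rad(crit.max_hda_angle))

    counts = np.zeros(trajectory.n_frames, dtype=int)
    pairs: list[list[tuple[int, int]]] = []
    for t in range(trajectory.n_frames):
        box = trajectory.box[t]
        pos = trajectory.coordinates[t]
        da = pos[a_idx][None, :, :] - pos[d_idx][:, None, :]
        da = minimum_image(da, box)
        dist = np.sqrt(np.einsum("ijk,ijk->ij", da, da))
        dh = minimum_image(pos[h_idx] - pos[d_idx], box)
        dh_n = dh / np.linalg.norm(dh, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.einsum("ik,ijk->ij", dh_n, da) / np.where(dist > 0, dist, np.inf)
        bonded = (dist <= crit.max_da_distance) & (cos >= cos_max)
        bonded &= a_idx[None, :] != d_idx[:, None]  # no self bonds
        bonded &= a_idx[None, :] != h_idx[:, None]
        frame_pairs = {
            (int(d_idx[i]), int(a_idx[j])) for i, j in zip(*np.nonzero(bonded))
        }
        counts[t] = len(frame_pairs)
        pairs.append(sorted(frame_pairs))
    return counts, pairs


def min_distance(
    trajectory: Trajectory, group_a: Selection, group_b: Selection
) -> np.ndarray:
    """Per-frame minimum pairwise distance (Å) between two groups.

    Exact minimum (no cutoff truncation), minimum-image convention.
    Identical groups give 0.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    out = np.empty(trajectory.n_frames)
    same = np.array_equal(group_a.indices, group_b.indices)
    for t in range(trajectory.n_frames):
        if same:
            out[t] = 0.0
            continue
        d = _pair_distances(
            trajectory.coordinates[t][group_a.indices],
            trajectory.coordinates[t][group_b.indices],
            trajectory.box[t],
        )
        out[t] = d.min()
    return out


def pore_radius_profile(
    trajectory: Trajectory,
    protein: Selection,
    geometry: PoreGeometry,
    slice_width: float = 0.5,
):
    """Simplified pore-radius profile (Å) along the cylinder axis.

    Per slice and frame: min over protein atoms in the slice of
    (lateral distance to the pore axis − vdW radius), clamped at 0,
    then averaged over frames. Slices never populated by any atom are
    masked (NaN). Requires vdW radii on the selected atoms.

    This is a slice-wise inscribed-radius approximation, not a
    sphere-propagation pore finder.
    """
    if len(protein) == 0:
        n_slices = int(round(geometry.L / slice_width))
        z_edges = geometry.z_lo + slice_width * np.arange(n_slices + 1)
        return z_edges, np.full(n_slices, np.nan)
    radii = []
    for i in protein.indices:
        r = trajectory.atoms[i].vdw_radius
        if r is None:
            raise ValueError(f"atom {i} has no vdW radius")
        radii.append(r)
    radii = np.array(radii)

    n_slices = int(round(geometry.L / slice_width))
    z_edges = geometry.z_lo + slice_width * np.arange(n_slices + 1)
    acc = np.zeros(n_slices)
    n_seen = np.zeros(n_slices, dtype=int)
    cx, cy = geometry.center
    for t in range(trajectory.n_frames):
        pos = trajectory.coordinates[t][protein.indices]
        box = trajectory.box[t]
        z = np.mod(pos[:, 2], box[2])
        dxy = pos[:, :2] - np.array([cx, cy])
        dxy = minimum_image(dxy, box[:2])
        lateral = np.sqrt(np.einsum("ik,ik->i", dxy, dxy))
        open_r = np.maximum(lateral - radii, 0.0)
        which = np.floor((z - geometry.z_lo) / slice_width).astype(int)
        valid = (which >= 0) & (which < n_slices)
        for s in np.unique(which[valid]):
            acc[s] += open_r[valid & (which == s)].min()
            n_seen[s] += 1
    profile = np.where(n_seen > 0, acc / np.maximum(n_seen, 1), np.nan)
    return z_edges, profile


def rdf(
    trajectory: Trajectory,
    reference: Selection,
    target: Selection,
    r_max: float,
    bin_width: float = 0.1,
) -> RdfResult:
    """Radial distribution function g(r) of ``target`` around ``reference``.

    Normalised by the ideal-gas expectation at the target's mean number
    density over the box, so an uncorrelated gas gives g(r) → 1.
    Self-pairs (atoms present in both groups) are excluded.
    """
    if len(reference) == 0 or len(target) == 0:
        raise ValueError("both groups must be non-empty")
    half_box = float(np.min(trajectory.box)) / 2.0
    if r_max >= half_box:
        raise ValueError(f"r_max {r_max} must be < half the min box length {half_box}")

    n_bins = int(np.ceil(r_max / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    hist = np.zeros(n_bins)
    overlap = np.intersect1d(reference.indices, target.indices).size
    for t in range(trajectory.n_frames):
        d = _pair_distances(
            trajectory.coordinates[t][reference.indices],
            trajectory.coordinates[t][target.indices],
            trajectory.box[t],
        )
        same = reference.indices[:, None] == target.indices[None, :]
        d = d[~same]
        h, _ = np.histogram(d, bins=edges)
        hist += h

    box_vol = float(np.mean(np.prod(trajectory.box, axis=1)))
    # each reference sees N_target minus any shared atoms
    rho = (len(target) - overlap / max(len(reference), 1)) / box_vol
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = trajectory.n_frames * len(reference) * rho * shell_vol
    g = hist / norm
    return RdfResult(
        r_edges=edges,
        g=g,
        reference_label=reference.label,
        target_label=target.label,
        n_frames=trajectory.n_frames,
    )


def dipole_moment(trajectory: Trajectory, selection: Selection) -> DipoleSeries:
    """Dipole moment μ = Σ qᵢ·(rᵢ − r_cog) per frame, in Debye.

    The reference point is the selection's center of geometry, which
    makes the result well defined for non-neutral selections (logged in
    the result's ``reference`` field). The z-angle is that of μ with
    the +z axis, in [0°, 180°]; frames with |μ| = 0 give NaN.
    """
    if len(selection) == 0:
        raise ValueError("selection is empty")
    missing = [
        int(i)
        for i in selection.indices
        if trajectory.atoms[i].partial_charge is None
    ]
    if missing:
        raise ValueError(f"atoms without partial charges: {missing}")
    q = np.array([trajectory.atoms[i].partial_charge for i in selection.indices])

    pos = trajectory.coordinates[:, selection.indices, :]
    cog = pos.mean(axis=1, keepdims=True)
    mu = np.einsum("i,fik->fk", q, pos - cog) * EA_TO_DEBYE
    mag = np.linalg.norm(mu, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        angle = np.degrees(np.arccos(np.clip(mu[:, 2] / mag, -1.0, 1.0)))
    angle[mag == 0] = np.nan
    return DipoleSeries(times=trajectory.times.copy(), vector=mu, angle_to_z=angle)


def potential_from_density(z_edges: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Electrostatic potential (mV) from a charge-density profile (e/Å³).

    Double integration of Poisson's equation φ'' = −ρ/ε0 in vacuum with
    φ = 0 and dφ/dz = 0 at the lower edge; returned at the bin edges.
    """
    from scipy.integrate import cumulative_trapezoid

    z_m = np.asarray(z_edges, dtype=float) * 1e-10
    rho_si = np.asarray(rho, dtype=float) * E_CHARGE / 1e-30  # e/Å³ → C/m³
    # density is per bin; evaluate at edges by padding with edge values
    rho_edges = np.concatenate([[rho_si[0]], 0.5 * (rho_si[1:] + rho_si[:-1]), [rho_si[-1]]])
    field = -cumulative_trapezoid(rho_edges, z_m, initial=0.0) / EPS0  # φ'
    phi = cumulative_trapezoid(field, z_m, initial=0.0)
    return phi * 1e3  # V → mV


def membrane_potential(
    trajectory: Trajectory, slice_width: float = 1.0
) -> PotentialProfile:
    """Potential profile φ(z) from the partial charges of all atoms.

    Charges are binned along z (frame-averaged, e/Å³) and Poisson's
    equation is double-integrated with vacuum permittivity and a
    zero-field, zero-potential lower box edge. A non-neutral system is
    reported with a warning (the double integral then acquires a slope).
    """
    missing = [
        i for i, a in enumerate(trajectory.atoms) if a.partial_charge is None
    ]
    if missing:
        raise ValueError(f"atoms without partial charges: {missing[:10]}...")
    q = np.array([a.partial_charge for a in trajectory.atoms])
    total = float(q.sum())
    if abs(total) > 1e-6:
        logger.warning("system not neutral: residual charge %.4g e", total)

    lz = float(np.mean(trajectory.box[:, 2]))
    n_bins = int(round(lz / slice_width))
    z_edges = np.linspace(0.0, lz, n_bins + 1)
    area = float(np.mean(trajectory.box[:, 0] * trajectory.box[:, 1]))
    bin_vol = area * (z_edges[1] - z_edges[0])

    dens = np.zeros(n_bins)
    for t in range(trajectory.n_frames):
        z = np.mod(trajectory.coordinates[t][:, 2], trajectory.box[t][2])
        h, _ = np.histogram(z, bins=z_edges, weights=q)
        dens += h
    dens /= trajectory.n_frames * bin_vol

    phi = potential_from_density(z_edges, dens)
    return PotentialProfile(
        z_edges=z_edges, charge_density=dens, potential=phi, total_charge=total
    )


def bond_vector_angle(trajectory: Trajectory, atom1: int, atom2: int) -> np.ndarray:
    """Per-frame angle (degrees) of the atom1→atom2 vector with +z.

    Coincident atoms give NaN for that frame.
    """
    if atom1 == atom2:
        raise ValueError("atoms must be distinct")
    v = trajectory.coordinates[:, atom2, :] - trajectory.coordinates[:, atom1, :]
    v = minimum_image(v, trajectory.box)
    norm = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ang = np.degrees(np.arccos(np.clip(v[:, 2] / norm, -1.0, 1.0)))
    ang[norm == 0] = np.nan
    return ang
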