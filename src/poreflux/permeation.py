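"""Permeation counting and the collective permeation coordinate.

A permeation event is an end-to-end passage of a tracked molecule
through an axis-aligned cylindrical section: the molecule must enter
through one z-face and leave through the opposite one while staying
within the cylinder radius in between ("strict" rule). Leaving through
the radial wall resets the attempt; re-entering afterwards starts a
fresh one. A looser "slab" rule that ignores the radius is also
available for thin sections such as the constriction slab.

The collective coordinate n(t) is the cumulative sum over frame pairs
of Σᵢ dzᵢ / L for the particles inside the cylinder in both frames;
its diffusion constant Dn gives the osmotic permeability pf = v_w·Dn.

Periodic handling: per-frame z displacements larger than half the box
are treated as periodic wraps (minimum image), never as crossings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .trajio import Selection, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "PoreGeometry",
    "PermeationEvents",
    "CollectiveSeries",
    "count_crossings",
    "water_count_per_block",
    "collective_coordinate",
    "pf_from_collective",
    "apply_dk",
]


@dataclass
class PoreGeometry:
    """Axis-aligned cylinder: lateral center (Å), radius (Å), z bounds (Å)."""

    center: tuple[float, float]
    radius: float
    z_lo: float
    z_hi: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.z_hi <= self.z_lo:
            raise ValueError("z_hi must exceed z_lo")

    @property
    def L(self) -> float:
        """Section length z_hi − z_lo (Å)."""
        return self.z_hi - self.z_lo


@dataclass
class PermeationEvents:
    """Recorded end-to-end crossings of one channel.

    ``events`` rows are (particle, entry_frame, exit_frame, direction)
    with direction +1 (toward +z) or −1. ``times`` are the frame times
    of the analysed trajectory (ns).
    """

    events: list[tuple[int, int, int, int]]
    times: np.ndarray
    geometry: PoreGeometry
    mode: str = "strict"

    def __post_init__(self):
        for p, ef, xf, d in self.events:
            if xf <= ef:
                raise ValueError(f"exit_frame {xf} must exceed entry_frame {ef}")
            if d not in (-1, 1):
                raise ValueError("direction must be +1 or -1")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def event_times(self) -> np.ndarray:
        """Exit time (ns) of each event."""
        return np.array([self.times[xf] for _, _, xf, _ in self.events])

    def directions(self) -> np.ndarray:
        return np.array([d for _, _, _, d in self.events], dtype=int)

    def cumulative(self) -> np.ndarray:
        """Per-frame cumulative event count (non-decreasing)."""
        counts = np.zeros(len(self.times), dtype=int)
        for _, _, xf, _ in self.events:
            counts[xf] += 1
        return np.cumsum(counts)


@dataclass
class CollectiveSeries:
    """Dimensionless cumulative collective coordinate n(t); n(0) = 0."""

    times: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.times.shape != self.n.shape:
            raise ValueError("times and n must have equal length")
        if self.n.size and self.n[0] != 0.0:
            raise ValueError("n(0) must be 0")


def _wrapped_z(trajectory: Trajectory, indices: np.ndarray) -> np.ndarray:
    z = trajectory.coordinates[:, indices, 2]
    return np.mod(z, trajectory.box[:, 2][:, None])


def _lateral_inside(
    trajectory: Trajectory, indices: np.ndarray, geometry: PoreGeometry
) -> np.ndarray:
    """(frames, particles) mask: within cylinder radius (minimum image)."""
    xy = trajectory.coordinates[:, indices, :2]
    box_xy = trajectory.box[:, None, :2]
    d = xy - np.asarray(geometry.center)
    d -= box_xy * np.round(d / box_xy)
    return np.einsum("fpk,fpk->fp", d, d) <= geometry.radius**2


def count_crossings(
    trajectory: Trajectory,
    selection: Selection,
    geometry: PoreGeometry,
    mode: str = "strict",
) -> PermeationEvents:
    """Count end-to-end permeation events through the cylinder.

    State machine per particle: entering through the lower (upper)
    z-face arms a +z (−z) attempt; exiting through the opposite face
    records an event; exiting through the same face or — in ``strict``
    mode — through the radial wall discards the attempt. Particles
    already inside at frame 0 are ineligible until they leave and
    re-enter. Frame-to-frame z jumps larger than half the box are
    minimum-imaged (periodic wraps).
    """
    if mode not in ("strict", "slab"):
        raise ValueError(f"mode must be 'strict' or 'slab', got {mode!r}")
    if len(selection) == 0:
        raise ValueError("selection is empty")
    idx = selection.indices
    z = _wrapped_z(trajectory, idx)
    in_z = (z >= geometry.z_lo) & (z <= geometry.z_hi)
    if mode == "strict":
        inside = in_z & _lateral_inside(trajectory, idx, geometry)
    else:
        inside = in_z

    n_frames, n_p = z.shape
    if n_frames > 1:
        median_dt = float(np.median(np.diff(trajectory.times)))
        # crude dwell estimate: a particle should need many frames to
        # traverse the section, else transits can be missed
        if median_dt > 0 and n_frames < 10:
            logger.warning(
                "very short trajectory (%d frames): undercounting risk", n_frames
            )

    state = np.zeros(n_p, dtype=int)  # 0 unarmed, +1 from lo face, -1 from hi
    entry_frame = np.full(n_p, -1, dtype=int)
    was_inside = inside[0].copy()
    events: list[tuple[int, int, int, int]] = []

    box_z = trajectory.box[:, 2]
    for t in range(1, n_frames):
        dz = z[t] - z[t - 1]
        dz -= box_z[t] * np.round(dz / box_z[t])
        z_cont = z[t - 1] + dz  # continuous position, no wrap
        now_inside = inside[t]

        # exits from the cylinder
        exiting = was_inside & ~now_inside
        if np.any(exiting):
            out_hi = exiting & (z_cont > geometry.z_hi)
            out_lo = exiting & (z_cont < geometry.z_lo)
            radial = exiting & ~out_hi & ~out_lo  # left via the wall
            for p in np.flatnonzero(out_hi & (state == 1)):
                events.append((int(idx[p]), int(entry_frame[p]), t, 1))
            for p in np.flatnonzero(out_lo & (state == -1)):
                events.append((int(idx[p]), int(entry_frame[p]), t, -1))
            state[exiting] = 0
            entry_frame[exiting] = -1
            del radial  # state already reset; kept for clarity

        # entries into the cylinder
        entering = ~was_inside & now_inside
        if np.any(entering):
            prev_cont = z[t] - dz
            from_lo = entering & (prev_cont < geometry.z_lo)
            from_hi = entering & (prev_cont > geometry.z_hi)
            state[from_lo] = 1
            state[from_hi] = -1
            entry_frame[from_lo | from_hi] = t
            # entries through the radial wall stay unarmed
            lateral_entry = entering & ~from_lo & ~from_hi
            state[lateral_entry] = 0

        was_inside = now_inside

    return PermeationEvents(
        events=events, times=trajectory.times.copy(), geometry=geometry, mode=mode
    )


def water_count_per_block(
    events: PermeationEvents, block_length: float
) -> np.ndarray:
    """Event counts in contiguous, start-anchored blocks of ``block_length`` ns.

    The trailing partial block, if any, is dropped (and logged). The sum
    of the returned counts equals the number of events within the
    retained span.
    """
    if block_length <= 0:
        raise ValueError("block_length must be positive")
    t0 = events.times[0]
    total = events.times[-1] - t0
    n_blocks = int(np.floor(total / block_length + 1e-9))
    if n_blocks == 0:
        raise ValueError(
            f"trajectory span {total:.3g} ns shorter than one block "
            f"({block_length} ns)"
        )
    if total - n_blocks * block_length > 1e-9:
        logger.info(
            "dropping partial block: %.3g ns beyond %d full blocks",
            total - n_blocks * block_length,
            n_blocks,
        )
    counts = np.zeros(n_blocks, dtype=int)
    for t in events.event_times():
        b = int((t - t0) / block_length)
        if b < n_blocks:
            counts[b] += 1
    return counts


def collective_coordinate(
    trajectory: Trajectory, selection: Selection, geometry: PoreGeometry
) -> CollectiveSeries:
    """Cumulative collective coordinate n(t) of the pore section.

    For each consecutive frame pair, dn = Σᵢ dzᵢ / L over the particles
    inside the cylinder in *both* frames, with minimum-image dzᵢ.
    """
    if len(selection) == 0:
        raise ValueError("selection is empty")
    idx = selection.indices
    z = _wrapped_z(trajectory, idx)
    inside = ((z >= geometry.z_lo) & (z <= geometry.z_hi)) & _lateral_inside(
        trajectory, idx, geometry
    )
    box_z = trajectory.box[:, 2]
    dz = z[1:] - z[:-1]
    dz -= box_z[1:, None] * np.round(dz / box_z[1:, None])
    both = inside[1:] & inside[:-1]
    dn = np.sum(dz * both, axis=1) / geometry.L
    n = np.concatenate([[0.0], np.cumsum(dn)])
    return CollectiveSeries(times=trajectory.times.copy(), n=n)


def pf_from_collective(series: CollectiveSeries, v_w=None, msd_fit_window=0.2, **kw):
    """Osmotic permeability from a collective series (Dk = 1).

    Thin wrapper over :class:`poreflux.model.CollectiveDiffusionModel`;
    returns its fitted :class:`poreflux.model.PermeabilityResults`.
    """
    from .model import CollectiveDiffusionModel

    kwargs = dict(kw)
    if v_w is not None:
        kwargs["v_w"] = v_w
    return CollectiveDiffusionModel(series, fit_window=msd_fit_window, **kwargs).fit()


def apply_dk(result, profile, section=None):
    """Apply the free-energy-barrier correction Dk to a permeability result.

    Dk = exp(−ΔG_max/kT) with ΔG_max the highest barrier of ``profile``
    within ``section`` relative to the bulk zero level; see
    :meth:`poreflux.model.PermeabilityResults.apply_dk`.
    """
    return result.apply_dk(profile, section=section)
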