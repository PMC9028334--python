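"""Trajectory container, file readers and atom selections.

File parsing (PDB/GRO topology, XTC/DCD coordinates) and the selection
grammar are delegated to MDAnalysis; this module only adapts them to the
package's in-memory :class:`Trajectory` model, which stores coordinates
in Å and times in ns regardless of the source format.

Periodic-boundary unwrapping is deliberately *not* applied on load:
permeation counting needs the raw wrapped coordinates with explicit
jump detection, and every analysis documents its own minimum-image
handling.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_CHAIN_TOKEN = re.compile(r"\bchain\b(?!ID)")


@dataclass
class AtomMeta:
    """Per-atom metadata carried alongside coordinates."""

    name: str
    residue_name: str
    residue_id: int
    chain_id: str = ""
    partial_charge: float | None = None
    vdw_radius: float | None = None

    def __post_init__(self):
        if self.residue_id < 0:
            raise ValueError(f"residue_id must be >= 0, got {self.residue_id}")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be > 0, got {self.vdw_radius}")


@dataclass
class Trajectory:
    """Frames × atoms × 3 coordinates (Å) with per-frame box and times (ns).

    Boxes are orthorhombic: three lengths per frame. Atom metadata is a
    list of :class:`AtomMeta`, one per atom, in coordinate order.
    """

    coordinates: np.ndarray
    box: np.ndarray
    times: np.ndarray
    atoms: list[AtomMeta] = field(repr=False)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError(
                f"coordinates must be (frames, atoms, 3), got {self.coordinates.shape}"
            )
        n_frames, n_atoms = self.coordinates.shape[:2]
        if n_frames == 0:
            raise ValueError("trajectory has 0 frames")
        if len(self.atoms) != n_atoms:
            raise ValueError(
                f"{len(self.atoms)} AtomMeta entries for {n_atoms} atoms"
            )
        if self.box.shape == (3,):
            self.box = np.tile(self.box, (n_frames, 1))
        if self.box.shape != (n_frames, 3):
            raise ValueError(f"box must be (frames, 3), got {self.box.shape}")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if self.times.shape != (n_frames,):
            raise ValueError("times must have one entry per frame")
        if n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        self._universe = None

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    # --- MDAnalysis adapter (cached), used by select() and writers ----
    def _as_universe(self):
        if self._universe is not None:
            return self._universe
        import MDAnalysis as mda

        names = [a.name for a in self.atoms]
        resnames = [a.residue_name for a in self.atoms]
        resids = [a.residue_id for a in self.atoms]
        chains = [a.chain_id or "X" for a in self.atoms]

        # group consecutive atoms with identical (resid, resname, chain)
        keys = list(zip(resids, resnames, chains))
        res_index = np.zeros(len(keys), dtype=int)
        uniq = []
        for i, k in enumerate(keys):
            if not uniq or k != uniq[-1]:
                uniq.append(k)
            res_index[i] = len(uniq) - 1

        u = mda.Universe.empty(
            n_atoms=self.n_atoms,
            n_residues=len(uniq),
            atom_resindex=res_index,
            residue_segindex=np.zeros(len(uniq), dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", names)
        u.add_TopologyAttr("resnames", [k[1] for k in uniq])
        u.add_TopologyAttr("resids", [k[0] for k in uniq])
        u.add_TopologyAttr("chainIDs", chains)
        charges = [a.partial_charge for a in self.atoms]
        if all(c is not None for c in charges):
            u.add_TopologyAttr("charges", charges)
        u.atoms.positions = self.coordinates[0]
        u.dimensions = [*self.box[0], 90.0, 90.0, 90.0]
        self._universe = u
        return u


@dataclass
class Selection:
    """A labelled, deduplicated set of atom indices into a Trajectory."""

    label: str
    indices: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.size != np.unique(idx).size:
            raise ValueError("selection indices must be unique")
        self.indices = np.sort(idx)

    def __len__(self) -> int:
        return len(self.indices)


def load_trajectory(topology_path, trajectory_path=None) -> Trajectory:
    """Read a topology (PDB/GRO) plus optional trajectory (XTC/DCD).

    Coordinates are returned in Å and times in ns whatever the native
    units of the source format (MDAnalysis converts XTC's nm and ps).
    An atom-count mismatch between the two files is a hard error naming
    both counts.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        top = mda.Universe(str(topology_path))
        n_top = len(top.atoms)
        if trajectory_path is None:
            u = top
        else:
            try:
                u = mda.Universe(str(topology_path), str(trajectory_path))
            except (ValueError, OSError) as exc:
                # re-probe the trajectory for a clear count mismatch message
                raise ValueError(
                    f"cannot pair topology ({n_top} atoms) with trajectory "
                    f"{trajectory_path}: {exc}"
                ) from exc

        n_frames = len(u.trajectory)
        if n_frames == 0:
            raise ValueError("trajectory contains 0 frames")

        coords = np.empty((n_frames, n_top, 3))
        box = np.empty((n_frames, 3))
        times = np.empty(n_frames)
        for i, ts in enumerate(u.trajectory):
            coords[i] = u.atoms.positions  # Å
            if ts.dimensions is None or np.all(ts.dimensions[:3] == 0):
                raise ValueError("frame without box dimensions")
            box[i] = ts.dimensions[:3]
            times[i] = ts.time / 1000.0  # ps → ns

        charges = getattr(u.atoms, "charges", None)
        try:
            chain_ids = u.atoms.chainIDs
        except (AttributeError, mda.exceptions.NoDataError):
            try:
                chain_ids = u.atoms.segids
            except (AttributeError, mda.exceptions.NoDataError):
                chain_ids = [""] * n_top

        atoms = [
            AtomMeta(
                name=str(u.atoms.names[i]),
                residue_name=str(u.atoms.resnames[i]),
                residue_id=int(u.atoms.resids[i]),
                chain_id=str(chain_ids[i]),
                partial_charge=None if charges is None else float(charges[i]),
            )
            for i in range(n_top)
        ]

    if n_frames > 1 and not np.all(np.diff(times) > 0):
        # some writers store zero/constant times; rebase to frame index
        times = np.arange(n_frames, dtype=float) * (
            times[1] - times[0] if n_frames > 1 and times[1] > times[0] else 1.0
        )
    return Trajectory(coordinates=coords, box=box, times=times, atoms=atoms)


def select(trajectory: Trajectory, expression: str) -> Selection:
    """Resolve a selection expression to atom indices.

    The grammar is the MDAnalysis selection language (``resname``,
    ``resid``, ``name``, ``chainID``, boolean ``and/or/not``, ...);
    the shorthand ``chain X`` is accepted for ``chainID X``. An empty
    result is legal but logged.
    """
    from MDAnalysis.exceptions import SelectionError

    expr = _CHAIN_TOKEN.sub("chainID", expression)
    u = trajectory._as_universe()
    try:
        group = u.select_atoms(expr)
    except SelectionError as exc:
        raise ValueError(f"malformed selection {expression!r}: {exc}") from exc
    if len(group) == 0:
        logger.warning("selection %r matched no atoms", expression)
    return Selection(label=expression, indices=group.indices)


def write_gro_xtc(trajectory: Trajectory, gro_path, xtc_path) -> None:
    """Write a GRO topology frame plus an XTC coordinate trajectory.

    Coordinates are converted to the formats' native nm by MDAnalysis;
    XTC stores positions with 0.001 nm precision.
    """
    import MDAnalysis as mda

    u = trajectory._as_universe()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.positions = trajectory.coordinates[0]
        u.dimensions = [*trajectory.box[0], 90.0, 90.0, 90.0]
        u.atoms.write(str(gro_path))
        with mda.Writer(str(xtc_path), trajectory.n_atoms) as w:
            for i in range(trajectory.n_frames):
                u.atoms.positions = trajectory.coordinates[i]
                u.dimensions = [*trajectory.box[i], 90.0, 90.0, 90.0]
                u.trajectory.ts.time = trajectory.times[i] * 1000.0  # ns → ps
                u.trajectory.ts.frame = i
                w.write(u.atoms)


def minimum_image(displacement: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap a displacement vector (or array of them) into the minimum image.

    ``box`` broadcasts against the last axis of ``displacement``.
    """
    return displacement - box * np.round(displacement / box)
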