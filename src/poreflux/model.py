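"""Collective-diffusion permeability model and its results object.

The osmotic permeability of a single channel is estimated from the
collective permeation coordinate n(t): at equilibrium n(t) performs a
one-dimensional random walk with diffusion constant Dn (ns⁻¹), and

    pf = v_w · Dn

with v_w the volume of one water molecule. Dn is obtained from a least
squares fit of the mean-squared displacement ⟨n(t)²⟩ = 2·Dn·t computed
over non-overlapping restart segments of the path.

Closed or obstructed channels still show thermal n(t) fluctuations, so
the raw estimator overstates their permeability. The Dk correction
multiplies pf by exp(−ΔG_max/kT), where ΔG_max is the highest
free-energy barrier along the pore section relative to bulk: a
barrier-free channel is untouched (Dk = 1), a kT barrier scales pf by
1/e, and Dk decreases monotonically with barrier height.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .permeation import CollectiveSeries
from .units import PER_NS_TO_PER_S, V_WATER_CM3, kt

__all__ = ["CollectiveDiffusionModel", "PermeabilityResults"]


def _fit_dn(n: np.ndarray, dt: float, n_segments: int, fit_window: float):
    """Dn (ns⁻¹) and its standard error from restart-segment MSD."""
    m = len(n) // n_segments
    if m < 5:
        raise ValueError(
            f"series too short: {len(n)} frames for {n_segments} segments"
        )
    segs = n[: n_segments * m].reshape(n_segments, m)
    paths = segs - segs[:, :1]
    msd = np.mean(paths**2, axis=0)  # ⟨n(τ)²⟩, τ = k·dt
    w = max(3, int(round(fit_window * m)))
    tau = np.arange(w) * dt
    y = msd[:w]
    x = np.column_stack([np.ones(w), tau])
    coef, res, *_ = np.linalg.lstsq(x, y, rcond=None)
    slope = coef[1]
    dof = max(w - 2, 1)
    sigma2 = (res[0] / dof) if res.size else 0.0
    cov = sigma2 * np.linalg.inv(x.T @ x)
    return slope / 2.0, np.sqrt(cov[1, 1]) / 2.0


class CollectiveDiffusionModel:
    """Permeability model built from a collective coordinate series.

    Parameters
    ----------
    series : CollectiveSeries or (times, n) pair
        The cumulative collective coordinate; times in ns.
    v_w : float
        Single-water volume in cm³ (default 18.07 cm³/mol / N_A).
    n_segments : int, optional
        Number of non-overlapping restart segments for the MSD. Default
        (None): one segment per ~50 frames, at least 10 segments — many
        short restarts keep the MSD variance at long lags in check.
    fit_window : float
        Fraction of each segment over which the MSD is fitted.
    block_length : float, optional
        If given, pf is additionally estimated per contiguous block of
        this many ns (e.g. the 10 ns replicates the statistics pipeline
        consumes).
    """

    def __init__(
        self,
        series,
        v_w: float = V_WATER_CM3,
        n_segments: int | None = None,
        fit_window: float = 0.2,
        block_length: float | None = None,
    ):
        if not isinstance(series, CollectiveSeries):
            times, n = series
            series = CollectiveSeries(times=times, n=n)
        if len(series.n) < 10:
            raise ValueError("series far shorter than any usable fit window")
        dts = np.diff(series.times)
        if not np.allclose(dts, dts[0], rtol=1e-6):
            raise ValueError("series must be uniformly sampled in time")
        self.series = series
        self.dt = float(dts[0])
        self.v_w = float(v_w)
        if n_segments is None:
            n_segments = max(10, len(series.n) // 50)
        self.n_segments = int(n_segments)
        self.fit_window = float(fit_window)
        self.block_length = block_length

    @classmethod
    def from_trajectory(cls, trajectory, selection, geometry, **kwargs):
        """Build the model directly from a trajectory + pore geometry."""
        from .permeation import collective_coordinate

        series = collective_coordinate(trajectory, selection, geometry)
        return cls(series, **kwargs)

    def fit(self) -> "PermeabilityResults":
        dn, dn_se = _fit_dn(self.series.n, self.dt, self.n_segments, self.fit_window)
        if dn < 0:
            warnings.warn(
                f"negative fitted MSD slope ({2 * dn:.3g}/ns); pf set to 0",
                stacklevel=2,
            )
            dn = 0.0
        block_values = None
        if self.block_length is not None:
            block_values = self._block_pf(self.block_length)
        return PermeabilityResults(
            Dn=dn,
            Dn_se=dn_se,
            v_w=self.v_w,
            Dk=1.0,
            block_values=block_values,
            n_obs=len(self.series.n),
            model=self,
        )

    def _block_pf(self, block_length: float) -> np.ndarray:
        frames_per_block = int(round(block_length / self.dt))
        n_blocks = (len(self.series.n) - 1) // frames_per_block
        vals = []
        for b in range(n_blocks):
            seg = self.series.n[b * frames_per_block : (b + 1) * frames_per_block + 1]
            seg = seg - seg[0]
            n_seg = max(4, len(seg) // 50)
            dn, _ = _fit_dn(seg, self.dt, n_seg, self.fit_window)
            vals.append(max(dn, 0.0) * self.v_w * PER_NS_TO_PER_S)
        return np.array(vals)


@dataclass
class PermeabilityResults:
    """Fitted permeability with optional barrier correction.

    Attributes use the field's reporting units: ``Dn`` in ns⁻¹, ``pf``
    and ``pf_corrected`` in cm³·s⁻¹, ``Dk`` dimensionless in (0, 1].
    """

    Dn: float
    Dn_se: float
    v_w: float
    Dk: float = 1.0
    block_values: np.ndarray | None = None
    n_obs: int = 0
    model: CollectiveDiffusionModel | None = None
    barrier_height: float | None = None  # kcal/mol, set by apply_dk
    barrier_z: float | None = None

    @property
    def pf(self) -> float:
        """Uncorrected osmotic permeability (cm³·s⁻¹)."""
        return self.v_w * self.Dn * PER_NS_TO_PER_S

    @property
    def pf_se(self) -> float:
        return self.v_w * self.Dn_se * PER_NS_TO_PER_S

    @property
    def pf_corrected(self) -> float:
        """Barrier-corrected permeability Dk · pf (cm³·s⁻¹)."""
        return self.Dk * self.pf

    def apply_dk(self, profile, section=None) -> "PermeabilityResults":
        """Return a copy with Dk = exp(−ΔG_max/kT) from a free-energy profile.

        ``profile`` is an :class:`poreflux.energetics.FreeEnergyProfile`;
        ``section`` restricts the barrier search to a (z_lo, z_hi) range
        (default: the whole profile). Undefined (zero-occupancy) slices
        inside the section are a hard error — they may hide the true
        barrier.
        """
        from .energetics import barrier

        dg_max, z_pos = barrier(profile, section=section, require_defined=True)
        dg_max = max(dg_max, 0.0)  # wells do not boost pf
        dk = float(np.exp(-dg_max / kt(profile.T)))
        return replace(self, Dk=dk, barrier_height=dg_max, barrier_z=z_pos)

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = [
            "Collective-diffusion permeability",
            "=" * 44,
            f"{'n(t) frames':<28}{self.n_obs:>16d}",
            f"{'Dn (ns^-1)':<28}{self.Dn:>16.6g}",
            f"{'Dn std err (ns^-1)':<28}{self.Dn_se:>16.3g}",
            f"{'v_w (cm^3)':<28}{self.v_w:>16.4g}",
            f"{'pf (cm^3 s^-1)':<28}{self.pf:>16.4g}",
            f"{'Dk':<28}{self.Dk:>16.4g}",
            f"{'pf corrected (cm^3 s^-1)':<28}{self.pf_corrected:>16.4g}",
        ]
        if self.barrier_height is not None:
            lines.append(
                f"{'barrier (kcal/mol @ z Å)':<28}"
                f"{self.barrier_height:>10.3g} @ {self.barrier_z:.1f}"
            )
        if self.block_values is not None and len(self.block_values):
            bv = self.block_values
            lines.append(
                f"{'block pf mean ± sd':<28}{np.mean(bv):>10.3g} ± {np.std(bv):.2g}"
                f"  (n={len(bv)})"
            )
        lines.append("=" * 44)
        return "\n".join(lines)
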