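"""Translational and rotational dynamics of the monomers.

Mean squared displacements of molecular centres of mass are averaged
over particles and time origins (FFT accelerated); the diffusion
coefficient follows from the Einstein relation MSD(tau) = 6 D tau.
Rotational dynamics are characterised by the autocorrelation of unit
vectors attached to each monomer: the hexagon plane normal, or the
dipole vector for the Mcoop variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import Trajectory


@dataclass
class MSDCurve:
    tau_ns: np.ndarray
    msd: np.ndarray  # nm^2
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tau_ns": self.tau_ns, "msd_nm2": self.msd})


@dataclass
class OrientationACF:
    lag_ns: np.ndarray
    acf: np.ndarray
    vector: str
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_ns": self.lag_ns, "acf": self.acf})


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD of one scalar coordinate series (F,)."""
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acorr = np.fft.irfft(f * f.conjugate(), nfft)[:n].real
    sq = x * x
    sumsq = np.cumsum(sq)
    tail = np.cumsum(sq[::-1])
    counts = n - np.arange(n)
    s1 = sumsq[-1] - np.concatenate([[0.0], sumsq[:-1]]) \
        + tail[-1] - np.concatenate([[0.0], tail[:-1]])
    # s1[k] = sum_{t} x_t^2 + x_{t+k}^2 over valid origins
    return s1 / counts - 2.0 * acorr / counts


def msd(traj: Trajectory, species: str | None = None) -> MSDCurve:
    """Particle- and time-origin-averaged MSD of molecular centres of mass.

    Requires unwrapped coordinates (the engine stores them natively);
    ``species`` restricts the average to one molecule type.
    """
    if not traj.unwrapped:
        raise ValueError("MSD needs unwrapped coordinates; this trajectory "
                         "is wrapped and carries no image information")
    com = traj.com_positions()
    if species is not None:
        sel = [m for m, s in enumerate(traj.species) if s == species]
        if not sel:
            raise ValueError(f"no molecules of species {species!r}")
        com = com[:, sel, :]
    n_frames = com.shape[0]
    total = np.zeros(n_frames)
    for m in range(com.shape[1]):
        for d in range(3):
            total += _msd_fft(np.ascontiguousarray(com[:, m, d]))
    total /= com.shape[1]
    dt = traj.sampling_dt_ns
    return MSDCurve(np.arange(n_frames) * dt, total,
                    meta={"n_molecules": com.shape[1], "species": species})


def diffusion_coefficient(curve: MSDCurve,
                          fit_window: tuple[float, float] = (0.2, 0.8)
                          ) -> float:
    """Einstein-relation diffusion coefficient, nm^2/ns.

    ``fit_window`` is (start, end) as fractions of the sampled lag range
    (default the central 20-80% band, where the curve is diffusive);
    the slope of an ordinary least-squares line over that window is
    divided by 6.
    """
    lo, hi = fit_window
    tmax = curve.tau_ns[-1]
    sel = (curve.tau_ns >= lo * tmax) & (curve.tau_ns <= hi * tmax)
    if sel.sum() < 2:
        raise ValueError("fit window selects fewer than two points")
    slope, _ = np.polyfit(curve.tau_ns[sel], curve.msd[sel], 1)
    return float(slope) / 6.0


def orientation_acf(traj: Trajectory, vector: str = "plane_normal",
                    max_lag_frames: int | None = None) -> OrientationACF:
    """Autocorrelation <u(t) . u(t+tau)> of a per-monomer unit vector.

    ``vector`` is ``plane_normal`` (any hexagonal species) or ``dipole``
    (Mcoop variants only; requesting it for a dipole-free system is an
    error).  Averaged over molecules and time origins; ACF(0) = 1.
    """
    if vector == "plane_normal":
        u = traj.plane_normals()
    elif vector == "dipole":
        u = traj.dipole_vectors()
    else:
        raise ValueError(f"unknown vector type {vector!r}")
    n_frames = u.shape[0]
    if max_lag_frames is None:
        max_lag_frames = n_frames - 1
    max_lag_frames = min(max_lag_frames, n_frames - 1)
    acf = np.empty(max_lag_frames + 1)
    for k in range(max_lag_frames + 1):
        dots = np.einsum("fmd,fmd->fm", u[:n_frames - k], u[k:])
        acf[k] = dots.mean()
    dt = traj.sampling_dt_ns
    return OrientationACF(np.arange(max_lag_frames + 1) * dt, acf, vector,
                          meta={"n_molecules": u.shape[1]})
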