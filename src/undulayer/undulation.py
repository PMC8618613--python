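"""Surface extraction, smoothing and sine fitting of the layer undulation.

The monolayer surface is represented by the base (aglycone-root) atom of each
molecule.  Per block of trajectory time the per-molecule coordinates are
averaged, binned along y into a middle line, and fitted with

    z(y) = y0 + A sin(2π y / B + C)

by nonlinear least squares with multi-start initialisation (amplitude and
offset from the data range, period candidates from the dominant discrete
Fourier mode of the line with the box length as fallback, phase from a coarse
8-point grid).  Fits are canonicalised to A ≥ 0 and C ∈ (−π, π].  The period
is deliberately *not* constrained to the box length: a wave can span more
than one periodic image, so B/Ly may exceed 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import AnalysisError, FitError, ParameterError
from .io import MonolayerFrame


@dataclass
class SurfacePointSet:
    """Per-molecule block-averaged base-atom coordinates."""

    time: float  # block start, ns
    mol_ids: np.ndarray
    xyz: np.ndarray  # (n_mol, 3) nm
    box: tuple[float, float, float]


@dataclass
class SurfaceWaveFit:
    """Fitted sine parameters with uncertainties."""

    A: float  # amplitude, nm (>= 0)
    B: float  # period, nm (> 0)
    C: float  # horizontal phase, rad, in (-pi, pi]
    y0: float  # vertical offset, nm
    se: tuple[float, float, float, float] = (np.nan,) * 4
    rms_residual: float = np.nan
    n_points: int = 0
    period_unidentifiable: bool = False

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.A, self.B, self.C, self.y0)

    def z(self, y) -> np.ndarray:
        return self.y0 + self.A * np.sin(2 * np.pi * np.asarray(y) / self.B + self.C)


def extract_surface_points(
    frames: list[MonolayerFrame], block: float = 50.0
) -> list[SurfacePointSet]:
    """Time-average base-atom coordinates per molecule over each block."""
    if not frames:
        raise ParameterError("need at least one frame")
    times = np.array([fr.time for fr in frames])
    duration = times[-1] - times[0] + (
        times[1] - times[0] if len(times) > 1 else block
    )
    n_blocks = int(math.floor(duration / block + 1e-9))
    if n_blocks < 1:
        raise ParameterError("block duration exceeds the trajectory length")
    mols = frames[0].surfactant_mol_ids()
    base_sel0 = frames[0].roles == "aglycone_base"
    out = []
    k_idx = np.floor((times - times[0]) / block).astype(int)
    for k in range(n_blocks):
        sel_frames = [fr for fr, kk in zip(frames, k_idx) if kk == k]
        acc = np.zeros((len(mols), 3))
        for frame in sel_frames:
            base_sel = frame.roles == "aglycone_base"
            order = np.argsort(frame.mol_ids[base_sel])
            acc += frame.xyz[base_sel][order]
        acc /= len(sel_frames)
        out.append(
            SurfacePointSet(
                time=float(times[0] + k * block),
                mol_ids=np.sort(frames[0].mol_ids[base_sel0]),
                xyz=acc,
                box=frames[0].box,
            )
        )
    return out


def smooth_profile(
    points: SurfacePointSet, n_bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Bin points along y into a middle line (mean z at the bin's mean y).

    y is partitioned into ``n_bins`` equal bins over [0, Ly); empty bins are
    dropped.  Each middle-line point is the centroid (mean y, mean z) of its
    bin, so points that already lie on a curve stay on it; binned means are
    deterministic and parameter-light, which is why they stand in for heavier
    smoothers.
    """
    if n_bins < 2:
        raise AnalysisError("need at least 2 bins to form a middle line")
    ly = points.box[1]
    y = np.mod(points.xyz[:, 1], ly)
    z = points.xyz[:, 2]
    edges = np.linspace(0.0, ly, n_bins + 1)
    idx = np.clip(np.digitize(y, edges) - 1, 0, n_bins - 1)
    centres, means = [], []
    for b in range(n_bins):
        sel = idx == b
        if np.any(sel):
            centres.append(float(np.mean(y[sel])))
            means.append(float(np.mean(z[sel])))
    if len(centres) < 2:
        raise AnalysisError("all points fall into a single y-bin")
    return np.array(centres), np.array(means)


def _sine(y, amp, period, phase, y0):
    return y0 + amp * np.sin(2 * np.pi * y / period + phase)


def _canonical(p):
    amp, period, phase, y0 = p
    period = abs(period)
    if amp < 0:
        amp, phase = -amp, phase + math.pi
    phase = math.remainder(phase, 2 * math.pi)
    if phase <= -math.pi:
        phase += 2 * math.pi
    elif phase > math.pi:
        phase -= 2 * math.pi
    return amp, period, phase, y0


def _period_candidates(y: np.ndarray, z: np.ndarray, box_ly: float) -> list[float]:
    cands = [box_ly]
    span = y.max() - y.min()
    if span > 0 and len(y) >= 8:
        grid = np.linspace(y.min(), y.max(), 256)
        zi = np.interp(grid, np.sort(y), z[np.argsort(y)])
        zi = zi - zi.mean()
        power = np.abs(np.fft.rfft(zi)) ** 2
        freqs = np.fft.rfftfreq(len(grid), d=grid[1] - grid[0])
        order = np.argsort(power[1:])[::-1] + 1  # skip the DC mode
        for k in order[:2]:
            if freqs[k] > 0:
                cands.append(1.0 / freqs[k])
    cands.extend([0.5 * box_ly, 1.5 * box_ly])
    return cands


def fit_sine(y, z, box_ly: float) -> SurfaceWaveFit:
    """Fit z(y) = y0 + A sin(2πy/B + C) by multi-start least squares."""
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if len(y) < 8:
        raise ParameterError("need at least 8 points to fit the sine")
    if y.max() - y.min() < box_ly / 2:
        raise ParameterError("points must span at least half the box length")
    a0 = (z.max() - z.min()) / 2.0
    y00 = float(np.mean(z))

    if a0 == 0.0:  # exactly flat line: amplitude zero, period meaningless
        return SurfaceWaveFit(
            A=0.0, B=box_ly, C=0.0, y0=y00,
            se=(0.0, np.nan, np.nan, 0.0),
            rms_residual=0.0, n_points=len(y), period_unidentifiable=True,
        )

    best = None
    for b0 in _period_candidates(y, z, box_ly):
        for c0 in np.linspace(-math.pi, math.pi, 8, endpoint=False):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, pcov = curve_fit(
                        _sine, y, z,
                        p0=[max(a0, 1e-6), b0, c0, y00],
                        maxfev=5000,
                    )
            except (RuntimeError, ValueError):
                continue
            resid = z - _sine(y, *popt)
            sse = float(np.dot(resid, resid))
            if best is None or sse < best[0]:
                best = (sse, popt, pcov)
    if best is None:
        raise FitError("sine fit did not converge from any start")
    sse, popt, pcov = best
    amp, period, phase, y0 = _canonical(popt)
    se = tuple(float(v) for v in np.sqrt(np.abs(np.diag(pcov))))
    rms = math.sqrt(sse / len(y))
    unident = bool(
        amp < 10 * rms / math.sqrt(len(y)) or (
            np.isfinite(se[1]) and se[1] > abs(period)
        )
    )
    return SurfaceWaveFit(
        A=amp, B=period, C=phase, y0=y0,
        se=se, rms_residual=rms, n_points=len(y),
        period_unidentifiable=unident,
    )


def wave_box_ratio(fit: SurfaceWaveFit, box_ly: float) -> float:
    """Ratio of the fitted period to the lateral box length, B / Ly."""
    return fit.B / box_ly


def fit_undulation(
    frames: list[MonolayerFrame],
    block: float = 50.0,
    n_bins: int = 50,
) -> list[tuple[SurfacePointSet, SurfaceWaveFit]]:
    """Full chain per block: extract points, smooth, fit the sine."""
    out = []
    for points in extract_surface_points(frames, block):
        yline, zline = smooth_profile(points, n_bins)
        out.append((points, fit_sine(yline, zline, points.box[1])))
    return out
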