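"""Molecular tilt, tilt histograms, rotational order parameter and the
surface-slope correction.

The tilt α of a molecule is the angle between its aglycone vector (tip −
base) and the +z axis, in degrees.  The orientation convention puts an
upright molecule — tip below base, pointing into the water — at α near 180°,
so reported tilts live in the 90–180° range.  The rotational order parameter
is the first-rank polar average OP = <cos(180° − α)> over molecules and/or
time: 1 for crystalline-like alignment along −z, 0 for an isotropic layer.

Because the layer undulates, part of the lab-frame tilt is surface slope, not
molecular orientation.  Two corrections are provided:

* :func:`corrected_tilt` — scalar subtraction of the fitted slope angle from
  the mean tilt.  This is the simple arithmetic used when reporting a single
  corrected mean (e.g. 142° − 37° = 105°), but it is ambiguous whenever the
  lab-frame angle folds at 180°.
* :func:`local_normal_tilt` — the exact per-molecule angle between the
  aglycone vector and the local surface normal of a fitted wave, immune to
  the folding ambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import AnalysisError, GeometryError, ParameterError
from .io import BlockSeries, MonolayerFrame, block_average


@dataclass
class TiltRecord:
    """Per-frame, per-molecule tilt angles (degrees in [0, 180])."""

    times: np.ndarray  # (n_frames,) ns
    mol_ids: np.ndarray  # (n_mol,)
    angles: np.ndarray  # (n_frames, n_mol) degrees
    base_y: np.ndarray  # (n_frames, n_mol) base-atom y, for spatial windows


@dataclass
class OrderParameterResult:
    """Rotational order parameter, block-resolved or per molecule."""

    mode: str  # "per_block" | "per_molecule"
    blocks: BlockSeries | None = None
    mol_ids: np.ndarray | None = None
    per_molecule: np.ndarray | None = None


@dataclass
class SlopeResult:
    """Surface slope vs the z-axis from a linear fit of base-atom (y, z)."""

    angle: float  # degrees, in [0, 90)
    stderr: float  # degrees
    window: tuple[float, float]  # y-range of the fit, nm
    n_points: int


def _axis_vectors(frame: MonolayerFrame):
    mols = frame.surfactant_mol_ids()
    base_sel = frame.roles == "aglycone_base"
    tip_sel = frame.roles == "aglycone_tip"
    base = np.zeros((len(mols), 3))
    tip = np.zeros((len(mols), 3))
    for k, mol in enumerate(mols):
        msel = frame.mol_ids == mol
        base[k] = frame.xyz[msel & base_sel][0]
        tip[k] = frame.xyz[msel & tip_sel][0]
    return mols, base, tip


def tilt_angles(frames: list[MonolayerFrame]) -> TiltRecord:
    """Tilt α per frame and molecule: angle between (tip − base) and +z."""
    if not frames:
        raise ParameterError("need at least one frame")
    mols0, _, _ = _axis_vectors(frames[0])
    angles = np.zeros((len(frames), len(mols0)))
    base_y = np.zeros_like(angles)
    for i, frame in enumerate(frames):
        mols, base, tip = _axis_vectors(frame)
        if not np.array_equal(mols, mols0):
            raise ParameterError("frames contain different surfactant molecules")
        vec = tip - base
        norm = np.linalg.norm(vec, axis=1)
        if np.any(norm == 0):
            raise GeometryError("zero-length aglycone vector")
        cosa = np.clip(vec[:, 2] / norm, -1.0, 1.0)
        angles[i] = np.degrees(np.arccos(cosa))
        base_y[i] = base[:, 1]
    return TiltRecord(
        times=np.array([fr.time for fr in frames]),
        mol_ids=mols0,
        angles=angles,
        base_y=base_y,
    )


def tilt_histogram(record: TiltRecord, edges) -> np.ndarray:
    """Fraction of tilt samples per bin; bins are half-open [lo, hi).

    The final edge is closed (numpy convention) so α exactly at the last edge
    is kept.  Fractions are normalised over the samples falling in the
    covered range.
    """
    edges = np.asarray(edges, dtype=float)
    if record.angles.size == 0:
        raise ParameterError("empty tilt record")
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ParameterError("bin edges must be a sorted 1-D array")
    hist, _ = np.histogram(record.angles.ravel(), bins=edges)
    total = hist.sum()
    if total == 0:
        raise AnalysisError("no tilt samples fall inside the bin range")
    return hist / total


def order_parameter(
    record: TiltRecord,
    mode: str = "per_block",
    block: float = 50.0,
    window: tuple[float, float] | None = None,
) -> OrderParameterResult:
    """Rotational order parameter OP = <cos(180° − α)>.

    ``per_block``: per-frame means over molecules, block-averaged over
    ``block`` ns.  ``per_molecule``: time average per molecule over ``window``
    (a (t0, t1) interval in ns; whole record when None).
    """
    if record.angles.size == 0:
        raise ParameterError("empty tilt record")
    op = np.cos(np.radians(180.0 - record.angles))  # (n_frames, n_mol)
    if window is not None:
        t0, t1 = window
        sel = (record.times >= t0) & (record.times < t1)
        if not np.any(sel):
            raise ParameterError("window contains no frames")
    else:
        sel = np.ones(len(record.times), dtype=bool)
    if mode == "per_block":
        frame_means = np.mean(op[sel], axis=1)
        return OrderParameterResult(
            mode=mode,
            blocks=block_average(record.times[sel], frame_means, block),
        )
    if mode == "per_molecule":
        return OrderParameterResult(
            mode=mode,
            mol_ids=record.mol_ids,
            per_molecule=np.mean(op[sel], axis=0),
        )
    raise ParameterError(f"unknown mode {mode!r}")


def segment_windows(
    wave: tuple[float, float, float, float],
    box_ly: float,
    central_fraction: float = 0.5,
) -> list[tuple[float, float]]:
    """Central part of each monotonic segment of the fitted wave in [0, Ly).

    Monotonic segments run between consecutive extrema of
    z = y0 + A sin(2πy/B + C); the default keeps the central 50% of each —
    the quasilinear part used for the straight-line slope fit.
    """
    amp, period, phase, _ = wave
    if amp == 0:
        raise AnalysisError("flat wave has no monotonic segments")
    # extrema where 2πy/B + C = π/2 + kπ
    k0 = math.floor((2 * math.pi * 0.0 / period + phase - math.pi / 2) / math.pi)
    ext = []
    k = k0 - 1
    while True:
        y = ((math.pi / 2 + k * math.pi) - phase) * period / (2 * math.pi)
        if y > box_ly + period:
            break
        ext.append(y)
        k += 1
    windows = []
    for y1, y2 in zip(ext[:-1], ext[1:]):
        mid = 0.5 * (y1 + y2)
        half = 0.5 * central_fraction * (y2 - y1)
        lo, hi = mid - half, mid + half
        if hi <= 0 or lo >= box_ly:
            continue
        windows.append((max(lo, 0.0), min(hi, box_ly)))
    return windows


def surface_slope(
    frames: list[MonolayerFrame],
    window: tuple[float, float],
    wave: tuple[float, float, float, float] | None = None,
) -> SlopeResult:
    """Least-squares straight line through base-atom (y, z) inside ``window``.

    Returns the slope angle arctan(|dz/dy|) in degrees.  When the fitted
    ``wave`` is supplied, a window containing one of its extrema is rejected
    (the surface is not quasilinear there).
    """
    lo, hi = window
    if hi <= lo:
        raise ParameterError("empty y-window")
    if wave is not None:
        amp, period, phase, _ = wave
        if amp > 0:
            k = math.floor((2 * math.pi * lo / period + phase - math.pi / 2)
                           / math.pi)
            while True:
                k += 1
                y_ext = ((math.pi / 2 + k * math.pi) - phase) * period / (2 * math.pi)
                if y_ext >= hi:
                    break
                if y_ext > lo:
                    raise AnalysisError(
                        f"window ({lo:.2f}, {hi:.2f}) contains a wave extremum "
                        f"at y = {y_ext:.2f} nm"
                    )
    ys, zs = [], []
    for frame in frames:
        sel = frame.roles == "aglycone_base"
        y = frame.xyz[sel, 1]
        z = frame.xyz[sel, 2]
        inside = (y >= lo) & (y < hi)
        ys.append(y[inside])
        zs.append(z[inside])
    y = np.concatenate(ys)
    z = np.concatenate(zs)
    if len(y) < 10:
        raise AnalysisError(
            f"only {len(y)} base atoms inside the window; need at least 10"
        )
    fit = stats.linregress(y, z)
    angle = math.degrees(math.atan(abs(fit.slope)))
    # propagate the slope SE through d/da arctan(a) = 1/(1+a^2)
    stderr = math.degrees(fit.stderr / (1.0 + fit.slope**2))
    return SlopeResult(angle=angle, stderr=stderr, window=(lo, hi),
                       n_points=len(y))


def corrected_tilt(
    record: TiltRecord,
    slope: SlopeResult,
    y_window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Mean tilt minus the slope angle, with SDs combined in quadrature.

    Molecules are restricted to ``y_window`` (default: the slope's own fit
    window) so the correction uses the same spatial region as the line fit.
    """
    lo, hi = y_window if y_window is not None else slope.window
    sel = (record.base_y >= lo) & (record.base_y < hi)
    if not np.any(sel):
        raise ParameterError("no molecules inside the correction window")
    a = record.angles[sel]
    mean = float(np.mean(a)) - slope.angle
    sd = math.sqrt(float(np.var(a)) + slope.stderr**2)
    return mean, sd


def local_normal_tilt(
    frames: list[MonolayerFrame],
    wave: tuple[float, float, float, float],
    y_window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Per-molecule tilt measured against the local normal of a fitted wave.

    For each surfactant the angle between (tip − base) and the *upward* local
    normal n(y) of z = y0 + A sin(2πy/B + C) is returned in degrees — 180°
    means aligned with the inward normal, the local-frame analogue of α.
    Pooled over frames; restricted to ``y_window`` when given.
    """
    amp, period, phase, _ = wave
    out = []
    for frame in frames:
        _, base, tip = _axis_vectors(frame)
        y = base[:, 1]
        if y_window is not None:
            inside = (y >= y_window[0]) & (y < y_window[1])
            base, tip, y = base[inside], tip[inside], y[inside]
        if len(y) == 0:
            continue
        m = amp * (2 * np.pi / period) * np.cos(2 * np.pi * y / period + phase)
        normal = np.stack([np.zeros_like(m), -m, np.ones_like(m)], axis=1)
        normal /= np.linalg.norm(normal, axis=1, keepdims=True)
        vec = tip - base
        norm = np.linalg.norm(vec, axis=1)
        if np.any(norm == 0):
            raise GeometryError("zero-length aglycone vector")
        cosa = np.clip(np.sum(vec * normal, axis=1) / norm, -1.0, 1.0)
        out.append(np.degrees(np.arccos(cosa)))
    if not out:
        raise ParameterError("no molecules inside the window")
    return np.concatenate(out)
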