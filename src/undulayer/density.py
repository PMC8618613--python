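"""Mass-density profiles along z, the equimolecular dividing surface, and
peak half-widths.

Profiles are computed per component (whole system, water, surfactant) on
unwrapped z coordinates: atoms lifted into the vacuum gap are counted in
their actual bins.  The equimolecular dividing surface (EDS) is the Gibbs
construction: the plane below which the integrated water deficit (relative to
bulk density) equals the integrated excess above.  "Half-width" of a peak
means half of the full width at half maximum (FWHM/2), measured by linear
interpolation between bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import AMU_PER_NM3_TO_KG_M3
from .errors import AnalysisError, ParameterError
from .io import MonolayerFrame

COMPONENTS = ("system", "water", "surfactant")


@dataclass
class DensityProfile:
    """Binned mass density vs z per component, in kg/m^3."""

    edges: np.ndarray  # (n_bins + 1,) nm
    density: dict[str, np.ndarray]  # component -> (n_bins,) kg/m^3
    sd: dict[str, np.ndarray]  # SD across 50-ns-style blocks
    area: float  # Lx * Ly, nm^2

    @property
    def centres(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def integral(self, component: str) -> float:
        """Total component mass implied by the profile, in amu."""
        rho = self.density[component]  # kg/m^3
        return float(
            np.sum(rho) * self.bin_width * self.area / AMU_PER_NM3_TO_KG_M3
        )


@dataclass
class EDSResult:
    """Equimolecular dividing surface position and the bulk density used."""

    z: float  # nm
    bulk_density: float  # kg/m^3
    bulk_window: tuple[float, float]  # nm


def _component_masses(frame: MonolayerFrame) -> dict[str, np.ndarray]:
    comp = frame.molecule_component()
    kind = np.array([comp[int(m)] for m in frame.mol_ids])
    return {
        "system": frame.masses,
        "water": np.where(kind == "water", frame.masses, 0.0),
        "surfactant": np.where(kind == "surfactant", frame.masses, 0.0),
    }


def compute_density_profile(
    frames: list[MonolayerFrame],
    bin_width: float = 0.05,
    block: float | None = 50.0,
) -> DensityProfile:
    """Block-averaged mass-density profile along z.

    The bin grid spans the union of all frames' z ranges.  Per-bin density is
    (mass in bin) / (Lx * Ly * bin_width) averaged over frames; the SD is
    taken across block means (one block when the trajectory is shorter than
    ``block`` or ``block`` is None).
    """
    if not frames:
        raise ParameterError("need at least one frame")
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    lx, ly, lz = frames[0].box
    if bin_width > lz:
        raise ParameterError("bin_width exceeds the box height")
    zlo = min(float(np.min(fr.xyz[:, 2])) for fr in frames)
    zhi = max(float(np.max(fr.xyz[:, 2])) for fr in frames)
    n_bins = max(1, int(np.ceil((zhi - zlo) / bin_width + 1e-12)))
    edges = zlo + bin_width * np.arange(n_bins + 1)
    area = lx * ly
    vol = area * bin_width  # nm^3

    times = np.array([fr.time for fr in frames])
    if block is None or times[-1] - times[0] < block:
        block_ids = np.zeros(len(frames), dtype=int)
    else:
        block_ids = np.floor((times - times[0]) / block).astype(int)
        # fold a trailing partial block into the last complete one
        n_full = int(np.floor((times[-1] - times[0] + 1e-9) / block))
        block_ids = np.minimum(block_ids, max(n_full - 1, 0))

    per_block: dict[str, dict[int, list[np.ndarray]]] = {
        c: {} for c in COMPONENTS
    }
    for frame, b in zip(frames, block_ids):
        masses = _component_masses(frame)
        for comp in COMPONENTS:
            hist, _ = np.histogram(
                frame.xyz[:, 2], bins=edges, weights=masses[comp]
            )
            per_block[comp].setdefault(int(b), []).append(hist)

    density: dict[str, np.ndarray] = {}
    sd: dict[str, np.ndarray] = {}
    for comp in COMPONENTS:
        block_means = np.array(
            [np.mean(v, axis=0) for v in per_block[comp].values()]
        )  # (n_blocks, n_bins) amu per bin
        rho_blocks = block_means / vol * AMU_PER_NM3_TO_KG_M3
        density[comp] = np.mean(rho_blocks, axis=0)
        sd[comp] = (
            np.std(rho_blocks, axis=0, ddof=1)
            if len(rho_blocks) > 1
            else np.zeros(rho_blocks.shape[1])
        )
    return DensityProfile(edges=edges, density=density, sd=sd, area=area)


def locate_eds(
    profile: DensityProfile,
    bulk_window: tuple[float, float] | None = None,
    window_width: float = 1.0,
    max_bulk_cv: float = 0.05,
) -> EDSResult:
    """Locate the equimolecular dividing surface of the water profile.

    Bulk water density is the mean over ``bulk_window`` when given, else over
    the ``window_width``-nm slab with the smallest mean density gradient.  The
    EDS is then z_e = z_a + M_above / rho_bulk, with z_a the top of the bulk
    window and M_above the integrated water density above z_a — the position
    where the deficit below balances the excess above (water assumed bulk
    below the interface, vacuum above).
    """
    rho = profile.density["water"]
    z = profile.centres
    dz = profile.bin_width
    nonzero = np.flatnonzero(rho > 0)
    if nonzero.size == 0:
        raise AnalysisError("water profile is empty")

    win_bins = max(2, int(round(window_width / dz)))
    if bulk_window is None:
        grad = np.gradient(rho, dz)
        best, best_score = None, np.inf
        floor = 0.5 * float(np.max(rho))  # bulk must be dense, not a far tail
        for start in range(0, len(rho) - win_bins + 1):
            seg = slice(start, start + win_bins)
            if np.mean(rho[seg]) < floor:
                continue
            score = float(np.mean(np.abs(grad[seg])))
            if score < best_score:
                best, best_score = seg, score
        if best is None:
            raise AnalysisError("no candidate bulk window with nonzero density")
        seg = best
    else:
        sel = (z >= bulk_window[0]) & (z < bulk_window[1])
        if not np.any(sel):
            raise AnalysisError("bulk window contains no bins")
        seg = np.flatnonzero(sel)
        seg = slice(int(seg[0]), int(seg[-1]) + 1)

    bulk = float(np.mean(rho[seg]))
    spread = float(np.std(rho[seg], ddof=0))
    drop = abs(float(rho[seg][0]) - float(rho[seg][-1]))
    # a plateau must have neither scatter nor a systematic trend across the
    # window, otherwise (e.g. a pure gradient) there is no bulk density
    if bulk <= 0 or spread > max_bulk_cv * bulk or drop > max_bulk_cv * bulk:
        raise AnalysisError(
            "no bulk plateau: candidate window varies by more than "
            f"{max_bulk_cv:.0%} of its mean"
        )
    z_a = float(profile.edges[seg.stop])  # top edge of the bulk window
    mass_above = float(np.sum(rho[seg.stop:]) * dz)
    z_e = z_a + mass_above / bulk
    lo = float(profile.edges[nonzero[0]])
    hi = float(profile.edges[nonzero[-1] + 1])
    if not lo <= z_e <= hi:
        raise AnalysisError(
            f"EDS {z_e:.3f} nm falls outside the nonzero water range"
        )
    return EDSResult(
        z=z_e,
        bulk_density=bulk,
        bulk_window=(float(profile.edges[seg.start]), z_a),
    )


def peak_half_width(profile: DensityProfile, component: str) -> float:
    """Half of the FWHM of the component's density peak, in nm."""
    rho = profile.density[component]
    z = profile.centres
    if np.all(rho <= 0):
        raise AnalysisError(f"{component} profile has no peak")
    imax = int(np.argmax(rho))
    peak = rho[imax]
    # reject ambiguous twin peaks: another equal maximum not adjacent
    ties = np.flatnonzero(np.isclose(rho, peak, rtol=0, atol=1e-12 * peak))
    if np.any(np.diff(ties) > 1):
        raise AnalysisError(f"{component} profile has two equal maxima")
    half = peak / 2.0

    def _cross(indices, side):
        prev = imax
        for i in indices:
            if rho[i] < half:
                z1, z2 = z[i], z[prev]
                r1, r2 = rho[i], rho[prev]
                return z1 + (half - r1) * (z2 - z1) / (r2 - r1)
            prev = i
        raise AnalysisError(
            f"{component} peak touches the {side} z-boundary before falling "
            "to half maximum"
        )

    left = _cross(range(imax - 1, -1, -1), "lower")
    right = _cross(range(imax + 1, len(rho)), "upper")
    return float(right - left) / 2.0
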