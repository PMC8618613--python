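"""2D (in-plane) and 3D radial distribution functions of reference atoms.

Distances use the lateral minimum image in x and y; z is non-periodic because
of the vacuum gap above the slab.  The 2D RDF projects all reference atoms to
the xy plane and normalises by the areal pair density, so a uniform in-plane
gas gives g(r) → 1.  The 3D RDF normalises by the ideal-gas shell count at
the whole-box volumetric density (the convention of common MD tools): in a
slab geometry g(r) therefore falls below 1 at large r — documented behaviour,
not an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .io import MonolayerFrame


@dataclass
class RDFResult:
    """g(r) on bin centres, with the reference density used."""

    r: np.ndarray  # bin centres, nm
    g: np.ndarray
    mode: str  # "2D" | "3D"
    reference_density: float  # per nm^2 (2D) or nm^3 (3D)
    n_pairs: int  # pairs per frame entering the histogram


def _pair_displacements(xyz: np.ndarray, lx: float, ly: float) -> np.ndarray:
    n = len(xyz)
    iu, ju = np.triu_indices(n, k=1)
    d = xyz[iu] - xyz[ju]
    d[:, 0] -= lx * np.round(d[:, 0] / lx)
    d[:, 1] -= ly * np.round(d[:, 1] / ly)
    return d


def _rdf(
    frames: list[MonolayerFrame],
    r_max: float,
    dr: float,
    mode: str,
    role: str = "aglycone_base",
) -> RDFResult:
    if not frames:
        raise ParameterError("need at least one frame")
    if dr <= 0 or r_max <= dr:
        raise ParameterError("need 0 < dr < r_max")
    lx, ly, lz = frames[0].box
    if r_max > min(lx, ly) / 2:
        raise ParameterError(
            "r_max exceeds half the smallest lateral box edge; the lateral "
            "minimum image is ill-defined beyond that"
        )
    edges = np.arange(0.0, r_max + dr / 2, dr)
    centres = 0.5 * (edges[:-1] + edges[1:])
    hist = np.zeros(len(centres))
    n_ref = None
    for frame in frames:
        xyz = frame.xyz[frame.roles == role]
        if n_ref is None:
            n_ref = len(xyz)
            if n_ref < 2:
                raise ParameterError("need at least 2 reference atoms")
        d = _pair_displacements(xyz, lx, ly)
        if mode == "2D":
            r = np.hypot(d[:, 0], d[:, 1])
        else:
            r = np.linalg.norm(d, axis=1)
        h, _ = np.histogram(r, bins=edges)
        hist += h
    hist /= len(frames)
    n_pairs = n_ref * (n_ref - 1) // 2
    if mode == "2D":
        ref_density = n_ref / (lx * ly)
        shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)  # = 2π r_c dr
        ideal = n_pairs * shell / (lx * ly)
    else:
        ref_density = n_ref / (lx * ly * lz)
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        ideal = n_pairs * shell / (lx * ly * lz)
    g = np.divide(hist, ideal, out=np.zeros_like(hist), where=ideal > 0)
    return RDFResult(
        r=centres, g=g, mode=mode, reference_density=ref_density, n_pairs=n_pairs
    )


def rdf_2d(
    frames: list[MonolayerFrame],
    r_max: float = 4.0,
    dr: float = 0.02,
    role: str = "aglycone_base",
) -> RDFResult:
    """In-plane radial distribution function of the reference atoms."""
    return _rdf(frames, r_max, dr, "2D", role)


def rdf_3d(
    frames: list[MonolayerFrame],
    r_max: float = 4.0,
    dr: float = 0.02,
    role: str = "aglycone_base",
) -> RDFResult:
    """Full 3D radial distribution function (lateral minimum image only)."""
    return _rdf(frames, r_max, dr, "3D", role)
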