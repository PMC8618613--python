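"""Geometric hydrogen-bond detection, categorised counts and plateau detection.

A hydrogen bond is declared for a (donor, hydrogen, acceptor) triple when the
donor–acceptor distance (lateral minimum image; z is non-periodic because of
the vacuum gap) is at most a cutoff and the hydrogen–donor–acceptor angle is
at most an angular cutoff.  The default criterion — 0.35 nm and 30° — is the
convention of common MD analysis tools; both values are configurable because
geometric criteria differ between packages.

Bonds are classified by the molecules they connect: surfactant–surfactant
(``ss``), surfactant–water (``sw``), water–water (``ww``) and intramolecular
(``intra``, off by default in the headline counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError, RoleError
from .io import BlockSeries, MonolayerFrame, block_average

CATEGORIES = ("ss", "sw", "ww", "intra")


@dataclass(frozen=True)
class HBondCriterion:
    """Distance (nm) and H–donor–acceptor angle (degrees) cutoffs."""

    max_distance: float = 0.35
    max_angle: float = 30.0

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ParameterError("max_distance must be positive")
        if not 0 < self.max_angle <= 90:
            raise ParameterError("max_angle must lie in (0, 90] degrees")


@dataclass(frozen=True)
class HBond:
    donor: int  # atom id
    hydrogen: int
    acceptor: int
    category: str


def _lateral_min_image(d: np.ndarray, lx: float, ly: float) -> np.ndarray:
    d = np.array(d, dtype=float, copy=True)
    d[..., 0] -= lx * np.round(d[..., 0] / lx)
    d[..., 1] -= ly * np.round(d[..., 1] / ly)
    return d


def _donors_and_hydrogens(frame: MonolayerFrame):
    """Pair each hydrogen with the nearest donor-capable atom of its molecule.

    Surfactant ``donor`` atoms must own at least one hydrogen; a bare water
    oxygen (one-bead water) simply cannot donate and acts as acceptor only.
    """
    donor_idx = np.flatnonzero(frame.mask("donor", "water_O"))
    hyd_idx = np.flatnonzero(frame.mask("hydrogen", "water_H"))
    owner: dict[int, list[int]] = {int(i): [] for i in donor_idx}
    by_mol: dict[int, np.ndarray] = {}
    for mol in np.unique(frame.mol_ids[donor_idx]):
        by_mol[int(mol)] = donor_idx[frame.mol_ids[donor_idx] == mol]
    for h in hyd_idx:
        cands = by_mol.get(int(frame.mol_ids[h]))
        if cands is None or len(cands) == 0:
            raise RoleError(
                f"hydrogen atom {frame.ids[h]} has no donor in molecule "
                f"{frame.mol_ids[h]}"
            )
        d2 = np.sum((frame.xyz[cands] - frame.xyz[h]) ** 2, axis=1)
        owner[int(cands[np.argmin(d2)])].append(int(h))
    for d in donor_idx:
        if frame.roles[d] == "donor" and not owner[int(d)]:
            raise RoleError(
                f"donor atom {frame.ids[d]} (molecule {frame.mol_ids[d]}) "
                "has no assigned hydrogen"
            )
    active = [int(d) for d in donor_idx if owner[int(d)]]
    return active, owner


def detect_hbonds(
    frame: MonolayerFrame,
    criterion: HBondCriterion | None = None,
    include_intramolecular: bool = False,
) -> list[HBond]:
    """Detect hydrogen bonds in one frame under the geometric criterion."""
    criterion = criterion or HBondCriterion()
    lx, ly, _ = frame.box
    acc_idx = np.flatnonzero(frame.mask("acceptor", "water_O"))
    donors, owner = _donors_and_hydrogens(frame)
    if len(acc_idx) == 0 or len(donors) == 0:
        return []
    component = frame.molecule_component()

    # lateral-periodic KD-tree: wrap x,y; shift z positive and pad the
    # (formally periodic) z edge far beyond the cutoff so z never wraps.
    xyz = frame.xyz
    zmin = float(np.min(xyz[:, 2]))
    zspan = float(np.max(xyz[:, 2])) - zmin
    boxz = zspan + 10.0 * criterion.max_distance + 1.0
    wrapped = np.column_stack(
        [np.mod(xyz[:, 0], lx), np.mod(xyz[:, 1], ly), xyz[:, 2] - zmin + 1.0]
    )
    tree = cKDTree(wrapped[acc_idx], boxsize=[lx, ly, boxz])
    hits = tree.query_ball_point(wrapped[donors], r=criterion.max_distance)

    cos_cut = np.cos(np.radians(criterion.max_angle))
    bonds: list[HBond] = []
    for d, neigh in zip(donors, hits):
        d_mol = int(frame.mol_ids[d])
        d_kind = component[d_mol]
        for ai in neigh:
            a = int(acc_idx[ai])
            if a == d:
                continue
            a_mol = int(frame.mol_ids[a])
            intra = a_mol == d_mol
            if intra and not include_intramolecular:
                continue
            da = _lateral_min_image(xyz[a] - xyz[d], lx, ly)
            da_norm = np.linalg.norm(da)
            if da_norm == 0:
                continue
            for h in owner[d]:
                dh = _lateral_min_image(xyz[h] - xyz[d], lx, ly)
                dh_norm = np.linalg.norm(dh)
                if dh_norm == 0:
                    continue
                cosang = float(np.dot(dh, da) / (dh_norm * da_norm))
                if cosang >= cos_cut - 1e-12:
                    if intra:
                        cat = "intra"
                    else:
                        a_kind = component[a_mol]
                        n_water = (d_kind == "water") + (a_kind == "water")
                        cat = ("ss", "sw", "ww")[n_water]
                    bonds.append(
                        HBond(
                            int(frame.ids[d]),
                            int(frame.ids[h]),
                            int(frame.ids[a]),
                            cat,
                        )
                    )
    return bonds


@dataclass
class HBondSeries:
    """Per-frame H-bond counts by category with per-molecule normalisation."""

    times: np.ndarray  # ns
    counts: dict[str, np.ndarray]  # category -> (n_frames,) int
    n_surfactants: int

    def per_molecule(self, category: str) -> np.ndarray:
        if self.n_surfactants == 0:
            raise ParameterError("no surfactant molecules in series")
        return self.counts[category] / self.n_surfactants

    def blocks(self, category: str, block_duration: float,
               per_molecule: bool = False) -> BlockSeries:
        values = (
            self.per_molecule(category) if per_molecule else self.counts[category]
        )
        return block_average(self.times, values, block_duration)


def hbond_timeseries(
    frames: list[MonolayerFrame],
    criterion: HBondCriterion | None = None,
    include_intramolecular: bool = False,
) -> HBondSeries:
    """Count H-bonds per frame, split by category."""
    if not frames:
        raise ParameterError("need at least one frame")
    times = np.array([fr.time for fr in frames])
    counts = {cat: np.zeros(len(frames), dtype=int) for cat in CATEGORIES}
    for k, frame in enumerate(frames):
        for bond in detect_hbonds(frame, criterion, include_intramolecular):
            counts[bond.category][k] += 1
    return HBondSeries(
        times=times,
        counts=counts,
        n_surfactants=len(frames[0].surfactant_mol_ids()),
    )


def detect_plateau(series: BlockSeries, rel_tol: float) -> float | None:
    """Earliest block time from which the series stays within ``rel_tol``.

    Returns the start time of the earliest suffix of at least 3 blocks whose
    means all lie within ``rel_tol`` (relative to the suffix mean) of the
    suffix mean, or None when no such suffix exists.
    """
    if rel_tol <= 0:
        raise ParameterError("rel_tol must be positive")
    if series.n_blocks < 3:
        raise ParameterError("need at least 3 blocks")
    means = series.means
    for k in range(series.n_blocks - 2):
        suffix = means[k:]
        mu = float(np.mean(suffix))
        tol = rel_tol * abs(mu) if mu != 0 else rel_tol
        if np.all(np.abs(suffix - mu) <= tol):
            return float(series.times[k])
    return None
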