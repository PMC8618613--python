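"""Synthetic undulated-monolayer generator with exact ground truth.

The generator emulates the study system — a dense layer of 441 surfactant
proxies at 0.49 nm² per molecule riding a sinusoidal surface undulation along
y, over a water slab — while keeping every structural quantity analytically
known: the wave parameters, each molecule's tilt to the *local* surface
normal, and the exact list of constructed hydrogen bonds.  Each proxy
molecule is minimal: two axis atoms (aglycone base and tip), a donor /
hydrogen / acceptor triad, and five inert mass beads that bring the molecular
mass to escin's 1101 amu.  Frames are statistical stand-ins for a relaxed MD
trajectory, not dynamics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import WATER_MASS
from .errors import ParameterError
from .io import BEAD_MASS, MonolayerFrame

_ESC_NAMES = ["BASE", "TIP", "DON", "HD", "ACC", "M1", "M2", "M3", "M4", "M5"]
_ESC_ROLES = [
    "aglycone_base", "aglycone_tip", "donor", "hydrogen", "acceptor",
    "other", "other", "other", "other", "other",
]
_ESC_MASSES = [12.011, 12.011, 15.999, 1.008, 15.999] + [BEAD_MASS] * 5
_ATOMS_PER_MOL = len(_ESC_NAMES)

# geometry of the H-bond triad (nm): donor sits above the base atom, the
# hydrogen 0.1 nm from the donor, and a constructed bond places the partner
# acceptor collinearly at 0.28 nm — inside any conventional geometric cutoff.
_DONOR_LIFT = 0.25
_OH_LENGTH = 0.10
_ACCEPTOR_LIFT = 0.45
_BOND_DA_DIST = 0.28


@dataclass
class HBondDrift:
    """Saturating-exponential relaxation of the bonded-molecule fraction.

    fraction(t) = plateau + (initial - plateau) * exp(-t / tau), emulating the
    slow equilibration of hydrogen-bond counts in a freshly built layer.
    """

    initial_fraction: float
    plateau_fraction: float
    tau: float  # ns

    def fraction_at(self, t: float) -> float:
        return self.plateau_fraction + (
            self.initial_fraction - self.plateau_fraction
        ) * math.exp(-t / self.tau)

    @property
    def settling_time_95(self) -> float:
        """Time at which 95% of the initial-to-plateau change is complete."""
        return self.tau * math.log(20.0)


@dataclass
class SyntheticLayerSpec:
    """Study conditions for one synthetic monolayer configuration.

    Defaults are the dense-layer conditions of the modelled system: 441
    molecules at 0.49 nm² each (lateral box 14.70 nm), a surface wave with
    amplitude 2.1 nm, period 16.6 nm, phase -0.5 and mean height 8.0 nm, a
    5 nm water slab at 998 kg/m³ (293 K), and molecular axes tilted
    75° ± 20° from the local surface normal (i.e. a tilt of 105° ± 20°
    measured from the local vertical in the 90–180° convention).
    """

    n_molecules: int = 441
    area_per_molecule: float = 0.49  # nm^2
    wave: tuple[float, float, float, float] = (2.1, 16.6, -0.5, 8.0)  # A, B, C, y0
    tilt_to_local_normal: tuple[float, float] = (75.0, 20.0)  # mean, SD (deg)
    z_noise: float = 0.3  # nm SD on base-atom height
    water_slab: tuple[float, float] = (5.0, 998.0)  # thickness nm, density kg/m^3
    hbond_fraction: float = 0.5
    n_frames: int = 1
    frame_jitter: float = 0.02  # nm SD, per-frame
    frame_interval: float = 1.0  # ns
    seed: int = 0
    axis_length: float = 1.0  # nm
    lattice_jitter: float = 0.05  # nm SD on lattice sites
    box_lz: float | None = None  # nm; auto-sized when None
    water_sites: int = 1  # 1 = bead, 3 = O + 2 H

    def validate(self) -> None:
        if self.n_molecules < 1:
            raise ParameterError("n_molecules must be >= 1")
        if self.area_per_molecule <= 0:
            raise ParameterError("area_per_molecule must be positive")
        amp, period, _, _ = self.wave
        if period <= 0:
            raise ParameterError("wave period B must be positive")
        if amp < 0:
            raise ParameterError("wave amplitude A must be non-negative")
        if not 0.0 <= self.hbond_fraction <= 1.0:
            raise ParameterError("hbond_fraction must lie in [0, 1]")
        thickness, density = self.water_slab
        if thickness > 0 and density <= 0:
            raise ParameterError("water density must be positive")
        if self.water_sites not in (1, 3):
            raise ParameterError("water_sites must be 1 or 3")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if period > 10.0 * self.box_lateral:
            warnings.warn(
                "wave period exceeds 10x the lateral box; the sine fit is "
                "unidentifiable at this scale",
                stacklevel=2,
            )

    @property
    def box_lateral(self) -> float:
        """Lateral box edge: Lx = Ly = sqrt(n * area_per_molecule)."""
        return math.sqrt(self.n_molecules * self.area_per_molecule)


@dataclass
class LayerTruth:
    """Ground truth returned alongside generated frames."""

    wave: tuple[float, float, float, float]
    lattice_spacing: float
    tilt_deg: np.ndarray  # per molecule, angle of axis to local inward normal
    azimuth: np.ndarray
    hbond_mol_pairs: list[tuple[int, int]]  # (donor molecule, acceptor molecule)
    hbond_triples: list[tuple[int, int, int]]  # atom ids (donor, hydrogen, acceptor)
    n_water: int
    base_y: np.ndarray = field(default=None)  # per-molecule base y (nm)

    def surface_z(self, y: np.ndarray) -> np.ndarray:
        amp, period, phase, y0 = self.wave
        return y0 + amp * np.sin(2 * np.pi * np.asarray(y) / period + phase)

    def surface_slope(self, y: np.ndarray) -> np.ndarray:
        """dz/dy of the analytic wave."""
        amp, period, phase, _ = self.wave
        return amp * (2 * np.pi / period) * np.cos(
            2 * np.pi * np.asarray(y) / period + phase
        )

    def local_normal(self, y: np.ndarray) -> np.ndarray:
        """Upward unit normal of the analytic wave at y, shape (n, 3)."""
        m = np.atleast_1d(self.surface_slope(y))
        n = np.stack([np.zeros_like(m), -m, np.ones_like(m)], axis=1)
        return n / np.linalg.norm(n, axis=1, keepdims=True)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Independent RNG streams so one knob does not shift unrelated draws."""
    root = np.random.SeedSequence(seed)
    names = ["placement", "tilt", "bonds", "water", "jitter"]
    return {n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))}


def _lattice_sites(spec: SyntheticLayerSpec, rng: np.random.Generator):
    # grid pitch from the box, not from sqrt(area): for non-square molecule
    # counts a sqrt(apm) pitch would overflow the box and wrap onto itself
    n_side = math.ceil(math.sqrt(spec.n_molecules))
    lbox = spec.box_lateral
    d = lbox / n_side
    ix, iy = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="ij")
    ix = ix.ravel()[: spec.n_molecules]
    iy = iy.ravel()[: spec.n_molecules]
    x = (ix + 0.5) * d + rng.normal(0.0, spec.lattice_jitter, spec.n_molecules)
    y = (iy + 0.5) * d + rng.normal(0.0, spec.lattice_jitter, spec.n_molecules)
    return np.mod(x, lbox), np.mod(y, lbox), ix, iy, d


def _candidate_pairs(ix: np.ndarray, iy: np.ndarray) -> list[tuple[int, int]]:
    """Disjoint horizontal-neighbour lattice pairs eligible for a bond."""
    site = {(int(a), int(b)): i for i, (a, b) in enumerate(zip(ix, iy))}
    pairs = []
    for i, (a, b) in enumerate(zip(ix, iy)):
        if a % 2 == 0 and (int(a) + 1, int(b)) in site:
            pairs.append((i, site[(int(a) + 1, int(b))]))
    return pairs


def _min_image_lateral(d: np.ndarray, lx: float, ly: float) -> np.ndarray:
    d = d.copy()
    d[..., 0] -= lx * np.round(d[..., 0] / lx)
    d[..., 1] -= ly * np.round(d[..., 1] / ly)
    return d


class _LayerBuilder:
    """Shared geometry for generate_layer / generate_trajectory."""

    def __init__(self, spec: SyntheticLayerSpec):
        spec.validate()
        self.spec = spec
        rng = _streams(spec.seed)
        self.rng = rng
        n = spec.n_molecules
        amp, period, phase, y0 = spec.wave
        self.lbox = spec.box_lateral

        x, y, ix, iy, d = _lattice_sites(spec, rng["placement"])
        zs = y0 + amp * np.sin(2 * np.pi * y / period + phase)
        z = zs + rng["placement"].normal(0.0, spec.z_noise, n)
        self.base = np.stack([x, y, z], axis=1)
        self.spacing = d

        # molecular axes: angle theta to the local inward normal, random azimuth
        mean, sd = spec.tilt_to_local_normal
        theta = np.abs(rng["tilt"].normal(mean, sd, n))
        theta = np.where(theta > 180.0, 360.0 - theta, theta)
        phi = rng["tilt"].uniform(0.0, 2 * np.pi, n)
        slope = amp * (2 * np.pi / period) * np.cos(2 * np.pi * y / period + phase)
        normal = np.stack(
            [np.zeros(n), -slope, np.ones(n)], axis=1
        )
        normal /= np.linalg.norm(normal, axis=1, keepdims=True)
        t1 = np.tile(np.array([1.0, 0.0, 0.0]), (n, 1))
        t2 = np.cross(normal, t1)
        th = np.radians(theta)
        axis = -(
            normal * np.cos(th)[:, None]
            + (t1 * np.cos(phi)[:, None] + t2 * np.sin(phi)[:, None])
            * np.sin(th)[:, None]
        )
        self.tip = self.base + spec.axis_length * axis
        self.theta = theta
        self.phi = phi

        # candidate bond pairs, in a fixed random priority order
        cands = _candidate_pairs(ix, iy)
        order = rng["bonds"].permutation(len(cands))
        self.pair_order = [cands[i] for i in order]

        # water slab
        thickness, density = spec.water_slab
        self.water_o = np.zeros((0, 3))
        if thickness > 0:
            top = y0 - amp - 0.2
            volume = self.lbox * self.lbox * thickness
            n_w = int(round(density * volume / (WATER_MASS * 1.66054)))
            w = rng["water"]
            self.water_o = np.stack(
                [
                    w.uniform(0, self.lbox, n_w),
                    w.uniform(0, self.lbox, n_w),
                    w.uniform(top - thickness, top, n_w),
                ],
                axis=1,
            )
            if spec.water_sites == 3:
                u1 = w.normal(size=(n_w, 3))
                u1 /= np.linalg.norm(u1, axis=1, keepdims=True)
                ref = w.normal(size=(n_w, 3))
                orth = ref - (np.sum(ref * u1, axis=1, keepdims=True)) * u1
                orth /= np.linalg.norm(orth, axis=1, keepdims=True)
                ang = math.radians(104.5)
                u2 = math.cos(ang) * u1 + math.sin(ang) * orth
                self.water_h1 = self.water_o + 0.0957 * u1
                self.water_h2 = self.water_o + 0.0957 * u2

        zmax = float(np.max(np.concatenate([self.base[:, 2], self.tip[:, 2]])))
        zmax = max(zmax, y0 + amp) + _ACCEPTOR_LIFT
        self.lz = spec.box_lz if spec.box_lz is not None else zmax + 5.0

    def n_bonds_for_fraction(self, fraction: float) -> int:
        want = int(round(fraction * self.spec.n_molecules / 2.0))
        return min(want, len(self.pair_order))

    def frame(
        self,
        time: float,
        fraction: float,
        jitter_rng: np.random.Generator | None = None,
    ) -> tuple[MonolayerFrame, list[tuple[int, int]], list[tuple[int, int, int]]]:
        spec = self.spec
        n = spec.n_molecules
        m = self.n_bonds_for_fraction(fraction)
        bonded = self.pair_order[:m]

        donor = self.base + np.array([0.0, 0.0, _DONOR_LIFT])
        hyd = donor + np.array([0.0, 0.0, _OH_LENGTH])
        acc = self.base + np.array([0.0, 0.0, _ACCEPTOR_LIFT])
        mol_pairs: list[tuple[int, int]] = []
        triples: list[tuple[int, int, int]] = []
        for i, j in bonded:
            u = _min_image_lateral(
                (self.base[j] - self.base[i])[None, :], self.lbox, self.lbox
            )[0]
            u[2] = 0.0
            u /= np.linalg.norm(u)
            hyd[i] = donor[i] + _OH_LENGTH * u
            acc[j] = donor[i] + _BOND_DA_DIST * u
            mol_pairs.append((i + 1, j + 1))
            triples.append(
                (
                    i * _ATOMS_PER_MOL + 3,  # DON id (1-based)
                    i * _ATOMS_PER_MOL + 4,  # HD id
                    j * _ATOMS_PER_MOL + 5,  # ACC id
                )
            )

        frac = np.linspace(1.0 / 6.0, 5.0 / 6.0, 5)
        beads = self.base[:, None, :] + frac[None, :, None] * (
            self.tip[:, None, :] - self.base[:, None, :]
        )
        per_mol = np.concatenate(
            [
                self.base[:, None, :],
                self.tip[:, None, :],
                donor[:, None, :],
                hyd[:, None, :],
                acc[:, None, :],
                beads,
            ],
            axis=1,
        )  # (n, 10, 3)
        xyz = per_mol.reshape(-1, 3)
        names = np.tile(np.array(_ESC_NAMES, dtype=object), n)
        roles = np.tile(np.array(_ESC_ROLES, dtype=object), n)
        masses = np.tile(np.array(_ESC_MASSES, dtype=float), n)
        resnames = np.repeat(np.array(["ESC"], dtype=object), n * _ATOMS_PER_MOL)
        mol_ids = np.repeat(np.arange(1, n + 1), _ATOMS_PER_MOL)

        n_w = len(self.water_o)
        if n_w:
            if spec.water_sites == 1:
                w_xyz = self.water_o
                w_names = np.array(["OW"] * n_w, dtype=object)
                w_roles = np.array(["water_O"] * n_w, dtype=object)
                w_masses = np.full(n_w, WATER_MASS)
                w_res = np.array(["SOL"] * n_w, dtype=object)
                w_mols = np.arange(n + 1, n + 1 + n_w)
            else:
                w_xyz = np.stack(
                    [self.water_o, self.water_h1, self.water_h2], axis=1
                ).reshape(-1, 3)
                w_names = np.tile(np.array(["OW", "HW1", "HW2"], dtype=object), n_w)
                w_roles = np.tile(
                    np.array(["water_O", "water_H", "water_H"], dtype=object), n_w
                )
                w_masses = np.tile(np.array([15.9994, 1.008, 1.008]), n_w)
                w_res = np.repeat(np.array(["SO3"], dtype=object), 3 * n_w)
                w_mols = np.repeat(np.arange(n + 1, n + 1 + n_w), 3)
            xyz = np.concatenate([xyz, w_xyz])
            names = np.concatenate([names, w_names])
            roles = np.concatenate([roles, w_roles])
            masses = np.concatenate([masses, w_masses])
            resnames = np.concatenate([resnames, w_res])
            mol_ids = np.concatenate([mol_ids, w_mols])

        if jitter_rng is not None and spec.frame_jitter > 0:
            xyz = xyz + jitter_rng.normal(0.0, spec.frame_jitter, xyz.shape)

        frame = MonolayerFrame(
            time=time,
            box=(self.lbox, self.lbox, float(self.lz)),
            ids=np.arange(1, len(xyz) + 1),
            mol_ids=mol_ids.astype(int),
            resnames=resnames.astype(str),
            names=names.astype(str),
            roles=roles.astype(str),
            masses=masses,
            xyz=xyz,
        )
        return frame, mol_pairs, triples


def generate_layer(
    spec: SyntheticLayerSpec,
) -> tuple[MonolayerFrame, LayerTruth]:
    """Generate one configuration plus its ground-truth record."""
    builder = _LayerBuilder(spec)
    frame, mol_pairs, triples = builder.frame(0.0, spec.hbond_fraction, None)
    frame.validate()
    truth = LayerTruth(
        wave=spec.wave,
        lattice_spacing=builder.spacing,
        tilt_deg=builder.theta,
        azimuth=builder.phi,
        hbond_mol_pairs=mol_pairs,
        hbond_triples=triples,
        n_water=len(builder.water_o),
        base_y=builder.base[:, 1].copy(),
    )
    return frame, truth


def generate_trajectory(
    spec: SyntheticLayerSpec, drift: HBondDrift | None = None
) -> tuple[list[MonolayerFrame], LayerTruth]:
    """Generate ``spec.n_frames`` frames sharing one ground-truth wave.

    Frame k sits at time ``k * frame_interval``; frames after the first carry
    Gaussian coordinate jitter of SD ``frame_jitter`` so the first frame equals
    :func:`generate_layer` exactly.  With ``drift``, the fraction of bonded
    molecules relaxes along the drift's saturating exponential, making plateau
    detection testable against the analytic settling time.
    """
    builder = _LayerBuilder(spec)
    jit = builder.rng["jitter"]
    frames: list[MonolayerFrame] = []
    mol_pairs0: list[tuple[int, int]] = []
    triples0: list[tuple[int, int, int]] = []
    for k in range(spec.n_frames):
        t = k * spec.frame_interval
        fraction = drift.fraction_at(t) if drift else spec.hbond_fraction
        frame, mol_pairs, triples = builder.frame(
            t, fraction, jit if k > 0 else None
        )
        if k == 0:
            mol_pairs0, triples0 = mol_pairs, triples
        frames.append(frame)
    truth = LayerTruth(
        wave=spec.wave,
        lattice_spacing=builder.spacing,
        tilt_deg=builder.theta,
        azimuth=builder.phi,
        hbond_mol_pairs=mol_pairs0,
        hbond_triples=triples0,
        n_water=len(builder.water_o),
        base_y=builder.base[:, 1].copy(),
    )
    return frames, truth
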