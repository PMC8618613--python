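"""Frame I/O, semantic role assignment and block averaging.

Coordinate frames of the monolayer + water slab are read from the standard
GRO / PDB / extended-XYZ formats and carried in memory as
:class:`MonolayerFrame` objects.  Internal units are nm / ns / amu; GRO files
are nm natively, PDB is Å (converted on read/write), the extended-XYZ dialect
written by this package stores nm.  Atoms acquire a semantic role (aglycone
base/tip, H-bond donor/acceptor/hydrogen, water O/H, other) through a
:class:`RoleMap`, never through bond perception.

GRO and PDB parsing and writing are delegated to MDAnalysis; this module only
splits concatenated GRO frames, stamps/parses ``t=`` time labels, and converts
units.
"""

from __future__ import annotations

import math
import re
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .constants import ESCIN_MASS, WATER_MASS
from .errors import FormatError, ParameterError, RoleError

#: Closed set of atom roles used by every analysis stage.
ROLES = frozenset(
    {
        "aglycone_base",
        "aglycone_tip",
        "donor",
        "acceptor",
        "hydrogen",
        "water_O",
        "water_H",
        "other",
    }
)

_TIME_RE = re.compile(r"t=\s*([0-9eE.+-]+)")

# mass of the 2 axis carbons + donor/acceptor oxygens + donor hydrogen
_SITE_MASS = 2 * 12.011 + 2 * 15.999 + 1.008
#: mass of each of the 5 inert beads completing the escin proxy molecule
BEAD_MASS = (ESCIN_MASS - _SITE_MASS) / 5.0


@dataclass
class RoleMap:
    """Mapping from (residue name, atom name) to semantic role and mass.

    The mapping is a plain function (a dict cannot hold duplicate keys).  When
    ``allow_other_fallback`` is true, unmapped atoms become role ``other``
    with zero mass; otherwise an unmapped atom raises :class:`RoleError`.
    """

    roles: dict[tuple[str, str], str]
    masses: dict[tuple[str, str], float]
    allow_other_fallback: bool = True

    def __post_init__(self) -> None:
        bad = set(self.roles.values()) - ROLES
        if bad:
            raise RoleError(f"unknown roles in map: {sorted(bad)}")
        for key, m in self.masses.items():
            if m < 0:
                raise RoleError(f"negative mass for {key}")

    def role_of(self, resname: str, atomname: str) -> str:
        try:
            return self.roles[(resname, atomname)]
        except KeyError:
            if self.allow_other_fallback:
                return "other"
            raise RoleError(
                f"atom ({resname}, {atomname}) has no role and fallback is disabled"
            ) from None

    def mass_of(self, resname: str, atomname: str) -> float:
        return self.masses.get((resname, atomname), 0.0)

    @classmethod
    def default(cls) -> "RoleMap":
        """Role map matching the synthetic escin-proxy / water naming."""
        roles: dict[tuple[str, str], str] = {
            ("ESC", "BASE"): "aglycone_base",
            ("ESC", "TIP"): "aglycone_tip",
            ("ESC", "DON"): "donor",
            ("ESC", "HD"): "hydrogen",
            ("ESC", "ACC"): "acceptor",
            ("SOL", "OW"): "water_O",
            ("SO3", "OW"): "water_O",
            ("SO3", "HW1"): "water_H",
            ("SO3", "HW2"): "water_H",
        }
        masses: dict[tuple[str, str], float] = {
            ("ESC", "BASE"): 12.011,
            ("ESC", "TIP"): 12.011,
            ("ESC", "DON"): 15.999,
            ("ESC", "HD"): 1.008,
            ("ESC", "ACC"): 15.999,
            ("SOL", "OW"): WATER_MASS,
            ("SO3", "OW"): 15.9994,
            ("SO3", "HW1"): 1.008,
            ("SO3", "HW2"): 1.008,
        }
        for k in range(1, 6):
            roles[("ESC", f"M{k}")] = "other"
            masses[("ESC", f"M{k}")] = BEAD_MASS
        return cls(roles=roles, masses=masses)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RoleMap":
        data = yaml.safe_load(Path(path).read_text())
        roles = {
            (res, atom): role
            for res, atoms in data.get("roles", {}).items()
            for atom, role in atoms.items()
        }
        masses = {
            (res, atom): float(m)
            for res, atoms in data.get("masses", {}).items()
            for atom, m in atoms.items()
        }
        return cls(roles=roles, masses=masses,
                   allow_other_fallback=bool(data.get("fallback_other", True)))

    def to_yaml(self, path: str | Path) -> None:
        roles: dict[str, dict[str, str]] = {}
        for (res, atom), role in self.roles.items():
            roles.setdefault(res, {})[atom] = role
        masses: dict[str, dict[str, float]] = {}
        for (res, atom), m in self.masses.items():
            masses.setdefault(res, {})[atom] = float(m)
        Path(path).write_text(
            yaml.safe_dump(
                {"roles": roles, "masses": masses,
                 "fallback_other": self.allow_other_fallback},
                sort_keys=True,
            )
        )


@dataclass
class MonolayerFrame:
    """One time point of the monolayer + water system.

    Coordinates are in nm and are *not* wrapped into the primary box; lateral
    periodic wrapping (minimum image in x, y) is applied per-analysis.
    """

    time: float  # ns
    box: tuple[float, float, float]  # Lx, Ly, Lz in nm
    ids: np.ndarray  # (N,) int
    mol_ids: np.ndarray  # (N,) int
    resnames: np.ndarray  # (N,) str
    names: np.ndarray  # (N,) str
    roles: np.ndarray  # (N,) str
    masses: np.ndarray  # (N,) float amu
    xyz: np.ndarray  # (N, 3) float nm

    @property
    def n_atoms(self) -> int:
        return len(self.ids)

    def mask(self, *roles: str) -> np.ndarray:
        return np.isin(self.roles, list(roles))

    def validate(self) -> None:
        if self.n_atoms == 0:
            raise ParameterError("frame has no atoms")
        if not np.all(np.isfinite(self.xyz)):
            raise ParameterError("non-finite coordinates in frame")
        if any(b <= 0 for b in self.box):
            raise ParameterError(f"box dimensions must be positive, got {self.box}")
        bad = set(np.unique(self.roles)) - ROLES
        if bad:
            raise RoleError(f"unknown roles in frame: {sorted(bad)}")
        # every surfactant molecule carries exactly one base and one tip atom
        surf_mols = np.unique(
            self.mol_ids[self.mask("aglycone_base", "aglycone_tip")]
        )
        for mol in surf_mols:
            sel = self.mol_ids == mol
            n_base = int(np.sum(self.roles[sel] == "aglycone_base"))
            n_tip = int(np.sum(self.roles[sel] == "aglycone_tip"))
            if n_base != 1 or n_tip != 1:
                raise RoleError(
                    f"surfactant molecule {mol} has {n_base} base / {n_tip} tip atoms"
                )

    def molecule_component(self) -> dict[int, str]:
        """Classify each molecule as 'water', 'surfactant' or 'other'."""
        out: dict[int, str] = {}
        for mol in np.unique(self.mol_ids):
            roles = self.roles[self.mol_ids == mol]
            if np.any((roles == "water_O") | (roles == "water_H")):
                out[int(mol)] = "water"
            elif np.any(roles == "aglycone_base"):
                out[int(mol)] = "surfactant"
            else:
                out[int(mol)] = "other"
        return out

    def surfactant_mol_ids(self) -> np.ndarray:
        return np.unique(self.mol_ids[self.roles == "aglycone_base"])


@dataclass
class BlockSeries:
    """Per-block mean and SD of a scalar time series."""

    block_duration: float  # ns
    times: np.ndarray  # (n_blocks,) block start times, ns
    means: np.ndarray
    sds: np.ndarray
    counts: np.ndarray

    @property
    def n_blocks(self) -> int:
        return len(self.times)


def block_average(times, values, block_duration: float) -> BlockSeries:
    """Average ``values`` over consecutive blocks of ``block_duration`` ns.

    Blocks are anchored at the first sample time; a trailing partial block is
    dropped so per-block statistics stay comparable.  The nominal series
    duration is ``t_last - t_first + dt`` with dt the first sampling interval,
    so a 1000 ns series sampled every 1 ns yields 20 blocks of 50 ns.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        raise ParameterError("empty series")
    if times.size != values.size:
        raise ParameterError("times and values must have equal length")
    if np.any(np.diff(times) <= 0):
        raise ParameterError("times must be strictly increasing")
    if block_duration <= 0:
        raise ParameterError("block_duration must be positive")
    t0 = times[0]
    dt = times[1] - times[0] if times.size > 1 else block_duration
    duration = times[-1] - t0 + dt
    n_blocks = int(math.floor(duration / block_duration + 1e-9))
    starts, means, sds, counts = [], [], [], []
    k_idx = np.floor((times - t0) / block_duration).astype(int)
    for k in range(n_blocks):
        sel = values[k_idx == k]
        starts.append(t0 + k * block_duration)
        counts.append(sel.size)
        if sel.size == 0:
            means.append(np.nan)
            sds.append(np.nan)
        else:
            means.append(float(np.mean(sel)))
            sds.append(float(np.std(sel, ddof=1)) if sel.size > 1 else 0.0)
    return BlockSeries(
        block_duration=block_duration,
        times=np.array(starts),
        means=np.array(means),
        sds=np.array(sds),
        counts=np.array(counts),
    )


# ---------------------------------------------------------------------------
# reading


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.upper()
    else:
        f = path.suffix.lstrip(".").upper()
    if f not in {"GRO", "PDB", "XYZ"}:
        raise ParameterError(f"unsupported format {f!r} (expected GRO, PDB or XYZ)")
    return f


def read_frames(
    path: str | Path,
    format: str | None = None,
    rolemap: RoleMap | None = None,
    frame_dt: float = 0.001,
    time0: float = 0.0,
) -> list[MonolayerFrame]:
    """Read an ordered sequence of frames from a coordinate file.

    ``frame_dt`` (ns) assigns times by fixed stride when the file embeds none
    (PDB models, untitled GRO frames); the default stride of 1 ps matches a
    typical trajectory write-out interval.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    fmt = _infer_format(path, format)
    rolemap = rolemap or RoleMap.default()
    if fmt == "GRO":
        frames = _read_gro(path, rolemap, frame_dt, time0)
    elif fmt == "PDB":
        frames = _read_pdb(path, rolemap, frame_dt, time0)
    else:
        frames = _read_xyz(path, rolemap, frame_dt, time0)
    if not frames:
        raise FormatError(f"{path}: no frames found")
    frames.sort(key=lambda fr: fr.time)
    return frames


def _assemble_frame(
    time, box, resids, resnames, names, xyz, rolemap: RoleMap
) -> MonolayerFrame:
    n = len(names)
    roles = np.array(
        [rolemap.role_of(r, a) for r, a in zip(resnames, names)], dtype=object
    ).astype(str)
    masses = np.array(
        [rolemap.mass_of(r, a) for r, a in zip(resnames, names)], dtype=float
    )
    frame = MonolayerFrame(
        time=float(time),
        box=(float(box[0]), float(box[1]), float(box[2])),
        ids=np.arange(1, n + 1),
        mol_ids=np.asarray(resids, dtype=int),
        resnames=np.asarray(resnames, dtype=str),
        names=np.asarray(names, dtype=str),
        roles=roles,
        masses=masses,
        xyz=np.asarray(xyz, dtype=float),
    )
    frame.validate()
    return frame


def _mda_universe(text: str, suffix: str):
    """Parse a single-frame coordinate block with MDAnalysis."""
    import MDAnalysis as mda

    with tempfile.NamedTemporaryFile(
        "w", suffix=suffix, delete=False
    ) as handle:
        handle.write(text)
        name = handle.name
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mda.Universe(name)
    finally:
        Path(name).unlink(missing_ok=True)


def _read_gro(path: Path, rolemap, frame_dt, time0) -> list[MonolayerFrame]:
    lines = path.read_text().splitlines()
    # strip trailing blank lines
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise FormatError(f"{path}: empty file")
    frames: list[MonolayerFrame] = []
    i = 0
    k = 0
    while i < len(lines):
        title = lines[i]
        if i + 1 >= len(lines):
            raise FormatError(f"{path}: line {i + 2}: missing atom-count line")
        try:
            natoms = int(lines[i + 1].strip())
        except ValueError:
            raise FormatError(
                f"{path}: line {i + 2}: expected integer atom count, "
                f"got {lines[i + 1]!r}"
            ) from None
        end = i + 2 + natoms + 1
        if end > len(lines):
            raise FormatError(
                f"{path}: line {len(lines)}: truncated frame "
                f"(need {natoms} atom records plus box line)"
            )
        block = "\n".join(lines[i:end]) + "\n"
        try:
            u = _mda_universe(block, ".gro")
        except Exception as exc:  # noqa: BLE001 - wrap parser errors
            raise FormatError(
                f"{path}: frame starting at line {i + 1} does not parse as GRO: {exc}"
            ) from exc
        m = _TIME_RE.search(title)
        time = float(m.group(1)) / 1000.0 if m else time0 + k * frame_dt
        frames.append(
            _assemble_frame(
                time,
                u.dimensions[:3] / 10.0,
                u.atoms.resids,
                u.atoms.resnames,
                u.atoms.names,
                u.atoms.positions / 10.0,
                rolemap,
            )
        )
        i = end
        k += 1
    return frames


def _read_pdb(path: Path, rolemap, frame_dt, time0) -> list[MonolayerFrame]:
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: does not parse as PDB: {exc}") from exc
    # multi-model files carry one header CRYST1 that the trajectory reader
    # does not attach to each model; keep the parsed records as fallback
    cryst = []
    for line in path.read_text().splitlines():
        if line.startswith("CRYST1"):
            try:
                cryst.append(tuple(float(v) for v in line.split()[1:4]))
            except ValueError as exc:
                raise FormatError(f"{path}: malformed CRYST1 record") from exc
    frames = []
    for k, ts in enumerate(u.trajectory):
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            box = ts.dimensions[:3]
        elif cryst:
            box = np.array(cryst[min(k, len(cryst) - 1)])
        else:
            raise FormatError(f"{path}: frame {k}: missing CRYST1 box record")
        frames.append(
            _assemble_frame(
                time0 + k * frame_dt,
                box / 10.0,
                u.atoms.resids,
                u.atoms.resnames,
                u.atoms.names,
                u.atoms.positions / 10.0,
                rolemap,
            )
        )
    return frames


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_XYZ_TIME_RE = re.compile(r"Time=([0-9eE.+-]+)")


def _read_xyz(path: Path, rolemap, frame_dt, time0) -> list[MonolayerFrame]:
    lines = path.read_text().splitlines()
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise FormatError(f"{path}: empty file")
    frames = []
    i = 0
    k = 0
    while i < len(lines):
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise FormatError(
                f"{path}: line {i + 1}: expected integer atom count, got {lines[i]!r}"
            ) from None
        if i + 2 + natoms > len(lines):
            raise FormatError(f"{path}: line {len(lines)}: truncated XYZ frame")
        comment = lines[i + 1]
        m = _LATTICE_RE.search(comment)
        if not m:
            raise FormatError(
                f'{path}: line {i + 2}: extended-XYZ comment must carry Lattice="..."'
            )
        lat = [float(v) for v in m.group(1).split()]
        if len(lat) != 9:
            raise FormatError(f"{path}: line {i + 2}: Lattice needs 9 components")
        box = (lat[0], lat[4], lat[8])
        tm = _XYZ_TIME_RE.search(comment)
        time = float(tm.group(1)) if tm else time0 + k * frame_dt
        names, xs, resnames, resids = [], [], [], []
        for j in range(natoms):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path}: line {i + 3 + j}: expected 'name x y z [resname mol]'"
                )
            names.append(parts[0])
            try:
                xs.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError:
                raise FormatError(
                    f"{path}: line {i + 3 + j}: non-numeric coordinate"
                ) from None
            resnames.append(parts[4] if len(parts) > 4 else "UNK")
            resids.append(int(parts[5]) if len(parts) > 5 else j + 1)
        frames.append(
            _assemble_frame(time, box, resids, resnames, names, np.array(xs), rolemap)
        )
        i += 2 + natoms
        k += 1
    return frames


# ---------------------------------------------------------------------------
# writing


def _frame_to_universe(frame: MonolayerFrame):
    import MDAnalysis as mda

    mols, inv = np.unique(frame.mol_ids, return_inverse=True)
    res_names = np.empty(len(mols), dtype=object)
    for idx, mol in enumerate(mols):
        res_names[idx] = frame.resnames[frame.mol_ids == mol][0]
    u = mda.Universe.empty(
        frame.n_atoms, n_residues=len(mols), atom_resindex=inv, trajectory=True
    )
    u.add_TopologyAttr("names", frame.names.tolist())
    u.add_TopologyAttr("resnames", res_names.tolist())
    u.add_TopologyAttr("resids", mols.astype(int).tolist())
    u.atoms.positions = frame.xyz * 10.0
    u.dimensions = [frame.box[0] * 10, frame.box[1] * 10, frame.box[2] * 10,
                    90.0, 90.0, 90.0]
    return u


def _gro_block(frame: MonolayerFrame) -> str:
    u = _frame_to_universe(frame)
    with tempfile.NamedTemporaryFile("r", suffix=".gro", delete=False) as handle:
        name = handle.name
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.atoms.write(name)
        lines = Path(name).read_text().splitlines()
    finally:
        Path(name).unlink(missing_ok=True)
    lines[0] = f"undulayer frame t= {frame.time * 1000.0:.5f}"
    return "\n".join(lines) + "\n"


def _xyz_block(frame: MonolayerFrame) -> str:
    lx, ly, lz = frame.box
    out = [str(frame.n_atoms)]
    out.append(
        f'Lattice="{lx:.6f} 0.0 0.0 0.0 {ly:.6f} 0.0 0.0 0.0 {lz:.6f}" '
        f"Time={frame.time:.6f} "
        "Properties=species:S:1:pos:R:3:resname:S:1:mol:I:1"
    )
    for nm, (x, y, z), res, mol in zip(
        frame.names, frame.xyz, frame.resnames, frame.mol_ids
    ):
        out.append(f"{nm} {x:.6f} {y:.6f} {z:.6f} {res} {int(mol)}")
    return "\n".join(out) + "\n"


def write_frames(
    frames: list[MonolayerFrame], path: str | Path, format: str | None = None
) -> Path:
    """Write one or more frames to ``path`` in GRO, PDB or extended-XYZ form."""
    import MDAnalysis as mda

    path = Path(path)
    if not frames:
        raise ParameterError("refusing to write zero frames")
    for frame in frames:
        if frame.n_atoms == 0:
            raise ParameterError("refusing to write an empty frame")
        frame.validate()
    fmt = _infer_format(path, format)
    try:
        if fmt == "GRO":
            path.write_text("".join(_gro_block(fr) for fr in frames))
        elif fmt == "XYZ":
            path.write_text("".join(_xyz_block(fr) for fr in frames))
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                with mda.Writer(
                    str(path), multiframe=len(frames) > 1, n_atoms=frames[0].n_atoms
                ) as writer:
                    for frame in frames:
                        writer.write(_frame_to_universe(frame).atoms)
    except OSError as exc:
        raise UndulayerIOError(f"cannot write {path}: {exc}") from exc
    return path


class UndulayerIOError(FormatError):
    """Unwritable or unreadable path."""


def write_frame(
    frame: MonolayerFrame, path: str | Path, format: str | None = None
) -> Path:
    """Write a single frame (see :func:`write_frames`)."""
    return write_frames([frame], path, format)
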