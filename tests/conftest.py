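import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from undulayer.io import MonolayerFrame

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_frame(
    xyz,
    roles,
    mol_ids=None,
    box=(10.0, 10.0, 10.0),
    masses=None,
    time=0.0,
    names=None,
    resnames=None,
):
    """Hand-build a frame for geometry-level tests."""
    xyz = np.asarray(xyz, dtype=float)
    n = len(xyz)
    roles = np.asarray(roles, dtype=str)
    mol_ids = (
        np.asarray(mol_ids, dtype=int) if mol_ids is not None
        else np.arange(1, n + 1)
    )
    return MonolayerFrame(
        time=time,
        box=box,
        ids=np.arange(1, n + 1),
        mol_ids=mol_ids,
        resnames=(np.asarray(resnames, dtype=str) if resnames is not None
                  else np.array(["UNK"] * n)),
        names=(np.asarray(names, dtype=str) if names is not None
               else np.array([f"A{i}" for i in range(n)])),
        roles=roles,
        masses=(np.asarray(masses, dtype=float) if masses is not None
                else np.ones(n)),
        xyz=xyz,
    )


def random_hbond_frame(rng, n_mol=200, box=(8.0, 8.0, 4.0)):
    """Random donor/H/acceptor molecules for oracle-equivalence tests."""
    don = np.column_stack(
        [rng.uniform(0, box[0], n_mol), rng.uniform(0, box[1], n_mol),
         rng.uniform(0, box[2], n_mol)]
    )
    direction = rng.normal(size=(n_mol, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    hyd = don + 0.1 * direction
    acc = np.column_stack(
        [rng.uniform(0, box[0], n_mol), rng.uniform(0, box[1], n_mol),
         rng.uniform(0, box[2], n_mol)]
    )
    xyz = np.concatenate([don, hyd, acc])
    roles = np.array(["donor"] * n_mol + ["hydrogen"] * n_mol + ["acceptor"] * n_mol)
    mol_ids = np.concatenate([np.arange(1, n_mol + 1)] * 3)
    return make_frame(xyz, roles, mol_ids, box=box)


def brute_force_hbonds(frame, dmax=0.35, amax=30.0):
    """Independent all-pairs O(N^2) oracle (one donor/H/acceptor per molecule)."""
    lx, ly, _ = frame.box

    def mi(d):
        d = np.array(d, copy=True)
        d[..., 0] -= lx * np.round(d[..., 0] / lx)
        d[..., 1] -= ly * np.round(d[..., 1] / ly)
        return d

    don = np.flatnonzero(frame.roles == "donor")
    acc = np.flatnonzero(frame.roles == "acceptor")
    h_of = {int(frame.mol_ids[i]): i
            for i in np.flatnonzero(frame.roles == "hydrogen")}
    out = []
    for d in don:
        h = h_of[int(frame.mol_ids[d])]
        dh = mi(frame.xyz[h] - frame.xyz[d])
        dh /= np.linalg.norm(dh)
        da = mi(frame.xyz[acc] - frame.xyz[d])
        dist = np.linalg.norm(da, axis=1)
        cos = np.sum(da * dh, axis=1) / np.where(dist > 0, dist, 1.0)
        ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        keep = (dist <= dmax) & (ang <= amax) & (
            frame.mol_ids[acc] != frame.mol_ids[d]
        )
        for a in acc[keep]:
            out.append((int(frame.ids[d]), int(frame.ids[h]), int(frame.ids[a])))
    return sorted(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
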