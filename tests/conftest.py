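import numpy as np
import pytest

from decoyreduce import Ensemble, Structure, SynthSpec, make_ensemble


def make_structure(coords, sid="s", energy=None, atom_names=None):
    coords = np.asarray(coords, dtype=float)
    return Structure(
        id=sid,
        coords=coords,
        atom_names=atom_names or ["CA"] * len(coords),
        residue_index=list(range(1, len(coords) + 1)),
        energy=energy,
    )


def random_structure(n_atoms=50, seed=0, scale=10.0):
    rng = np.random.default_rng(seed)
    return make_structure(rng.normal(scale=scale, size=(n_atoms, 3)), sid=f"r{seed}")


def random_rigid_motion(rng):
    """A uniformly random proper rotation matrix plus a random translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q, rng.normal(scale=20.0, size=3)


def apply_rigid(structure, rotation, translation):
    return make_structure(
        structure.coords @ rotation.T + translation,
        sid=structure.id,
        energy=structure.energy,
        atom_names=list(structure.atom_names),
    )


def simplex_blobs(G, n, seed, sep_factor=10.0, dim=12):
    """G planted Gaussian clusters in `dim`-d space at equal pairwise
    centroid separations of sep_factor times the within-cluster spread."""
    rng = np.random.default_rng(seed)
    spread = np.sqrt(dim)  # mean distance to centroid of a unit Gaussian
    C = np.eye(G) - 1.0 / G
    C = C / np.linalg.norm(C[0] - C[1]) * sep_factor * spread
    Q, _ = np.linalg.qr(rng.normal(size=(dim, dim)))
    centers = np.hstack([C, np.zeros((G, dim - G))]) @ Q.T
    sizes = [n // G] * (G - 1) + [n - (n // G) * (G - 1)]
    X = np.vstack(
        [centers[g] + rng.normal(size=(s, dim)) for g, s in enumerate(sizes)]
    )
    return X, np.repeat(np.arange(G), sizes)


@pytest.fixture(scope="session")
def small_ensemble():
    """80 structures, 4 planted basins, funnel energies with noise."""
    spec = SynthSpec(length=40, n_clusters=4, sizes=[20] * 4, seed=11)
    ensemble, truth = make_ensemble(spec)
    return ensemble, truth


@pytest.fixture()
def tiny_ensemble():
    """Five hand-built structures with energies, plus a native."""
    rng = np.random.default_rng(3)
    native = random_structure(n_atoms=20, seed=99)
    structures = [
        make_structure(
            native.coords + rng.normal(scale=0.5 * (i + 1), size=(20, 3)),
            sid=f"t{i}",
            energy=-10.0 + i,
        )
        for i in range(5)
    ]
    return Ensemble(structures, native=native, name="tiny")
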