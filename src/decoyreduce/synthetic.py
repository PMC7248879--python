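"""Desk-scale synthetic decoy ensembles with known ground truth.

Real decoy generators explore a multi-basin structure space and assign
energies that correlate only weakly with nativeness. This module emulates
exactly those two statistical properties so every pipeline stage can be
exercised without external data: a self-avoiding CA trace acts as the
native; G cluster seeds are large perturbations of it (planting structural
basins); members are small perturbations of their seed; and the energy is
linear in lRMSD to the native plus Gaussian noise — a noisy funnel whose
steepness and noisiness are tunable.

What this generator does not emulate: realistic secondary structure,
physical torsion/bond geometry beyond the fixed CA-CA distance, side
chains, and any genuine force-field ruggedness. Tests passing on these
ensembles demonstrate the reduction machinery, not force-field behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import kabsch_lrmsd
from .io import Ensemble, Structure, write_pdb

__all__ = ["SynthSpec", "make_native", "perturb", "make_ensemble", "write_dataset"]

_CA_STEP = 3.8  # consecutive CA-CA distance, Angstrom
_MIN_CLEARANCE = 4.0  # minimum non-consecutive CA-CA distance, Angstrom


@dataclass
class SynthSpec:
    """Parameters of a synthetic decoy ensemble.

    Defaults describe a small, clearly multi-basin ensemble: 4 planted
    clusters of 50 members on a 60-residue chain, basins separated by
    6 A perturbations versus 0.3 A within-basin jitter (20x separation),
    and a funnel of 2 REU per Angstrom with 3 REU of energy noise around
    a floor of -150 REU — weak enough correlation that energy alone ranks
    structures unreliably, the regime the reduction method is built for.
    """

    length: int = 60
    n_clusters: int = 4
    sizes: list[int] | None = None
    cluster_spread: float = 6.0  # A, native -> cluster-seed perturbation
    member_spread: float = 0.3  # A, cluster-seed -> member perturbation
    e0: float = -150.0  # REU, energy floor at the native
    slope: float = 2.0  # REU per A of lRMSD (funnel steepness)
    energy_noise: float = 3.0  # REU, Gaussian noise on energies
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 5:
            raise ValueError("chain length must be at least 5 residues")
        if self.n_clusters < 1:
            raise ValueError("need at least one planted cluster")
        if self.sizes is None:
            self.sizes = [50] * self.n_clusters
        if len(self.sizes) != self.n_clusters:
            raise ValueError("sizes must have one entry per cluster")
        if any(s < 1 for s in self.sizes):
            raise ValueError("cluster sizes must be positive")
        if self.cluster_spread <= 0 or self.member_spread <= 0:
            raise ValueError("spreads must be positive")
        if self.member_spread >= self.cluster_spread:
            raise ValueError(
                "member_spread must be smaller than cluster_spread for "
                "separable planted clusters"
            )
        if self.energy_noise < 0:
            raise ValueError("energy noise must be non-negative")

    @property
    def n_structures(self) -> int:
        return sum(self.sizes)


def make_native(
    length: int, seed: int | None = 0, max_restarts: int = 200
) -> Structure:
    """Generate a self-avoiding CA-only chain to serve as the native trace.

    Consecutive CA atoms are exactly 3.8 A apart; every non-consecutive
    pair is at least 4 A apart. The walk turns by at most 90 degrees per
    step and restarts (bounded) when it traps itself.
    """
    if length < 5:
        raise ValueError("chain length must be at least 5")
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        coords = np.zeros((length, 3))
        direction = _random_unit(rng)
        coords[1] = coords[0] + _CA_STEP * direction
        ok = True
        for i in range(2, length):
            placed = False
            for _ in range(200):
                cand_dir = _random_unit(rng)
                if cand_dir @ direction < 0:  # turn limited to 90 degrees
                    continue
                cand = coords[i - 1] + _CA_STEP * cand_dir
                clearance = np.linalg.norm(coords[: i - 1] - cand, axis=1).min()
                if clearance >= _MIN_CLEARANCE:
                    coords[i] = cand
                    direction = cand_dir
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return Structure(id="native", coords=coords)
    raise RuntimeError(
        f"failed to build a self-avoiding chain of length {length} "
        f"after {max_restarts} restarts"
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def perturb(
    structure: Structure,
    sigma: float,
    seed: int | np.random.Generator | None = None,
) -> Structure:
    """Displace every atom by zero-mean Gaussian noise (per-coordinate std
    ``sigma``, in Angstrom)."""
    if sigma <= 0:
        raise ValueError("perturbation sigma must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    noise = rng.normal(scale=sigma, size=structure.coords.shape)
    return Structure(
        id=structure.id,
        coords=structure.coords + noise,
        atom_names=list(structure.atom_names),
        residue_index=list(structure.residue_index),
        energy=structure.energy,
    )


def make_ensemble(spec: SynthSpec) -> tuple[Ensemble, np.ndarray]:
    """Generate an ensemble with planted clusters and funnel-plus-noise
    energies; returns the ensemble (native attached) and the ground-truth
    cluster label per structure."""
    ss = np.random.SeedSequence(spec.seed)
    native_seed, *streams = ss.spawn(3)
    native = make_native(spec.length, seed=np.random.default_rng(native_seed))
    rng_struct = np.random.default_rng(streams[0])
    rng_energy = np.random.default_rng(streams[1])

    width = len(str(spec.n_structures - 1))
    structures: list[Structure] = []
    labels: list[int] = []
    idx = 0
    for g, size in enumerate(spec.sizes):
        seed_structure = perturb(native, spec.cluster_spread, rng_struct)
        for _ in range(size):
            member = perturb(seed_structure, spec.member_spread, rng_struct)
            lrmsd = kabsch_lrmsd(member, native)
            energy = (
                spec.e0
                + spec.slope * lrmsd
                + (rng_energy.normal(scale=spec.energy_noise) if spec.energy_noise else 0.0)
            )
            structures.append(
                Structure(
                    id=f"d{idx:0{width}d}",
                    coords=member.coords,
                    atom_names=list(member.atom_names),
                    residue_index=list(member.residue_index),
                    energy=float(energy),
                )
            )
            labels.append(g)
            idx += 1
    ensemble = Ensemble(structures, native=native, name=f"synthetic_seed{spec.seed}")
    return ensemble, np.array(labels, dtype=int)


def write_dataset(
    ensemble: Ensemble,
    labels: np.ndarray,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write an ensemble to disk in the formats the loaders accept: a
    directory of PDB files, ``scores.csv`` (id,score), ``native.pdb`` and
    ``truth.csv`` (id,cluster). Returns the paths written."""
    out_dir = Path(out_dir)
    pdb_dir = out_dir / "decoys"
    pdb_dir.mkdir(parents=True, exist_ok=True)
    for s in ensemble:
        write_pdb(s, pdb_dir / f"{s.id}.pdb")
    scores = pd.DataFrame({"id": ensemble.ids, "score": ensemble.energies})
    scores_path = out_dir / "scores.csv"
    scores.to_csv(scores_path, index=False)
    paths = {"pdb_dir": pdb_dir, "scores": scores_path}
    if ensemble.native is not None:
        paths["native"] = write_pdb(ensemble.native, out_dir / "native.pdb")
    truth = pd.DataFrame({"id": ensemble.ids, "cluster": np.asarray(labels, int)})
    paths["truth"] = out_dir / "truth.csv"
    truth.to_csv(paths["truth"], index=False)
    return paths
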