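"""Reading and writing decoy structures, energy tables and manifests.

The on-disk interface is deliberately narrow: single-model, single-decoy
PDB files (ATOM records only), an energy table keyed by structure id
(CSV with an ``id,score`` header, or a Rosetta plain-text score file whose
last column is ``description``), a plain-text manifest (one id per line)
for reduced ensembles.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Structure",
    "Ensemble",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "read_scores",
    "load_ensemble",
    "write_reduced",
    "read_manifest",
]


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed into a Structure."""


@dataclass
class Structure:
    """One tertiary structure: coordinates in Angstrom plus atom metadata.

    Parameters
    ----------
    id : str
        Identifier, by convention the source file stem.
    coords : (n_atoms, 3) float array
        Cartesian coordinates in Angstrom, in record order.
    atom_names : sequence of str
        Per-atom PDB atom name (e.g. ``"CA"``).
    residue_index : sequence of int
        Per-atom 1-based residue number, non-decreasing within a chain.
    energy : float, optional
        Scalar energy in Rosetta Energy Units (REU).
    """

    id: str
    coords: np.ndarray
    atom_names: Sequence[str] = field(default_factory=list)
    residue_index: Sequence[int] = field(default_factory=list)
    energy: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.coords) < 1:
            raise ValueError(f"structure {self.id!r} has no atoms")
        if not np.isfinite(self.coords).all():
            raise ValueError(f"structure {self.id!r} has non-finite coordinates")
        if not self.atom_names:
            self.atom_names = ["CA"] * len(self.coords)
        if len(self.atom_names) != len(self.coords):
            raise ValueError("atom_names length does not match coords")
        if len(self.residue_index) == 0:
            self.residue_index = list(range(1, len(self.coords) + 1))
        if len(self.residue_index) != len(self.coords):
            raise ValueError("residue_index length does not match coords")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def ca_mask(self) -> np.ndarray:
        return np.array([name.strip() == "CA" for name in self.atom_names])

    @property
    def ca_coords(self) -> np.ndarray:
        return self.coords[self.ca_mask]

    def select(self, selection: str) -> np.ndarray:
        """Coordinates under an atom selection: ``all_atoms`` or ``ca_only``."""
        if selection == "all_atoms":
            return self.coords
        if selection == "ca_only":
            out = self.ca_coords
            if len(out) == 0:
                raise ValueError(f"structure {self.id!r} has no CA atoms")
            return out
        raise ValueError(f"unknown selection {selection!r}")

    def with_energy(self, energy: float) -> "Structure":
        return replace(self, energy=float(energy))


@dataclass
class Ensemble:
    """An ordered collection of structures, optionally with a native reference."""

    structures: list[Structure]
    native: Structure | None = None
    name: str = "ensemble"

    def __post_init__(self) -> None:
        ids = [s.id for s in self.structures]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate structure ids: {dupes}")
        if self.native is not None and not self.native.ca_mask.any():
            raise ValueError("native structure has no CA atoms")

    def __len__(self) -> int:
        return len(self.structures)

    def __iter__(self):
        return iter(self.structures)

    def __getitem__(self, key: int | str) -> Structure:
        if isinstance(key, str):
            return self.structures[self.index(key)]
        return self.structures[key]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.structures]

    def index(self, sid: str) -> int:
        try:
            return self.ids.index(sid)
        except ValueError:
            raise KeyError(f"unknown structure id {sid!r}") from None

    @property
    def energies(self) -> np.ndarray:
        vals = [s.energy for s in self.structures]
        if any(v is None for v in vals):
            missing = [s.id for s in self.structures if s.energy is None]
            raise ValueError(f"structures missing energies: {missing[:5]}")
        return np.asarray(vals, dtype=float)

    def subset(self, ids: Iterable[str], name: str | None = None) -> "Ensemble":
        ids = list(ids)
        unknown = [i for i in ids if i not in set(self.ids)]
        if unknown:
            raise KeyError(f"unknown structure ids: {unknown[:5]}")
        lookup = {s.id: s for s in self.structures}
        return Ensemble(
            [lookup[i] for i in ids],
            native=self.native,
            name=name or f"{self.name}_subset",
        )


def read_pdb(path: str | Path) -> Structure:
    """Parse one tertiary structure from a PDB file.

    Only ATOM records are read; HETATM is ignored. For alternate locations
    the first altloc encountered for an atom is kept. If MODEL records are
    present only the first model is read. The structure id is the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    coords: list[tuple[float, float, float]] = []
    names: list[str] = []
    resix: list[int] = []
    seen_altloc: set[tuple[str, str, str]] = set()
    model_no = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                model_no += 1
                if model_no > 1:
                    break
                continue
            if rec.startswith("ENDMDL"):
                break
            if rec != "ATOM  ":
                continue
            name = line[12:16].strip()
            altloc = line[16:17]
            chain = line[21:22]
            resseq = line[22:26].strip()
            if altloc not in (" ", ""):
                key = (chain, resseq, name)
                if key in seen_altloc:
                    continue
                seen_altloc.add(key)
            try:
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                res = int(resseq)
            except ValueError as exc:
                raise PDBParseError(
                    f"{path.name}: unparseable ATOM record at line {lineno}: {exc}"
                ) from None
            coords.append(xyz)
            names.append(name)
            resix.append(res)
    if not coords:
        raise PDBParseError(f"{path.name}: zero ATOM records")
    return Structure(
        id=path.stem,
        coords=np.array(coords),
        atom_names=names,
        residue_index=resix,
    )


def write_pdb(structure: Structure, path: str | Path) -> Path:
    """Write a Structure as single-chain ATOM records (fixed-width PDB)."""
    path = Path(path)
    lines = []
    for i, (xyz, name, res) in enumerate(
        zip(structure.coords, structure.atom_names, structure.residue_index), start=1
    ):
        # PDB atom-name column convention: names < 4 chars start in col 14
        pname = f" {name:<3s}" if len(name) < 4 else name[:4]
        lines.append(
            f"ATOM  {i:5d} {pname} ALA A{int(res):4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_scores(path: str | Path, dialect: str = "csv") -> dict[str, float]:
    """Read an id -> energy (REU) table.

    ``csv``: comma-separated with header columns ``id`` and ``score``.
    ``rosetta_scorefile``: whitespace table whose header's last column is
    ``description`` and which contains a ``total_score`` (or ``score``)
    column; an optional leading ``SCORE:`` tag per line is accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such score file: {path}")
    if dialect == "csv":
        df = pd.read_csv(path)
        for col in ("id", "score"):
            if col not in df.columns:
                raise ValueError(f"{path.name}: missing column {col!r}")
        ids = df["id"].astype(str)
        scores = pd.to_numeric(df["score"], errors="coerce")
    elif dialect == "rosetta_scorefile":
        rows = []
        for line in path.read_text().splitlines():
            parts = line.split()
            if parts and parts[0] == "SCORE:":
                parts = parts[1:]
            if parts:
                rows.append(parts)
        header = next((r for r in rows if r[-1] == "description"), None)
        if header is None:
            raise ValueError(f"{path.name}: no header row ending in 'description'")
        score_col = next((c for c in ("total_score", "score") if c in header), None)
        if score_col is None:
            raise ValueError(f"{path.name}: no total-score column in header")
        j = header.index(score_col)
        data = [r for r in rows if r != header and len(r) == len(header)]
        ids = pd.Series([r[-1] for r in data], dtype=str)
        scores = pd.to_numeric(pd.Series([r[j] for r in data]), errors="coerce")
    else:
        raise ValueError(f"unknown score dialect {dialect!r}")
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"{path.name}: duplicate ids: {dupes[:5]}")
    if scores.isna().any():
        bad = ids[scores.isna()].tolist()
        raise ValueError(f"{path.name}: non-numeric score for ids {bad[:5]}")
    return dict(zip(ids, scores.astype(float)))


def load_ensemble(
    pdb_dir: str | Path,
    scores: Mapping[str, float],
    native: str | Path | None = None,
    name: str | None = None,
) -> Ensemble:
    """Assemble an Ensemble from a directory of PDB files plus an energy map.

    Structures are ordered lexicographically by id; every structure must
    have an energy in ``scores``.
    """
    pdb_dir = Path(pdb_dir)
    paths = sorted(pdb_dir.glob("*.pdb"), key=lambda p: p.stem)
    if not paths:
        raise FileNotFoundError(f"no PDB files in {pdb_dir}")
    structures = [read_pdb(p) for p in paths]
    missing = [s.id for s in structures if s.id not in scores]
    if missing:
        raise KeyError(f"no energy for structure ids: {missing[:10]}")
    structures = [s.with_energy(scores[s.id]) for s in structures]
    native_structure = read_pdb(native) if native is not None else None
    return Ensemble(structures, native=native_structure, name=name or pdb_dir.name)


def write_reduced(
    ensemble: Ensemble,
    selected_ids: Sequence[str],
    out_dir: str | Path,
    copy_pdbs: str | Path | None = None,
) -> Path:
    """Write a reduced-ensemble manifest (one id per line); optionally copy
    the selected PDB files from ``copy_pdbs`` into the output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    known = set(ensemble.ids)
    unknown = [i for i in selected_ids if i not in known]
    if unknown:
        raise KeyError(f"unknown structure ids in selection: {unknown[:5]}")
    if not selected_ids:
        logger.warning("empty selection: writing empty manifest to %s", out_dir)
    manifest = out_dir / "manifest.txt"
    manifest.write_text("".join(f"{i}\n" for i in selected_ids))
    if copy_pdbs is not None:
        src = Path(copy_pdbs)
        for sid in selected_ids:
            shutil.copyfile(src / f"{sid}.pdb", out_dir / f"{sid}.pdb")
    return manifest


def read_manifest(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
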