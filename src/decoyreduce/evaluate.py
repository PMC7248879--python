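"""Compare a source ensemble with its reduction.

Metrics follow the usual decoy-ensemble conventions: least RMSD (lRMSD)
over CA atoms after optimal rigid-body superposition (Kabsch, proper
rotations only), energy summary statistics including the energy diameter
(max minus min), the reduction percentage, and the Pearson correlation
between per-structure USR distance to the native and lRMSD to the native.
Landscape and histogram exports are data tables; plotting is left to the
caller.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .featurize import usr_distance, usr_features
from .io import Ensemble, Structure

__all__ = [
    "ReductionReport",
    "kabsch_lrmsd",
    "lrmsd_stats",
    "energy_stats",
    "reduction_pct",
    "pearson_usr_lrmsd",
    "compare",
    "landscape_table",
    "histogram_table",
]


def kabsch_lrmsd(a: Structure, b: Structure, selection: str = "ca_only") -> float:
    """Least RMSD between two structures after optimal superposition.

    Coordinates are centered, the optimal proper rotation (determinant +1
    enforced, so no reflections) is found by SVD of the covariance matrix,
    and the RMSD over paired atoms is returned, in Angstrom. Atoms are
    paired by position in the selection; equal counts are required.
    """
    P = a.select(selection)
    Q = b.select(selection)
    if len(P) != len(Q):
        raise ValueError(
            f"atom count mismatch: {a.id!r} has {len(P)}, {b.id!r} has {len(Q)}"
        )
    if len(P) < 1:
        raise ValueError("superposition needs at least one atom")
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    # flip the smallest singular direction if the optimum is a reflection
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = (R @ P.T).T - Q
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def _as_structures(ensemble: Ensemble | list[Structure]) -> list[Structure]:
    return list(ensemble)


def lrmsd_stats(
    ensemble: Ensemble | list[Structure],
    native: Structure,
    selection: str = "ca_only",
) -> dict[str, float]:
    """Min / mean / population std of per-structure lRMSD to the native."""
    if native is None:
        raise ValueError("lRMSD statistics need a native reference structure")
    values = np.array(
        [kabsch_lrmsd(s, native, selection) for s in _as_structures(ensemble)]
    )
    return {
        "min": float(values.min()),
        "avg": float(values.mean()),
        "std": float(values.std()),
    }


def energy_stats(ensemble: Ensemble | list[Structure]) -> dict[str, float]:
    """Min / mean / max / diameter (max - min) of ensemble energies, in REU."""
    structures = _as_structures(ensemble)
    if isinstance(ensemble, Ensemble):
        energies = ensemble.energies
    else:
        if any(s.energy is None for s in structures):
            raise ValueError("structures missing energies")
        energies = np.array([s.energy for s in structures], dtype=float)
    return {
        "min": float(energies.min()),
        "avg": float(energies.mean()),
        "max": float(energies.max()),
        "diameter": float(energies.max() - energies.min()),
    }


def reduction_pct(n_gen: int, n_red: int) -> float:
    """Percentage of the source ensemble removed: (1 - n_red/n_gen) * 100."""
    if n_gen <= 0:
        raise ValueError("source ensemble size must be positive")
    if not 0 <= n_red <= n_gen:
        raise ValueError(f"reduced size {n_red} outside [0, {n_gen}]")
    return (1.0 - n_red / n_gen) * 100.0


def pearson_usr_lrmsd(
    ensemble: Ensemble,
    native: Structure | None = None,
    selection: str = "ca_only",
) -> float:
    """Pearson r between USR distance to the native and lRMSD to the native.

    The USR side uses raw feature-space distances; r is invariant to the
    positive scaling that normalization would apply.
    """
    native = native if native is not None else ensemble.native
    if native is None:
        raise ValueError("correlation needs a native reference structure")
    if len(ensemble) < 3:
        raise ValueError("correlation needs at least 3 structures")
    native_feats = usr_features(native, selection)
    usr = np.array(
        [usr_distance(usr_features(s, selection), native_feats) for s in ensemble]
    )
    lrmsd = np.array([kabsch_lrmsd(s, native, selection) for s in ensemble])
    if usr.std() == 0 or lrmsd.std() == 0:
        raise ValueError("undefined correlation: zero variance on one axis")
    return float(stats.pearsonr(usr, lrmsd).statistic)


@dataclass
class ReductionReport:
    """Machine-readable ensemble-reduction summary.

    Diff entries are absolute magnitudes |value(reduced) - value(source)|,
    matching the non-negative convention of reduction comparison tables.
    """

    name: str
    n_gen: int
    n_red: int
    reduction_pct: float
    energy_gen: dict[str, float]
    energy_red: dict[str, float]
    energy_diff: dict[str, float]
    lrmsd_gen: dict[str, float] | None = None
    lrmsd_red: dict[str, float] | None = None
    lrmsd_diff: dict[str, float] | None = None
    pearson_r: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_frame(self) -> pd.DataFrame:
        """One row per metric: (metric, gen, red, diff)."""
        rows = []
        rows.append(("size", self.n_gen, self.n_red, self.n_gen - self.n_red))
        rows.append(("reduction_pct", np.nan, self.reduction_pct, np.nan))
        for key in ("min", "avg", "max", "diameter"):
            rows.append(
                (
                    f"energy_{key}",
                    self.energy_gen[key],
                    self.energy_red[key],
                    self.energy_diff[key],
                )
            )
        if self.lrmsd_gen is not None:
            for key in ("min", "avg", "std"):
                rows.append(
                    (
                        f"lrmsd_{key}",
                        self.lrmsd_gen[key],
                        self.lrmsd_red[key],
                        self.lrmsd_diff[key],
                    )
                )
        if self.pearson_r is not None:
            rows.append(("pearson_usr_lrmsd", self.pearson_r, np.nan, np.nan))
        return pd.DataFrame(rows, columns=["metric", "gen", "red", "diff"])


def _abs_diff(red: dict[str, float], gen: dict[str, float]) -> dict[str, float]:
    return {k: abs(red[k] - gen[k]) for k in red}


def compare(
    gen: Ensemble,
    red_ids: list[str],
    native: Structure | None = None,
    selection: str = "ca_only",
    with_correlation: bool = False,
) -> ReductionReport:
    """Assemble the full source-vs-reduced comparison report."""
    reduced = gen.subset(red_ids)
    native = native if native is not None else gen.native
    e_gen = energy_stats(gen)
    e_red = energy_stats(reduced)
    report = ReductionReport(
        name=gen.name,
        n_gen=len(gen),
        n_red=len(reduced),
        reduction_pct=reduction_pct(len(gen), len(reduced)),
        energy_gen=e_gen,
        energy_red=e_red,
        energy_diff=_abs_diff(e_red, e_gen),
    )
    if native is not None:
        l_gen = lrmsd_stats(gen, native, selection)
        l_red = lrmsd_stats(reduced, native, selection)
        report.lrmsd_gen = l_gen
        report.lrmsd_red = l_red
        report.lrmsd_diff = _abs_diff(l_red, l_gen)
        if with_correlation:
            report.pearson_r = pearson_usr_lrmsd(gen, native, selection)
    return report


def landscape_table(
    gen: Ensemble,
    red_ids: list[str],
    native: Structure | None = None,
    selection: str = "ca_only",
) -> pd.DataFrame:
    """Per-structure landscape data: id, lRMSD to native (if available),
    energy, and whether the structure survived the reduction."""
    native = native if native is not None else gen.native
    in_reduced = set(red_ids)
    unknown = in_reduced - set(gen.ids)
    if unknown:
        raise KeyError(f"unknown reduced ids: {sorted(unknown)[:5]}")
    rows = []
    for s in gen:
        lrmsd = kabsch_lrmsd(s, native, selection) if native is not None else np.nan
        rows.append((s.id, lrmsd, s.energy, s.id in in_reduced))
    return pd.DataFrame(rows, columns=["id", "lrmsd_A", "energy_REU", "in_reduced"])


def histogram_table(
    gen: Ensemble,
    red_ids: list[str],
    quantity: str = "energy",
    native: Structure | None = None,
    bins: int = 30,
    selection: str = "ca_only",
) -> pd.DataFrame:
    """Shared-bin histogram counts for source and reduced ensembles.

    ``quantity`` is ``energy`` (REU) or ``lrmsd`` (Angstrom, needs native).
    """
    if quantity == "energy":
        values = gen.energies
    elif quantity == "lrmsd":
        native = native if native is not None else gen.native
        if native is None:
            raise ValueError("lRMSD histogram needs a native reference")
        values = np.array([kabsch_lrmsd(s, native, selection) for s in gen])
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    mask_red = np.array([sid in set(red_ids) for sid in gen.ids])
    edges = np.histogram_bin_edges(values, bins=bins)
    count_gen, _ = np.histogram(values, bins=edges)
    count_red, _ = np.histogram(values[mask_red], bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "count_gen": count_gen, "count_red": count_red}
    )
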