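"""Populate the reduced ensemble from clusters via energy-level binning.

Within every cluster, structures whose energies coincide after rounding to
the bin width (default 0.01 REU, i.e. two decimal places) share an energy
level; one structure is drawn at random from each non-empty (cluster, bin)
pair. The reduced ensemble therefore covers every energy level of every
cluster, which bounds how much the minimum energy and the energy diameter
can shift: the minimum rises by less than one bin width and the diameter
shrinks by less than two.

The truncation baseline simply keeps the M lowest-energy structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cluster import ClusterResult
from .io import Ensemble

__all__ = [
    "SelectionResult",
    "energy_bin_key",
    "select_reduced",
    "truncation_select",
    "auto_truncation_size",
]


@dataclass
class SelectionResult:
    """Ids kept in the reduced ensemble plus the bins they were drawn from."""

    selected_ids: list[str]
    bins: dict[tuple[int, int], list[str]] = field(default_factory=dict)
    bin_width: float | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.selected_ids)


def energy_bin_key(energy: float, width: float = 0.01, mode: str = "round") -> int:
    """Integer bin key of an energy level.

    ``round`` (default): round-half-even of energy/width, so energies equal
    after rounding to two decimals (at the default width) share a key.
    ``truncate``: truncation toward zero, offered as an alternative keying.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    if not math.isfinite(energy):
        raise ValueError(f"non-finite energy {energy}")
    scaled = energy / width
    if mode == "round":
        return int(np.round(scaled))  # numpy rounds half to even
    if mode == "truncate":
        return int(math.trunc(scaled))
    raise ValueError(f"unknown binning mode {mode!r}")


def select_reduced(
    ensemble: Ensemble,
    clusters: ClusterResult,
    width: float = 0.01,
    seed: int | None = 0,
    mode: str = "round",
) -> SelectionResult:
    """Select one random structure per (cluster, energy bin).

    The set of non-empty bins — and hence the reduced-ensemble size — is
    fully determined by the clustering, the energies and the bin width;
    only which member represents a bin depends on the seed.
    """
    energies = ensemble.energies
    labels = clusters.labels
    if len(labels) != len(ensemble):
        raise ValueError("cluster labels do not cover the ensemble")
    bins: dict[tuple[int, int], list[str]] = {}
    for sid, lab, energy in zip(ensemble.ids, labels, energies):
        key = (int(lab), energy_bin_key(energy, width, mode))
        bins.setdefault(key, []).append(sid)
    rng = np.random.default_rng(seed)
    selected = [
        members[rng.integers(len(members))] for _, members in sorted(bins.items())
    ]
    return SelectionResult(
        selected_ids=selected, bins=bins, bin_width=width, seed=seed
    )


def truncation_select(ensemble: Ensemble, M: int) -> SelectionResult:
    """Keep the M lowest-energy structures (stable order on ties).

    The global minimum-energy structure is always retained, so the
    min-energy difference to the source ensemble is exactly 0.
    """
    n = len(ensemble)
    if not 1 <= M <= n:
        raise ValueError(f"target size M={M} outside [1, {n}]")
    order = np.argsort(ensemble.energies, kind="stable")
    ids = ensemble.ids
    return SelectionResult(selected_ids=[ids[i] for i in order[:M]])


def auto_truncation_size(results: list[SelectionResult]) -> int:
    """Truncation target M = the largest reduced-ensemble size among the
    supplied cluster-based selections."""
    if not results:
        raise ValueError("auto truncation size needs at least one selection result")
    return max(len(r) for r in results)
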