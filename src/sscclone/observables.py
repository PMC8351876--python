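"""Ensemble statistics of cross-sectional clone observations.

The statistics follow the conventions of clonal lineage-tracing analyses:

* ``survival_fraction`` — fraction of clones retaining at least one GFRα1+
  cell ("persisting" clones), S(t) = 1 - P(n=0, t);
* ``mean_persisting_size`` — mean GFRα1+ cell content among persisting
  clones only (the size distribution conditioned on n >= 1);
* ``persisting_size_cdf`` — empirical cumulative size distribution of the
  persisting clones;
* ``mean_progeny`` — mean GFRα1- progeny per clone, over *all* clones
  including extinct ones (the asymmetry with the persisting-only mean size
  is deliberate and preserved);
* ``syncytial_composition`` — relative frequencies r_k of unit lengths,
  pooled over all clones and normalized to sum to one.

Statistics at different timepoints may come from disjoint clone sets
(cross-sectional design, one host cohort per harvest); no identity linkage
across timepoints is assumed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .model import CloneTrajectory

__all__ = [
    "CloneObservation",
    "TimepointStatistics",
    "EnsembleStatistics",
    "LengthBins",
    "DEFAULT_BINS",
    "survival_fraction",
    "mean_persisting_size",
    "persisting_size_cdf",
    "mean_progeny",
    "syncytial_composition",
    "compute_statistics",
    "trajectories_to_observations",
]


@dataclass
class CloneObservation:
    """One clone scored at one harvest timepoint."""

    clone_id: str
    timepoint: float
    composition: dict[int, int]
    n_total: int | None = None
    m_prog: int | None = None

    def __post_init__(self) -> None:
        comp = {int(k): int(c) for k, c in self.composition.items()}
        if any(k < 1 or c < 0 for k, c in comp.items()):
            raise ValueError(f"clone {self.clone_id}: invalid composition {comp}")
        self.composition = {k: c for k, c in comp.items() if c > 0}
        n = sum(k * c for k, c in self.composition.items())
        if self.n_total is None:
            self.n_total = n
        elif int(self.n_total) != n:
            raise ValueError(
                f"clone {self.clone_id}: n_total={self.n_total} inconsistent with "
                f"composition (sum k*n_k = {n})"
            )
        if self.m_prog is not None and int(self.m_prog) < 0:
            raise ValueError(f"clone {self.clone_id}: m_prog must be >= 0")


@dataclass(frozen=True)
class LengthBins:
    """Named syncytial-length bins used for composition reporting and fitting.

    ``edges`` are (label, lo, hi) with inclusive bounds; ``hi=None`` is open.
    """

    edges: tuple[tuple[str, int, int | None], ...]

    @property
    def labels(self) -> list[str]:
        return [e[0] for e in self.edges]

    def index_of(self, k: int) -> int:
        for i, (_, lo, hi) in enumerate(self.edges):
            if k >= lo and (hi is None or k <= hi):
                return i
        raise ValueError(f"length {k} falls in no bin")

    def aggregate(self, per_length: dict[int, float]) -> np.ndarray:
        out = np.zeros(len(self.edges))
        for k, v in per_length.items():
            out[self.index_of(k)] += v
        return out


#: A_s, A_pr, A_al4 (3-4), A_al8 (5-8), A_al16+ (>= 9) — the scoring bins
#: used for syncytial-composition plots.
DEFAULT_BINS = LengthBins((
    ("A_s", 1, 1),
    ("A_pr", 2, 2),
    ("A_al4", 3, 4),
    ("A_al8", 5, 8),
    ("A_al16+", 9, None),
))


def _as_list(observations: Iterable[CloneObservation]) -> list[CloneObservation]:
    obs = list(observations)
    if not obs:
        raise ValueError("no observations supplied")
    return obs


def survival_fraction(observations: Iterable[CloneObservation]) -> float:
    """Fraction of clones with at least one GFRα1+ cell."""
    obs = _as_list(observations)
    return sum(1 for o in obs if o.n_total >= 1) / len(obs)


def mean_persisting_size(observations: Iterable[CloneObservation]) -> float:
    """Mean GFRα1+ cell content among persisting clones (n >= 1)."""
    sizes = [o.n_total for o in _as_list(observations) if o.n_total >= 1]
    if not sizes:
        raise ValueError("no persisting clones: mean persisting size is undefined")
    return float(np.mean(sizes))


def persisting_size_cdf(
    observations: Iterable[CloneObservation],
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of GFRα1+ cell number among persisting clones.

    Returns ``(sizes, cdf)`` where ``sizes`` are the distinct clone sizes in
    ascending order and ``cdf[i]`` is P(n <= sizes[i] | n >= 1).
    """
    sizes = np.sort([o.n_total for o in _as_list(observations) if o.n_total >= 1])
    if sizes.size == 0:
        raise ValueError("no persisting clones: size distribution is undefined")
    values, counts = np.unique(sizes, return_counts=True)
    return values, np.cumsum(counts) / sizes.size


def mean_progeny(observations: Iterable[CloneObservation]) -> float:
    """Mean GFRα1- progeny per clone, extinct clones included."""
    obs = _as_list(observations)
    missing = [o.clone_id for o in obs if o.m_prog is None]
    if missing:
        raise ValueError(f"m_prog missing for clones: {missing}")
    return float(np.mean([o.m_prog for o in obs]))


def syncytial_composition(
    observations: Iterable[CloneObservation],
    bins: LengthBins | None = None,
) -> tuple[list, np.ndarray]:
    """Relative syncytial-length composition r, pooled over all clones.

    r_k is the ensemble-average occupation of length k divided by the
    ensemble-average total unit count, which equals the pooled unit-length
    histogram normalized to one.  With ``bins`` given, frequencies are
    aggregated into the named bins; otherwise raw lengths are returned.
    """
    obs = _as_list(observations)
    pooled: Counter = Counter()
    for o in obs:
        pooled.update(o.composition)
    total = sum(pooled.values())
    if total == 0:
        raise ValueError("no syncytial units in the ensemble")
    if bins is None:
        lengths = sorted(pooled)
        return lengths, np.array([pooled[k] / total for k in lengths])
    return bins.labels, bins.aggregate(pooled) / total


@dataclass
class TimepointStatistics:
    """All ensemble observables at one harvest timepoint."""

    timepoint: float
    n_clones: int
    survival: float
    mean_n_persisting: float | None
    size_values: np.ndarray | None
    size_cdf: np.ndarray | None
    mean_m: float | None
    composition_labels: list
    composition_r: np.ndarray

    def to_dict(self) -> dict:
        return {
            "timepoint": self.timepoint,
            "n_clones": self.n_clones,
            "survival": self.survival,
            "mean_n_persisting": self.mean_n_persisting,
            "size_values": None if self.size_values is None else self.size_values.tolist(),
            "size_cdf": None if self.size_cdf is None else self.size_cdf.tolist(),
            "mean_m": self.mean_m,
            "composition_labels": list(self.composition_labels),
            "composition_r": self.composition_r.tolist(),
        }


@dataclass
class EnsembleStatistics:
    """Per-timepoint statistics of a cross-sectional clone ensemble."""

    by_time: dict[float, TimepointStatistics]
    bins: LengthBins | None = None

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.by_time)

    def __getitem__(self, t: float) -> TimepointStatistics:
        return self.by_time[t]

    def to_dict(self) -> dict:
        return {str(t): s.to_dict() for t, s in sorted(self.by_time.items())}


def compute_statistics(
    observations: Iterable[CloneObservation],
    bins: LengthBins | None = DEFAULT_BINS,
    require_m: bool = False,
) -> EnsembleStatistics:
    """Compute all per-timepoint statistics from a flat observation list.

    Statistics that are undefined at a timepoint (no persisting clone, no
    unit, missing m) are set to None instead of raising, unless ``require_m``
    demands the progeny mean.
    """
    obs = _as_list(observations)
    by_time: dict[float, TimepointStatistics] = {}
    for t in sorted({o.timepoint for o in obs}):
        at_t = [o for o in obs if o.timepoint == t]
        surv = survival_fraction(at_t)
        try:
            mean_n = mean_persisting_size(at_t)
            size_values, size_cdf = persisting_size_cdf(at_t)
        except ValueError:
            mean_n, size_values, size_cdf = None, None, None
        if require_m or all(o.m_prog is not None for o in at_t):
            mean_m = mean_progeny(at_t)
        else:
            mean_m = None
        try:
            labels, r = syncytial_composition(at_t, bins=bins)
        except ValueError:
            labels = bins.labels if bins is not None else []
            r = np.zeros(len(labels))
        by_time[t] = TimepointStatistics(
            timepoint=t, n_clones=len(at_t), survival=surv,
            mean_n_persisting=mean_n, size_values=size_values,
            size_cdf=size_cdf, mean_m=mean_m,
            composition_labels=labels, composition_r=r,
        )
    return EnsembleStatistics(by_time=by_time, bins=bins)


def trajectories_to_observations(
    trajectories: Sequence[CloneTrajectory],
    id_prefix: str = "sim",
) -> list[CloneObservation]:
    """Flatten simulated trajectories into per-(clone, time) observations."""
    out = []
    for i, traj in enumerate(trajectories):
        for state in traj.states:
            out.append(CloneObservation(
                clone_id=f"{id_prefix}_{i}",
                timepoint=float(state.time),
                composition=dict(state.composition),
                m_prog=int(state.m_prog),
            ))
    return out
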