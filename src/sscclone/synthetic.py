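"""Synthetic cross-sectional clone-table generator.

Emulates the statistical structure of a pulse-transplantation clonal fate
study: at each harvest timepoint an *independent* ensemble of clones is
drawn (hosts are sacrificed per timepoint, so no clone is observed twice),
each clone seeded at ``t_start`` from a configurable initial-configuration
distribution (mostly single cells plus some short syncytia) and evolved
under the lattice model at known ground-truth rates.  The output table and
its truth manifest make every downstream stage — statistics, fitting,
sensitivity — testable end to end without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .model import ModelParams, SeedDistribution, simulate_ensemble
from .observables import CloneObservation

__all__ = ["StudyDesign", "generate_dataset"]


@dataclass
class StudyDesign:
    """Design of a synthetic cross-sectional study."""

    truth: ModelParams
    harvest_times: tuple[float, ...] = (2.0, 6.0, 10.0, 14.0, 20.0)
    clones_per_time: int = 300
    seed: int = 0
    seed_distribution: SeedDistribution = field(
        default_factory=SeedDistribution.default
    )
    dropout: float = 0.0  # per-clone probability of being lost to scoring

    def __post_init__(self) -> None:
        if self.clones_per_time < 1:
            raise ValueError("clones_per_time must be >= 1")
        if any(t < self.truth.t_start for t in self.harvest_times):
            raise ValueError("harvest times must be >= t_start")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


def generate_dataset(design: StudyDesign) -> tuple[pd.DataFrame, dict]:
    """Generate a clone table and its ground-truth manifest.

    Returns ``(table, manifest)``: one row per clone per harvest time with
    columns ``clone_id, timepoint_days, composition, n_total, m_prog``
    (composition serialized as ``"k:count"`` pairs joined by ``';'`` with
    ascending k), and a manifest recording the truth parameters, design and
    seed for parameter-recovery tests.
    """
    from .io import composition_to_str

    rows = []
    for j, tp in enumerate(design.harvest_times):
        trajs = simulate_ensemble(
            design.seed_distribution,
            design.truth,
            design.clones_per_time,
            record_times=[tp] if tp > design.truth.t_start else [design.truth.t_start],
            seed=[design.seed, j],
            m_mode="stochastic",
        )
        if design.dropout > 0:
            drop_rng = np.random.default_rng([design.seed, j, 999_983])
            keep = drop_rng.random(len(trajs)) >= design.dropout
        else:
            keep = np.ones(len(trajs), dtype=bool)
        for i, traj in enumerate(trajs):
            if not keep[i]:
                continue
            state = traj.states[-1]
            comp = dict(state.composition)
            rows.append({
                "clone_id": f"tp{tp:g}_c{i:04d}",
                "timepoint_days": float(tp),
                "composition": composition_to_str(comp),
                "n_total": int(state.n_total),
                "m_prog": int(state.m_prog),
            })
    table = pd.DataFrame(rows, columns=[
        "clone_id", "timepoint_days", "composition", "n_total", "m_prog",
    ])
    manifest = {
        "generator": "sscclone.synthetic.generate_dataset",
        "version": _pkg_version,
        "seed": design.seed,
        "truth": design.truth.to_dict(),
        "harvest_times": [float(t) for t in design.harvest_times],
        "clones_per_time": design.clones_per_time,
        "dropout": design.dropout,
        "seed_distribution": [
            {"weight": w, "composition": {str(k): c for k, c in comp.items()},
             "m0": m0}
            for w, comp, m0 in design.seed_distribution.entries
        ],
    }
    return table, manifest
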