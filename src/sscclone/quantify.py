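"""Closed-form colony quantification arithmetic.

Three small calculations used when interpreting transplantation data:

* the probability that a repopulating colony is a chance merger of two
  independently seeded clones, for clusters positioned randomly along a
  tubule;
* labeling efficiencies as plain count ratios;
* the chain of scalings that converts testis-level cell counts into the
  number of labeled stem cells actually injected per host testis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MergerInputs",
    "CellBudget",
    "merger_probability",
    "round_to_sig_figs",
    "labeling_efficiency",
    "injected_cell_budget",
]


@dataclass(frozen=True)
class MergerInputs:
    """Geometry of the merger estimate: N clusters of mean extent a on length L."""

    n_clusters: int       # N, average number of clusters per testis
    mean_extent_a: float  # a, mean cluster extent along the tubule (mm)
    tubule_length_L: float  # L, total tubule length scored (mm)

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not 0 < self.mean_extent_a <= self.tubule_length_L:
            raise ValueError("need 0 < a <= L")


def merger_probability(inputs: MergerInputs) -> float:
    """Probability that a given cluster overlaps at least one other.

    For N clusters positioned independently and uniformly along a tubule of
    length L, each of typical extent a, the chance that a given cluster is
    merged with another is approximately p = 1 - (1 - a/L)^(N-1).
    """
    frac = inputs.mean_extent_a / inputs.tubule_length_L
    return 1.0 - (1.0 - frac) ** (inputs.n_clusters - 1)


def round_to_sig_figs(x: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures (report-parity helper)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + sig - 1)


def labeling_efficiency(labeled_count: float, reference_count: float) -> float:
    """Labeling efficiency as labeled / reference; also see ``as_percent``."""
    if reference_count <= 0:
        raise ValueError("reference_count must be > 0")
    if labeled_count < 0:
        raise ValueError("labeled_count must be >= 0")
    return labeled_count / reference_count


def as_percent(fraction: float, decimals: int = 1) -> float:
    """Render a fraction as a percentage rounded to ``decimals`` places."""
    return round(100.0 * fraction, decimals)


@dataclass(frozen=True)
class CellBudget:
    """Inputs of the injected-cell budget chain.

    The marker population per testis is either counted directly from a
    linear density along the tubules (``route='gfra1'``: density x length)
    or scaled from that total by the ratio of two immunophenotype
    percentages among undifferentiated spermatogonia (``route='ngn3'``,
    using that Ngn3+ cells exclusively express RARγ).
    """

    gfra1_density: float          # GFRα1+ cells per mm of tubule
    tubule_length: float          # mm of tubule per testis
    testis_cell_total: float      # total cells per donor testis
    injected_total: float         # cells injected per host testis
    viability: float              # fraction of injected cells viable
    labeling_efficiency: float    # fraction of marker+ cells labeled
    marker_pos_fraction_in_labeled: float  # marker+ fraction among labeled cells
    route: str = "gfra1"
    rarg_pos_pct: float | None = None   # RARγ+ fraction of A_undiff (ngn3 route)
    gfra1_pos_pct: float | None = None  # GFRα1+ fraction of A_undiff (ngn3 route)

    def __post_init__(self) -> None:
        fractions = {
            "viability": self.viability,
            "labeling_efficiency": self.labeling_efficiency,
            "marker_pos_fraction_in_labeled": self.marker_pos_fraction_in_labeled,
        }
        for name, v in fractions.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("gfra1_density", "tubule_length", "testis_cell_total",
                     "injected_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.route not in ("gfra1", "ngn3"):
            raise ValueError("route must be 'gfra1' or 'ngn3'")
        if self.route == "ngn3":
            if not self.rarg_pos_pct or not self.gfra1_pos_pct:
                raise ValueError("ngn3 route needs rarg_pos_pct and gfra1_pos_pct")


def injected_cell_budget(budget: CellBudget) -> dict:
    """Derive the injected marker-positive and labeled cell counts.

    Returns exact (float) values plus integer-rounded report values; all
    rounding happens at the final step only, so chained quantities do not
    accumulate rounding error.
    """
    if budget.testis_cell_total == 0:
        raise ValueError("testis_cell_total must be > 0")
    if budget.marker_pos_fraction_in_labeled == 0:
        raise ValueError("marker_pos_fraction_in_labeled must be > 0")
    gfra1_total = budget.gfra1_density * budget.tubule_length
    if budget.route == "gfra1":
        total_per_testis = gfra1_total
    else:
        total_per_testis = gfra1_total * (budget.rarg_pos_pct / budget.gfra1_pos_pct)
    injected_marker_pos = (
        total_per_testis
        * (budget.injected_total / budget.testis_cell_total)
        * budget.viability
    )
    injected_labeled = (
        injected_marker_pos
        * budget.labeling_efficiency
        / budget.marker_pos_fraction_in_labeled
    )
    return {
        "total_per_testis": total_per_testis,
        "injected_marker_pos": injected_marker_pos,
        "injected_labeled": injected_labeled,
        "total_per_testis_rounded": round(total_per_testis),
        "injected_marker_pos_rounded": round(injected_marker_pos),
        "injected_labeled_rounded": round(injected_labeled),
    }
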