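"""Run configuration for the immune-scoring pipeline.

A :class:`RunConfig` pins every tunable of the workflow — marker panels,
the ordered cell-classification rule table, stratification cut-points,
QC thresholds for single-cell data, resampling sizes and the random
seed — so that a whole analysis is reproducible from a single YAML file.
CLI flags override individual fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

__all__ = [
    "ClassRule",
    "RunConfig",
    "DEFAULT_PANELS",
    "DEFAULT_RULE_TABLE",
    "load_config",
]


@dataclass(frozen=True)
class ClassRule:
    """One row of the ordered marker-combination rule table.

    A cell of ``panel`` is assigned ``class_name`` when every marker in
    ``positive`` is flagged positive and every marker in ``negative`` is
    flagged negative.  The first matching rule wins.
    """

    panel: str
    positive: tuple[str, ...]
    negative: tuple[str, ...]
    class_name: str


#: Marker panels: panel id -> ordered marker names.  Two five-marker
#: panels plus cytokeratin (CK) for tumour-cell identification, one for
#: adaptive lymphocytes, one for NK cells and the monocyte/macrophage
#: lineage.
DEFAULT_PANELS: dict[str, tuple[str, ...]] = {
    "lymphocyte": ("CD4", "CD8", "CD20", "FoxP3", "CD45RO", "CK"),
    "macrophage": ("CD3", "CD56", "NKp46", "CD68", "CD163", "CK"),
}


def _rule(panel, pos, neg, name) -> ClassRule:
    return ClassRule(panel, tuple(pos), tuple(neg), name)


#: Default 15-class rule table.  The exact subclass definitions used to
#: produce published density tables live in supplementary material that
#: is not reproduced here; this table is a documented reconstruction
#: from the two marker panels above and is fully configurable.
DEFAULT_RULE_TABLE: tuple[ClassRule, ...] = (
    # tumour cells first: CK+ always wins and is excluded from densities
    _rule("lymphocyte", ["CK"], [], "tumour"),
    _rule("macrophage", ["CK"], [], "tumour"),
    # adaptive lymphocyte panel
    _rule("lymphocyte", ["CD8", "FoxP3"], ["CK"], "CD8+FoxP3+ T cell"),
    _rule("lymphocyte", ["CD8", "CD45RO"], ["CK"], "CD8+CD45RO+ memory T cell"),
    _rule("lymphocyte", ["CD8"], ["CK"], "CD8+ T cell"),
    _rule("lymphocyte", ["CD4", "FoxP3"], ["CK"], "CD4+FoxP3+ regulatory T cell"),
    _rule("lymphocyte", ["CD4", "CD45RO"], ["CK"], "CD4+CD45RO+ memory T cell"),
    _rule("lymphocyte", ["CD4"], ["CK"], "CD4+ helper T cell"),
    _rule("lymphocyte", ["CD20"], ["CK"], "CD20+ B cell"),
    _rule("lymphocyte", ["CD45RO"], ["CK"], "CD45RO+ cell"),
    # NK / macrophage panel
    _rule("macrophage", ["CD68", "CD163"], ["CK"], "CD68+CD163+ macrophage"),
    _rule("macrophage", ["CD68"], ["CD163", "CK"], "CD68+CD163- macrophage"),
    _rule("macrophage", ["CD163"], ["CD68", "CK"], "CD68-CD163+ cell"),
    _rule("macrophage", ["CD3", "CD56"], ["CK"], "NKT-like cell"),
    _rule("macrophage", ["CD56"], ["CD3", "CK"], "NK cell"),
    _rule("macrophage", ["NKp46"], ["CD3", "CK"], "NK cell"),
    _rule("macrophage", ["CD3"], ["CK"], "CD3+ T cell"),
)


@dataclass
class RunConfig:
    """All pipeline settings in one place.

    Parameters
    ----------
    panels
        Panel id -> ordered marker names.
    rule_table
        Ordered classification rules; first match wins.
    tercile_cutpoints
        Percentile cut-offs used for low/intermediate/high score
        stratification.  Must be strictly increasing within (0, 100).
    is_bounds
        Mean-percentile bounds separating the Low / Intermediate / High
        categories of the Immunoscore-like metric.
    is_region_mode
        ``"centre+margin"`` (up to four density channels per patient) or
        ``"bulk"`` (two channels).
    sc_positivity_threshold
        A cell is positive for a gene when its count is strictly greater
        than this value (default 0, i.e. any detected expression).
    min_genes
        Minimum detected genes per cell in single-cell QC (250 default;
        100 used for plate-based checkpoint-therapy cohorts).
    mito_ceiling
        Maximum mitochondrial read fraction per cell.  Interpreted as a
        fraction (0.05 = 5%).  A literal per-mille reading can be set
        explicitly by the user.
    bootstrap_replicates, ks_iterations
        Resampling sizes for the bootstrap AUC and the tile
        representativeness test.
    alpha
        Significance level for resampling tests.
    cutoff_window
        Quantile window searched by optimal-cut-off dichotomisation.
    seed
        Master seed; fixing it makes every stochastic stage reproducible.
    """

    panels: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PANELS)
    )
    rule_table: tuple[ClassRule, ...] = DEFAULT_RULE_TABLE
    tercile_cutpoints: tuple[float, float] = (33.3, 66.6)
    is_bounds: tuple[float, float] = (25.0, 70.0)
    is_region_mode: str = "centre+margin"
    sc_positivity_threshold: float = 0.0
    min_genes: int = 250
    mito_ceiling: float = 0.05
    mito_prefix: str = "MT-"
    bootstrap_replicates: int = 1000
    ks_iterations: int = 1000
    alpha: float = 0.05
    cutoff_window: tuple[float, float] = (0.10, 0.90)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.tercile_cutpoints
        if not (0.0 < lo < hi < 100.0):
            raise ValueError(
                "tercile cutpoints must be strictly increasing within (0, 100); "
                f"got {self.tercile_cutpoints}"
            )
        lo, hi = self.is_bounds
        if not (0.0 < lo < hi < 100.0):
            raise ValueError(
                "IS category bounds must be strictly increasing within (0, 100); "
                f"got {self.is_bounds}"
            )
        if self.is_region_mode not in ("centre+margin", "bulk"):
            raise ValueError(f"unknown IS region mode: {self.is_region_mode!r}")
        if self.min_genes < 0 or not (0.0 <= self.mito_ceiling <= 1.0):
            raise ValueError("invalid single-cell QC settings")
        qlo, qhi = self.cutoff_window
        if not (0.0 <= qlo <= qhi <= 1.0):
            raise ValueError(f"invalid cut-off quantile window: {self.cutoff_window}")

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rule_table"] = [
            {
                "panel": r.panel,
                "positive": list(r.positive),
                "negative": list(r.negative),
                "class_name": r.class_name,
            }
            for r in self.rule_table
        ]
        d["panels"] = {k: list(v) for k, v in self.panels.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "rule_table" in d:
            d["rule_table"] = tuple(
                ClassRule(
                    r["panel"],
                    tuple(r.get("positive", ())),
                    tuple(r.get("negative", ())),
                    r["class_name"],
                )
                for r in d["rule_table"]
            )
        if "panels" in d:
            d["panels"] = {k: tuple(v) for k, v in d["panels"].items()}
        for key in ("tercile_cutpoints", "is_bounds", "cutoff_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path) -> RunConfig:
    """Read a :class:`RunConfig` from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def markers_for_panel(config: RunConfig, panel_id: str) -> Sequence[str]:
    try:
        return config.panels[panel_id]
    except KeyError as exc:
        raise KeyError(f"panel {panel_id!r} not defined in configuration") from exc
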