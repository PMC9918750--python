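"""Cell classification and area-normalised density computation.

Positivity-flagged cells are assigned to immune classes by an ordered
marker-combination rule table (first matching rule wins; CK+ cells are
tumour cells and are excluded from immune densities).  Densities are
computed per patient by pooling: total cell count across all of a
patient's cores divided by total tissue area — never a mean of per-core
densities, which would over-weight small cores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("siascore")

__all__ = [
    "classify_cells",
    "compute_densities",
    "coexpression_summary",
    "categorize_tercile",
    "PatientProfiles",
]

NON_IMMUNE_CLASSES = ("tumour", "unclassified")


def classify_cells(cells: pd.DataFrame, rule_table, config) -> pd.DataFrame:
    """Assign each cell its immune class via the ordered rule table.

    Every cell receives exactly one ``class_label``; cells matching no
    rule are labelled ``"unclassified"``.  Rules referencing a marker
    absent from their panel raise a configuration error.
    """
    out = cells.copy()
    out["class_label"] = "unclassified"
    assigned = pd.Series(False, index=out.index)
    seen_patterns: dict[tuple, str] = {}
    for rule in rule_table:
        if rule.panel not in config.panels:
            raise ValueError(f"rule {rule.class_name!r} references unknown panel "
                             f"{rule.panel!r}")
        panel_markers = set(config.panels[rule.panel])
        unknown = (set(rule.positive) | set(rule.negative)) - panel_markers
        if unknown:
            raise ValueError(
                f"rule {rule.class_name!r} references marker(s) {sorted(unknown)} "
                f"absent from panel {rule.panel!r}"
            )
        key = (rule.panel, rule.positive, rule.negative)
        if key in seen_patterns:
            logger.warning(
                "rule %r duplicates the marker pattern of earlier rule %r; "
                "the first rule wins", rule.class_name, seen_patterns[key],
            )
            continue
        seen_patterns[key] = rule.class_name

        mask = (out["panel_id"] == rule.panel) & ~assigned
        if not mask.any():
            continue
        for m in rule.positive:
            mask &= out[f"pos_{m}"].astype(bool)
        for m in rule.negative:
            mask &= ~out[f"pos_{m}"].astype(bool)
        out.loc[mask, "class_label"] = rule.class_name
        assigned |= mask
    return out


@dataclass
class PatientProfiles:
    """Per-patient immune profile: densities, scores and strata.

    ``density`` is a patients x classes table in cells/mm^2 computed by
    pooling counts and areas over all cores; ``density_by_region``
    restricts pooling to cores of one region (centre/margin/bulk).
    Score columns (SIA, IS ...) are attached by the scoring module.
    """

    density: pd.DataFrame
    density_by_region: pd.DataFrame  # long: patient_id, region, class, density
    total_area: pd.Series
    scores: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def patients(self) -> pd.Index:
        return self.density.index

    def class_density(self, class_name: str) -> pd.Series:
        if class_name in self.density.columns:
            return self.density[class_name]
        return pd.Series(0.0, index=self.density.index, name=class_name)


def compute_densities(cells: pd.DataFrame, cores: pd.DataFrame,
                      exclude_flag: str | None = "excluded") -> PatientProfiles:
    """Pooled per-patient, per-class densities (cells/mm^2).

    For each patient: density(class) = sum of cells of that class over
    all the patient's cores / sum of core areas.  Cores with zero cells
    still contribute their area.  Cells carrying a truthy value in the
    optional ``exclude_flag`` column (manual artefact/necrosis curation)
    are dropped before counting.
    """
    unknown = ~cells["core_id"].isin(cores["core_id"])
    if unknown.any():
        bad = cells.loc[unknown, "core_id"].unique()
        raise ValueError(f"cells reference unknown core(s): {list(bad)[:5]}")
    use = cells
    if exclude_flag is not None and exclude_flag in cells.columns:
        use = cells.loc[~cells[exclude_flag].astype(bool)]
    use = use[~use["class_label"].isin(NON_IMMUNE_CLASSES)]

    area_by_patient = cores.groupby("patient_id")["area_mm2"].sum()
    counts = (
        use.groupby(["patient_id", "class_label"]).size().unstack(fill_value=0)
        .reindex(area_by_patient.index, fill_value=0)
    )
    density = counts.div(area_by_patient, axis=0)
    density.columns.name = None

    core_region = cores.set_index("core_id")["region"]
    region_area = cores.groupby(["patient_id", "region"])["area_mm2"].sum()
    use = use.assign(region=use["core_id"].map(core_region))
    region_counts = use.groupby(["patient_id", "region", "class_label"]).size()
    long = (
        region_counts.reindex(
            pd.MultiIndex.from_tuples(
                [(p, r, c) for (p, r) in region_area.index for c in density.columns],
                names=["patient_id", "region", "class_label"],
            ),
            fill_value=0,
        )
        .rename("count").reset_index()
    )
    long["density"] = long["count"] / long.set_index(
        ["patient_id", "region"]).index.map(region_area)
    return PatientProfiles(
        density=density,
        density_by_region=long.drop(columns="count"),
        total_area=area_by_patient,
    )


def marker_positive_densities(cells: pd.DataFrame, cores: pd.DataFrame,
                              markers: list[str],
                              by_region: bool = True) -> pd.DataFrame:
    """Pooled densities of marker-positive, non-tumour cells.

    Used for Immunoscore-style inputs where the channel is defined by a
    single marker (CD3, CD8) rather than a cell class.  Returns a long
    table (patient_id, region, marker, density); region is ``"bulk"``
    when ``by_region`` is false.
    """
    core_region = cores.set_index("core_id")["region"]
    if "class_label" in cells.columns:
        cells = cells[cells["class_label"] != "tumour"]
    if by_region:
        area = cores.groupby(["patient_id", "region"])["area_mm2"].sum()
        cells = cells.assign(_region=cells["core_id"].map(core_region))
    else:
        area = cores.groupby("patient_id")["area_mm2"].sum()

    rows = []
    for marker in markers:
        col = f"pos_{marker}"
        flagged = cells[cells[col].astype(bool)] if col in cells.columns \
            else cells.iloc[0:0]
        if by_region:
            counts = flagged.groupby(["patient_id", "_region"]).size()
            for (patient, region), a in area.items():
                rows.append({
                    "patient_id": patient, "region": region, "marker": marker,
                    "density": counts.get((patient, region), 0) / a,
                })
        else:
            counts = flagged.groupby("patient_id").size()
            for patient, a in area.items():
                rows.append({
                    "patient_id": patient, "region": "bulk", "marker": marker,
                    "density": counts.get(patient, 0) / a,
                })
    return pd.DataFrame(rows)


def coexpression_summary(cells: pd.DataFrame, marker_a: str, marker_b: str) -> dict:
    """Single/double-positive counts for two markers over all cells.

    Returns counts ``a_only``, ``b_only``, ``both`` and the fraction of
    each single-marker-positive population that co-expresses the other
    marker, e.g. ``frac_a_double = both / (a_only + both)``.
    """
    a = cells[f"pos_{marker_a}"].astype(bool).to_numpy()
    b = cells[f"pos_{marker_b}"].astype(bool).to_numpy()
    both = int((a & b).sum())
    a_only = int((a & ~b).sum())
    b_only = int((~a & b).sum())
    return {
        "a_only": a_only, "b_only": b_only, "both": both,
        "frac_a_double": both / (a_only + both) if (a_only + both) else 0.0,
        "frac_b_double": both / (b_only + both) if (b_only + both) else 0.0,
    }


def categorize_tercile(values: pd.Series, cutpoints=(33.3, 66.6)) -> tuple[pd.Series, dict]:
    """Stratify a per-patient score into low/intermediate/high terciles.

    Cut-offs are the 33.3rd and 66.6th empirical percentiles (linear
    interpolation); ties go to the lower stratum (v <= cut).  When the
    cuts coincide, or a single value occupies at least a third of the
    cohort (as happens when many patients reach the maximal possible
    score), tercile cuts are uninformative and the cohort is split at
    the median instead (low: v <= median, high: v > median).  Missing
    scores are excluded.
    """
    v = values.dropna()
    if len(v) < 3:
        raise ValueError("need at least 3 non-missing values for stratification")
    if v.nunique() == 1:
        raise ValueError("all values identical: no informative split")
    c1, c2 = np.percentile(v, cutpoints)
    top_share = v.value_counts(normalize=True).iloc[0]
    if c1 == c2 or top_share >= 1 / 3:
        median = float(np.median(v))
        labels = pd.Series(
            np.where(v <= median, "low", "high"), index=v.index, name="stratum"
        )
        logger.info(
            "tercile cuts uninformative (most frequent value holds %.0f%% of "
            "patients); falling back to median split at %.4g",
            100 * top_share, median,
        )
        meta = {"mode": "median", "cut": median, "top_share": float(top_share)}
    else:
        labels = pd.Series(
            np.where(v <= c1, "low", np.where(v <= c2, "intermediate", "high")),
            index=v.index, name="stratum",
        )
        meta = {"mode": "tercile", "cuts": (float(c1), float(c2)),
                "top_share": float(top_share)}
    return labels.reindex(values.index), meta
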