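"""End-to-end orchestration: thresholds -> phenotypes -> densities -> scores.

The individual stages live in their own modules; this module wires them
together for the common case of running a whole cohort from a raw cell
table plus labelled reference cells.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import RunConfig
from .phenotyping import (PatientProfiles, categorize_tercile, classify_cells,
                          compute_densities, marker_positive_densities)
from .scoring import compute_is, compute_sia
from .simulate import CD8_CLASS, M2_CLASS
from .thresholding import apply_thresholds, thresholds_from_reference_table

logger = logging.getLogger("siascore")

__all__ = ["attach_scores", "is_channels_from_cells", "run_pipeline"]


def attach_scores(profiles: PatientProfiles, config: RunConfig,
                  cells: pd.DataFrame | None = None,
                  cores: pd.DataFrame | None = None,
                  cd8_class: str = CD8_CLASS,
                  m2_class: str = M2_CLASS) -> PatientProfiles:
    """Compute SIA (+ stratum) and, when cells are given, IS per patient."""
    cd8 = profiles.class_density(cd8_class)
    m2 = profiles.class_density(m2_class)
    sia = pd.Series(compute_sia(cd8.to_numpy(), m2.to_numpy()),
                    index=profiles.patients, name="SIA")
    strata, strat_meta = categorize_tercile(sia, config.tercile_cutpoints)
    scores = pd.DataFrame({"SIA": sia, "sia_stratum": strata})
    scores.attrs["sia_stratification"] = strat_meta
    if cells is not None and cores is not None:
        channels = is_channels_from_cells(cells, cores, config)
        is_result = compute_is(channels, config.is_bounds)
        scores = scores.join(is_result)
    profiles.scores = scores
    return profiles


def is_channels_from_cells(cells: pd.DataFrame, cores: pd.DataFrame,
                           config: RunConfig) -> pd.DataFrame:
    """CD3/CD8 marker-density channels for the Immunoscore-like metric.

    In centre+margin mode this yields up to four columns per patient
    (CD3 and CD8 densities in tumour centre and invasive margin), with
    NaN for regions a patient has no cores in (incomplete cases); in
    bulk mode, two columns.
    """
    by_region = config.is_region_mode == "centre+margin"
    dens = marker_positive_densities(cells, cores, ["CD3", "CD8"],
                                     by_region=by_region)
    wide = dens.pivot_table(index="patient_id", columns=["marker", "region"],
                            values="density")
    wide.columns = [f"{m.lower()}_{r}" for m, r in wide.columns]
    return wide


def run_pipeline(cells: pd.DataFrame, cores: pd.DataFrame,
                 reference_cells: pd.DataFrame,
                 config: RunConfig | None = None) -> dict:
    """Threshold, phenotype, and score a cohort in one call.

    Returns a dict with the per-marker ``thresholds``, the classified
    ``cells``, and the scored ``profiles``.
    """
    config = config or RunConfig()
    thresholds = thresholds_from_reference_table(reference_cells)
    flagged = apply_thresholds(cells, thresholds, config)
    classified = classify_cells(flagged, config.rule_table, config)
    profiles = compute_densities(classified, cores)
    profiles = attach_scores(profiles, config, cells=classified, cores=cores)
    return {"thresholds": thresholds, "cells": classified, "profiles": profiles}
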