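import numpy as np
import pandas as pd
import pytest

import siascore as s


@pytest.fixture(scope="session")
def config():
    return s.RunConfig()


@pytest.fixture(scope="session")
def all_markers(config):
    return sorted({m for p in config.panels.values() for m in p})


@pytest.fixture(scope="session")
def small_cohort(config, all_markers):
    """A 30-patient simulated cohort run through the full pipeline once."""
    spec = s.SimulationSpec(n_patients=30, seed=1)
    cells, cores, truth = s.simulate_cell_table(spec, config)
    refs = s.reference_table_from_truth(cells, truth, all_markers,
                                        n_per_group=200,
                                        rng=np.random.default_rng(2))
    result = s.run_pipeline(cells, cores, refs, config)
    return {
        "spec": spec, "cells": cells, "cores": cores, "truth": truth,
        "refs": refs, "result": result,
        "ground_truth": s.ground_truth_profiles(cells, cores, truth),
    }


@pytest.fixture()
def toy_cells():
    """Six positivity-flagged cells across both panels."""
    rows = []

    def cell(i, panel, pos, patient="P1", core="C1"):
        markers = s.DEFAULT_PANELS[panel]
        row = {"cell_id": f"c{i}", "patient_id": patient, "core_id": core,
               "panel_id": panel}
        row.update({m: 5.0 if m in pos else 0.5 for m in markers})
        row.update({f"pos_{m}": (m in pos) for m in markers})
        return row

    rows.append(cell(0, "macrophage", {"CD68", "CD163"}))
    rows.append(cell(1, "macrophage", {"CD68"}))
    rows.append(cell(2, "macrophage", set()))
    rows.append(cell(3, "lymphocyte", {"CD8"}))
    rows.append(cell(4, "lymphocyte", {"CK"}))
    rows.append(cell(5, "macrophage", {"CD3"}))
    return pd.DataFrame(rows)


@pytest.fixture()
def toy_cores():
    return pd.DataFrame({
        "core_id": ["C1"], "patient_id": ["P1"],
        "region": ["centre"], "area_mm2": [2.0],
    })
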