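"""Synthetic study data with closed-form ground truth.

Every input of the pipeline can be generated here: per-cell marker
intensity tables with known positivity, TMA core metadata, survival
outcomes under a proportional-hazards model whose hazard depends on the
SIA stratum, bulk and single-cell expression matrices in which the
transcript surrogates track the simulated cell densities, and
whole-slide tile grids with controllable spatial heterogeneity.

Model choices (documented in the methods note):

* cell counts per core are Poisson with mean density x area, with
  patient-level log-normal heterogeneity of the per-class densities;
* marker intensities are log-normal mixtures — one component for truly
  negative and one for truly positive cells — whose overlap is set by
  the separation of the two log-means;
* event times are exponential with rate = baseline x HR(stratum),
  censored by an administrative horizon and independent exponential
  drop-out, so every recovery test has a closed-form truth.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import ExpressionMatrix

__all__ = [
    "SimulationSpec",
    "simulate_cell_table",
    "simulate_survival",
    "simulate_survival_from_strata",
    "simulate_bulk_expression",
    "simulate_single_cell",
    "simulate_tile_grid",
    "reference_table_from_truth",
    "ground_truth_profiles",
]

CD8_CLASS = "CD8+ T cell"
M2_CLASS = "CD68+CD163+ macrophage"

#: Default mean immune-cell densities (cells/mm^2), chosen to resemble
#: the dynamic range of multiplex-IHC colon-cancer cohorts: abundant T
#: helper and cytotoxic infiltrates, sparser B/NK cells and macrophage
#: subsets, plus an epithelial (CK+) tumour compartment.
DEFAULT_CLASS_DENSITIES: dict[str, float] = {
    "CD8+ T cell": 150.0,
    "CD8+CD45RO+ memory T cell": 40.0,
    "CD4+ helper T cell": 200.0,
    "CD4+FoxP3+ regulatory T cell": 30.0,
    "CD20+ B cell": 50.0,
    "tumour": 300.0,
    "CD3+ T cell": 180.0,
    "CD68+CD163- macrophage": 120.0,
    "CD68+CD163+ macrophage": 50.0,
    "CD68-CD163+ cell": 60.0,
    "NK cell": 30.0,
}


@dataclass
class SimulationSpec:
    """All knobs of the synthetic cohort.

    Defaults encode the study conditions: one to four cores per
    patient with a mean analysed area of 1.84 mm^2, unadjusted overall
    survival hazard ratios of 0.65 (intermediate) and 0.43 (high) vs
    the low SIA stratum, and recurrence-free analogues 0.65 / 0.46.
    Time is measured in weeks.
    """

    n_patients: int = 100
    cores_per_patient: int = 2
    core_area: float = 1.84
    class_densities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_DENSITIES)
    )
    patient_density_sigma: float = 0.5  # log-normal between-patient spread

    # intensity mixture (log scale)
    neg_logmean: float = 0.0
    pos_logmean: float = 2.0
    intensity_logsd: float = 0.35

    # survival
    hr_os: tuple[float, float] = (0.65, 0.43)   # intermediate, high vs low
    hr_rfs: tuple[float, float] = (0.65, 0.46)
    baseline_hazard: float = 0.004              # events per week in the low stratum
    censor_horizon: float = 520.0               # administrative, weeks (~10 y)
    dropout_rate: float = 0.0005                # independent exponential drop-out

    # bulk expression
    expression_noise_sigma: float = 0.3
    n_decoy_genes: int = 50

    # single cell
    cells_per_patient: int = 400
    sc_effect_size: float = 3.0     # responder fold-change of the CD8:M2 ratio
    sc_immune_share: float = 0.30   # share of cells in the CD8 + M2 pool
    sc_marker_mean: float = 10.0    # NB mean of a marker in its positive class
    sc_decoy_mean: float = 2.0
    sc_nb_dispersion: float = 2.0   # NB size parameter r
    sc_n_decoys: int = 300
    sc_low_quality_rate: float = 0.05
    sc_high_mito_rate: float = 0.05

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not 1 <= self.cores_per_patient <= 4:
            raise ValueError("cores_per_patient must be in 1-4")
        if self.core_area <= 0 or self.baseline_hazard <= 0:
            raise ValueError("areas and rates must be positive")
        if any(d < 0 for d in self.class_densities.values()):
            raise ValueError("class densities must be non-negative")
        if any(h <= 0 for h in self.hr_os + self.hr_rfs):
            raise ValueError("hazard ratios must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _class_marker_truth(config: RunConfig) -> dict[str, tuple[str, dict[str, bool]]]:
    """class -> (panel, marker -> true positivity) from the rule table.

    The union of required-positive markers over all rules naming a class
    defines its true pattern (e.g. NK cells, reachable via CD56 or
    NKp46, truly express both); markers of the panel not required
    positive by any rule are truly negative.
    """
    truth: dict[str, tuple[str, dict[str, bool]]] = {}
    for rule in config.rule_table:
        if rule.class_name in truth:
            panel, pattern = truth[rule.class_name]
            if panel == rule.panel:
                for m in rule.positive:
                    pattern[m] = True
            continue
        markers = config.panels[rule.panel]
        truth[rule.class_name] = (
            rule.panel,
            {m: (m in rule.positive) for m in markers},
        )
    return truth


def simulate_cell_table(spec: SimulationSpec, config: RunConfig | None = None,
                        rng: np.random.Generator | None = None):
    """Generate cell, core and ground-truth tables.

    Per patient and core, the count of each simulated class is Poisson
    with mean = (patient-specific class density) x core area; each cell
    receives one intensity per marker of its panel, drawn from the
    positive or negative log-normal component according to the class's
    true marker pattern.

    Returns ``(cells, cores, truth)``: the cell table ready for
    thresholding (with intensities only), the core table, and a truth
    table carrying each cell's true class and per-marker positivity
    plus per-patient true densities.
    """
    config = config or RunConfig()
    rng = rng if rng is not None else spec.rng()
    marker_truth = _class_marker_truth(config)
    for cls in spec.class_densities:
        if cls not in marker_truth:
            raise ValueError(f"class {cls!r} has no rule in the configuration")

    regions = (["centre", "margin"] if config.is_region_mode == "centre+margin"
               else ["bulk"])
    sigma = spec.patient_density_sigma
    patients = [f"P{i:05d}" for i in range(spec.n_patients)]

    core_rows, cell_rows, truth_rows, patient_truth = [], [], [], []
    cell_counter = 0
    for pi, pid in enumerate(patients):
        # patient-level heterogeneity with mean preserved
        pt_density = {
            cls: mean * np.exp(rng.normal(-0.5 * sigma**2, sigma)) if sigma > 0
            else mean
            for cls, mean in spec.class_densities.items()
        }
        patient_truth.append({"patient_id": pid, **{
            f"true_density_{cls}": d for cls, d in pt_density.items()}})
        for ci in range(spec.cores_per_patient):
            core_id = f"{pid}_C{ci}"
            region = regions[ci % len(regions)]
            core_rows.append({
                "core_id": core_id, "patient_id": pid,
                "region": region, "area_mm2": spec.core_area,
            })
            for cls, dens in pt_density.items():
                panel, pattern = marker_truth[cls]
                n_cells = rng.poisson(dens * spec.core_area)
                if n_cells == 0:
                    continue
                markers = config.panels[panel]
                mus = np.array([
                    spec.pos_logmean if pattern[m] else spec.neg_logmean
                    for m in markers
                ])
                intens = np.exp(
                    rng.normal(mus, spec.intensity_logsd, size=(n_cells, len(markers)))
                )
                for k in range(n_cells):
                    cid = f"cell{cell_counter:08d}"
                    cell_counter += 1
                    row = {"cell_id": cid, "patient_id": pid,
                           "core_id": core_id, "panel_id": panel}
                    row.update({m: intens[k, j] for j, m in enumerate(markers)})
                    cell_rows.append(row)
                    trow = {"cell_id": cid, "true_class": cls}
                    trow.update({f"true_pos_{m}": pattern[m] for m in markers})
                    truth_rows.append(trow)

    cores = pd.DataFrame(core_rows)
    all_markers = sorted({m for p in config.panels.values() for m in p})
    cells = pd.DataFrame(
        cell_rows, columns=["cell_id", "patient_id", "core_id", "panel_id",
                            *all_markers]
    )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["patient_truth"] = pd.DataFrame(patient_truth).set_index("patient_id")
    return cells, cores, truth


def ground_truth_profiles(cells: pd.DataFrame, cores: pd.DataFrame,
                          truth: pd.DataFrame) -> pd.DataFrame:
    """Realised per-patient class densities and SIA from the truth table.

    Densities pool true class counts over all of a patient's cores and
    divide by total area — the same pooling rule the pipeline applies —
    so the pipeline run on noiseless data must reproduce these exactly.
    """
    merged = cells[["cell_id", "patient_id"]].merge(truth, on="cell_id")
    area = cores.groupby("patient_id")["area_mm2"].sum()
    counts = (
        merged.groupby(["patient_id", "true_class"]).size().unstack(fill_value=0)
        .reindex(area.index, fill_value=0)
    )
    density = counts.div(area, axis=0)
    cd8 = density.get(CD8_CLASS, pd.Series(0.0, index=density.index))
    m2 = density.get(M2_CLASS, pd.Series(0.0, index=density.index))
    total = cd8 + m2
    out = density.add_prefix("density_")
    out["cd8_density"] = cd8
    out["m2_density"] = m2
    out["sia_true"] = np.where(total > 0, cd8 / total.replace(0, np.nan), np.nan)
    return out


def reference_table_from_truth(cells: pd.DataFrame, truth: pd.DataFrame,
                               markers, n_per_group: int = 500,
                               rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Labelled reference cells for threshold training.

    Samples up to ``n_per_group`` truly positive and truly negative
    cells per marker from the simulated table, emulating the manual
    selection of reference cells on images.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    merged = cells.merge(truth, on="cell_id")
    rows = []
    for m in markers:
        flag_col = f"true_pos_{m}"
        sub = merged[merged[flag_col].notna()] if flag_col in merged else merged.iloc[0:0]
        for label, want in (("pos", True), ("neg", False)):
            grp = sub[sub[flag_col] == want]
            if len(grp) == 0:
                continue
            take = grp.sample(n=min(n_per_group, len(grp)),
                              random_state=rng.integers(2**31))
            for _, r in take.iterrows():
                rows.append({"marker": m, "intensity": r[m], "label": label})
    return pd.DataFrame(rows)


HR_BY_STRATUM = {"low": 0, "intermediate": 1, "high": 1}  # index into hr tuple


def simulate_survival_from_strata(strata: pd.Series, spec: SimulationSpec,
                                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Survival records from per-patient SIA strata.

    Event times are exponential with rate = baseline x HR(stratum); the
    observed time is the minimum of the event time, an independent
    exponential drop-out and the administrative horizon.  OS and RFS
    are generated independently with their own hazard ratios.  Patients
    with an undefined stratum (NaN) are excluded with a log entry.
    Clinical covariates are drawn independently of outcome (null
    covariates) for use in adjusted-model testing.
    """
    rng = rng if rng is not None else spec.rng()
    strata = strata.dropna()
    n = len(strata)

    def _hr(hrs):
        mapping = {"low": 1.0, "intermediate": hrs[0], "high": hrs[1]}
        unknown = set(strata.unique()) - set(mapping)
        if unknown:
            raise ValueError(f"unknown stratum label(s): {sorted(unknown)}")
        return strata.map(mapping).to_numpy(float)

    out = pd.DataFrame({"patient_id": strata.index, "sia_stratum": strata.values})
    for endpoint, hrs in (("os", spec.hr_os), ("rfs", spec.hr_rfs)):
        rate = spec.baseline_hazard * _hr(hrs)
        event_t = rng.exponential(1.0 / rate)
        if spec.dropout_rate > 0:
            drop_t = rng.exponential(1.0 / spec.dropout_rate, size=n)
        else:
            drop_t = np.full(n, np.inf)
        censor_t = np.minimum(drop_t, spec.censor_horizon)
        time = np.minimum(event_t, censor_t)
        out[f"{endpoint}_time"] = time
        out[f"{endpoint}_event"] = event_t <= censor_t
    # null clinical covariates (independent of outcome)
    out["t_stage"] = rng.choice(["T1", "T2", "T3", "T4"], size=n,
                                p=[0.1, 0.2, 0.5, 0.2])
    out["n_stage"] = rng.choice(["N0", "N+"], size=n, p=[0.6, 0.4])
    out["age_group"] = rng.choice(["<=75", ">75"], size=n, p=[0.7, 0.3])
    out["sex"] = rng.choice(["female", "male"], size=n)
    out["msi"] = rng.choice(["proficient", "deficient", "missing"], size=n,
                            p=[0.8, 0.15, 0.05])
    return out.set_index("patient_id")


def simulate_survival(profiles: pd.DataFrame, spec: SimulationSpec,
                      stratum_col: str = "sia_stratum",
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Survival records for profiled patients (see
    :func:`simulate_survival_from_strata`)."""
    return simulate_survival_from_strata(profiles[stratum_col], spec, rng=rng)


def simulate_bulk_expression(profiles: pd.DataFrame, spec: SimulationSpec,
                             rng: np.random.Generator | None = None) -> ExpressionMatrix:
    """Bulk expression in which transcripts track cell densities.

    CD8A and CD3E are proportional to the CD8+ density and C1QA/B/C to
    the CD68+CD163+ density, each multiplied by independent log-normal
    noise; decoy genes are density-independent.
    """
    rng = rng if rng is not None else spec.rng()
    cd8 = profiles["cd8_density"].to_numpy(float)
    m2 = profiles["m2_density"].to_numpy(float)
    n = len(profiles)
    s = spec.expression_noise_sigma

    def noisy(base, scale):
        noise = np.exp(rng.normal(0.0, s, size=n)) if s > 0 else 1.0
        return scale * base * noise

    rows = {
        "CD8A": noisy(cd8, 1.0),
        "CD3E": noisy(cd8, 1.5),
        "C1QA": noisy(m2, 2.0),
        "C1QB": noisy(m2, 1.8),
        "C1QC": noisy(m2, 2.2),
    }
    for i in range(spec.n_decoy_genes):
        rows[f"DECOY{i + 1}"] = np.exp(rng.normal(2.0, 1.0, size=n))
    values = pd.DataFrame(rows, index=profiles.index).T
    obs = pd.DataFrame({"patient": profiles.index}, index=profiles.index)
    return ExpressionMatrix(values, obs, "linear")


SC_CLASSES = ("CD8 T cell", "M2 macrophage", "M1 macrophage", "other")
SC_MARKER_CLASSES = {
    "CD8A": ("CD8 T cell",),
    "CD3E": ("CD8 T cell",),
    "CD68": ("M2 macrophage", "M1 macrophage"),
    "CD163": ("M2 macrophage",),
    "C1QA": ("M2 macrophage",),
    "C1QB": ("M2 macrophage",),
    "C1QC": ("M2 macrophage",),
}
MITO_GENES = ("MT-CO1", "MT-ND1", "MT-CYB")


def _nb_counts(rng, mean, r, size):
    if np.all(mean <= 0):
        return np.zeros(size, dtype=int)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_single_cell(spec: SimulationSpec, n_patients: int,
                         response_labels=None,
                         rng: np.random.Generator | None = None) -> ExpressionMatrix:
    """Single-cell counts with class, patient and response labels.

    Responders carry a CD8+:M2 cell-ratio ``sc_effect_size`` times that
    of non-responders; within the immune pool (share ``sc_immune_share``
    of all cells) the CD8/M2 split follows that ratio.  Counts are
    negative binomial with class-specific marker means, a constant
    decoy background, and three mitochondrial genes.  A configurable
    fraction of cells is generated as low-quality (tiny library) or
    high-mitochondrial, for exercising the QC filter; the truth flags
    are carried in the cell annotations.
    """
    rng = rng if rng is not None else spec.rng()
    if response_labels is None:
        response_labels = ["responder" if i < n_patients // 2 else "non-responder"
                           for i in range(n_patients)]
    if len(response_labels) != n_patients:
        raise ValueError("need one response label per patient")

    genes = list(SC_MARKER_CLASSES) + list(MITO_GENES) + \
        [f"DECOY{i + 1}" for i in range(spec.sc_n_decoys)]
    r = spec.sc_nb_dispersion
    base_ratio = 1.0
    blocks, obs_rows = [], []
    for pi in range(n_patients):
        pid = f"SC{pi:03d}"
        resp = response_labels[pi]
        ratio = base_ratio * (spec.sc_effect_size if resp == "responder" else 1.0)
        share = spec.sc_immune_share
        p_cd8 = share * ratio / (1 + ratio)
        p_m2 = share / (1 + ratio)
        p_m1 = 0.10
        p_other = 1.0 - p_cd8 - p_m2 - p_m1
        classes = rng.choice(SC_CLASSES, size=spec.cells_per_patient,
                             p=[p_cd8, p_m2, p_m1, p_other])
        low_q = rng.random(spec.cells_per_patient) < spec.sc_low_quality_rate
        hi_mito = (~low_q) & (rng.random(spec.cells_per_patient)
                              < spec.sc_high_mito_rate)
        lib_scale = np.where(low_q, 0.02, 1.0)

        counts = np.zeros((len(genes), spec.cells_per_patient), dtype=int)
        for gi, gene in enumerate(genes):
            if gene in SC_MARKER_CLASSES:
                mean = np.where(np.isin(classes, SC_MARKER_CLASSES[gene]),
                                spec.sc_marker_mean, 0.0)
            elif gene in MITO_GENES:
                mean = np.where(hi_mito, 100.0, 2.0)
            else:
                mean = np.full(spec.cells_per_patient, spec.sc_decoy_mean)
            mean = mean * lib_scale
            pos = mean > 0
            if pos.any():
                counts[gi, pos] = _nb_counts(rng, mean[pos], r, int(pos.sum()))
        blocks.append(counts)
        for k in range(spec.cells_per_patient):
            obs_rows.append({
                "cell": f"{pid}_c{k:04d}", "patient": pid, "response": resp,
                "true_class": classes[k], "low_quality": bool(low_q[k]),
                "high_mito": bool(hi_mito[k]),
            })
    values = pd.DataFrame(
        np.concatenate(blocks, axis=1), index=genes,
        columns=[r["cell"] for r in obs_rows],
    )
    obs = pd.DataFrame(obs_rows).set_index("cell")
    return ExpressionMatrix(values, obs, "linear")


def simulate_tile_grid(n_slides: int, tiles_per_slide,
                       heterogeneity: str = "homogeneous",
                       markers=("CD8", "CD68_CD163pp", "CD68_CD163mp",
                                "CD68_CD163pm"),
                       gradient_fold: float = 10.0,
                       mean_density: float = 100.0,
                       tile_area: float = 1.86 * 1.39,
                       rng: np.random.Generator | None = None,
                       seed: int = 0) -> pd.DataFrame:
    """Whole-slide tile grids with controllable spatial structure.

    ``tiles_per_slide`` is an int, a per-slide sequence, or the string
    ``"auto"`` which draws 13-93 tiles per slide (the realistic range
    for core-sized tiles on whole sections).  Homogeneous grids draw all
    tiles of a slide i.i.d. from one gamma density law per marker;
    gradient grids scale the mean linearly across the tile index by
    ``gradient_fold``.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    if heterogeneity not in ("homogeneous", "gradient"):
        raise ValueError(f"unknown heterogeneity {heterogeneity!r}")
    if isinstance(tiles_per_slide, str) and tiles_per_slide == "auto":
        sizes = rng.integers(13, 94, size=n_slides)
    elif np.isscalar(tiles_per_slide):
        sizes = np.full(n_slides, int(tiles_per_slide))
    else:
        sizes = np.asarray(tiles_per_slide, dtype=int)
        if len(sizes) != n_slides:
            raise ValueError("need one tile count per slide")
    if (sizes < 2).any():
        raise ValueError("every slide needs at least 2 tiles")

    shape = 4.0  # gamma shape: moderately overdispersed densities
    rows = []
    for si in range(n_slides):
        m = sizes[si]
        for mk in markers:
            if heterogeneity == "gradient":
                factor = np.linspace(1.0, gradient_fold, m)
            else:
                factor = np.ones(m)
            dens = rng.gamma(shape, scale=mean_density * factor / shape, size=m)
            for ti in range(m):
                rows.append((f"S{si}", f"S{si}_T{ti:03d}", tile_area, mk,
                             dens[ti]))
    df = pd.DataFrame(rows, columns=["slide_id", "tile_id", "area_mm2",
                                     "marker", "density"])
    wide = df.pivot_table(index=["slide_id", "tile_id", "area_mm2"],
                          columns="marker", values="density").reset_index()
    wide.columns.name = None
    return wide
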