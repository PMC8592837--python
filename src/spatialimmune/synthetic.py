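"""Synthetic cohort generator.

Emulates the data structure of a tissue-microarray immunoprofiling study of
clear cell renal cell carcinoma: one 2 mm core per patient split into an
intratumoral (IT) and a peritumoral (PT) region, per-cell coordinates in
pixels (0.22 um/px), an H&E-style lymphocyte flag, multiplex-IHC marker
intensities, a clinical table with overall survival, and a binary
patient x gene somatic-mutation table.

Ground truth (topography label per patient, class and marker positivity per
cell, survival coefficients, mutation odds ratios) is returned alongside the
tables so that downstream recovery tests can score the analysis pipeline.

Distributional choices
----------------------
* Per-region lymphocyte fractions are beta-distributed with
  topography-specific means (immune hot: high IT; cold: low everywhere;
  excluded: high PT, low IT).
* Cell positions follow either a homogeneous Poisson process or a
  Thomas-type parent/offspring cluster process mixed with a uniform
  background.
* Marker intensities are two-mode log-normal mixtures (negative / positive
  mode); truth positivity is Bernoulli with class-specific probabilities,
  optionally enriched for cells that sit inside spatial clusters.
* Survival times are exponential proportional-hazards draws with
  independent exponential censoring.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

REGIONS = ("IT", "PT")
TOPOGRAPHIES = ("hot", "cold", "excluded")
LYMPHOCYTE_CLASSES = ("Th", "Tc", "NK")
CELL_CLASSES = ("Th", "Tc", "NK", "CD16", "other")

DEFAULT_PIXEL_SIZE_UM = 0.22


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in pixel coordinates."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        x, y = xy[:, 0], xy[:, 1]
        return (
            (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)
        )

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        x = rng.uniform(self.xmin, self.xmax, size=n)
        y = rng.uniform(self.ymin, self.ymax, size=n)
        return np.column_stack([x, y])


@dataclass(frozen=True)
class SpatialProcess:
    """Point-process specification for one tissue region.

    ``kind="uniform"`` is a homogeneous Poisson process. ``kind="clustered"``
    superposes a uniform background (fraction ``background_fraction`` of the
    expected count) with a Thomas process: Poisson parents, Poisson(mean
    ``mean_offspring``) offspring per parent, isotropic Gaussian dispersion
    ``cluster_radius_px`` around each parent.
    """

    kind: str = "clustered"
    mean_offspring: float = 25.0
    cluster_radius_px: float = 30.0
    background_fraction: float = 0.5

    def validate(self) -> None:
        if self.kind not in ("uniform", "clustered"):
            raise ConfigurationError(f"spatial_process.kind: unknown kind {self.kind!r}")
        if self.kind == "clustered":
            if self.mean_offspring <= 0:
                raise ConfigurationError("spatial_process.mean_offspring must be > 0")
            if self.cluster_radius_px <= 0:
                raise ConfigurationError("spatial_process.cluster_radius_px must be > 0")
            if not 0.0 <= self.background_fraction <= 1.0:
                raise ConfigurationError(
                    "spatial_process.background_fraction must be in [0, 1]"
                )


@dataclass(frozen=True)
class IntensityMixture:
    """Two-mode log-normal intensity model (negative mode / positive mode)."""

    neg_log_mean: float = 0.0
    pos_log_mean: float = 2.3
    neg_log_sd: float = 0.35
    pos_log_sd: float = 0.35

    @property
    def midpoint(self) -> float:
        """Geometric midpoint between the two modes, in intensity units."""
        return float(np.exp(0.5 * (self.neg_log_mean + self.pos_log_mean)))

    def validate(self) -> None:
        if not self.pos_log_mean > self.neg_log_mean:
            raise ConfigurationError(
                "marker mixture: pos_log_mean must exceed neg_log_mean"
            )
        if self.neg_log_sd <= 0 or self.pos_log_sd <= 0:
            raise ConfigurationError("marker mixture: log-sds must be > 0")


@dataclass(frozen=True)
class MarkerSpec:
    """One marker of the mIHC panel.

    ``positivity`` maps cell class -> probability of true positivity; the
    ``"default"`` key applies to unlisted classes. ``clustered_enrichment``
    multiplies the positivity probability (capped at 1) for cells placed by
    the clustered component of the point process.
    """

    name: str
    positivity: Mapping[str, float]
    mixture: IntensityMixture = IntensityMixture()
    clustered_enrichment: float = 1.0

    def prob(self, cell_class: str) -> float:
        return float(self.positivity.get(cell_class, self.positivity.get("default", 0.0)))

    def validate(self) -> None:
        self.mixture.validate()
        for cls, p in self.positivity.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"marker_panel[{self.name}].positivity[{cls}] must be in [0, 1]"
                )
        if self.clustered_enrichment <= 0:
            raise ConfigurationError(
                f"marker_panel[{self.name}].clustered_enrichment must be > 0"
            )


@dataclass(frozen=True)
class GeneModel:
    """Per-gene mutation prevalence with per-topography odds ratios."""

    name: str
    prevalence: float
    topography_or: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError(
                f"mutation_model[{self.name}].prevalence must be in (0, 1)"
            )
        for topo, odds in self.topography_or.items():
            if odds <= 0:
                raise ConfigurationError(
                    f"mutation_model[{self.name}].topography_or[{topo}] must be > 0"
                )


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential proportional-hazards survival model.

    ``coefficients`` maps covariate names to log-hazard coefficients.
    Recognized names: topography indicators (``topo_hot``, ``topo_cold``,
    ``topo_excluded``), mutation indicators (``mut_<gene>``) and numeric
    clinical columns (``age_years``, ``tumor_stage``, ``fuhrman_grade``,
    ``n_metastatic_organs``, ``tumor_size``).
    """

    baseline_rate: float = float(np.log(2) / 1460.0)  # median OS ~4 years, per day
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: {"topo_excluded": float(np.log(0.2))}
    )
    censoring_rate: float = 0.3

    def validate(self) -> None:
        if self.baseline_rate <= 0:
            raise ConfigurationError("survival_model.baseline_rate must be > 0")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ConfigurationError("survival_model.censoring_rate must be in [0, 1]")


def default_marker_panel() -> tuple[MarkerSpec, ...]:
    """Default 13-marker panel: 5 lineage + 8 functional markers.

    Lineage positivity is deterministic given the true cell class so that
    class recovery through gating is limited only by intensity-mode overlap.
    CD45RO carries a 3x enrichment among spatially clustered cells, mirroring
    the association between cell-cell interaction and memory phenotype.
    """
    lineage = [
        MarkerSpec("CD3", {"Th": 1.0, "Tc": 1.0, "default": 0.0}),
        MarkerSpec("CD4", {"Th": 1.0, "default": 0.0}),
        MarkerSpec("CD8", {"Tc": 1.0, "default": 0.0}),
        MarkerSpec("CD2", {"NK": 1.0, "Th": 1.0, "Tc": 1.0, "default": 0.0}),
        MarkerSpec("CD16", {"CD16": 1.0, "default": 0.0}),
    ]
    functional = [
        MarkerSpec(
            "CD45RO",
            {"Th": 0.12, "Tc": 0.12, "NK": 0.05, "default": 0.01},
            clustered_enrichment=3.0,
        ),
        MarkerSpec("PD1", {"Tc": 0.25, "Th": 0.15, "NK": 0.08, "default": 0.01}),
        MarkerSpec("LAG3", {"Tc": 0.12, "Th": 0.08, "NK": 0.05, "default": 0.01}),
        MarkerSpec("TIM3", {"Tc": 0.10, "Th": 0.08, "NK": 0.06, "default": 0.01}),
        MarkerSpec("GrB", {"Tc": 0.30, "NK": 0.35, "default": 0.02}),
        MarkerSpec("CD57", {"NK": 0.25, "Tc": 0.10, "default": 0.02}),
        MarkerSpec("OX40", {"Th": 0.12, "Tc": 0.08, "NK": 0.04, "default": 0.01}),
        MarkerSpec("PDL1", {"CD16": 0.20, "other": 0.08, "default": 0.05}),
    ]
    return tuple(lineage + functional)


def default_mutation_model() -> tuple[GeneModel, ...]:
    """Genes mutated in >=5% of patients, with topography-linked odds ratios."""
    return (
        GeneModel("VHL", 0.62, {"excluded": 0.35}),
        GeneModel("PBRM1", 0.43, {"cold": 2.5}),
        GeneModel("SETD2", 0.15, {}),
        GeneModel("BAP1", 0.10, {"excluded": 2.0, "hot": 0.4}),
        GeneModel("STAG2", 0.08, {"hot": 5.0}),
    )


def _default_geometry() -> dict[str, Rect]:
    # IT and PT are disjoint halves of a core-sized field; CTRL its own field.
    return {
        "IT": Rect(0.0, 1800.0, 0.0, 1800.0),
        "PT": Rect(2000.0, 3400.0, 0.0, 1800.0),
        "CTRL": Rect(0.0, 1800.0, 0.0, 1800.0),
    }


def _default_lymph_params() -> dict[tuple[str, str], tuple[float, float]]:
    # (mean, concentration) of the beta lymphocyte fraction per topography x region
    return {
        ("hot", "IT"): (0.25, 120.0),
        ("hot", "PT"): (0.15, 120.0),
        ("cold", "IT"): (0.03, 120.0),
        ("cold", "PT"): (0.05, 120.0),
        ("excluded", "IT"): (0.04, 120.0),
        ("excluded", "PT"): (0.20, 120.0),
        ("control", "CTRL"): (0.02, 120.0),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort. Defaults mirror the study
    design: 64 patients, topography weights equal to the observed cluster
    sizes 14/38/12, one core per patient with IT and PT regions."""

    n_patients: int = 64
    n_controls: int = 0
    cores_per_patient: int = 1
    topography_weights: tuple[float, float, float] = (14 / 64, 38 / 64, 12 / 64)
    region_geometry: Mapping[str, Rect] = field(default_factory=_default_geometry)
    cell_density: Mapping[str, float] = field(
        default_factory=lambda: {"IT": 2600.0, "PT": 1700.0, "CTRL": 1500.0}
    )
    lymph_fraction_params: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=_default_lymph_params
    )
    lymph_composition: tuple[float, float, float] = (0.40, 0.35, 0.25)  # Th, Tc, NK
    myeloid_fraction: float = 0.06
    spatial_process: SpatialProcess = SpatialProcess()
    marker_panel: tuple[MarkerSpec, ...] = field(default_factory=default_marker_panel)
    mutation_model: tuple[GeneModel, ...] = field(default_factory=default_mutation_model)
    survival_model: SurvivalModel = SurvivalModel()
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0

    def replace(self, **kwargs) -> "CohortConfig":
        return dataclasses.replace(self, **kwargs)


def validate_config(config: CohortConfig) -> None:
    """Raise :class:`ConfigurationError` naming the first invalid field."""
    w = np.asarray(config.topography_weights, dtype=float)
    if w.shape != (3,):
        raise ConfigurationError("topography_weights must have three entries")
    if np.any(w < 0):
        raise ConfigurationError("topography_weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ConfigurationError("topography_weights must sum to 1 (within 1e-9)")
    if config.n_patients < 0 or config.n_controls < 0:
        raise ConfigurationError("n_patients and n_controls must be nonnegative")
    if config.cores_per_patient < 1:
        raise ConfigurationError("cores_per_patient must be >= 1")
    for region, density in config.cell_density.items():
        if density <= 0:
            raise ConfigurationError(f"cell_density[{region}] must be > 0")
    for region, rect in config.region_geometry.items():
        if rect.area <= 0:
            raise ConfigurationError(f"region_geometry[{region}] has non-positive area")
    it, pt = config.region_geometry["IT"], config.region_geometry["PT"]
    if not (
        it.xmax <= pt.xmin or pt.xmax <= it.xmin or it.ymax <= pt.ymin or pt.ymax <= it.ymin
    ):
        raise ConfigurationError("region_geometry: IT and PT rectangles must be disjoint")
    for key, (mean, conc) in config.lymph_fraction_params.items():
        if not 0.0 < mean < 1.0:
            raise ConfigurationError(f"lymph_fraction_params[{key}] mean must be in (0, 1)")
        if conc <= 0:
            raise ConfigurationError(
                f"lymph_fraction_params[{key}] concentration must be > 0"
            )
    comp = np.asarray(config.lymph_composition, dtype=float)
    if np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
        raise ConfigurationError("lymph_composition must be nonnegative and sum to 1")
    if not 0.0 <= config.myeloid_fraction <= 1.0:
        raise ConfigurationError("myeloid_fraction must be in [0, 1]")
    if config.pixel_size_um <= 0:
        raise ConfigurationError("pixel_size_um must be > 0")
    config.spatial_process.validate()
    for marker in config.marker_panel:
        marker.validate()
    for gene in config.mutation_model:
        gene.validate()
    config.survival_model.validate()


@dataclass
class CohortTruth:
    """Generator ground truth for recovery tests."""

    patients: pd.DataFrame  # patient_id, topography, <region>_frac_true, linear_predictor
    cells: pd.DataFrame  # cell_id, true_class, in_cluster, pos_<marker>...
    survival_coefficients: dict[str, float]
    mutation_model: tuple[GeneModel, ...]


def sample_point_pattern(
    n_expected: float,
    geometry: Rect,
    process: SpatialProcess,
    rng: np.random.Generator,
    return_labels: bool = False,
):
    """Sample a planar point pattern inside ``geometry``.

    Returns an ``(n, 2)`` coordinate array; with ``return_labels=True`` also a
    boolean array marking points placed by the clustered component.
    """
    if geometry.area <= 0:
        raise ValidationError("sample_point_pattern: geometry has non-positive area")
    if n_expected < 0:
        raise ValidationError("sample_point_pattern: n_expected must be >= 0")
    process.validate()
    if n_expected == 0:
        coords = np.empty((0, 2))
        labels = np.empty(0, dtype=bool)
        return (coords, labels) if return_labels else coords

    if process.kind == "uniform":
        n = rng.poisson(n_expected)
        coords = geometry.sample_uniform(n, rng)
        labels = np.zeros(n, dtype=bool)
    else:
        n_bg = rng.poisson(n_expected * process.background_fraction)
        bg = geometry.sample_uniform(n_bg, rng)
        n_clustered_expected = n_expected * (1.0 - process.background_fraction)
        n_parents = rng.poisson(n_clustered_expected / process.mean_offspring)
        parents = geometry.sample_uniform(n_parents, rng)
        offspring_counts = rng.poisson(process.mean_offspring, size=n_parents)
        centers = np.repeat(parents, offspring_counts, axis=0)
        jitter = rng.normal(0.0, process.cluster_radius_px, size=centers.shape)
        clustered = centers + jitter
        clustered[:, 0] = np.clip(clustered[:, 0], geometry.xmin, geometry.xmax)
        clustered[:, 1] = np.clip(clustered[:, 1], geometry.ymin, geometry.ymax)
        coords = np.vstack([bg, clustered])
        labels = np.concatenate(
            [np.zeros(len(bg), dtype=bool), np.ones(len(clustered), dtype=bool)]
        )
    return (coords, labels) if return_labels else coords


def sample_marker_intensities(
    true_positivity: np.ndarray,
    mixture: IntensityMixture,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw strictly positive intensities: positives from the high log-normal
    mode, negatives from the low mode."""
    mixture.validate()
    pos = np.asarray(true_positivity, dtype=bool)
    log_mean = np.where(pos, mixture.pos_log_mean, mixture.neg_log_mean)
    log_sd = np.where(pos, mixture.pos_log_sd, mixture.neg_log_sd)
    return np.exp(rng.normal(log_mean, log_sd))


def sample_survival(
    covariates: np.ndarray,
    coefficients: np.ndarray,
    baseline_rate: float,
    censoring_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential proportional-hazards survival with independent censoring.

    Hazard for subject i is ``baseline_rate * exp(x_i . beta)``. Censoring
    times are exponential with rate chosen so the expected censored fraction
    under the baseline hazard equals ``censoring_rate``; ``censoring_rate=1``
    censors everyone, ``0`` no one.
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    beta = np.asarray(coefficients, dtype=float)
    if X.shape[1] != beta.shape[0]:
        raise ValidationError(
            f"sample_survival: covariates have {X.shape[1]} columns but "
            f"{beta.shape[0]} coefficients were given"
        )
    if baseline_rate <= 0:
        raise ValidationError("sample_survival: baseline_rate must be > 0")
    if not 0.0 <= censoring_rate <= 1.0:
        raise ValidationError("sample_survival: censoring_rate must be in [0, 1]")
    lp = X @ beta
    event_times = rng.exponential(1.0 / (baseline_rate * np.exp(lp)))
    if censoring_rate >= 1.0:
        times = event_times * rng.uniform(0.05, 0.95, size=len(event_times))
        return times, np.zeros(len(times), dtype=int)
    if censoring_rate <= 0.0:
        return event_times, np.ones(len(event_times), dtype=int)
    cens_rate = baseline_rate * censoring_rate / (1.0 - censoring_rate)
    cens_times = rng.exponential(1.0 / cens_rate, size=len(event_times))
    times = np.minimum(event_times, cens_times)
    events = (event_times <= cens_times).astype(int)
    return times, events


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # Hierarchical stream: patient i's draws do not depend on cohort size.
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


_CLINICAL_STAGE_P = (0.125, 0.141, 0.250, 0.484)
_CLINICAL_GRADE_P = (0.063, 0.381, 0.460, 0.096)


def _sample_clinical(label: str, rng: np.random.Generator) -> dict:
    age = float(np.clip(rng.normal(64.9, 9.0), 41.0, 84.0))
    stage = int(rng.choice(4, p=_CLINICAL_STAGE_P)) + 1
    grade = int(rng.choice(4, p=_CLINICAL_GRADE_P)) + 1
    # excluded tumors metastasize less and never fall in the poor MSKCC class
    n_met = int(rng.poisson(0.5 if label == "excluded" else 1.3))
    if label == "excluded":
        mskcc = str(rng.choice(["low", "intermediate"], p=[0.4, 0.6]))
    else:
        mskcc = str(rng.choice(["low", "intermediate", "high"], p=[0.20, 0.67, 0.13]))
    tumor_size = float(np.exp(rng.normal(np.log(60.0), 0.4)))  # mm
    necrosis = int(rng.random() < 0.3)
    return {
        "age_years": age,
        "tumor_stage": stage,
        "fuhrman_grade": grade,
        "n_metastatic_organs": n_met,
        "mskcc_class": mskcc,
        "tumor_size": tumor_size,
        "necrosis": necrosis,
    }


def _survival_feature(name: str, label: str, clinical: dict, mutations: dict) -> float:
    if name.startswith("topo_"):
        return float(label == name[len("topo_"):])
    if name.startswith("mut_"):
        gene = name[len("mut_"):]
        if gene not in mutations:
            raise ConfigurationError(f"survival_model.coefficients: unknown gene {gene!r}")
        return float(mutations[gene])
    if name in clinical and isinstance(clinical[name], (int, float)):
        return float(clinical[name])
    raise ConfigurationError(f"survival_model.coefficients: unknown covariate {name!r}")


def _generate_region_cells(
    patient_id: str,
    core_id: str,
    region: str,
    label: str,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Cells for one core x region; returns (cells, cell truth, true fraction)."""
    geometry = config.region_geometry[region]
    coords, in_cluster = sample_point_pattern(
        config.cell_density[region], geometry, config.spatial_process, rng,
        return_labels=True,
    )
    n = len(coords)
    key = ("control" if label == "control" else label, region)
    mean, conc = config.lymph_fraction_params[key]
    frac = rng.beta(mean * conc, (1.0 - mean) * conc)
    is_lymph = rng.random(n) < frac
    classes = np.full(n, "other", dtype=object)
    n_lymph = int(is_lymph.sum())
    classes[is_lymph] = rng.choice(
        LYMPHOCYTE_CLASSES, size=n_lymph, p=config.lymph_composition
    )
    non_lymph = ~is_lymph
    classes[non_lymph & (rng.random(n) < config.myeloid_fraction)] = "CD16"

    marker_pos: dict[str, np.ndarray] = {}
    marker_int: dict[str, np.ndarray] = {}
    for marker in config.marker_panel:
        p = np.array([marker.prob(c) for c in classes])
        if marker.clustered_enrichment != 1.0:
            p = np.where(
                in_cluster, np.minimum(1.0, p * marker.clustered_enrichment), p
            )
        pos = rng.random(n) < p
        marker_pos[marker.name] = pos
        marker_int[marker.name] = sample_marker_intensities(pos, marker.mixture, rng)

    cell_ids = np.array([f"{core_id}-{region}-{k:05d}" for k in range(n)], dtype=object)
    cell_cols = {
        "cell_id": cell_ids,
        "patient_id": np.repeat(patient_id, n),
        "core_id": np.repeat(core_id, n),
        "region": np.repeat(region, n),
        "x_px": coords[:, 0],
        "y_px": coords[:, 1],
        "is_lymphocyte": is_lymph.astype(int),
    }
    truth_cols = {
        "cell_id": cell_ids,
        "true_class": classes,
        "in_cluster": in_cluster,
    }
    for marker in config.marker_panel:
        cell_cols[marker.name] = marker_int[marker.name]
        truth_cols[f"pos_{marker.name}"] = marker_pos[marker.name]
    return pd.DataFrame(cell_cols), pd.DataFrame(truth_cols), float(frac)


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Generate (cell table, clinical table, mutation table, truth).

    Deterministic given ``config`` (including its seed): each patient consumes
    an independent child stream of the cohort seed, so adding patients leaves
    earlier patients' draws unchanged.
    """
    validate_config(config)
    all_cells: list[pd.DataFrame] = []
    all_cell_truth: list[pd.DataFrame] = []
    clinical_rows: list[dict] = []
    mutation_rows: list[dict] = []
    patient_truth_rows: list[dict] = []

    coef_names = list(config.survival_model.coefficients.keys())
    beta = np.array([config.survival_model.coefficients[k] for k in coef_names])

    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        patient_id = f"P{i + 1:03d}"
        label = TOPOGRAPHIES[
            rng.choice(3, p=np.asarray(config.topography_weights, dtype=float))
        ]
        truth_row: dict = {"patient_id": patient_id, "topography": label}
        for j in range(config.cores_per_patient):
            core_id = f"{patient_id}-c{j + 1}"
            for region in REGIONS:
                cells, cell_truth, frac = _generate_region_cells(
                    patient_id, core_id, region, label, config, rng
                )
                all_cells.append(cells)
                all_cell_truth.append(cell_truth)
                truth_row.setdefault(f"{region.lower()}_frac_true", frac)
        clinical = _sample_clinical(label, rng)
        mutations = {}
        for gene in config.mutation_model:
            logit = np.log(gene.prevalence / (1.0 - gene.prevalence))
            logit += np.log(gene.topography_or.get(label, 1.0))
            mutations[gene.name] = int(rng.random() < _sigmoid(logit))
        x = np.array(
            [
                _survival_feature(name, label, clinical, mutations)
                for name in coef_names
            ]
        )
        times, events = sample_survival(
            x.reshape(1, -1),
            beta,
            config.survival_model.baseline_rate,
            config.survival_model.censoring_rate,
            rng,
        )
        clinical_rows.append(
            {
                "patient_id": patient_id,
                "os_time": float(times[0]),
                "os_event": int(events[0]),
                **clinical,
            }
        )
        mutation_rows.append({"patient_id": patient_id, **mutations})
        truth_row["linear_predictor"] = float(x @ beta)
        patient_truth_rows.append(truth_row)

    for i in range(config.n_controls):
        rng = _patient_rng(config.seed, config.n_patients + i)
        patient_id = f"CTRL{i + 1:02d}"
        for j in range(config.cores_per_patient):
            core_id = f"{patient_id}-c{j + 1}"
            cells, cell_truth, frac = _generate_region_cells(
                patient_id, core_id, "CTRL", "control", config, rng
            )
            all_cells.append(cells)
            all_cell_truth.append(cell_truth)
        patient_truth_rows.append(
            {"patient_id": patient_id, "topography": "control", "ctrl_frac_true": frac}
        )

    cell_table = (
        pd.concat(all_cells, ignore_index=True) if all_cells else pd.DataFrame()
    )
    clinical_table = pd.DataFrame(clinical_rows)
    mutation_table = pd.DataFrame(mutation_rows)
    truth = CohortTruth(
        patients=pd.DataFrame(patient_truth_rows),
        cells=(
            pd.concat(all_cell_truth, ignore_index=True)
            if all_cell_truth
            else pd.DataFrame()
        ),
        survival_coefficients=dict(config.survival_model.coefficients),
        mutation_model=config.mutation_model,
    )
    return cell_table, clinical_table, mutation_table, truth
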