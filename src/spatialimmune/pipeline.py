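"""End-to-end pipeline: filter -> topography -> phenotyping -> interaction
-> statistics, with CSV outputs and a provenance sidecar.

Configured through a YAML/dict with either a ``simulate`` section (synthetic
cohort overrides) or an ``inputs`` section naming CSV paths. Stage failures
abort with an error naming the stage; outputs written before the failure are
preserved.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from . import synthetic
from .errors import PipelineStageError
from .interactions import InteractionConfig, interaction_matrix, interaction_phenotype_fc
from .phenotyping import (
    classify_cell_types,
    contexture_medians,
    correlate_it_pt,
    gate_cells,
    normalize_for_heatmap,
    build_phenotype_matrix,
)
from .stats import group_fc_panel, survival_screen
from .topography import (
    assign_topographies,
    mutation_topography_association,
    proportions_wide,
    region_lymphocyte_proportion,
    topography_summary,
)

__version__ = "0.1.0"


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def load_config(source) -> dict:
    if isinstance(source, dict):
        return dict(source)
    text = Path(source).read_text()
    return yaml.safe_load(text) or {}


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@_stage("load")
def _load_inputs(config: dict):
    if "simulate" in config:
        overrides = dict(config.get("simulate") or {})
        overrides.setdefault("seed", int(config.get("seed", 0)))
        cohort_cfg = synthetic.CohortConfig(**overrides)
        cells, clinical, mutations, truth = synthetic.generate_cohort(cohort_cfg)
        return cells, clinical, mutations, "mihc" if cohort_cfg.marker_panel else "hne"
    inputs = config.get("inputs")
    if not inputs or "cells" not in inputs:
        raise PipelineStageError(
            "stage 'load' failed: config needs a 'simulate' or 'inputs.cells' entry"
        )
    flavor = inputs.get("flavor", "hne")
    cells = cio.read_cell_table(inputs["cells"], flavor=flavor)
    clinical = (
        cio.read_clinical_table(inputs["clinical"]) if "clinical" in inputs else None
    )
    mutations = (
        cio.read_mutation_table(inputs["mutations"]) if "mutations" in inputs else None
    )
    return cells, clinical, mutations, flavor


def run_pipeline(config_source, out_dir) -> Path:
    """Execute the full analysis and write tables + provenance to ``out_dir``.

    Deterministic: rerunning with the same config and seed reproduces
    byte-identical result CSVs.
    """
    config = load_config(config_source)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": int(config.get("seed", 0)),
        "version": __version__,
        "outputs": [],
    }

    cells, clinical, mutations, flavor = _load_inputs(config)

    def save(df: pd.DataFrame, name: str, index=False):
        path = out / name
        df.to_csv(path, index=index, float_format="%.10g")
        provenance["outputs"].append(name)

    # --- core filter -----------------------------------------------------
    min_cells = int(config.get("min_cells_per_core", 1500))
    cells, dropped = _filter(cells, min_cells)
    provenance["dropped_cores"] = [str(c) for c in dropped]
    save(cells[["cell_id", "patient_id", "core_id", "region"]].head(0),
         "cells_schema.csv")

    # --- topography -------------------------------------------------------
    topo, summary = _topography(cells, flavor)
    save(topo, "topography.csv")
    save(summary, "topography_summary.csv")

    if mutations is not None and len(mutations.columns) > 1:
        target = str(config.get("mutation_target_class", "cold"))
        assoc = _mutation(topo, mutations, target)
        save(assoc, "mutation_association.csv")

    if flavor == "mihc":
        matrix, normalized, corr, interactions, fc = _mihc_stages(cells, config)
        save(matrix, "phenotype_matrix.csv", index=True)
        save(normalized, "phenotype_matrix_normalized.csv", index=True)
        save(contexture_medians(matrix), "contexture_medians.csv", index=True)
        save(corr, "it_pt_correlation.csv")
        save(interactions, "interactions.csv")
        save(fc, "interaction_fc.csv")

        if clinical is not None:
            surv = _survival(matrix, topo, clinical)
            save(surv, "survival_screen.csv")
            panel = _fc_panel(matrix, topo)
            if panel is not None:
                save(panel, "topography_fc_panel.csv")

    cio.write_provenance(out / "provenance.json", provenance)
    return out


@_stage("filter")
def _filter(cells, min_cells):
    return cio.filter_low_cellularity(cells, min_cells=min_cells)


@_stage("topography")
def _topography(cells, flavor):
    if "is_lymphocyte" not in cells.columns:
        raise ValueError("cell table lacks is_lymphocyte; cannot assign topographies")
    tumor_cells = cells.loc[cells["region"].isin(["IT", "PT"])]
    props = region_lymphocyte_proportion(tumor_cells)
    wide = proportions_wide(props)
    topo = assign_topographies(wide)
    return topo, topography_summary(topo["label"])


@_stage("mutation_association")
def _mutation(topo, mutations, target):
    return mutation_topography_association(topo, mutations, target_class=target)


@_stage("phenotyping_and_interaction")
def _mihc_stages(cells, config):
    tumor = cells.loc[cells["region"].isin(["IT", "PT", "CTRL"])].reset_index(drop=True)
    positivity = gate_cells(tumor)
    classes = classify_cell_types(positivity)
    matrix = build_phenotype_matrix(tumor, classes, positivity)
    normalized = normalize_for_heatmap(matrix)
    corr, _ = correlate_it_pt(matrix)
    icfg = InteractionConfig(
        threshold_px=float(config.get("interaction_threshold_px", 100.0))
    )
    interactions = interaction_matrix(tumor, classes, icfg)
    fc_markers = [m for m in ("CD45RO", "PD1", "TIM3") if m in positivity.columns]
    fc = interaction_phenotype_fc(
        tumor, classes, positivity, pairs=[("T", "NK"), ("Th", "Tc")],
        markers=fc_markers, config=icfg,
    )
    return matrix, normalized, corr, interactions, fc


@_stage("survival")
def _survival(matrix, topo, clinical):
    it = matrix.xs("IT", level="region")
    feats = it.copy()
    feats.columns = [f"IT {c}" for c in feats.columns]
    labels = topo.set_index("patient_id")["label"].reindex(feats.index)
    feats["excluded topography"] = (labels == "excluded").astype(float)
    return survival_screen(feats, clinical)


@_stage("fc_panel")
def _fc_panel(matrix, topo):
    it = matrix.xs("IT", level="region")
    labels = topo.set_index("patient_id")["label"].reindex(it.index)
    if labels.nunique() < 2:
        return None
    return group_fc_panel(it, labels)
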