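"""Cell-cell spatial interaction analysis.

Two cells *interact* when their Euclidean distance is at most 100 pixels
(22 um at 0.22 um/px). For cell types *a* (m cells) and *b* (n cells) in a
sample with *c* cells in total, the interaction frequency

    i_ab = sum_{j in a} sum_{k in b} 1[d(a_j, b_k) <= threshold]

counts interacting pairs (pairs formed by the same physical cell appearing
under both type labels are excluded by cell id; same-type pairs are
unordered with self-pairs excluded), and the sample-level interaction index

    I_ab = i_ab * c / sqrt(m * n)

normalizes the count by the geometric-mean pair proportion sqrt(mn)/c, so
that samples rich in the examined pair are not trivially favored. An
alternative normalization sqrt(m+n)/c sits behind ``index_variant="sum"``.

Pair counting uses a KD-tree and is exactly equivalent to the O(mn) double
loop. Interactions are never computed across region or core boundaries.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import cKDTree

from .errors import ValidationError
from .stats import adjust_bh

DEFAULT_TYPES = ("T", "Th", "Tc", "NK", "CD16")


@dataclass(frozen=True)
class InteractionConfig:
    threshold_px: float = 100.0
    pixel_size_um: float = 0.22
    types: tuple[str, ...] = DEFAULT_TYPES
    index_variant: str = "geometric"  # or "sum"

    @property
    def threshold_um(self) -> float:
        return self.threshold_px * self.pixel_size_um

    def validate(self) -> None:
        if self.threshold_px <= 0:
            raise ValidationError("threshold_px must be positive")
        if self.index_variant not in ("geometric", "sum"):
            raise ValidationError("index_variant must be 'geometric' or 'sum'")


def pair_distance(cell_a, cell_b) -> float:
    """Euclidean distance in pixels between two (x, y) points."""
    a = np.asarray(cell_a, dtype=float)
    b = np.asarray(cell_b, dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("pair_distance: non-finite coordinate")
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def is_interacting(distance: float, threshold: float = 100.0) -> int:
    """1 iff ``distance <= threshold`` (boundary inclusive)."""
    if distance < 0:
        raise ValidationError("is_interacting: distance must be >= 0")
    return int(distance <= threshold)


def _check_single_region(*frames: pd.DataFrame) -> None:
    regions = set()
    for f in frames:
        if "region" in f.columns:
            regions.update(f["region"].unique())
    if len(regions) > 1:
        raise ValidationError(
            f"interaction inputs span multiple regions: {sorted(regions)}"
        )


def interaction_frequency(
    cells_a: pd.DataFrame,
    cells_b: pd.DataFrame,
    config: InteractionConfig = InteractionConfig(),
) -> int:
    """Interacting-pair count i_ab for two cell subsets of one sample.

    Cross-type: every (j, k) combination with distance <= threshold counts,
    except combinations where j and k are the same physical cell (same
    ``cell_id``). Same-type (identical id sets): unordered distinct pairs.
    """
    config.validate()
    _check_single_region(cells_a, cells_b)
    r = config.threshold_px
    ids_a = cells_a["cell_id"].to_numpy()
    ids_b = cells_b["cell_id"].to_numpy()
    xy_a = cells_a[["x_px", "y_px"]].to_numpy(dtype=float)
    xy_b = cells_b[["x_px", "y_px"]].to_numpy(dtype=float)
    if len(ids_a) == 0 or len(ids_b) == 0:
        return 0
    same = len(ids_a) == len(ids_b) and set(ids_a) == set(ids_b)
    if same:
        tree = cKDTree(xy_a)
        return int(len(tree.query_pairs(r)))
    total = int(cKDTree(xy_a).count_neighbors(cKDTree(xy_b), r))
    shared = len(set(ids_a) & set(ids_b))
    return total - shared


def interaction_index(
    i_ab: float, m: int, n: int, c: int, variant: str = "geometric"
) -> float:
    """Normalized interaction index I_ab; NaN (logged) when m or n is 0."""
    if m == 0 or n == 0:
        warnings.warn("interaction_index: empty cell type; index undefined",
                      stacklevel=2)
        return float("nan")
    if c < max(m, n):
        raise ValidationError("interaction_index: total cell count c < max(m, n)")
    if variant == "geometric":
        return float(i_ab * c / np.sqrt(m * n))
    if variant == "sum":
        return float(i_ab * c / np.sqrt(m + n))
    raise ValidationError("variant must be 'geometric' or 'sum'")


def _type_pairs(types: Sequence[str]) -> list[tuple[str, str]]:
    return list(itertools.combinations_with_replacement(types, 2))


def interaction_matrix(
    cells: pd.DataFrame,
    classes: pd.DataFrame,
    config: InteractionConfig = InteractionConfig(),
) -> pd.DataFrame:
    """Interaction records for every patient x region x type pair.

    Pair counts are computed per core (cells never pair across cores or
    regions); multi-core patients are aggregated by summing i_ab, m, n and c
    across cores before computing I_ab. One record per unordered type pair
    (the index is symmetric in its types).
    """
    config.validate()
    missing = [t for t in config.types if t not in classes.columns]
    if missing:
        raise ValidationError(f"interaction_matrix: unknown cell type(s) {missing}")
    pairs = _type_pairs(config.types)
    acc: dict[tuple, dict] = {}
    for (patient, region, core), idx in cells.groupby(
        ["patient_id", "region", "core_id"]
    ).groups.items():
        sub = cells.loc[idx]
        sub_cls = classes.loc[idx]
        c_total = len(sub)
        for a, b in pairs:
            ca = sub.loc[sub_cls[a].to_numpy(dtype=bool)]
            cb = sub.loc[sub_cls[b].to_numpy(dtype=bool)]
            i_ab = interaction_frequency(ca, cb, config)
            key = (patient, region, a, b)
            rec = acc.setdefault(
                key, {"i_ab": 0, "m": 0, "n": 0, "c": 0}
            )
            rec["i_ab"] += i_ab
            rec["m"] += len(ca)
            rec["n"] += len(cb)
            rec["c"] += c_total
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty types yield NaN silently here
        for (patient, region, a, b), rec in acc.items():
            index = interaction_index(
                rec["i_ab"], rec["m"], rec["n"], rec["c"], config.index_variant
            )
            rows.append(
                {
                    "patient_id": patient,
                    "region": region,
                    "type_a": a,
                    "type_b": b,
                    "i_ab": rec["i_ab"],
                    "m": rec["m"],
                    "n": rec["n"],
                    "c": rec["c"],
                    "I_ab": index,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "region", "type_a", "type_b", "i_ab", "m", "n", "c",
                 "I_ab"],
    )


def flag_interacting_cells(
    cells: pd.DataFrame,
    classes: pd.DataFrame,
    focal_type: str,
    partner_type: str,
    config: InteractionConfig = InteractionConfig(),
) -> pd.Series:
    """Per focal-type cell: True iff a *distinct* partner-type cell lies
    within the threshold in the same patient x core x region."""
    config.validate()
    for t in (focal_type, partner_type):
        if t not in classes.columns:
            raise ValidationError(f"flag_interacting_cells: unknown type {t!r}")
    flags = {}
    r = config.threshold_px
    for _, idx in cells.groupby(["patient_id", "region", "core_id"]).groups.items():
        sub = cells.loc[idx]
        sub_cls = classes.loc[idx]
        focal = sub.loc[sub_cls[focal_type].to_numpy(dtype=bool)]
        partner = sub.loc[sub_cls[partner_type].to_numpy(dtype=bool)]
        if len(focal) == 0:
            continue
        if len(partner) == 0:
            for cid in focal["cell_id"]:
                flags[cid] = False
            continue
        tree = cKDTree(partner[["x_px", "y_px"]].to_numpy(dtype=float))
        counts = tree.query_ball_point(
            focal[["x_px", "y_px"]].to_numpy(dtype=float), r, return_length=True
        )
        partner_ids = set(partner["cell_id"])
        self_hits = focal["cell_id"].isin(partner_ids).to_numpy()
        has_partner = counts - self_hits.astype(int) > 0
        for cid, f in zip(focal["cell_id"], has_partner):
            flags[cid] = bool(f)
    return pd.Series(flags, name=f"interacts_{focal_type}_{partner_type}", dtype=bool)


def interaction_phenotype_fc(
    cells: pd.DataFrame,
    classes: pd.DataFrame,
    positivity: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    markers: Sequence[str],
    config: InteractionConfig = InteractionConfig(),
    min_cells: int = 10,
) -> pd.DataFrame:
    """Fold-change of marker positivity between interacting and
    non-interacting focal cells.

    For each region, type pair (focal, partner) and marker: per patient,
    ``p_int`` / ``p_non`` are the marker-positive proportions among
    interacting / non-interacting focal cells (patients contribute only when
    both groups hold at least ``min_cells`` cells). The fold-change is
    ``log10(median(p_int) / median(p_non))`` across patients; the p-value a
    two-sided Wilcoxon signed-rank test of the paired per-patient
    proportions, BH-adjusted across the panel.
    """
    pos_by_cell = positivity.set_axis(cells["cell_id"], axis=0)
    cls_by_cell = classes.set_axis(cells["cell_id"], axis=0)
    patient_of = cells.set_index("cell_id")["patient_id"]
    rows = []
    for region in sorted(cells["region"].unique()):
        region_cells = cells.loc[cells["region"] == region]
        region_classes = classes.loc[region_cells.index]
        for focal, partner in pairs:
            flags = flag_interacting_cells(
                region_cells, region_classes, focal, partner, config
            )
            if flags.empty:
                continue
            for marker in markers:
                if marker not in positivity.columns:
                    raise ValidationError(f"unknown marker {marker!r}")
                p_int, p_non = [], []
                focal_ids = flags.index
                df = pd.DataFrame(
                    {
                        "patient": patient_of.loc[focal_ids],
                        "flag": flags,
                        "pos": pos_by_cell.loc[focal_ids, marker].to_numpy(dtype=bool),
                    }
                )
                for _, grp in df.groupby("patient"):
                    g_int = grp.loc[grp["flag"], "pos"]
                    g_non = grp.loc[~grp["flag"], "pos"]
                    if len(g_int) < min_cells or len(g_non) < min_cells:
                        continue
                    p_int.append(g_int.mean())
                    p_non.append(g_non.mean())
                n_pat = len(p_int)
                if n_pat < 3:
                    rows.append(
                        {"region": region, "type_a": focal, "type_b": partner,
                         "marker": marker, "fc_log10": float("nan"),
                         "p_value": float("nan"), "n_patients": n_pat}
                    )
                    continue
                med_i = float(np.median(p_int))
                med_n = float(np.median(p_non))
                fc = (
                    float(np.log10(med_i / med_n))
                    if med_i > 0 and med_n > 0
                    else float("nan")
                )
                diffs = np.asarray(p_int) - np.asarray(p_non)
                if np.allclose(diffs, 0):
                    p = 1.0
                else:
                    _, p = sps.wilcoxon(p_int, p_non, alternative="two-sided")
                rows.append(
                    {"region": region, "type_a": focal, "type_b": partner,
                     "marker": marker, "fc_log10": fc, "p_value": float(p),
                     "n_patients": n_pat}
                )
    out = pd.DataFrame(
        rows, columns=["region", "type_a", "type_b", "marker", "fc_log10",
                       "p_value", "n_patients"],
    )
    valid = out["p_value"].notna()
    out["q_value"] = np.nan
    if valid.any():
        out.loc[valid, "q_value"] = adjust_bh(out.loc[valid, "p_value"].to_numpy())
    return out


def digital_stain(
    cells: pd.DataFrame,
    classes: pd.DataFrame,
    positivity: pd.DataFrame,
    phenotype,
    out_path,
) -> dict:
    """Digital staining: scatter cell positions, phenotype-positive cells
    highlighted, one facet per region. Returns figure metadata including the
    per-facet point counts; styling is deterministic."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .phenotyping import Phenotype

    if not isinstance(phenotype, Phenotype):
        raise ValidationError("digital_stain expects a Phenotype")
    n = len(cells)
    mask = np.ones(n, dtype=bool)
    if phenotype.cls is not None:
        if phenotype.cls not in classes.columns:
            raise ValidationError(f"unknown phenotype class {phenotype.cls!r}")
        mask &= classes[phenotype.cls].to_numpy(dtype=bool)
    for m in phenotype.markers:
        if m not in positivity.columns:
            raise ValidationError(f"unknown phenotype marker {m!r}")
        mask &= positivity[m].to_numpy(dtype=bool)

    regions = sorted(cells["region"].unique()) or ["IT"]
    fig, axes = plt.subplots(
        1, len(regions), figsize=(4 * len(regions), 4), squeeze=False
    )
    meta = {"phenotype": phenotype.name, "path": str(out_path), "facets": {}}
    for ax, region in zip(axes[0], regions):
        sel = (cells["region"] == region).to_numpy()
        bg = cells.loc[sel & ~mask]
        fg = cells.loc[sel & mask]
        ax.scatter(bg["x_px"], bg["y_px"], s=2, c="#bbbbbb", linewidths=0)
        ax.scatter(fg["x_px"], fg["y_px"], s=6, c="#c62828", linewidths=0)
        ax.set_title(f"{region} ({phenotype.name})")
        ax.set_aspect("equal")
        ax.set_xticks([])
        ax.set_yticks([])
        meta["facets"][region] = {"n_points": int(sel.sum()),
                                  "n_positive": int((sel & mask).sum())}
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return meta
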