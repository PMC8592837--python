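"""Marker gating, cell-type classification, and phenotype matrices.

Continuous mIHC marker intensities are gated into binary positivity calls
(a cell is positive when its intensity is at or above the marker threshold;
thresholds may be fixed or derived automatically as the midpoint of a
bimodal intensity distribution). Boolean class rules over the positivity
calls define overlapping cell types — a CD3+CD8+ cell is both a T cell and
a cytotoxic T cell — and immunophenotype proportions are quantified either
against all cells or against a parent class (e.g. PD1+LAG3+ as a fraction
of CD3+CD8+ cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.mixture import GaussianMixture

from .errors import DegenerateDataError, ValidationError
from .io import marker_columns
from .stats import adjust_bh

#: The 23 markers of the staining panels (labels only; panels are config).
PANEL_MARKERS = (
    "CD3", "CD4", "CD8", "CD2", "CD16", "CD25", "CD27", "CD45RO", "CD57",
    "GrB", "PD1", "PDL1", "LAG3", "TIM3", "OX40", "HLA-ABC", "HLA-G",
    "CD11c", "CD14", "CD15", "CD68", "FOXP3", "Ki67",
)


@dataclass(frozen=True)
class ClassRule:
    """A cell class as a conjunction over marker positivity.

    ``requires`` maps marker -> required positivity (True = must be
    positive, False = must be negative).
    """

    name: str
    requires: Mapping[str, bool]


#: Default class set: T, helper T, cytotoxic T, NK, CD16+ myeloid.
DEFAULT_CLASS_RULES = (
    ClassRule("T", {"CD3": True}),
    ClassRule("Th", {"CD3": True, "CD4": True}),
    ClassRule("Tc", {"CD3": True, "CD8": True}),
    ClassRule("NK", {"CD2": True, "CD3": False}),
    ClassRule("CD16", {"CD16": True}),
)


class MarkerGater(TransformerMixin, BaseEstimator):
    """Gate marker intensities into boolean positivity calls.

    Parameters
    ----------
    thresholds : mapping marker -> float or "auto", or None
        Fixed thresholds per marker; ``"auto"`` (and every marker missing
        from the mapping when ``default="auto"``) derives the threshold as
        the midpoint between the two modes of a two-component Gaussian
        mixture fitted to log intensities. On a unimodal distribution the
        midpoint of the intensity range is used, with a warning.
    markers : sequence of str, optional
        Restrict gating to these markers (default: every intensity column).

    A cell is positive when its intensity is **>= threshold** (boundary
    positive). Fitted thresholds land in ``thresholds_``.
    """

    def __init__(self, thresholds=None, markers: Sequence[str] | None = None):
        self.thresholds = thresholds
        self.markers = markers

    def fit(self, X: pd.DataFrame, y=None):
        cols = list(self.markers) if self.markers is not None else marker_columns(X)
        missing = [m for m in cols if m not in X.columns]
        if missing:
            raise ValidationError(f"MarkerGater: marker(s) missing from table: {missing}")
        conf = dict(self.thresholds or {})
        unknown = [m for m in conf if m not in cols]
        if unknown:
            raise ValidationError(f"MarkerGater: thresholds for unknown marker(s): {unknown}")
        thresholds: dict[str, float] = {}
        for m in cols:
            rule = conf.get(m, "auto")
            if rule == "auto":
                thresholds[m] = self._auto_threshold(X[m].to_numpy(dtype=float), m)
            else:
                thr = float(rule)
                if not np.isfinite(thr) or thr <= 0:
                    raise ValidationError(
                        f"MarkerGater: threshold for {m!r} must be positive and finite"
                    )
                thresholds[m] = thr
        self.thresholds_ = thresholds
        self.markers_ = cols
        return self

    @staticmethod
    def _auto_threshold(values: np.ndarray, name: str) -> float:
        v = values[np.isfinite(values) & (values > 0)]
        if len(v) < 10:
            raise ValidationError(f"MarkerGater: too few positive intensities for {name!r}")
        logv = np.log(v).reshape(-1, 1)
        # tied covariance + extreme-quantile init keeps the fit bimodal even
        # when positives are rare (<2% of cells)
        init = np.array([[np.quantile(logv, 0.25)], [logv.max()]])
        gmm = GaussianMixture(
            n_components=2, random_state=0, covariance_type="tied", means_init=init
        )
        gmm.fit(logv)
        means = np.sort(gmm.means_.ravel())
        sd = float(np.sqrt(gmm.covariances_.ravel()[0]))
        # a split single mode shows ~1 sd of separation; true modes far more
        if means[1] - means[0] < 2.0 * sd:
            warnings.warn(
                f"marker {name!r}: intensity distribution looks unimodal; "
                "using midpoint of range", stacklevel=3,
            )
            return float((v.min() + v.max()) / 2.0)
        return float(np.exp(means.mean()))

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "thresholds_"):
            raise ValidationError("MarkerGater: call fit before transform")
        missing = [m for m in self.markers_ if m not in X.columns]
        if missing:
            raise ValidationError(f"MarkerGater: marker(s) missing from table: {missing}")
        out = pd.DataFrame(index=X.index)
        for m in self.markers_:
            out[m] = X[m].to_numpy(dtype=float) >= self.thresholds_[m]
        return out


def gate_cells(
    cells: pd.DataFrame,
    thresholds=None,
    markers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Functional wrapper over :class:`MarkerGater` (fit + transform)."""
    gater = MarkerGater(thresholds=thresholds, markers=markers)
    return gater.fit(cells).transform(cells)


def classify_cell_types(
    positivity: pd.DataFrame,
    rules: Sequence[ClassRule] = DEFAULT_CLASS_RULES,
) -> pd.DataFrame:
    """Evaluate class rules on a positivity matrix.

    Returns a boolean cell x class membership matrix; classes may overlap
    (multi-label), e.g. every Tc cell is also a T cell.
    """
    out = pd.DataFrame(index=positivity.index)
    for rule in rules:
        unknown = [m for m in rule.requires if m not in positivity.columns]
        if unknown:
            raise ValidationError(
                f"class rule {rule.name!r} references unknown marker(s): {unknown}"
            )
        mask = np.ones(len(positivity), dtype=bool)
        for marker, wanted in rule.requires.items():
            col = positivity[marker].to_numpy(dtype=bool)
            mask &= col if wanted else ~col
        out[rule.name] = mask
    return out


def class_sets(classes: pd.DataFrame) -> pd.Series:
    """Per-cell frozenset of class labels (the multi-label view)."""
    names = np.asarray(classes.columns, dtype=object)
    arr = classes.to_numpy(dtype=bool)
    return pd.Series(
        [frozenset(names[row]) for row in arr], index=classes.index, name="classes"
    )


@dataclass(frozen=True)
class Phenotype:
    """An immunophenotype: an optional parent class plus required-positive
    markers, quantified against ``all_cells`` or the ``parent_class``."""

    cls: str | None = None
    markers: tuple[str, ...] = ()
    denominator: str = "all_cells"

    @property
    def name(self) -> str:
        mk = "".join(f"{m}+" for m in self.markers)
        if self.cls is None:
            return mk or "all"
        return f"{self.cls}/{mk}" if mk else self.cls


def phenotype_proportion(
    classes: pd.DataFrame,
    positivity: pd.DataFrame,
    phenotype: Phenotype,
    min_cells: int = 10,
) -> float:
    """Proportion of phenotype-positive cells.

    Numerator: cells of ``phenotype.cls`` (if set) positive for every marker
    in ``phenotype.markers``. Denominator: all cells, or the parent class.
    Returns NaN when the denominator holds fewer than ``min_cells`` cells.
    """
    if phenotype.denominator not in ("all_cells", "parent_class"):
        raise ValueError("denominator must be 'all_cells' or 'parent_class'")
    n = len(classes)
    num_mask = np.ones(n, dtype=bool)
    if phenotype.cls is not None:
        if phenotype.cls not in classes.columns:
            raise ValidationError(f"unknown class {phenotype.cls!r}")
        num_mask &= classes[phenotype.cls].to_numpy(dtype=bool)
    for m in phenotype.markers:
        if m not in positivity.columns:
            raise ValidationError(f"unknown marker {m!r}")
        num_mask &= positivity[m].to_numpy(dtype=bool)
    if phenotype.denominator == "parent_class":
        if phenotype.cls is None:
            raise ValidationError("parent_class denominator requires a class")
        den_mask = classes[phenotype.cls].to_numpy(dtype=bool)
    else:
        den_mask = np.ones(n, dtype=bool)
    den = int(den_mask.sum())
    if den < max(min_cells, 1):
        return float("nan")
    return float(num_mask.sum() / den)


def default_phenotypes(
    functional_markers: Sequence[str] = ("CD45RO", "PD1", "LAG3", "TIM3", "GrB"),
) -> tuple[Phenotype, ...]:
    """Class proportions of all cells plus single-marker phenotypes of each
    lymphocyte class (parent-class denominators)."""
    phenos = [Phenotype(cls=c) for c in ("T", "Th", "Tc", "NK", "CD16")]
    for cls in ("T", "Th", "Tc", "NK"):
        for m in functional_markers:
            phenos.append(Phenotype(cls=cls, markers=(m,), denominator="parent_class"))
    return tuple(phenos)


def build_phenotype_matrix(
    cells: pd.DataFrame,
    classes: pd.DataFrame,
    positivity: pd.DataFrame,
    phenotypes: Sequence[Phenotype] | None = None,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Patients x (region, phenotype) proportion matrix.

    One row per patient x region present in the cell table; values are
    :func:`phenotype_proportion` evaluated on the cells of that stratum.
    """
    if phenotypes is None:
        phenotypes = default_phenotypes(
            [m for m in ("CD45RO", "PD1", "LAG3", "TIM3", "GrB")
             if m in positivity.columns]
        )
    rows = {}
    for (patient, region), idx in cells.groupby(["patient_id", "region"]).groups.items():
        sub_classes = classes.loc[idx]
        sub_pos = positivity.loc[idx]
        rows[(patient, region)] = {
            ph.name: phenotype_proportion(sub_classes, sub_pos, ph, min_cells)
            for ph in phenotypes
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["patient_id", "region"])
    return out.sort_index()


def contexture_medians(matrix: pd.DataFrame) -> pd.DataFrame:
    """Contexture-level aggregation: per-region median across patients."""
    return matrix.groupby(level="region").median()


def normalize_for_heatmap(matrix: pd.DataFrame) -> pd.DataFrame:
    """Median-center then max-scale each feature (column).

    Per column: subtract the median across rows, then divide by the maximum
    absolute centered value; a constant column maps to zeros. Output columns
    satisfy max |value| <= 1.
    """
    out = matrix.copy().astype(float)
    for col in out.columns:
        v = out[col].to_numpy(dtype=float)
        centered = v - np.nanmedian(v)
        m = np.nanmax(np.abs(centered))
        out[col] = np.zeros_like(v) if (not np.isfinite(m) or m == 0) else centered / m
    return out


@dataclass
class ClusterResult:
    linkage: np.ndarray
    order: list  # leaf order; unclusterable (constant) items appended last
    clustered: list
    unclustered: list


def cluster_profiles(
    matrix: pd.DataFrame,
    axis: str = "rows",
    metric: str = "spearman",
) -> ClusterResult:
    """Hierarchical clustering of heatmap rows or columns.

    ``metric="spearman"`` uses 1 - Spearman correlation as the distance;
    ``metric="euclidean_of_correlations"`` uses Euclidean distance between
    rows of the Spearman correlation matrix. Linkage is Ward.D2. Items with
    constant profiles (correlation undefined) are excluded from clustering
    and appended last in the returned order; fewer than 3 clusterable items
    is an error.
    """
    data = matrix if axis == "rows" else matrix.T
    labels = list(data.index)
    arr = data.to_numpy(dtype=float)
    variable = [i for i in range(len(labels)) if np.nanstd(arr[i]) > 0]
    constant = [i for i in range(len(labels)) if i not in variable]
    if len(variable) < 3:
        raise DegenerateDataError("cluster_profiles needs >=3 clusterable profiles")
    sub = arr[variable]
    corr = pd.DataFrame(sub.T).corr(method="spearman").to_numpy()
    corr = np.clip(corr, -1.0, 1.0)
    if metric == "spearman":
        dist = 1.0 - corr
    elif metric == "euclidean_of_correlations":
        diff = corr[:, None, :] - corr[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
    else:
        raise ValueError("metric must be 'spearman' or 'euclidean_of_correlations'")
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="ward")
    order = [labels[variable[i]] for i in leaves_list(Z)]
    order += [labels[i] for i in constant]
    return ClusterResult(
        linkage=Z,
        order=order,
        clustered=[labels[i] for i in variable],
        unclustered=[labels[i] for i in constant],
    )


def correlate_it_pt(
    matrix: pd.DataFrame,
    min_pairs: int = 5,
    families: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Spearman correlation of each phenotype between IT and PT regions.

    The matrix must be indexed by (patient_id, region). Phenotypes with
    fewer than ``min_pairs`` complete IT/PT patient pairs get missing
    values. Returns (per-phenotype table with BH q-values, per-family median
    R; the family map defaults to one global family).
    """
    it = matrix.xs("IT", level="region")
    pt = matrix.xs("PT", level="region")
    common = it.index.intersection(pt.index)
    rows = []
    for col in matrix.columns:
        a = it.loc[common, col]
        b = pt.loc[common, col]
        ok = a.notna() & b.notna()
        if ok.sum() < min_pairs:
            rows.append({"phenotype": col, "r": float("nan"), "p_value": float("nan"),
                         "n": int(ok.sum())})
            continue
        r, p = sps.spearmanr(a[ok], b[ok])
        rows.append({"phenotype": col, "r": float(r), "p_value": float(p),
                     "n": int(ok.sum())})
    out = pd.DataFrame(rows)
    valid = out["p_value"].notna()
    out["q_value"] = np.nan
    if valid.any():
        out.loc[valid, "q_value"] = adjust_bh(out.loc[valid, "p_value"].to_numpy())
    fam = pd.Series(families) if families else pd.Series("all", index=out["phenotype"])
    fam = fam.reindex(out["phenotype"]).fillna("other")
    medians = out.set_index("phenotype")["r"].groupby(fam).median()
    return out, medians
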