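"""Immune topography classification and mutation association.

Patients are assigned one of three immune topographies from H&E lymphocyte
proportions:

* **hot** — high intratumoral (IT) infiltration;
* **excluded** — lymphocytes accumulate peritumorally (PT) but not in IT;
* **cold** — low infiltration everywhere.

The assignment is a two-phase unsupervised procedure: phase 1 clusters the
1-D IT lymphocyte proportions (Ward.D2 linkage, Euclidean distance) into two
groups, the higher-mean group being *hot*; phase 2 clusters the remaining
patients on ``delta = pt_prop - it_prop``, the higher-mean-delta group being
*excluded* and the rest *cold*.

Topography classes are then screened against a binary patient x gene
mutation table with 2x2 contingency tests: chi-square with Yates continuity
correction when all observed cell counts exceed 5, otherwise the two-sided
Fisher exact test, with Benjamini-Hochberg adjustment across genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import DegenerateDataError, ValidationError
from .stats import adjust_bh

LABELS = ("hot", "cold", "excluded")


def region_lymphocyte_proportion(cells: pd.DataFrame) -> pd.DataFrame:
    """Per patient x region lymphocyte proportion from an H&E cell table.

    Returns a long table with columns ``patient_id``, ``region``,
    ``n_cells``, ``n_lymphocytes``, ``proportion``. A region with zero cells
    yields no row (a missing value after pivoting), with a warning.
    """
    if "is_lymphocyte" not in cells.columns:
        raise ValidationError(
            "region_lymphocyte_proportion: cell table lacks is_lymphocyte"
        )
    grouped = cells.groupby(["patient_id", "region"], sort=True).agg(
        n_cells=("cell_id", "size"),
        n_lymphocytes=("is_lymphocyte", "sum"),
    )
    out = grouped.reset_index()
    out["proportion"] = out["n_lymphocytes"] / out["n_cells"]
    return out


def proportions_wide(props: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long proportion table to one row per patient with
    ``it_prop``, ``pt_prop`` and ``delta = pt_prop - it_prop``."""
    wide = props.pivot(index="patient_id", columns="region", values="proportion")
    out = pd.DataFrame(index=wide.index)
    out["it_prop"] = wide["IT"] if "IT" in wide.columns else np.nan
    out["pt_prop"] = wide["PT"] if "PT" in wide.columns else np.nan
    out["delta"] = out["pt_prop"] - out["it_prop"]
    return out.reset_index()


def _cut_two(values: np.ndarray) -> np.ndarray:
    """Ward.D2 / Euclidean 2-cluster cut of 1-D data.

    Returns a boolean mask of the higher-mean cluster. Raises
    :class:`DegenerateDataError` when all values are identical (no cut
    exists); equal cluster means are treated the same way.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise DegenerateDataError("clustering phase needs at least 2 patients")
    if np.ptp(values) == 0:
        raise DegenerateDataError("all values identical; 2-cluster cut undefined")
    Z = linkage(values.reshape(-1, 1), method="ward")
    assignment = fcluster(Z, t=2, criterion="maxclust")
    m1 = values[assignment == 1].mean()
    m2 = values[assignment == 2].mean()
    if m1 == m2:
        raise DegenerateDataError("cluster means tie; 2-cluster cut undefined")
    high = 1 if m1 > m2 else 2
    return assignment == high


class TopographyClassifier(ClusterMixin, BaseEstimator):
    """Two-phase hot/cold/excluded topography assignment.

    Parameters
    ----------
    on_degenerate : {"raise", "cold"}
        Behavior when a clustering phase is degenerate (all inputs equal):
        raise an error (default) or fall back to labeling the affected
        patients *cold* (the conservative class).

    Attributes
    ----------
    labels_ : ndarray of str
        Per-patient topography labels after :meth:`fit`.

    The assignment is invariant to patient row permutation and to adding a
    constant to every ``it_prop`` (labels depend on relative structure);
    multiplicative rescaling is *not* an invariance.
    """

    def __init__(self, on_degenerate: str = "raise"):
        self.on_degenerate = on_degenerate

    def fit(self, X, y=None):
        if self.on_degenerate not in ("raise", "cold"):
            raise ValueError("on_degenerate must be 'raise' or 'cold'")
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValidationError(
                "TopographyClassifier expects two columns (it_prop, pt_prop)"
            )
        if not np.isfinite(arr).all():
            raise ValidationError("TopographyClassifier: non-finite proportions")
        n = arr.shape[0]
        if n < 4:
            raise ValidationError(
                "TopographyClassifier needs >=4 patients with both regions"
            )
        it = arr[:, 0]
        delta = arr[:, 1] - arr[:, 0]
        labels = np.full(n, "cold", dtype=object)
        try:
            hot = _cut_two(it)
        except DegenerateDataError:
            if self.on_degenerate == "raise":
                raise
            hot = np.zeros(n, dtype=bool)
        labels[hot] = "hot"
        rest = ~hot
        if rest.sum() >= 2:
            try:
                excluded_rest = _cut_two(delta[rest])
                idx = np.flatnonzero(rest)[excluded_rest]
                labels[idx] = "excluded"
            except DegenerateDataError:
                if self.on_degenerate == "raise":
                    raise
                # fallback: all non-hot patients stay cold
        elif rest.sum() == 1 and self.on_degenerate == "raise":
            raise DegenerateDataError(
                "phase 2 has fewer patients than clusters"
            )
        self._check_label_means(it, delta, labels)
        self.labels_ = np.asarray(labels, dtype=object)
        return self

    @staticmethod
    def _check_label_means(it, delta, labels):
        # Contract: hot mean IT >= non-hot mean IT; excluded mean delta >= cold.
        labels = np.asarray(labels)
        if (labels == "hot").any() and (labels != "hot").any():
            assert it[labels == "hot"].mean() >= it[labels != "hot"].mean()
        if (labels == "excluded").any() and (labels == "cold").any():
            assert delta[labels == "excluded"].mean() >= delta[labels == "cold"].mean()

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def assign_topographies(
    props: pd.DataFrame, on_degenerate: str = "raise"
) -> pd.DataFrame:
    """Label a wide proportion table (``patient_id``, ``it_prop``,
    ``pt_prop``) with topographies; patients missing a region are excluded
    with a warning and get a missing label."""
    df = props.copy()
    if "delta" not in df.columns:
        df["delta"] = df["pt_prop"] - df["it_prop"]
    usable = df["it_prop"].notna() & df["pt_prop"].notna()
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} patient(s) lack a region proportion; excluded",
            stacklevel=2,
        )
    clf = TopographyClassifier(on_degenerate=on_degenerate)
    labels = clf.fit_predict(df.loc[usable, ["it_prop", "pt_prop"]].to_numpy())
    df["label"] = pd.NA
    df.loc[usable, "label"] = labels
    return df


def topography_summary(labels) -> pd.DataFrame:
    """Counts and percentages (one decimal) per topography class."""
    s = pd.Series(labels).dropna()
    counts = s.value_counts()
    out = pd.DataFrame({"count": counts})
    out["percent"] = np.round(100.0 * out["count"] / out["count"].sum(), 1)
    out.index.name = "label"
    return out.reset_index()


def association_test(table, override: str | None = None):
    """2x2 contingency test with the dispatch rule used throughout.

    Chi-square with Yates continuity correction when every observed cell
    count exceeds 5, otherwise two-sided Fisher exact; ``override`` forces
    ``"chi2"`` or ``"fisher"``. Returns ``(test_used, p_value, odds_ratio)``
    with the unconditional sample odds ratio ``ad/bc``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.isfinite(t).all():
        raise ValidationError("association_test expects a nonnegative 2x2 table")
    if override is None:
        test = "chi2" if (t > 5).all() else "fisher"
    elif override in ("chi2", "fisher"):
        test = override
    else:
        raise ValueError("override must be None, 'chi2' or 'fisher'")
    if test == "chi2":
        _, p, _, _ = stats.chi2_contingency(t, correction=True)
    else:
        _, p = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (a * d) / (b * c)
    return test, float(p), float(odds)


def mutation_topography_association(
    labels: pd.DataFrame,
    mutations: pd.DataFrame,
    target_class: str,
    test_override: str | None = None,
    min_prevalence: float = 0.05,
) -> pd.DataFrame:
    """Associate each gene's mutation status with one topography class.

    Per gene, patients with a topography label and a non-missing mutation
    call form a 2x2 table ``[[in-class mutated, in-class wild-type],
    [rest mutated, rest wild-type]]``. Genes mutated in fewer than
    ``min_prevalence`` of callable patients are skipped, as are genes with an
    empty table margin. Returns per-gene counts, test used, odds ratio,
    p-value, and BH-adjusted q-value.
    """
    if target_class not in LABELS:
        raise ValueError(f"target_class must be one of {LABELS}")
    lab = labels.set_index("patient_id")["label"].dropna()
    mut = mutations.set_index("patient_id")
    shared = lab.index.intersection(mut.index)
    if len(shared) == 0:
        raise ValidationError("no patients shared between labels and mutation table")
    lab = lab.loc[shared]
    rows = []
    for gene in mut.columns:
        calls = mut.loc[shared, gene].dropna()
        if len(calls) == 0:
            continue
        if calls.mean() < min_prevalence:
            continue
        in_class = lab.loc[calls.index] == target_class
        mutated = calls.astype(int) == 1
        a = int((in_class & mutated).sum())
        b = int((in_class & ~mutated).sum())
        c = int((~in_class & mutated).sum())
        d = int((~in_class & ~mutated).sum())
        t = np.array([[a, b], [c, d]])
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            warnings.warn(f"gene {gene}: empty 2x2 margin; skipped", stacklevel=2)
            continue
        test, p, odds = association_test(t, override=test_override)
        rows.append(
            {
                "gene": gene,
                "n_class_mut": a,
                "n_class_wt": b,
                "n_rest_mut": c,
                "n_rest_wt": d,
                "test_used": test,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "n_class_mut",
            "n_class_wt",
            "n_rest_mut",
            "n_rest_wt",
            "test_used",
            "odds_ratio",
            "p_value",
        ],
    )
    if len(out):
        out["q_value"] = adjust_bh(out["p_value"].to_numpy())
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out
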