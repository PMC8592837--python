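"""Statistical utilities and the clinical / survival association layer.

Two-group continuous comparisons use the unpaired two-sided Mann-Whitney
rank-sum test and three or more groups the Kruskal-Wallis test; paired
contrasts (interacting vs non-interacting cells) use the Wilcoxon
signed-rank test. Multiple testing is controlled with the
Benjamini-Hochberg step-up procedure. Survival screens are univariate Cox
proportional-hazards fits with log-rank tests on median-dichotomized
features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, ValidationError


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (same order as input)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("adjust_bh: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log10_median_fc(values_a, values_b) -> float:
    """log10 of the ratio of group medians; NaN when either median is 0 or
    negative (undefined fold-change)."""
    ma = float(np.nanmedian(np.asarray(values_a, dtype=float)))
    mb = float(np.nanmedian(np.asarray(values_b, dtype=float)))
    if ma <= 0 or mb <= 0 or not (np.isfinite(ma) and np.isfinite(mb)):
        return float("nan")
    return float(np.log10(ma / mb))


@dataclass
class GroupComparison:
    feature: str
    groups: tuple
    test_used: str
    statistic: float
    p_value: float
    fc_log10: float
    q_value: float = float("nan")


def compare_groups(values, group_labels, feature: str = "") -> GroupComparison:
    """Compare a continuous variable across groups.

    Two groups: unpaired two-sided Mann-Whitney rank-sum; three or more:
    Kruskal-Wallis. The fold-change is the log10 ratio of the first two
    group medians (NaN when a median is zero). A group with fewer than two
    observations yields a missing p-value with a warning.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    mask = np.isfinite(v)
    v, g = v[mask], g[mask]
    names = list(pd.unique(g))
    if len(names) < 2:
        raise ValidationError("compare_groups needs >=2 non-empty groups")
    samples = [v[g == name] for name in names]
    fc = log10_median_fc(samples[0], samples[1])
    if any(len(s) < 2 for s in samples):
        warnings.warn("a group has <2 observations; p-value missing", stacklevel=2)
        return GroupComparison(feature, tuple(names), "none", float("nan"),
                               float("nan"), fc)
    if len(names) == 2:
        stat, p = sps.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        test = "mannwhitney"
    else:
        stat, p = sps.kruskal(*samples)
        test = "kruskal"
    return GroupComparison(feature, tuple(names), test, float(stat), float(p), fc)


def dichotomize_by_median(values) -> np.ndarray:
    """Median split: ``high`` iff value > median, ties at the median go to
    ``low``. Raises on an all-identical vector (degenerate split)."""
    v = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(v)) < 2:
        raise ValidationError("dichotomize_by_median needs >=2 finite values")
    if np.nanmax(v) == np.nanmin(v):
        raise DegenerateDataError("dichotomize_by_median: all values identical")
    med = np.nanmedian(v)
    out = np.where(v > med, "high", "low").astype(object)
    out[~np.isfinite(v)] = None
    return out


@dataclass
class SurvivalResult:
    feature: str
    dichotomized: bool
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    events: int
    converged: bool = True
    km: dict = field(default_factory=dict)


def cox_survival(
    feature: pd.Series,
    clinical: pd.DataFrame,
    dichotomize: bool = True,
    time_col: str = "os_time",
    event_col: str = "os_event",
) -> SurvivalResult:
    """Univariate Cox proportional-hazards fit against overall survival.

    With ``dichotomize=True`` the feature is median-split (high vs low;
    binary 0/1 features pass through unchanged) and the p-value is the
    log-rank test between the two groups; for a continuous feature the Wald
    p of the Cox coefficient is reported. Kaplan-Meier coordinates for each
    group are attached for plotting.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import logrank_test

    df = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    x = pd.Series(feature).astype(float)
    if x.index.equals(pd.RangeIndex(len(x))) and len(x) == len(df):
        x.index = df.index
    data = pd.DataFrame(
        {"time": df[time_col].astype(float), "event": df[event_col].astype(int)}
    )
    data["x"] = x
    data = data.dropna()
    n, events = len(data), int(data["event"].sum())
    if n < 10:
        raise ValidationError(f"cox_survival: only {n} patients (need >=10)")
    if events < 3:
        raise ValidationError(f"cox_survival: only {events} events (need >=3)")
    name = getattr(feature, "name", None) or "feature"

    if dichotomize:
        uniq = set(np.unique(data["x"]))
        if uniq <= {0.0, 1.0}:
            data["group"] = data["x"].astype(int)
        else:
            data["group"] = (dichotomize_by_median(data["x"]) == "high").astype(int)
        fit_df = data[["time", "event"]].copy()
        fit_df["x"] = data["group"]
    else:
        fit_df = data[["time", "event", "x"]].copy()

    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(fit_df, duration_col="time", event_col="event")
        with np.errstate(over="ignore"):
            hr = float(np.exp(cph.params_["x"]))
            ci = cph.confidence_intervals_
            ci_low = float(np.exp(ci.iloc[0, 0]))
            ci_high = float(np.exp(ci.iloc[0, 1]))
        p_wald = float(cph.summary["p"].iloc[0])
    except Exception:
        converged = False
        hr = ci_low = ci_high = p_wald = float("nan")

    km: dict = {}
    if dichotomize:
        high = data["group"] == 1
        res = logrank_test(
            data.loc[high, "time"], data.loc[~high, "time"],
            event_observed_A=data.loc[high, "event"],
            event_observed_B=data.loc[~high, "event"],
        )
        p = float(res.p_value)
        for label, mask in (("high", high), ("low", ~high)):
            if mask.sum() == 0:
                continue
            kmf = KaplanMeierFitter()
            kmf.fit(data.loc[mask, "time"], data.loc[mask, "event"])
            km[label] = {
                "time": kmf.survival_function_.index.to_numpy().tolist(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy().tolist(),
            }
    else:
        p = p_wald
    return SurvivalResult(
        feature=name, dichotomized=dichotomize, hazard_ratio=hr,
        ci_low=ci_low, ci_high=ci_high, p_value=p, n=n, events=events,
        converged=converged, km=km,
    )


def survival_screen(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    dichotomize: bool = True,
) -> pd.DataFrame:
    """Univariate Cox screen over feature columns, BH-adjusted."""
    rows = []
    for col in features.columns:
        try:
            res = cox_survival(features[col].rename(col), clinical, dichotomize)
        except (ValidationError, DegenerateDataError) as exc:
            warnings.warn(f"survival screen: {col}: {exc}", stacklevel=2)
            continue
        rows.append(
            {
                "feature": col,
                "hazard_ratio": res.hazard_ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "n": res.n,
                "events": res.events,
                "converged": res.converged,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = adjust_bh(out["p_value"].fillna(1.0).to_numpy())
    return out


def group_fc_panel(
    matrix: pd.DataFrame,
    grouping: pd.Series,
    p_keep: float = 0.05,
    min_class: int = 3,
) -> pd.DataFrame:
    """One-vs-rest comparison of every feature column across grouping classes.

    For each class with at least ``min_class`` members, each feature is
    compared between the class and the pooled remainder (rank-sum test,
    log10 fold-change of medians), BH-adjusted within the panel. The
    ``keep`` column marks features significant (p < ``p_keep``) in at least
    one comparison — the display rule for balloon plots.
    """
    g = pd.Series(grouping).dropna()
    classes = list(pd.unique(g))
    if len(classes) < 2:
        raise ValidationError("group_fc_panel needs >=2 classes")
    common = matrix.index.intersection(g.index)
    m = matrix.loc[common]
    g = g.loc[common]
    rows = []
    for cls in classes:
        mask = (g == cls).to_numpy()
        if mask.sum() < min_class:
            warnings.warn(f"class {cls!r} has <{min_class} patients; skipped",
                          stacklevel=2)
            continue
        for col in m.columns:
            v = m[col].to_numpy(dtype=float)
            ok = np.isfinite(v)
            a, b = v[ok & mask], v[ok & ~mask]
            if len(a) < 2 or len(b) < 2:
                continue
            if np.ptp(np.concatenate([a, b])) == 0:
                continue  # identical feature carries no contrast
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            rows.append(
                {
                    "class": cls,
                    "feature": col,
                    "fc_log10": log10_median_fc(a, b),
                    "statistic": float(stat),
                    "p_value": float(p),
                }
            )
    out = pd.DataFrame(rows, columns=["class", "feature", "fc_log10", "statistic",
                                      "p_value"])
    if len(out):
        out["q_value"] = adjust_bh(out["p_value"].to_numpy())
        sig = out.groupby("feature")["p_value"].transform("min") < p_keep
        out["keep"] = sig
    else:
        out["q_value"] = pd.Series(dtype=float)
        out["keep"] = pd.Series(dtype=bool)
    return out
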