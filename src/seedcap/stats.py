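"""Composition, overlap and group statistics for CAP analyses.

Covers: percentage overlap of each CAP's suprathreshold voxels with a labelled
resting-state-network parcellation (17-network convention); between-cohort CAP
spatial overlap (Jaccard of suprathreshold sets, in %, with correlation-based
CAP pairing); covariate-adjusted group comparison of temporal metrics (long
format OLS, omnibus F-tests for state and group x state, per-state post-hoc
group contrasts with Benjamini-Hochberg FDR); and exploratory Pearson
correlations between temporal metrics and clinical variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

from ._errors import ConfigurationError, SeedcapError
from .estimation import CapSet

#: Covariates entered in the group models, matching the clinical table schema:
#: censored-frame count, selected-volume count, age, sex, psychotropic
#: medication (binary), depression (BDI) and state anxiety (STAI-S).
DEFAULT_COVARIATES = (
    "n_censored",
    "n_selected",
    "age",
    "sex",
    "medication",
    "bdi",
    "stai_s",
)


@dataclass
class ParcellationOverlay:
    """Integer network labels over the grey-matter voxels.

    ``labels[i]`` is the network id of masked voxel i (0 = background);
    ``names`` maps ids to network names.
    """

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    def name(self, network_id: int) -> str:
        if network_id == 0:
            return "background"
        return self.names.get(network_id, f"network_{network_id}")


def network_overlap(caps: CapSet, parc: ParcellationOverlay) -> pd.DataFrame:
    """Percentage of each CAP's suprathreshold voxels falling in each network.

    Rows: (cap, sign, network_id, network, pct).  Percentages within each
    CAP x sign sum to 100 over all networks including background; seed voxels
    were already removed from the suprathreshold sets when the CapSet was
    finalised with its seed.  Suprathreshold voxels without a network label are
    tallied under ``background``.
    """
    if parc.labels.size != caps.maps.shape[1]:
        raise ConfigurationError("parcellation and CAP maps differ in voxel count")
    rows = []
    for c in range(caps.k):
        for sign, vox in (("positive", caps.pos_voxels[c]), ("negative", caps.neg_voxels[c])):
            total = vox.size
            labs = parc.labels[vox]
            for net in np.unique(labs) if total else []:
                pct = 100.0 * (labs == net).sum() / total
                rows.append(
                    {
                        "cap": c + 1,
                        "sign": sign,
                        "network_id": int(net),
                        "network": parc.name(int(net)),
                        "pct": float(pct),
                    }
                )
    return pd.DataFrame(rows, columns=["cap", "sign", "network_id", "network", "pct"])


def pair_caps(caps_a: CapSet, caps_b: CapSet) -> np.ndarray:
    """Pair CAPs across cohorts by maximal total map correlation.

    Returns ``pairing`` with ``pairing[i]`` the index in ``caps_b`` matched to
    CAP i of ``caps_a`` (Hungarian assignment on the correlation matrix).
    """
    if caps_a.k != caps_b.k:
        raise ConfigurationError("CapSets have different K")
    a = caps_a.maps - caps_a.maps.mean(axis=1, keepdims=True)
    b = caps_b.maps - caps_b.maps.mean(axis=1, keepdims=True)
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    corr = a @ b.T
    _, cols = linear_sum_assignment(-corr)
    return cols


def cap_spatial_overlap(
    caps_a: CapSet,
    caps_b: CapSet,
    method: str = "jaccard",
    pairing: np.ndarray | None = None,
) -> np.ndarray:
    """Percentage voxel overlap between corresponding CAPs of two cohorts.

    The combined suprathreshold set (positive union negative) of each CAP is
    compared: ``jaccard`` gives 100 x |A∩B| / |A∪B| (the default);
    ``containment`` gives 100 x |A∩B| / |A|.  CAPs are paired by map
    correlation unless an explicit pairing is given.  Empty sets give 0 with a
    warning.
    """
    if pairing is None:
        pairing = pair_caps(caps_a, caps_b)
    out = np.zeros(caps_a.k)
    for i, j in enumerate(pairing):
        a = np.union1d(caps_a.pos_voxels[i], caps_a.neg_voxels[i])
        b = np.union1d(caps_b.pos_voxels[j], caps_b.neg_voxels[j])
        inter = np.intersect1d(a, b).size
        if method == "jaccard":
            denom = np.union1d(a, b).size
        elif method == "containment":
            denom = a.size
        else:
            raise ConfigurationError(f"unknown overlap method {method!r}")
        if denom == 0:
            warnings.warn(f"CAP{i + 1}: empty suprathreshold sets; overlap set to 0",
                          stacklevel=2)
            out[i] = 0.0
        else:
            out[i] = 100.0 * inter / denom
    return out


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotonicity enforced)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise SeedcapError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GroupStatsResult:
    """Omnibus and post-hoc output of the covariate-adjusted group model."""

    metric: str
    omnibus: pd.DataFrame  # rows: state, group:state, with F, df, p
    posthoc: pd.DataFrame  # per-state group contrast: estimate, raw p, FDR p
    covariates: tuple[str, ...]
    n_obs: int


def _check_full_rank(X: pd.DataFrame) -> None:
    """Raise naming aliased columns if the design matrix is rank deficient."""
    arr = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        aliased = []
        running: list[int] = []
        r = 0
        for j in range(arr.shape[1]):
            new = np.linalg.matrix_rank(arr[:, running + [j]])
            if new > r:
                running.append(j)
                r = new
            else:
                aliased.append(X.columns[j])
        raise ConfigurationError(
            f"design matrix is rank deficient; aliased columns: {aliased}"
        )


def fit_group_model(
    metrics: pd.DataFrame,
    clinical: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
) -> GroupStatsResult:
    """Covariate-adjusted comparison of a temporal metric between two groups.

    ``metrics`` is the tidy subject x CAP table (columns ``subject_id``,
    ``cap`` and the metric); ``clinical`` carries the group column and the
    covariates.  Rows with missing covariates are dropped with a log entry.
    The omnibus model is a long-format OLS

        metric ~ C(group) * C(cap) + covariates

    with type-II F-tests for the ``state`` (cap) and ``group x state`` terms.
    Post-hoc, the group contrast is estimated per CAP (metric ~ group +
    covariates on that CAP's rows) and the per-CAP p-values are BH-FDR
    adjusted as one family.
    """
    if metric not in metrics.columns:
        raise ConfigurationError(f"metric {metric!r} not in metrics table")
    df = metrics.merge(clinical, on="subject_id", how="inner")
    need = [metric, group_col, "cap", *covariates]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing columns: {missing}")
    n0 = df["subject_id"].nunique()
    df = df.dropna(subset=need)
    n1 = df["subject_id"].nunique()
    if n1 < n0:
        warnings.warn(
            f"{n0 - n1} subject(s) dropped for missing covariates", stacklevel=2
        )
    groups = sorted(df[group_col].unique())
    if len(groups) != 2:
        raise ConfigurationError(f"need exactly 2 groups, got {groups}")

    cov_terms = " + ".join(covariates)
    formula = f"{metric} ~ C({group_col}) * C(cap)" + (
        f" + {cov_terms}" if covariates else ""
    )
    model = smf.ols(formula, data=df)
    _check_full_rank(pd.DataFrame(model.exog, columns=model.exog_names))
    fit = model.fit()
    anova = sm.stats.anova_lm(fit, typ=2)

    def _row(term: str, label: str) -> dict:
        r = anova.loc[term]
        return {
            "term": label,
            "F": float(r["F"]),
            "df_num": float(r["df"]),
            "df_den": float(anova.loc["Residual", "df"]),
            "p": float(r["PR(>F)"]),
        }

    omnibus = pd.DataFrame(
        [
            _row("C(cap)", "state"),
            _row(f"C({group_col}):C(cap)", "group:state"),
        ]
    )

    rows = []
    post_formula = f"{metric} ~ C({group_col})" + (f" + {cov_terms}" if covariates else "")
    for cap in sorted(df["cap"].unique()):
        sub = df[df["cap"] == cap]
        m = smf.ols(post_formula, data=sub)
        _check_full_rank(pd.DataFrame(m.exog, columns=m.exog_names))
        f = m.fit()
        term = f"C({group_col})[T.{groups[1]}]"
        rows.append(
            {
                "cap": int(cap),
                "contrast": f"{groups[1]} - {groups[0]}",
                "estimate": float(f.params[term]),
                "p_raw": float(f.pvalues[term]),
            }
        )
    posthoc = pd.DataFrame(rows)
    posthoc["p_fdr"] = fdr_adjust(posthoc["p_raw"].to_numpy())
    posthoc["significant"] = posthoc["p_fdr"] < alpha
    return GroupStatsResult(
        metric=metric,
        omnibus=omnibus,
        posthoc=posthoc,
        covariates=tuple(covariates),
        n_obs=len(df),
    )


def correlate_clinical(
    metrics: pd.DataFrame,
    clinical: pd.DataFrame,
    pairs: list[tuple[str, int, str]],
    subgroup_col: str = "subgroup",
    subgroups: list[str] | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Exploratory metric-vs-clinical correlations per subgroup.

    ``pairs`` lists (metric_column, cap, clinical_variable) triples.  Pearson r
    with two-sided p by default (Spearman via ``method``); no multiplicity
    correction.  Triples with fewer than 3 complete observations or zero
    variance are reported with NaN.
    """
    df = metrics.merge(clinical, on="subject_id", how="inner")
    if subgroups is None:
        subgroups = sorted(df[subgroup_col].dropna().unique())
    corr_fn = scipy.stats.pearsonr if method == "pearson" else scipy.stats.spearmanr
    rows = []
    for sg in subgroups:
        for metric_col, cap, var in pairs:
            sub = df[(df[subgroup_col] == sg) & (df["cap"] == cap)][
                [metric_col, var]
            ].dropna()
            x, y = sub[metric_col].to_numpy(float), sub[var].to_numpy(float)
            if len(sub) < 3 or x.std() == 0 or y.std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = corr_fn(x, y)
            rows.append(
                {
                    "subgroup": sg,
                    "metric": metric_col,
                    "cap": cap,
                    "variable": var,
                    "n": len(sub),
                    "r": float(r) if r == r else np.nan,
                    "p": float(p) if p == p else np.nan,
                }
            )
    return pd.DataFrame(rows)
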