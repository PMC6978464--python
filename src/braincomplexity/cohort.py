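"""Cohort-level aggregation: the higher-order "overall complexity" analysis.

Per-scan profiles of the seven complexity measures are pooled across
conditions; the analyses are (i) the inter-metric Pearson correlation
matrix, (ii) a PCA over the standardised metric columns whose first
component is read as overall complexity, (iii) Kruskal-Wallis /
Wilcoxon-signed-rank condition comparisons, and (iv) Pearson correlation of
each metric with the serum-concentration covariate over sedated scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .network import DEFAULT_THRESHOLDS, connectivity_matrix, threshold_curve
from .signal_prep import RoiTimeSeries, hilbert_envelope
from .temporal import (
    higuchi_fd,
    hurst_rs,
    lzc_normalised,
    pca_compressibility,
    sample_entropy,
    select_kmax,
)

__all__ = [
    "METRICS",
    "MetricParams",
    "ComplexityProfile",
    "CohortResult",
    "compute_profile",
    "profiles_to_frame",
    "metric_correlation_matrix",
    "overall_complexity_pca",
    "group_comparison",
    "dose_correlation",
    "analyse_cohort",
]

METRICS = ("lzc", "sampen", "pca_n", "hurst", "higuchi", "alg_conn", "lz_graph")


@dataclass
class MetricParams:
    """Tunable parameters of the seven measures (defaults follow common practice)."""

    m: int = 2
    r_coef: float = 0.3
    k_max: int | str = "auto"  # "auto" = stability sweep over powers of two
    variance_threshold: float = 0.95
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
    surrogate_seed: int = 0
    n_surrogates: int = 1
    kmax_sample_rows: int = 10  # rows used by the k_max stability sweep


@dataclass
class ComplexityProfile:
    subject_id: str
    condition: str
    lzc: float
    sampen: float
    pca_n: float
    hurst: float
    higuchi: float
    alg_conn: float
    lz_graph: float
    dose: float = np.nan
    k_max: int | None = None

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "condition": self.condition,
            **{m: getattr(self, m) for m in METRICS},
            "dose": self.dose,
        }


def compute_profile(
    scan: RoiTimeSeries,
    subject_id: str = "",
    condition: str = "",
    dose: float = np.nan,
    params: MetricParams | None = None,
) -> ComplexityProfile:
    """All seven complexity measures for one scan.

    The Hilbert envelope is computed once; LZC runs on the whole binarised
    matrix, SampEn / Hurst / Higuchi run per region and are averaged, PCA
    compressibility and the two threshold-integrated graph measures run on
    the envelope matrix. Deterministic given the scan and the surrogate
    seed. Any non-finite measure aborts the profile with the metric named.
    """
    params = params or MetricParams()
    env = hilbert_envelope(scan)
    env_series = RoiTimeSeries(
        values=np.maximum(env.values, 0.0),
        region_ids=list(scan.region_ids),
        sampling_interval=scan.sampling_interval,
    )

    lz = lzc_normalised(scan, seed=params.surrogate_seed,
                        n_surrogates=params.n_surrogates)

    rows = env.values
    sampen_vals = []
    for row in rows:
        res = sample_entropy(row, m=params.m, r_coef=params.r_coef)
        if np.isfinite(res.value):
            sampen_vals.append(res.value)
        else:
            warnings.warn(f"non-finite SampEn row excluded ({res.flag})",
                          RuntimeWarning, stacklevel=2)
    if not sampen_vals:
        raise ValueError("profile rejected: sampen (no finite rows)")

    hurst_vals = [hurst_rs(row).exponent for row in rows]

    if params.k_max == "auto":
        k_max = select_kmax(rows[: params.kmax_sample_rows])
    else:
        k_max = int(params.k_max)
    higuchi_vals = [higuchi_fd(row, k_max).dimension for row in rows]

    pca_res = pca_compressibility(env_series, params.variance_threshold)

    conn = connectivity_matrix(env)
    ac = threshold_curve(conn, "algebraic_connectivity", params.thresholds)
    lz_g = threshold_curve(conn, "graph_lz", params.thresholds)

    profile = ComplexityProfile(
        subject_id=subject_id,
        condition=condition,
        lzc=lz.normalised,
        sampen=float(np.mean(sampen_vals)),
        pca_n=float(pca_res.n_components),
        hurst=float(np.mean(hurst_vals)),
        higuchi=float(np.mean(higuchi_vals)),
        alg_conn=ac.integral,
        lz_graph=lz_g.integral,
        dose=dose,
        k_max=k_max,
    )
    for name in METRICS:
        if not np.isfinite(getattr(profile, name)):
            raise ValueError(f"profile rejected: {name} is not finite")
    return profile


def profiles_to_frame(profiles: list[ComplexityProfile]) -> pd.DataFrame:
    return pd.DataFrame([p.as_dict() for p in profiles])


def metric_correlation_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between metric pairs across pooled profiles.

    The diagonal is masked to NaN; a zero-variance metric has its row and
    column masked with a warning.
    """
    if len(profiles) < 4:
        raise ValueError("need at least 4 profiles")
    data = profiles[list(METRICS)].astype(float)
    zero_var = data.std(axis=0) == 0
    if zero_var.any():
        warnings.warn(
            f"zero-variance metric(s) masked: {list(data.columns[zero_var])}",
            RuntimeWarning,
            stacklevel=2,
        )
    corr = data.corr(method="pearson")
    np.fill_diagonal(corr.values, np.nan)
    corr.loc[zero_var, :] = np.nan
    corr.loc[:, zero_var] = np.nan
    return corr


def overall_complexity_pca(profiles: pd.DataFrame) -> dict:
    """First principal component of the standardised metric columns.

    Returns scores, per-metric loadings, and the explained-variance
    fraction. The component sign is a reporting convention only; it is
    oriented so the LZC loading is negative (matching the convention that
    the overall-complexity score rises as sedation deepens). Zero-variance
    metric columns carry no information and are excluded with a warning
    (their loading is reported as 0).
    """
    if len(profiles) < 4:
        raise ValueError("need at least 4 profiles")
    data = profiles[list(METRICS)].astype(float).to_numpy()
    sd = data.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all metric columns constant; PCA undefined")
    if not keep.all():
        dropped = [m for m, k in zip(METRICS, keep) if not k]
        warnings.warn(f"zero-variance metric(s) excluded from PCA: {dropped}",
                      RuntimeWarning, stacklevel=2)
    z = (data[:, keep] - data[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=int(keep.sum()))
    scores = pca.fit_transform(z)
    loadings = np.zeros(len(METRICS))
    loadings[keep] = pca.components_[0]
    pc1 = scores[:, 0]
    anchor = METRICS.index("lzc") if keep[METRICS.index("lzc")] else int(np.argmax(keep))
    if loadings[anchor] > 0:
        loadings = -loadings
        pc1 = -pc1
    return {
        "pc1_scores": pc1,
        "pc1_loadings": pd.Series(loadings, index=METRICS),
        "pc1_variance_explained": float(pca.explained_variance_ratio_[0]),
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }


def _paired_wilcoxon(diffs: np.ndarray) -> tuple[float, float]:
    """Signed-rank test on paired differences; exact null when feasible."""
    if np.all(diffs == 0):
        return 0.0, 1.0
    nonzero = diffs[diffs != 0]
    has_ties = len(np.unique(np.abs(nonzero))) < nonzero.size
    method = "exact" if (nonzero.size <= 25 and not has_ties) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(nonzero, method=method)
    return float(res.statistic), float(res.pvalue)


def group_comparison(
    values: pd.Series, labels: pd.Series, paired_by: pd.Series
) -> dict:
    """Kruskal-Wallis omnibus plus pairwise Wilcoxon signed-rank tests.

    Pairwise tests use within-subject differences; subjects missing from
    either condition are dropped with a warning. The Wilcoxon statistic is
    the smaller signed-rank sum, with the exact small-sample null when there
    are no ties or zeros and n <= 25.
    """
    df = pd.DataFrame({"value": values, "label": labels, "subject": paired_by})
    conditions = list(pd.unique(df["label"]))
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")

    groups = [df.loc[df["label"] == c, "value"].to_numpy() for c in conditions]
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        omnibus = {"H": 0.0, "p": 1.0}
    else:
        h, p = stats.kruskal(*groups)
        omnibus = {"H": float(h), "p": float(p)}

    pairwise = {}
    for i, a in enumerate(conditions):
        for b in conditions[i + 1 :]:
            wide = df[df["label"].isin([a, b])].pivot(
                index="subject", columns="label", values="value"
            )
            complete = wide.dropna()
            if len(complete) < len(wide):
                warnings.warn(
                    f"{len(wide) - len(complete)} unpaired subject(s) dropped "
                    f"for {a} vs {b}",
                    RuntimeWarning,
                    stacklevel=2,
                )
            diffs = (complete[a] - complete[b]).to_numpy(dtype=float)
            w, p = _paired_wilcoxon(diffs)
            pairwise[(a, b)] = {"W": w, "p": p, "n": len(complete)}
    return {"omnibus": omnibus, "pairwise": pairwise}


def dose_correlation(values: pd.Series, dose: pd.Series) -> tuple[float, float]:
    """Pearson correlation of a metric with the dose covariate (sedated scans).

    Zero-dose (awake) profiles must be excluded by the caller; a constant
    dose vector is rejected.
    """
    v = np.asarray(values, dtype=float)
    d = np.asarray(dose, dtype=float)
    mask = np.isfinite(v) & np.isfinite(d) & (d > 0)
    if mask.sum() < 4:
        raise ValueError("need at least 4 profiles with nonzero dose")
    if np.ptp(d[mask]) == 0:
        raise ValueError("constant dose: correlation undefined")
    r, p = stats.pearsonr(v[mask], d[mask])
    return float(r), float(p)


@dataclass
class CohortResult:
    metric_correlations: pd.DataFrame
    pc1_scores: np.ndarray
    pc1_loadings: pd.Series
    pc1_variance_explained: float
    omnibus_tests: dict = field(default_factory=dict)
    pairwise_tests: dict = field(default_factory=dict)
    dose_correlations: dict = field(default_factory=dict)


def analyse_cohort(profiles: pd.DataFrame) -> CohortResult:
    """Run the full higher-order analysis on a pooled profile table.

    Expects columns subject_id, condition, the seven metrics, and optionally
    dose. Dose correlations are computed over sedated (dose > 0) scans only
    and skipped when fewer than 4 such scans exist.
    """
    corr = metric_correlation_matrix(profiles)
    pca_out = overall_complexity_pca(profiles)
    scored = profiles.copy()
    scored["overall"] = pca_out["pc1_scores"]

    omnibus, pairwise = {}, {}
    for name in (*METRICS, "overall"):
        tests = group_comparison(
            scored[name], scored["condition"], scored["subject_id"]
        )
        omnibus[name] = tests["omnibus"]
        pairwise[name] = tests["pairwise"]

    dose_corr = {}
    if "dose" in scored and (scored["dose"].fillna(0) > 0).sum() >= 4:
        sedated = scored[scored["dose"].fillna(0) > 0]
        for name in (*METRICS, "overall"):
            if sedated[name].nunique() > 1:
                dose_corr[name] = dose_correlation(sedated[name], sedated["dose"])
    return CohortResult(
        metric_correlations=corr,
        pc1_scores=pca_out["pc1_scores"],
        pc1_loadings=pca_out["pc1_loadings"],
        pc1_variance_explained=pca_out["pc1_variance_explained"],
        omnibus_tests=omnibus,
        pairwise_tests=pairwise,
        dose_correlations=dose_corr,
    )
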