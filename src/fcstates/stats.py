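"""Group statistics for the three-condition design.

The design compares normal controls (NC) against the same patient cohort
measured twice: at baseline (IBSbs) and after the intervention (IBS1st).
Each feature (an edge's Fisher-z weight, or a node metric) is tested with

* p1 — NC vs IBSbs, two-sample t-test,
* p2 — IBSbs vs IBS1st, paired t-test on the per-patient differences,
* p3 — NC vs IBS1st, two-sample t-test,

with Bonferroni correction applied within each comparison family.  The
significance pattern S(p) = (corrected p < alpha) assigns exactly one
state per feature:

========== =============================
state      pattern
========== =============================
cured      S1 and S2 and not S3
disorder   S1 and not S2
activated  not S1 and S2 and S3
unchanged  anything else
========== =============================

"cured" operationalises "abnormal at baseline, returned to the control
level afterwards" as significance against NC at baseline, a significant
within-patient change, and no remaining difference from NC.  The omnibus
one-way ANOVA across the three conditions is computed and stored per
feature but does not enter the decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "StudyDesign",
    "EdgeStateRecord",
    "DeltaCorrelationResult",
    "two_sample_t",
    "two_sample_t_from_summary",
    "paired_t",
    "one_way_anova",
    "chi_square_test",
    "bonferroni_adjust",
    "pearson_r",
    "p_from_r",
    "assign_state",
    "classify_edge_states",
    "classify_node_metric_states",
    "delta_correlations",
]

TVariant = Literal["welch", "pooled"]
Correction = Literal["bonferroni", "none"]

STATES = ("disorder", "cured", "activated", "unchanged")


@dataclass
class TestResult:
    statistic: float
    kind: str  # t | F | chi2 | r
    df: float | tuple[float, float]
    p: float
    p_corrected: float | None = None
    n: tuple[int, ...] = ()
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p out of range: {self.p}")
        if self.p_corrected is not None and self.p_corrected < self.p - 1e-15:
            raise ValueError("corrected p cannot be below raw p")


@dataclass
class StudyDesign:
    """Subject membership and the patient baseline/post pairing."""

    controls: list[str]
    patients: list[str]

    def __post_init__(self) -> None:
        if len(set(self.controls)) != len(self.controls):
            raise ValueError("duplicate control ids")
        if len(set(self.patients)) != len(self.patients):
            raise ValueError("duplicate patient ids")

    @property
    def n_controls(self) -> int:
        return len(self.controls)

    @property
    def n_patients(self) -> int:
        return len(self.patients)


@dataclass
class EdgeStateRecord:
    feature: tuple  # (roi_i, roi_j) for an edge, (roi, metric) for a node
    nc_vs_bs: TestResult
    bs_vs_1st: TestResult
    nc_vs_1st: TestResult
    anova: TestResult
    state: str
    direction: str  # increase | decrease | none

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")


@dataclass
class DeltaCorrelationResult:
    feature: tuple
    score: str
    r: float
    p: float
    n: int
    feature_deltas: np.ndarray = field(default_factory=lambda: np.array([]))
    score_deltas: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------- test battery

def two_sample_t(x: Sequence[float], y: Sequence[float],
                 variant: TVariant = "welch") -> TestResult:
    """Two-sided two-sample t-test; Welch by default, pooled on request."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return TestResult(float(res.statistic), "t", float(res.df),
                      float(res.pvalue), n=(len(x), len(y)))


def two_sample_t_from_summary(n1: int, mean1: float, sd1: float,
                              n2: int, mean2: float, sd2: float,
                              variant: TVariant = "welch") -> TestResult:
    """Two-sample t-test from sufficient statistics (n, mean, SD)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                   equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return TestResult(float(res.statistic), "t", df, float(res.pvalue), n=(n1, n2))


def paired_t(pre: Sequence[float], post: Sequence[float]) -> TestResult:
    """Paired t-test: one-sample t on the per-subject differences.

    Zero-variance differences are degenerate: the t statistic is infinite
    (or 0 when the differences are all zero); the result is flagged.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre/post must be aligned by subject")
    n = len(pre)
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = post - pre
    if np.ptp(d) == 0:
        if d[0] == 0:
            return TestResult(0.0, "t", float(n - 1), 1.0, n=(n,), degenerate=True)
        t = np.inf if d[0] > 0 else -np.inf
        return TestResult(float(t), "t", float(n - 1), 0.0, n=(n,), degenerate=True)
    res = sps.ttest_rel(post, pre)
    return TestResult(float(res.statistic), "t", float(n - 1),
                      float(res.pvalue), n=(n,))


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA; F on (k-1, N-k) degrees of freedom."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    res = sps.f_oneway(*arrays)
    k = len(arrays)
    n_tot = sum(len(g) for g in arrays)
    return TestResult(float(res.statistic), "F", (float(k - 1), float(n_tot - k)),
                      float(res.pvalue), n=tuple(len(g) for g in arrays))


def chi_square_test(contingency: Sequence[Sequence[int]]) -> TestResult:
    """Pearson chi-square on a 2 x k table, no continuity correction."""
    table = np.asarray(contingency)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("contingency table must hold non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table margins must be positive")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(float(chi2), "chi2", float(dof), float(p),
                      n=tuple(int(x) for x in table.sum(axis=1)))


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """p_adj = min(1, m * p); m defaults to the number of hypotheses."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Sample Pearson r with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need aligned samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), "r", float(len(x) - 2), float(p), n=(len(x),))


def p_from_r(r: float, n: int) -> float:
    """Two-sided p for a correlation via t = r sqrt(n-2)/sqrt(1-r^2)."""
    if not -1.0 < r < 1.0:
        raise ValueError("|r| must be < 1")
    if n < 3:
        raise ValueError("need n >= 3")
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), n - 2))


# -------------------------------------------------------------- state taxonomy

def assign_state(s1: bool, s2: bool, s3: bool) -> str:
    """Map the significance pattern (S1, S2, S3) to a state label."""
    if s1 and s2 and not s3:
        return "cured"
    if s1 and not s2:
        return "disorder"
    if not s1 and s2 and s3:
        return "activated"
    return "unchanged"


def _family_tests(nc: np.ndarray, bs: np.ndarray, post: np.ndarray,
                  variant: TVariant) -> tuple[np.ndarray, ...]:
    """Vectorised p1/p2/p3 (+ statistics, + omnibus F) across feature columns."""
    eq = variant == "pooled"
    t1 = sps.ttest_ind(nc, bs, axis=0, equal_var=eq)
    t2 = sps.ttest_rel(post, bs, axis=0)
    t3 = sps.ttest_ind(nc, post, axis=0, equal_var=eq)
    f = sps.f_oneway(nc, bs, post, axis=0)
    return (np.atleast_1d(t1.statistic), np.atleast_1d(t1.pvalue),
            np.atleast_1d(t2.statistic), np.atleast_1d(t2.pvalue),
            np.atleast_1d(t3.statistic), np.atleast_1d(t3.pvalue),
            np.atleast_1d(f.statistic), np.atleast_1d(f.pvalue))


def _classify_matrix(features: Sequence[tuple], nc: np.ndarray, bs: np.ndarray,
                     post: np.ndarray, alpha: float, correction: Correction,
                     variant: TVariant) -> list[EdgeStateRecord]:
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    n_feat = len(features)
    if nc.shape[1] != n_feat or bs.shape[1] != n_feat or post.shape[1] != n_feat:
        raise ValueError("feature axis mismatch across conditions")
    if bs.shape[0] != post.shape[0]:
        raise ValueError("baseline/post patient rows must be paired")
    stat1, p1, stat2, p2, stat3, p3, fstat, pf = _family_tests(nc, bs, post, variant)
    # NaNs arise only from all-constant columns; treat as no evidence
    for arr in (p1, p2, p3, pf):
        np.nan_to_num(arr, copy=False, nan=1.0)
    if correction == "bonferroni":
        p1c, p2c, p3c = (bonferroni_adjust(p, m=n_feat) for p in (p1, p2, p3))
    else:
        p1c, p2c, p3c = p1.copy(), p2.copy(), p3.copy()
    mean_nc = nc.mean(axis=0)
    mean_bs = bs.mean(axis=0)
    mean_post = post.mean(axis=0)
    n_nc, n_pat = nc.shape[0], bs.shape[0]
    df1 = float(n_nc + n_pat - 2) if variant == "pooled" else np.nan
    records = []
    for k, feat in enumerate(features):
        s1, s2, s3 = p1c[k] < alpha, p2c[k] < alpha, p3c[k] < alpha
        state = assign_state(bool(s1), bool(s2), bool(s3))
        if state in ("disorder", "cured"):
            direction = "increase" if mean_bs[k] > mean_nc[k] else "decrease"
        elif state == "activated":
            direction = "increase" if mean_post[k] > mean_nc[k] else "decrease"
        else:
            direction = "none"
        records.append(EdgeStateRecord(
            feature=feat,
            nc_vs_bs=TestResult(float(stat1[k]), "t", df1, float(p1[k]),
                                float(p1c[k]), n=(n_nc, n_pat)),
            bs_vs_1st=TestResult(float(stat2[k]), "t", float(n_pat - 1),
                                 float(p2[k]), float(p2c[k]), n=(n_pat,)),
            nc_vs_1st=TestResult(float(stat3[k]), "t", df1, float(p3[k]),
                                 float(p3c[k]), n=(n_nc, n_pat)),
            anova=TestResult(float(fstat[k]), "F",
                             (2.0, float(n_nc + 2 * n_pat - 3)), float(pf[k]),
                             n=(n_nc, n_pat, n_pat)),
            state=state,
            direction=direction,
        ))
    return records


def classify_edge_states(nc_weights: np.ndarray, bs_weights: np.ndarray,
                         post_weights: np.ndarray, edges: Sequence[tuple],
                         alpha: float = 0.05,
                         correction: Correction = "bonferroni",
                         variant: TVariant = "welch") -> list[EdgeStateRecord]:
    """Assign a disorder/cured/activated/unchanged state to every edge.

    ``nc_weights`` is (n_controls, n_edges); ``bs_weights`` and
    ``post_weights`` are (n_patients, n_edges) with identical patient row
    order (the pairing).  ``edges`` names each column, e.g. ROI label
    pairs.  The Bonferroni family is all tested edges, applied within each
    of the three comparison families separately.
    """
    return _classify_matrix(list(edges), np.asarray(nc_weights, float),
                            np.asarray(bs_weights, float),
                            np.asarray(post_weights, float),
                            alpha, correction, variant)


def classify_node_metric_states(metric_table: pd.DataFrame, design: StudyDesign,
                                alpha: float = 0.05,
                                correction: Correction = "bonferroni",
                                variant: TVariant = "welch",
                                metrics: Sequence[str] = ("degree", "clustering",
                                                          "local_efficiency"),
                                ) -> list[EdgeStateRecord]:
    """State taxonomy applied per (node, metric) on a tidy metric table.

    The Bonferroni family is all nodes for one metric; each metric forms
    its own family.
    """
    records: list[EdgeStateRecord] = []
    for metric in metrics:
        piv = metric_table.pivot_table(index="subject_id", columns="roi",
                                       values=metric, aggfunc="first")
        rois = list(piv.columns)
        by_session = {
            sess: metric_table[metric_table["session"] == sess]
            .pivot(index="subject_id", columns="roi", values=metric)
            for sess in ("single", "baseline", "post")
        }
        missing = [p for p in design.patients
                   if p not in by_session["baseline"].index
                   or p not in by_session["post"].index]
        if missing:
            raise ValueError(f"patients missing a paired session: {missing}")
        nc = by_session["single"].loc[design.controls, rois].to_numpy(float)
        bs = by_session["baseline"].loc[design.patients, rois].to_numpy(float)
        post = by_session["post"].loc[design.patients, rois].to_numpy(float)
        records.extend(_classify_matrix([(roi, metric) for roi in rois],
                                        nc, bs, post, alpha, correction, variant))
    return records


def delta_correlations(feature_deltas: Mapping[tuple, np.ndarray],
                       clinical: pd.DataFrame, design: StudyDesign,
                       scores: Sequence[str] = ("ibs_sss", "ibs_qol", "hama"),
                       ) -> list[DeltaCorrelationResult]:
    """Correlate per-patient feature changes with clinical-score changes.

    ``feature_deltas`` maps each feature to its per-patient (post minus
    baseline) values, ordered as ``design.patients``.  ``clinical`` is the
    long-format score table (subject_id, session, one column per score);
    the score delta is post minus baseline.  Patients with a missing score
    at either session are dropped from that correlation; n records the
    complete pairs used.
    """
    base = clinical[clinical["session"] == "baseline"].set_index("subject_id")
    post = clinical[clinical["session"] == "post"].set_index("subject_id")
    missing = [p for p in design.patients if p not in base.index or p not in post.index]
    if missing:
        raise ValueError(f"patients missing clinical sessions: {missing}")
    results = []
    for feat, deltas in feature_deltas.items():
        deltas = np.asarray(deltas, dtype=float)
        if len(deltas) != design.n_patients:
            raise ValueError(f"feature {feat}: expected {design.n_patients} deltas")
        for score in scores:
            sc = (post.loc[design.patients, score].to_numpy(float)
                  - base.loc[design.patients, score].to_numpy(float))
            ok = np.isfinite(sc) & np.isfinite(deltas)
            if ok.sum() < 3:
                continue
            res = pearson_r(deltas[ok], sc[ok])
            results.append(DeltaCorrelationResult(
                feature=feat, score=score, r=res.statistic, p=res.p,
                n=int(ok.sum()), feature_deltas=deltas[ok], score_deltas=sc[ok]))
    return results
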