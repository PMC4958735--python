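"""Agreement statistics between automated and visual Ki67 scores.

The validation framework: per-method quartile binning, linearly
weighted kappa with bootstrap confidence intervals, observed agreement,
ROC AUC (at the conventional 10 % visual positivity cut-off) with DeLong
confidence intervals and the DeLong paired test, stratified analyses by
QC category and by machine-counted total nuclei (500-cell bins),
extreme-discrepancy tabulation (Q1 vs Q4 flips), subject-level
averaging, and the count-vs-agreement trend correlation.

Linearly weighted kappa over K ordered categories uses weights
``w_ij = 1 - |i-j|/(K-1)`` and

    kappa = (sum w_ij p_ij - sum w_ij p_i. p_.j) / (1 - sum w_ij p_i. p_.j)

with the observed joint distribution ``p_ij`` and its marginals.  At
K = 2 this reduces to the unweighted Cohen kappa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

DICHOTOMY_CUTOFF = 10.0  # % positive cells; the conventional visual cut-off
DEFAULT_BOOTSTRAP = 2000

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")

NUCLEI_BIN_EDGES = (50, 500, 1000, 1500, 2000, 2500, 3000, 3500, 4000, 4500)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def quartile_bin(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bin scores into quartile categories 1-4 of their own distribution.

    Boundaries are the 25th/50th/75th percentiles (linear
    interpolation).  Interval convention: Q1 strictly below the 25th
    percentile, Q2 from the 25th through the 50th, Q3 above the 50th
    through the 75th, Q4 above the 75th — a value exactly on the 25th
    percentile belongs to Q2, one exactly on the 50th to Q2, one exactly
    on the 75th to Q3.

    Returns (categories as int 1..4, boundaries array of length 3).
    A degenerate all-equal vector yields all Q1 (single-bin).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN; drop undefined scores first")
    if np.ptp(scores) == 0:
        warnings.warn("degenerate score distribution: all values equal, single-bin output")
        return np.ones(scores.shape, dtype=int), np.full(3, scores.flat[0], dtype=float)
    q25, q50, q75 = np.percentile(scores, [25, 50, 75])
    cats = np.ones(scores.shape, dtype=int)
    cats[scores >= q25] = 2
    cats[scores > q50] = 3
    cats[scores > q75] = 4
    return cats, np.array([q25, q50, q75])


def nuclei_bin(totals: np.ndarray) -> np.ndarray:
    """Bin machine total-nuclei counts at 500-cell intervals.

    Labels: ``50-500``, ``>500-1,000`` ... ``>4,000-4,500``, ``>4,500``
    (everything above 4,500 pooled).  Counts below 50 should already be
    QC-excluded and raise an error.
    """
    totals = np.asarray(totals)
    if (totals < NUCLEI_BIN_EDGES[0]).any():
        raise ValueError("total nuclei count below 50: core should have been QC-excluded")
    labels = ["50-500"] + [
        f">{lo:,}-{hi:,}" for lo, hi in zip(NUCLEI_BIN_EDGES[1:-1], NUCLEI_BIN_EDGES[2:])
    ] + [">4,500"]
    idx = np.searchsorted(NUCLEI_BIN_EDGES[1:], totals, side="left")
    return np.array([labels[i] for i in idx])


# ---------------------------------------------------------------------------
# kappa and observed agreement
# ---------------------------------------------------------------------------

def _validate_pair(cat_a, cat_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(cat_a)
    b = np.asarray(cat_b)
    if a.shape != b.shape:
        raise ValueError(f"rating vectors differ in length: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty rating vectors")
    return a, b


def linear_weighted_kappa_point(cat_a, cat_b, n_categories: int | None = None) -> float:
    """Point estimate of the linearly weighted kappa (categories 1..K)."""
    a, b = _validate_pair(cat_a, cat_b)
    a = a.astype(int)
    b = b.astype(int)
    k = int(n_categories or max(a.max(), b.max()))
    if k < 2:
        return 1.0 if (a == b).all() else float("nan")
    joint = np.zeros((k, k))
    np.add.at(joint, (a - 1, b - 1), 1.0)
    joint /= joint.sum()
    pa, pb = joint.sum(axis=1), joint.sum(axis=0)
    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    w = 1.0 - np.abs(ii - jj) / (k - 1)
    po = float((w * joint).sum())
    pe = float((w * np.outer(pa, pb)).sum())
    if pe == 1.0:
        return 1.0 if po == 1.0 else float("nan")
    return (po - pe) / (1.0 - pe)


def _bootstrap_ci(
    stat, a: np.ndarray, b: np.ndarray, n_boot: int, seed: int, level: float = 0.95
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = len(a)
    vals = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        vals[i] = stat(a[idx], b[idx])
    vals = vals[~np.isnan(vals)]
    lo = (1 - level) / 2
    return tuple(np.percentile(vals, [100 * lo, 100 * (1 - lo)]))


def weighted_kappa(
    cat_a,
    cat_b,
    n_categories: int | None = None,
    n_boot: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
) -> dict:
    """Linearly weighted kappa with a seeded percentile-bootstrap 95 % CI.

    Returns ``{"kappa", "ci", "n", "se"}`` where ``se`` is the bootstrap
    standard error (used by the kappa-comparison test).
    """
    a, b = _validate_pair(cat_a, cat_b)
    point = linear_weighted_kappa_point(a, b, n_categories)
    stat = lambda x, y: linear_weighted_kappa_point(x, y, n_categories)  # noqa: E731
    rng = np.random.default_rng(seed)
    n = len(a)
    vals = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        vals[i] = stat(a[idx], b[idx])
    vals = vals[~np.isnan(vals)]
    ci = tuple(np.percentile(vals, [2.5, 97.5])) if len(vals) else (float("nan"),) * 2
    se = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
    return {"kappa": point, "ci": ci, "n": n, "se": se}


def observed_agreement(cat_a, cat_b, n_boot: int = DEFAULT_BOOTSTRAP, seed: int = 0) -> dict:
    """Exact-category agreement in % with a seeded bootstrap 95 % CI."""
    a, b = _validate_pair(cat_a, cat_b)
    point = 100.0 * float(np.mean(a == b))
    ci = _bootstrap_ci(lambda x, y: 100.0 * np.mean(x == y), a, b, n_boot, seed)
    return {"agreement": point, "ci": ci, "n": len(a)}


def compare_kappa(
    cat_a1,
    cat_b1,
    cat_a2,
    cat_b2,
    n_categories: int | None = None,
    n_boot: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
    min_n: int = 10,
) -> dict:
    """Two-sided z-test for a kappa difference between independent strata.

    Standard errors come from each stratum's seeded bootstrap; the
    method is recorded in the returned report.
    """
    for name, (a, b) in {"stratum_1": (cat_a1, cat_b1), "stratum_2": (cat_a2, cat_b2)}.items():
        a, b = _validate_pair(a, b)
        if len(a) < min_n:
            raise ValueError(f"{name} has n={len(a)} < {min_n}; too small to compare kappas")
    k1 = weighted_kappa(cat_a1, cat_b1, n_categories, n_boot=n_boot, seed=seed)
    k2 = weighted_kappa(cat_a2, cat_b2, n_categories, n_boot=n_boot, seed=seed + 1)
    delta = k1["kappa"] - k2["kappa"]
    se = float(np.hypot(k1["se"], k2["se"]))
    z = delta / se if se > 0 else float("nan")
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else float("nan")
    return {
        "delta_kappa": delta,
        "z": z,
        "p_value": float(p),
        "kappa_1": k1,
        "kappa_2": k2,
        "method": "bootstrap z-test",
    }


# ---------------------------------------------------------------------------
# ROC / AUC (DeLong)
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong covariance machinery for one or more score vectors.

    ``scores`` has shape (k, n).  Returns (aucs of shape (k,), covariance
    matrix of shape (k, k)).
    """
    labels = np.asarray(labels, dtype=bool)
    pos = scores[:, labels]
    neg = scores[:, ~labels]
    m, n = pos.shape[1], neg.shape[1]
    if m == 0 or n == 0:
        raise ValueError("AUC undefined: both label classes must be present")
    k = scores.shape[0]
    aucs = np.empty(k)
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    for r in range(k):
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(np.concatenate([pos[r], neg[r]]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    def _cov(v: np.ndarray) -> np.ndarray:
        if v.shape[1] < 2:  # a single case/control gives no variance information
            return np.full((k, k), np.nan)
        return np.atleast_2d(np.cov(v))

    cov = _cov(v01) / m + _cov(v10) / n
    return aucs, np.atleast_2d(cov)


def roc_auc(scores, labels, ci_level: float = 0.95) -> dict:
    """AUC of continuous scores against binary labels, with DeLong CI.

    The AUC equals the Mann-Whitney probability with half credit for
    ties.  Raises when only one label class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if labels.all() or (~labels).all():
        raise ValueError("AUC undefined: both label classes must be present")
    auc = float(roc_auc_score(labels, scores))
    _, cov = _delong_variance(scores[None, :], labels)
    se = float(np.sqrt(cov[0, 0]))
    zq = stats.norm.ppf(0.5 + ci_level / 2)
    ci = (max(0.0, auc - zq * se), min(1.0, auc + zq * se))
    return {"auc": auc, "ci": ci, "se": se, "n": len(scores)}


def dichotomize(visual_scores, cutoff: float = DICHOTOMY_CUTOFF) -> np.ndarray:
    """Binary positivity labels: visual score >= cutoff (default 10 %)."""
    return np.asarray(visual_scores, dtype=float) >= cutoff


def compare_auc(scores_a, scores_b, labels) -> dict:
    """DeLong two-sided paired test for a difference between two AUCs
    computed against the same labels on the same units."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if not (a.shape == b.shape == labels.shape):
        raise ValueError("paired AUC comparison requires equal-length score/label vectors")
    aucs, cov = _delong_variance(np.vstack([a, b]), labels)
    delta = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    if var <= 0:
        return {"delta_auc": delta, "z": 0.0, "p_value": 1.0, "aucs": tuple(aucs)}
    z = delta / np.sqrt(var)
    return {
        "delta_auc": delta,
        "z": float(z),
        "p_value": float(2.0 * stats.norm.sf(abs(z))),
        "aucs": (float(aucs[0]), float(aucs[1])),
    }


# ---------------------------------------------------------------------------
# discrepancy, trend, aggregation
# ---------------------------------------------------------------------------

def extreme_discrepancy(cat_a, cat_b) -> dict:
    """Rate of extreme quartile flips: one method Q1 while the other is Q4."""
    a, b = _validate_pair(cat_a, cat_b)
    flips = ((a == 1) & (b == 4)) | ((a == 4) & (b == 1))
    return {"rate_percent": 100.0 * float(flips.mean()), "count": int(flips.sum()), "n": len(a)}


def agreement_trend(bin_mean_counts, metric_values) -> dict:
    """Pearson correlation between per-bin mean nuclei count and an
    agreement metric, with a two-sided t-test."""
    x = np.asarray(bin_mean_counts, dtype=float)
    y = np.asarray(metric_values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 bins for a trend correlation")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return {"r": float("nan"), "p_value": float("nan"), "degenerate": True}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p_value": float(p), "degenerate": False}


def subject_average(scores: pd.DataFrame, passing_core_ids: set[str] | None = None) -> pd.DataFrame:
    """Average core scores to the subject level over QC-passing cores.

    ``scores`` needs columns ``subject_id``, ``core_id``, ``score``.
    Cores outside ``passing_core_ids`` (when given) are dropped;
    subjects left without any passing core are dropped and counted in
    the ``attrs['n_subjects_dropped']`` of the returned frame.
    """
    required = {"subject_id", "core_id", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores table must have columns {sorted(required)}")
    all_subjects = scores["subject_id"].nunique()
    kept = scores
    if passing_core_ids is not None:
        kept = scores[scores["core_id"].isin(passing_core_ids)]
    kept = kept.dropna(subset=["score"])
    out = kept.groupby("subject_id", as_index=False)["score"].mean()
    out.attrs["n_subjects_dropped"] = int(all_subjects - out["subject_id"].nunique())
    return out


# ---------------------------------------------------------------------------
# high-level report
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Kappa / observed agreement / AUC (with CIs) for one set of pairs."""

    n: int
    kappa: float
    kappa_ci: tuple[float, float]
    agreement_percent: float
    agreement_ci: tuple[float, float]
    auc: float | None
    auc_ci: tuple[float, float] | None
    extreme_discrepancy_percent: float
    strata: dict[str, "AgreementReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "kappa": self.kappa,
            "kappa_ci": list(self.kappa_ci),
            "observed_agreement": self.agreement_percent,
            "observed_agreement_ci": list(self.agreement_ci),
            "auc": self.auc,
            "auc_ci": list(self.auc_ci) if self.auc_ci else None,
            "extreme_discrepancy_percent": self.extreme_discrepancy_percent,
        }
        if self.strata:
            d["strata"] = {k: v.to_dict() for k, v in self.strata.items()}
        return d


def agreement_report(
    auto_scores,
    visual_scores,
    strata: np.ndarray | None = None,
    cutoff: float = DICHOTOMY_CUTOFF,
    pooled_quartiles: bool = True,
    n_boot: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
) -> AgreementReport:
    """Full agreement analysis of paired automated vs visual scores.

    Quartile categories are computed per method (each against its own
    distribution); with ``pooled_quartiles`` the boundaries come from
    the whole analysis set, otherwise they are re-derived inside each
    stratum.  AUC uses the continuous automated score against visual
    positivity at ``cutoff``; it is None when the dichotomized labels
    are single-class.
    """
    auto = np.asarray(auto_scores, dtype=float)
    vis = np.asarray(visual_scores, dtype=float)
    if auto.shape != vis.shape:
        raise ValueError("paired score vectors differ in length")

    def build(auto_s, vis_s, cat_a, cat_v, seed_offset: int) -> AgreementReport:
        kap = weighted_kappa(cat_a, cat_v, 4, n_boot=n_boot, seed=seed + seed_offset)
        agr = observed_agreement(cat_a, cat_v, n_boot=n_boot, seed=seed + seed_offset)
        labels = dichotomize(vis_s, cutoff)
        if labels.all() or (~labels).all():
            auc_res = None
        else:
            auc_res = roc_auc(auto_s, labels)
        disc = extreme_discrepancy(cat_a, cat_v)
        return AgreementReport(
            n=len(auto_s),
            kappa=kap["kappa"],
            kappa_ci=kap["ci"],
            agreement_percent=agr["agreement"],
            agreement_ci=agr["ci"],
            auc=auc_res["auc"] if auc_res else None,
            auc_ci=auc_res["ci"] if auc_res else None,
            extreme_discrepancy_percent=disc["rate_percent"],
        )

    cat_auto, _ = quartile_bin(auto)
    cat_vis, _ = quartile_bin(vis)
    report = build(auto, vis, cat_auto, cat_vis, 0)
    if strata is not None:
        strata = np.asarray(strata)
        for off, s in enumerate(pd.unique(strata), start=1):
            m = strata == s
            if m.sum() < 4:
                continue
            if pooled_quartiles:
                ca, cv = cat_auto[m], cat_vis[m]
            else:
                ca, _ = quartile_bin(auto[m])
                cv, _ = quartile_bin(vis[m])
            report.strata[str(s)] = build(auto[m], vis[m], ca, cv, off)
    return report
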