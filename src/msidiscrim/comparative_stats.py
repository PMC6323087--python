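"""Cancer-vs-epithelium comparative statistics on molecular components.

Per component: coefficient of variation, Lilliefors normality and F-test
variance screens (descriptive), Mann-Whitney U with Benjamini-Hochberg
control across the domain, and a robust effect size from trimmed means over
a pooled Winsorized SD, banded into negligible / medium / large /
very-large categories at 0.5 / 0.8 / 1.2.  Also the mean-spectrum
similarity-index curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .io_core import FeatureTable, RoiMask, ValidationError

EFFECT_THRESHOLDS = (0.5, 0.8, 1.2)
EFFECT_NAMES = ("negligible", "medium", "large", "very_large")


@dataclass
class EffectRecord:
    component_id: float
    cv_all: float
    cv_cancer: float
    cv_epithelium: float
    lilliefors_p: float
    f_test_p: float
    u_stat: float
    p_raw: float
    p_adj: float
    d: float
    category: str


def _split_groups(
    table: FeatureTable, mask: RoiMask
) -> tuple[np.ndarray, np.ndarray]:
    mask.require_two_groups()
    cancer = table.abundances[:, mask.labels == "cancer"]
    epith = table.abundances[:, mask.labels == "epithelium"]
    return cancer, epith


def _cv(x: np.ndarray, axis: int = -1) -> np.ndarray:
    mean = x.mean(axis=axis)
    sd = x.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mean > 0, sd / mean, np.nan)
    return out


def cv_per_component(table: FeatureTable, mask: RoiMask) -> pd.DataFrame:
    """CV = sample SD / mean, overall and per ROI; zero means give NaN."""
    cancer, epith = _split_groups(table, mask)
    if cancer.shape[1] < 2 or epith.shape[1] < 2:
        raise ValidationError("need >= 2 pixels per group for CV")
    assigned = table.abundances[:, mask.labels != "unassigned"]
    return pd.DataFrame(
        {
            "component_id": table.component_ids,
            "cv_all": _cv(assigned),
            "cv_cancer": _cv(cancer),
            "cv_epithelium": _cv(epith),
        }
    )


def distribution_screens(table: FeatureTable, mask: RoiMask) -> pd.DataFrame:
    """Lilliefors normality p (on assigned pixels) and two-sided variance
    F-test p between cancer and epithelium, per component."""
    cancer, epith = _split_groups(table, mask)
    n1, n2 = cancer.shape[1], epith.shape[1]
    if n1 < 5 or n2 < 5:
        raise ValidationError("need >= 5 pixels per group for screens")
    lf_p = np.empty(table.n_components)
    f_p = np.empty(table.n_components)
    for i in range(table.n_components):
        joint = np.concatenate([cancer[i], epith[i]])
        if np.ptp(joint) == 0:
            lf_p[i] = np.nan
        else:
            _, lf_p[i] = lilliefors(joint, dist="norm")
        v1, v2 = cancer[i].var(ddof=1), epith[i].var(ddof=1)
        if v1 == 0 or v2 == 0:
            f_p[i] = np.nan
            continue
        f = v1 / v2
        p = stats.f.sf(f, n1 - 1, n2 - 1)
        f_p[i] = min(1.0, 2.0 * min(p, 1.0 - p))
    return pd.DataFrame(
        {
            "component_id": table.component_ids,
            "lilliefors_p": lf_p,
            "f_test_p": f_p,
        }
    )


def mw_bh_test(
    table: FeatureTable, mask: RoiMask, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per component, BH-adjusted across the
    domain.  Exact enumeration when both groups have <= 8 pixels."""
    cancer, epith = _split_groups(table, mask)
    exact = cancer.shape[1] <= 8 and epith.shape[1] <= 8
    u = np.empty(table.n_components)
    p = np.empty(table.n_components)
    for i in range(table.n_components):
        if np.ptp(np.concatenate([cancer[i], epith[i]])) == 0:
            u[i], p[i] = cancer.shape[1] * epith.shape[1] / 2.0, 1.0
            continue
        method = "exact" if exact else "asymptotic"
        res = stats.mannwhitneyu(
            cancer[i], epith[i], alternative="two-sided", method=method
        )
        u[i], p[i] = res.statistic, res.pvalue
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "component_id": table.component_ids,
            "u_stat": u,
            "p_raw": p,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        }
    )


def _winsorized_var(x: np.ndarray, trim: float) -> float:
    n = x.size
    g = int(np.floor(trim * n))
    xs = np.sort(x)
    w = xs.copy()
    w[:g] = xs[g]
    w[n - g :] = xs[n - g - 1]
    return float(w.var(ddof=1))


def cohens_d_robust(x: np.ndarray, y: np.ndarray, trim: float = 0.2) -> float:
    """(trimmed mean x - trimmed mean y) / pooled Winsorized SD.

    Pooling weights each group's Winsorized variance by (size - 1); at
    ``trim = 0`` this is the classical pooled-SD Cohen's d.  Sign convention
    is first argument minus second (cancer minus epithelium).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5 or y.size < 5:
        raise ValidationError("need >= 5 observations per group")
    if not 0.0 <= trim < 0.5:
        raise ValidationError("trim must be in [0, 0.5)")
    tmx = stats.trim_mean(x, trim) if trim > 0 else x.mean()
    tmy = stats.trim_mean(y, trim) if trim > 0 else y.mean()
    vx, vy = _winsorized_var(x, trim), _winsorized_var(y, trim)
    pooled = np.sqrt(
        ((x.size - 1) * vx + (y.size - 1) * vy) / (x.size + y.size - 2)
    )
    if pooled == 0:
        return float(np.inf) if tmx != tmy else 0.0
    return float((tmx - tmy) / pooled)


def effect_category(d: float) -> str:
    """|d| <= 0.5 negligible; (0.5, 0.8] medium; (0.8, 1.2] large; above
    very_large (boundaries belong to the lower category)."""
    if not np.isfinite(d):
        raise ValidationError("effect size must be finite")
    a = abs(d)
    if a <= EFFECT_THRESHOLDS[0]:
        return EFFECT_NAMES[0]
    if a <= EFFECT_THRESHOLDS[1]:
        return EFFECT_NAMES[1]
    if a <= EFFECT_THRESHOLDS[2]:
        return EFFECT_NAMES[2]
    return EFFECT_NAMES[3]


def effect_records(
    table: FeatureTable, mask: RoiMask, alpha: float = 0.05, trim: float = 0.2
) -> pd.DataFrame:
    """Full per-component table: CVs, screens, U/p/p_adj, d and category."""
    cvs = cv_per_component(table, mask)
    screens = distribution_screens(table, mask)
    mw = mw_bh_test(table, mask, alpha=alpha)
    cancer, epith = _split_groups(table, mask)
    d = np.array(
        [cohens_d_robust(cancer[i], epith[i], trim) for i in range(table.n_components)]
    )
    cat = np.array(
        [effect_category(v) if np.isfinite(v) else "very_large" for v in d],
        dtype=object,
    )
    out = cvs.merge(screens, on="component_id").merge(mw, on="component_id")
    out["d"] = d
    out["category"] = cat
    return out


def similarity_index(
    mean_a: np.ndarray,
    mean_b: np.ndarray,
    top_n: int | np.ndarray,
) -> float | np.ndarray:
    """Cosine similarity of sqrt-transformed mean abundances over the
    ``top_n`` components ranked by combined mean abundance."""
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("mean vectors must share shape")
    order = np.argsort(-(a + b), kind="stable")
    scalar = np.isscalar(top_n)
    tops = np.atleast_1d(np.asarray(top_n, dtype=int))
    if np.any(tops > a.size) or np.any(tops < 1):
        raise ValidationError("top_n out of range")
    out = np.empty(tops.size)
    sa, sb = np.sqrt(np.clip(a, 0, None)), np.sqrt(np.clip(b, 0, None))
    for i, t in enumerate(tops):
        idx = order[:t]
        na, nb = np.linalg.norm(sa[idx]), np.linalg.norm(sb[idx])
        if na == 0 or nb == 0:
            out[i] = np.nan
        else:
            out[i] = float(np.dot(sa[idx], sb[idx]) / (na * nb))
    return float(out[0]) if scalar else out


def similarity_curve(
    table: FeatureTable, mask: RoiMask, top_ns: np.ndarray | None = None
) -> pd.DataFrame:
    """Similarity index of cancer vs epithelium mean component vectors for a
    range of top-N values."""
    cancer, epith = _split_groups(table, mask)
    ma, mb = cancer.mean(axis=1), epith.mean(axis=1)
    if top_ns is None:
        top_ns = np.unique(
            np.round(np.geomspace(1, table.n_components, 20)).astype(int)
        )
    sims = similarity_index(ma, mb, top_ns)
    return pd.DataFrame({"top_n": top_ns, "similarity": sims})
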