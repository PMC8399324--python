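"""Whole-dataset endpoint models and descriptive summaries.

Complements the block screen with cohort-level views: univariate linear
models of each candidate metabolite on the pregnancy endpoints adjusted
for the fixed factors (with Bonferroni control over the candidate
family), taxonomy x endpoint x cryopreservation tallies of predictive
blocks, the AUC-versus-sample-number summary, and descriptive pregnancy
rate tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .config import ENDPOINTS
from .screen import ScreenHit

FIXED_FACTORS = ("cryo", "culture", "breed", "stage0h", "stage24h", "age")


@dataclass
class EndpointModelResult:
    feature_id: str
    endpoint: str
    p_value: float
    degenerate: bool = False

    def bonferroni_pass(self, level: float, m: int) -> bool:
        """Family control: raw p below level / m over m candidates."""
        return (not self.degenerate) and self.p_value <= level / m


def fit_endpoint_model(
    feature_values: pd.Series,
    samples: pd.DataFrame,
    endpoint: str,
    feature_id: str = "",
) -> EndpointModelResult:
    """OLS of net intensity on the fixed factors plus the endpoint term.

    Intensities are continuous, so the linear model uses a Gaussian
    identity link.  For the binary endpoints the reported p is the Wald
    test of the endpoint coefficient; for the three-way miscarriage
    contrast (term birth vs post-Day-40 loss vs open) it is the F-test of
    the outcome factor.
    """
    data = samples.set_index("sample_id").copy()
    data["y"] = feature_values.reindex(data.index)
    if data["y"].nunique() <= 1:
        return EndpointModelResult(feature_id, endpoint, 1.0, degenerate=True)
    if endpoint == "miscarriage":
        outcome = np.where(
            data["Birth"] == 1, "term",
            np.where(data["D40"] == 1, "late_loss", "open"),
        )
        data["outcome"] = pd.Categorical(outcome, categories=["open", "late_loss", "term"])
        term = "C(outcome)"
    else:
        if endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {endpoint!r}")
        data["outcome"] = data[endpoint].astype(float)
        term = "outcome"
    factor_terms = []
    for f in FIXED_FACTORS:
        if f in data.columns and data[f].nunique() > 1:
            factor_terms.append(f"C({f})")
    formula = "y ~ " + " + ".join(factor_terms + [term]) if factor_terms else f"y ~ {term}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.ols(formula, data=data).fit()
        if endpoint == "miscarriage":
            try:
                anova = sm.stats.anova_lm(model, typ=2)
                p = float(anova.loc["C(outcome)", "PR(>F)"])
            except Exception:
                p = 1.0
        else:
            p = float(model.pvalues.get("outcome", 1.0))
    if not np.isfinite(p):
        return EndpointModelResult(feature_id, endpoint, 1.0, degenerate=True)
    return EndpointModelResult(feature_id, endpoint, p)


def endpoint_model_table(
    net: pd.DataFrame,
    samples: pd.DataFrame,
    candidate_features: list[str],
    levels: tuple[float, float] = (0.05, 0.10),
) -> pd.DataFrame:
    """Per-candidate endpoint p-values with Bonferroni flags.

    The Bonferroni family is the candidate-metabolite set identified by
    the block screen (size m = len(candidate_features)), per endpoint.
    """
    m = max(len(candidate_features), 1)
    wide = net.set_index("feature_id")
    sample_cols = [c for c in wide.columns if c in set(samples["sample_id"])]
    rows = []
    for fid in candidate_features:
        vals = wide.loc[fid, sample_cols]
        for endpoint in list(ENDPOINTS) + ["miscarriage"]:
            res = fit_endpoint_model(vals, samples, endpoint, feature_id=fid)
            passed = [lvl for lvl in levels if res.bonferroni_pass(lvl, m)]
            rows.append(
                {
                    "feature_id": fid,
                    "endpoint": endpoint,
                    "p_value": res.p_value,
                    "bonferroni_level": min(passed) if passed else np.nan,
                    "degenerate": int(res.degenerate),
                }
            )
    return pd.DataFrame(rows)


def _cryo_status(hit: ScreenHit) -> str:
    if hit.block.cryo is None:
        return "FF"          # independent of cryopreservation
    return "Fz" if hit.block.cryo == "frozen" else "Fh"


def tally_by_class(
    hits: list[ScreenHit], taxonomy_map: dict[str, object]
) -> pd.DataFrame:
    """Cross-tabulate predictive blocks by taxonomy class, endpoint and
    cryopreservation status (Fz frozen / Fh fresh / FF independent)."""
    rows = []
    for h in hits:
        rows.append(
            {
                "feature_id": h.feature_id,
                "class": taxonomy_map.get(h.feature_id, "unknown"),
                "endpoint": h.block.endpoint,
                "cryo_status": _cryo_status(h),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["class", "endpoint", "cryo_status", "n_blocks"]
        )
    df = pd.DataFrame(rows)
    tally = (
        df.groupby(["class", "endpoint", "cryo_status"], observed=True)
        .size()
        .rename("n_blocks")
        .reset_index()
    )
    return tally


def endpoint_heatmap(hits: list[ScreenHit]) -> pd.DataFrame:
    """Metabolite x endpoint block counts, ranked by total blocks."""
    rows = [{"feature_id": h.feature_id, "endpoint": h.block.endpoint} for h in hits]
    if not rows:
        return pd.DataFrame(columns=list(ENDPOINTS) + ["Total"])
    df = pd.DataFrame(rows)
    mat = df.pivot_table(
        index="feature_id", columns="endpoint", aggfunc="size", fill_value=0
    )
    for ep in ENDPOINTS:
        if ep not in mat.columns:
            mat[ep] = 0
    mat = mat[list(ENDPOINTS)]
    mat["Total"] = mat.sum(axis=1)
    return mat.sort_values("Total", ascending=False)


def auc_vs_n_summary(
    hits: list[ScreenHit], bin_edges: list[float] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Binned AUC / p-value means versus block sample count, with Pearson
    correlations over the hit list (p-values reported on a x10 scale in
    the binned table for visual comparability with AUC)."""
    if bin_edges is None:
        bin_edges = [0, 9, 12, 15, 18, 21, 27, np.inf]
    ns = np.array([h.block.n_pregnant + h.block.n_open for h in hits], dtype=float)
    aucs = np.array([h.auc for h in hits], dtype=float)
    ps = np.array([h.p1 for h in hits], dtype=float)
    if len(set(ns)) < 2:
        raise ValueError("need at least two distinct sample counts")
    cats = pd.cut(ns, bins=bin_edges)
    summary = []
    for interval in cats.categories:
        mask = cats == interval
        k = int(mask.sum())
        if k == 0:
            summary.append(
                {"bin": str(interval), "n_hits": 0, "auc_mean": np.nan,
                 "auc_sem": np.nan, "p10_mean": np.nan, "p10_sem": np.nan}
            )
            continue
        summary.append(
            {
                "bin": str(interval),
                "n_hits": k,
                "auc_mean": float(aucs[mask].mean()),
                "auc_sem": float(aucs[mask].std(ddof=1) / np.sqrt(k)) if k > 1 else np.nan,
                "p10_mean": float((ps[mask] * 10).mean()),
                "p10_sem": float((ps[mask] * 10).std(ddof=1) / np.sqrt(k)) if k > 1 else np.nan,
            }
        )
    def _pearson(x, y):
        # a constant series carries no trend: report r = 0 rather than NaN
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return 0.0, 1.0
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)

    r_auc, p_auc = _pearson(aucs, ns)
    r_p, p_p = _pearson(ps, ns)
    corr = {
        "r_auc_vs_n": float(r_auc),
        "p_auc_vs_n": float(p_auc),
        "r_p_vs_n": float(r_p),
        "p_p_vs_n": float(p_p),
    }
    return pd.DataFrame(summary), corr


def pregnancy_rate_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Descriptive pregnancy rates per (cryo, culture, age) group.

    Counts and percentages (one decimal) at each endpoint.  Samples
    flagged ``exclude_birth`` (e.g. recipient deceased before term) are
    excluded from the birth denominator only; the cell is then rendered
    as ``count/denominator (pct)``.
    """
    rows = []
    for (cryo, culture, age), grp in samples.groupby(
        ["cryo", "culture", "age"], observed=True
    ):
        n = len(grp)
        row = {"cryo": cryo, "culture": culture, "age": age, "n": n}
        for ep in ENDPOINTS:
            sub = grp
            denom = n
            if ep == "Birth" and "exclude_birth" in grp.columns:
                sub = grp[grp["exclude_birth"] == 0]
                denom = len(sub)
            count = int(sub[ep].sum())
            pct = 100.0 * count / denom if denom else 0.0
            if denom == n:
                cell = f"{count} ({pct:.1f})"
            else:
                cell = f"{count}/{denom} ({pct:.1f})"
            row[ep] = cell
            row[f"{ep}_count"] = count
            row[f"{ep}_denom"] = denom
            row[f"{ep}_pct"] = round(pct, 1)
        rows.append(row)
    return pd.DataFrame(rows)
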