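"""Feature-table post-processing: from raw aligned peak areas to the
blank-subtracted analysis matrix.

The pipeline order is fixed and recorded in the processing log:

1. average duplicate injections,
2. consistency filter (a feature must be observed in at least 80% of the
   samples of at least one comparison group),
3. missing-value cap (25%) and iterative random-forest imputation,
4. total-intensity normalization (every sample scaled to the grand mean
   of sample totals; blanks are scaled to the same target),
5. subtraction of the matched culture-batch blank, preserving negative
   net values, which represent consumption of medium constituents.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .config import RunConfig

META_COLUMNS = ("feature_id", "rt_min", "mz")
_REPLICATE_RE = re.compile(r"^(?P<sample>.+)_r(?P<rep>\d+)$")


@dataclass
class ProcessingLog:
    """Per-feature drop reasons and all scale factors, for the sidecar."""

    steps: list[str] = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)   # feature_id -> reason
    sample_scale: dict[str, float] = field(default_factory=dict)
    blank_scale: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "steps": self.steps,
            "dropped": self.dropped,
            "sample_scale": self.sample_scale,
            "blank_scale": self.blank_scale,
        }


def _split_meta(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    meta_cols = [c for c in META_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c in ("constituent", "net_sign")]
    meta = table[meta_cols + extra]
    values = table.drop(columns=meta_cols + extra)
    return meta, values


def average_replicates(raw: pd.DataFrame) -> pd.DataFrame:
    """Collapse ``<sample>_r<k>`` injection columns to one column per sample.

    A cell is the arithmetic mean of its non-missing replicates and stays
    missing only when every replicate is missing.
    """
    meta, values = _split_meta(raw)
    groups: dict[str, list[str]] = {}
    for col in values.columns:
        m = _REPLICATE_RE.match(str(col))
        sample = m.group("sample") if m else str(col)
        groups.setdefault(sample, []).append(col)
    out = meta.copy()
    for sample, cols in groups.items():
        out[sample] = values[cols].mean(axis=1, skipna=True)
    return out


def consistency_filter(
    table: pd.DataFrame,
    group_labels: pd.Series | np.ndarray,
    threshold: float = 0.8,
    log: ProcessingLog | None = None,
) -> pd.DataFrame:
    """Keep features observed in >= ``threshold`` of at least one group.

    ``group_labels`` assigns each sample column to a comparison group
    (default downstream usage: the pregnancy endpoint classes).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    meta, values = _split_meta(table)
    labels = pd.Series(np.asarray(group_labels), index=values.columns)
    if labels.isna().all() or len(labels) == 0:
        raise ValueError("empty group labels")
    keep = np.zeros(len(table), dtype=bool)
    for _, cols in labels.groupby(labels):
        group_cols = list(cols.index)
        if not group_cols:
            raise ValueError("empty group")
        frac = values[group_cols].notna().mean(axis=1)
        keep |= (frac >= threshold).to_numpy()
    if log is not None:
        log.steps.append(f"consistency_filter(threshold={threshold})")
        for fid in table.loc[~keep, "feature_id"]:
            log.dropped[str(fid)] = "consistency"
    return table.loc[keep].reset_index(drop=True)


def impute_missing(
    table: pd.DataFrame,
    max_missing_fraction: float = 0.25,
    seed: int = 0,
    n_estimators: int = 25,
    max_iter: int = 3,
    log: ProcessingLog | None = None,
) -> pd.DataFrame:
    """Drop features missing in more than ``max_missing_fraction`` of
    samples, then impute the rest with iterative random-forest regression
    on the other features (missForest-style), clipping imputed values to
    each feature's observed range.
    """
    meta, values = _split_meta(table)
    frac_missing = values.isna().mean(axis=1)
    if (frac_missing >= 1.0).any():
        bad = table.loc[frac_missing >= 1.0, "feature_id"].tolist()
        raise ValueError(f"all-missing features reached imputation: {bad}")
    keep = (frac_missing <= max_missing_fraction).to_numpy()
    if log is not None:
        log.steps.append(
            f"impute_missing(max_missing_fraction={max_missing_fraction}, seed={seed})"
        )
        for fid in table.loc[~keep, "feature_id"]:
            log.dropped[str(fid)] = "missingness"
    meta = meta.loc[keep].reset_index(drop=True)
    values = values.loc[keep].reset_index(drop=True)
    if not values.isna().to_numpy().any():
        return pd.concat([meta, values], axis=1)

    # samples x features orientation: each feature with holes is regressed
    # on the other features across samples.
    X = values.to_numpy(dtype=float).T
    lo = np.nanmin(X, axis=0)
    hi = np.nanmax(X, axis=0)
    imputer = IterativeImputer(
        estimator=RandomForestRegressor(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        ),
        max_iter=max_iter,
        random_state=seed,
        min_value=lo,
        max_value=hi,
        sample_posterior=False,
    )
    filled = imputer.fit_transform(X).T
    out_values = pd.DataFrame(filled, columns=values.columns)
    return pd.concat([meta, out_values], axis=1)


def normalize_total_intensity(
    table: pd.DataFrame,
    log: ProcessingLog | None = None,
) -> pd.DataFrame:
    """Scale every sample so its total intensity equals the grand mean of
    the pre-scaling sample totals ("abundance balancing")."""
    meta, values = _split_meta(table)
    if values.isna().to_numpy().any():
        raise ValueError("normalization requires a complete (imputed) matrix")
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"non-positive sample totals: {bad}")
    grand = float(totals.mean())
    scale = grand / totals
    out = pd.concat([meta, values * scale], axis=1)
    if log is not None:
        log.steps.append("normalize_total_intensity")
        log.sample_scale.update({str(k): float(v) for k, v in scale.items()})
    return out


def scale_blanks_to_samples(
    blanks: pd.DataFrame,
    sample_scale: Mapping[str, float],
    pairing: pd.Series | dict,
    log: ProcessingLog | None = None,
) -> pd.DataFrame:
    """Carry each blank onto the normalized sample scale.

    A blank's own total is not comparable to sample totals (it lacks the
    embryo-released material), so each blank column is multiplied by the
    mean normalization factor of the samples of its batch rather than
    being balanced to the sample grand mean.  Batches without samples
    keep scale 1.
    """
    pairing = dict(pairing)
    by_batch: dict[str, list[float]] = {}
    for sample, batch in pairing.items():
        if sample in sample_scale:
            by_batch.setdefault(str(batch), []).append(float(sample_scale[sample]))
    bmeta, bvalues = _split_meta(blanks)
    bscale = {
        col: float(np.mean(by_batch[str(col)])) if str(col) in by_batch else 1.0
        for col in bvalues.columns
    }
    scaled = bvalues * pd.Series(bscale)
    if log is not None:
        log.steps.append("scale_blanks_to_samples")
        log.blank_scale.update(bscale)
    return pd.concat([bmeta, scaled], axis=1)


def subtract_blank(
    table: pd.DataFrame,
    blanks: pd.DataFrame,
    pairing: pd.Series | dict,
    log: ProcessingLog | None = None,
) -> pd.DataFrame:
    """Per feature, subtract each sample's matched culture-batch blank.

    ``pairing`` maps sample id -> blank column.  Negative net values are
    preserved: they represent consumption of a medium constituent.
    """
    meta, values = _split_meta(table)
    bmeta, bvalues = _split_meta(blanks)
    blank_aligned = (
        blanks.set_index("feature_id")
        .reindex(meta["feature_id"])
    )
    pairing = dict(pairing)
    missing = [s for s in values.columns if s not in pairing]
    if missing:
        raise ValueError(f"samples without a matched blank: {missing}")
    bad_batches = sorted({pairing[s] for s in values.columns} - set(bvalues.columns))
    if bad_batches:
        raise ValueError(f"pairing references unknown blank columns: {bad_batches}")
    net = values.copy()
    for s in values.columns:
        net[s] = values[s].to_numpy() - blank_aligned[pairing[s]].to_numpy()
    if log is not None:
        log.steps.append("subtract_blank")
    return pd.concat([meta.reset_index(drop=True), net.reset_index(drop=True)], axis=1)


def preprocess(
    raw: pd.DataFrame,
    blanks: pd.DataFrame,
    samples: pd.DataFrame,
    config: RunConfig,
    group_endpoint: str = "D40",
) -> tuple[pd.DataFrame, ProcessingLog]:
    """Run the full fixed-order pipeline and return (net matrix, log)."""
    log = ProcessingLog()
    log.steps.append("average_replicates")
    table = average_replicates(raw)
    labels = samples.set_index("sample_id")[group_endpoint]
    meta, values = _split_meta(table)
    table = consistency_filter(
        table, labels.reindex(values.columns), config.consistency_threshold, log=log
    )
    table = impute_missing(
        table,
        max_missing_fraction=config.max_missing_fraction,
        seed=config.seed,
        n_estimators=config.impute_estimators,
        max_iter=config.impute_max_iter,
        log=log,
    )
    table = normalize_total_intensity(table, log=log)
    pairing = samples.set_index("sample_id")["batch"]
    nblanks = scale_blanks_to_samples(blanks, log.sample_scale, pairing, log=log)
    net = subtract_blank(table, nblanks, pairing, log=log)
    return net, log
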