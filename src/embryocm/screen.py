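"""Exhaustive fixed-factor block screening of the net-intensity matrix.

A *block* is a subset of embryos defined by constraints on the fixed
factors (cryopreservation, bull breed, culture supplement, developmental
stage at 0 h and 24 h of single culture, embryo age) crossed with one
pregnancy endpoint (Day-40, Day-62 or birth).  Within each block every
feature runs through a two-level screen:

* level 1 (volcano): |fold change| >= 2 — or the qualitative sentinel —
  and the better of a two-sample t-test (one-way ANOVA with two groups)
  and a Kruskal-Wallis test below 0.10, with p < 0.05 flagged
  "significant" and [0.05, 0.10) flagged "tendency";
* level 2 (ROC): empirical rank ROC-AUC > 0.700 with t-test p < 0.10, or
  the small-block exception (fewer than 12 samples, AUC >= 0.850,
  p < 0.15).

Fold changes are log2 pregnant-over-open ratios of group means on the
blank-subtracted (net) scale; when one class sits at or below blank level
the ratio is undefined and the +/-99.000 sentinel is reported with the
sign of the pregnant-minus-open contrast ("qualitative" difference).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ENDPOINTS, RunConfig

SENTINEL = 99.0

FACTORS = ("cryo", "breed", "culture", "age")


@dataclass(frozen=True)
class BlockSpec:
    """One fixed-factor stratum crossed with one pregnancy endpoint.

    ``None`` means the factor is free (the block is independent of it);
    stage constraints are frozensets of levels.
    """

    endpoint: str
    cryo: str | None = None
    breed: str | None = None
    culture: str | None = None
    stage0h: frozenset | None = None
    stage24h: frozenset | None = None
    age: int | None = None
    pregnant_ids: tuple[str, ...] = ()
    open_ids: tuple[str, ...] = ()

    @property
    def n_pregnant(self) -> int:
        return len(self.pregnant_ids)

    @property
    def n_open(self) -> int:
        return len(self.open_ids)

    @property
    def n_constraints(self) -> int:
        return sum(
            c is not None
            for c in (self.cryo, self.breed, self.culture, self.stage0h, self.stage24h, self.age)
        )

    def constraint_key(self) -> tuple:
        return (
            self.endpoint, self.cryo, self.breed, self.culture,
            self.stage0h, self.stage24h, self.age,
        )

    def describe(self) -> dict:
        fmt = lambda s: "" if s is None else " + ".join(sorted(s, key=str))
        return {
            "endpoint": self.endpoint,
            "cryo": self.cryo or "",
            "breed": self.breed or "",
            "culture": self.culture or "",
            "stage0h": fmt(self.stage0h),
            "stage24h": fmt(self.stage24h),
            "age": "" if self.age is None else self.age,
            "n_pregnant": self.n_pregnant,
            "n_open": self.n_open,
        }


@dataclass
class ScreenHit:
    """A feature passing both screen levels inside one block."""

    block: BlockSpec
    feature_id: str
    log_fch: float
    p1: float                 # t-test
    p2: float                 # Kruskal-Wallis (secondary)
    auc: float
    significance: str         # "significant" | "tendency"
    small_n_exception: bool = False
    annotation: str = ""


def resolve_block(
    samples: pd.DataFrame,
    endpoint: str,
    cryo: str | None = None,
    breed: str | None = None,
    culture: str | None = None,
    stage0h: frozenset | None = None,
    stage24h: frozenset | None = None,
    age: int | None = None,
) -> BlockSpec:
    """Resolve a constraint tuple to its pregnant/open sample lists."""
    mask = np.ones(len(samples), dtype=bool)
    for col, val in (("cryo", cryo), ("breed", breed), ("culture", culture), ("age", age)):
        if val is not None:
            mask &= (samples[col] == val).to_numpy()
    if stage0h is not None:
        mask &= samples["stage0h"].isin(stage0h).to_numpy()
    if stage24h is not None:
        mask &= samples["stage24h"].isin(stage24h).to_numpy()
    sub = samples.loc[mask]
    outcome = sub[endpoint].astype(int)
    return BlockSpec(
        endpoint=endpoint, cryo=cryo, breed=breed, culture=culture,
        stage0h=stage0h, stage24h=stage24h, age=age,
        pregnant_ids=tuple(sub.loc[outcome == 1, "sample_id"]),
        open_ids=tuple(sub.loc[outcome == 0, "sample_id"]),
    )


def enumerate_blocks(
    samples: pd.DataFrame,
    min_class: int = 3,
    config: RunConfig | None = None,
    endpoints: tuple[str, ...] = ENDPOINTS,
) -> list[BlockSpec]:
    """All factorial blocks meeting ``min_class`` in both outcome classes.

    The grid is the Cartesian product of {each factor's levels + free}
    with the whitelisted stage subsets, crossed with the endpoints.
    Constraint tuples resolving to identical pregnant/open sample sets
    are collapsed to the coarsest one (fewest active constraints).
    """
    config = config or RunConfig()
    cryo_levels = [None] + sorted(samples["cryo"].unique())
    breed_levels = [None] + sorted(samples["breed"].unique())
    culture_levels = [None] + sorted(samples["culture"].unique())
    age_levels = [None] + sorted(samples["age"].unique())

    ids = samples["sample_id"].to_numpy()
    ones = np.ones(len(samples), dtype=bool)

    def level_masks(col, levels):
        return {
            lvl: (ones if lvl is None else (samples[col] == lvl).to_numpy())
            for lvl in levels
        }

    m_cryo = level_masks("cryo", cryo_levels)
    m_breed = level_masks("breed", breed_levels)
    m_culture = level_masks("culture", culture_levels)
    m_age = level_masks("age", age_levels)
    m_s0 = {
        s: (ones if s is None else samples["stage0h"].isin(s).to_numpy())
        for s in config.stage0h_subsets
    }
    m_s24 = {
        s: (ones if s is None else samples["stage24h"].isin(s).to_numpy())
        for s in config.stage24h_subsets
    }
    outcome = {ep: samples[ep].to_numpy(dtype=bool) for ep in endpoints}

    out: dict[tuple, BlockSpec] = {}
    for endpoint in endpoints:
        preg = outcome[endpoint]
        for cryo, breed, culture, age, s0, s24 in itertools.product(
            cryo_levels, breed_levels, culture_levels, age_levels,
            config.stage0h_subsets, config.stage24h_subsets,
        ):
            mask = (
                m_cryo[cryo] & m_breed[breed] & m_culture[culture]
                & m_age[age] & m_s0[s0] & m_s24[s24]
            )
            p_mask = mask & preg
            o_mask = mask & ~preg
            if p_mask.sum() < min_class or o_mask.sum() < min_class:
                continue
            block = BlockSpec(
                endpoint=endpoint, cryo=cryo, breed=breed, culture=culture,
                stage0h=s0, stage24h=s24, age=age,
                pregnant_ids=tuple(ids[p_mask]),
                open_ids=tuple(ids[o_mask]),
            )
            key = (endpoint, frozenset(block.pregnant_ids), frozenset(block.open_ids))
            prev = out.get(key)
            if prev is None or block.n_constraints < prev.n_constraints:
                out[key] = block
    def _key(b: BlockSpec) -> tuple:
        return tuple(
            ("" if v is None else str(sorted(v)) if isinstance(v, frozenset) else str(v))
            for v in b.constraint_key()
        )

    return sorted(out.values(), key=_key)


def log_fold_change(pregnant_values, open_values) -> float:
    """Signed log2 pregnant/open contrast of group means on the net scale.

    Both means positive -> log2(mean_P / mean_O).  Both strictly negative
    (mutual consumption) -> log2(|mean_P| / |mean_O|).  Opposite signs, or
    exactly one mean at/below zero -> the qualitative sentinel +/-99.000
    signed by (mean_P - mean_O).  Both means exactly zero -> NaN.
    """
    p = np.asarray(pregnant_values, dtype=float)
    o = np.asarray(open_values, dtype=float)
    if p.size == 0 or o.size == 0:
        raise ValueError("empty group")
    mp, mo = p.mean(), o.mean()
    if mp == 0.0 and mo == 0.0:
        return float("nan")
    if mp > 0.0 and mo > 0.0:
        return math.log2(mp / mo)
    if mp < 0.0 and mo < 0.0:
        return math.log2(abs(mp) / abs(mo))
    return math.copysign(SENTINEL, mp - mo)


def is_sentinel(log_fch: float) -> bool:
    return not math.isnan(log_fch) and abs(log_fch) >= SENTINEL


def roc_auc(pregnant_values, open_values) -> float:
    """Direction-free empirical rank ROC-AUC (Mann-Whitney), in [0.5, 1].

    Equal to the concordant-pair fraction with half credit for ties; the
    larger of A and 1-A is returned because a biomarker is informative in
    either direction.
    """
    p = np.asarray(pregnant_values, dtype=float)
    o = np.asarray(open_values, dtype=float)
    if p.size == 0 or o.size == 0:
        raise ValueError("empty group")
    combined = np.concatenate([p, o])
    ranks = stats.rankdata(combined)
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    a = u / (p.size * o.size)
    return float(max(a, 1.0 - a))


@dataclass
class Level1Record:
    block: BlockSpec
    feature_id: str
    log_fch: float
    p_param: float
    p_nonparam: float
    passed: bool
    significance: str = ""    # "significant" | "tendency" | ""


def volcano_level1(
    block: BlockSpec,
    pregnant_values,
    open_values,
    feature_id: str = "",
    config: RunConfig | None = None,
) -> Level1Record:
    """Level-1 volcano gate: fold change and parametric/non-parametric p."""
    config = config or RunConfig()
    p = np.asarray(pregnant_values, dtype=float)
    o = np.asarray(open_values, dtype=float)
    lfc = log_fold_change(p, o)
    fch_ok = (not math.isnan(lfc)) and (
        is_sentinel(lfc) or abs(lfc) >= math.log2(config.fold_change_gate)
    )
    if np.ptp(p) == 0 and np.ptp(o) == 0 and p.mean() == o.mean():
        # degenerate: two identical constant groups carry no signal
        return Level1Record(block, feature_id, lfc, 1.0, 1.0, False)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_res = stats.ttest_ind(p, o, equal_var=True)
        p_param = float(t_res.pvalue) if np.isfinite(t_res.pvalue) else 1.0
        try:
            kw = stats.kruskal(p, o)
            p_nonparam = float(kw.pvalue) if np.isfinite(kw.pvalue) else 1.0
        except ValueError:  # all values identical across both groups
            p_nonparam = 1.0
    best_p = min(p_param, p_nonparam)
    passed = bool(fch_ok and best_p < config.level1_tendency)
    significance = ""
    if passed:
        significance = "significant" if best_p < config.level1_alpha else "tendency"
    return Level1Record(block, feature_id, lfc, p_param, p_nonparam, passed, significance)


def roc_level2(
    record: Level1Record,
    pregnant_values,
    open_values,
    config: RunConfig | None = None,
) -> ScreenHit | None:
    """Level-2 ROC gate applied to a level-1 passer; None if rejected."""
    config = config or RunConfig()
    if not record.passed:
        return None
    auc = roc_auc(pregnant_values, open_values)
    n_total = record.block.n_pregnant + record.block.n_open
    p1 = record.p_param
    hit = auc > config.auc_gate and p1 < config.level1_tendency
    exception = False
    if not hit and n_total < config.small_n_total and auc >= config.small_n_auc:
        if config.level1_tendency <= p1 < config.small_n_p:
            hit, exception = True, True
    if not hit:
        return None
    return ScreenHit(
        block=record.block,
        feature_id=record.feature_id,
        log_fch=record.log_fch,
        p1=p1,
        p2=record.p_nonparam,
        auc=auc,
        significance=record.significance,
        small_n_exception=exception,
    )


def screen_block(
    block: BlockSpec,
    net: pd.DataFrame,
    config: RunConfig | None = None,
) -> list[ScreenHit]:
    """Run both screen levels for every feature of one block.

    ``net`` is the preprocessed matrix with a ``feature_id`` column and
    one column per sample.  Blocks are independent, so results do not
    depend on the order in which they are screened.
    """
    config = config or RunConfig()
    p_cols = list(block.pregnant_ids)
    o_cols = list(block.open_ids)
    P = net[p_cols].to_numpy(dtype=float)
    O = net[o_cols].to_numpy(dtype=float)
    feature_ids = net["feature_id"].to_numpy()

    # Vectorized fold-change gate across all features of the block; the
    # per-feature path (volcano_level1/roc_level2) defines the semantics
    # and only gate survivors go through it.
    mp, mo = P.mean(axis=1), O.mean(axis=1)
    gate = math.log2(config.fold_change_gate)
    both_pos = (mp > 0) & (mo > 0)
    both_neg = (mp < 0) & (mo < 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(mp) / np.abs(mo)
        lfc = np.where(both_pos | both_neg, np.log2(ratio), np.nan)
    sentinel_mask = ~(both_pos | both_neg) & ~((mp == 0) & (mo == 0))
    fch_ok = sentinel_mask | (np.abs(lfc) >= gate)

    hits = []
    for i in np.nonzero(fch_ok)[0]:
        rec = volcano_level1(block, P[i], O[i], feature_id=str(feature_ids[i]), config=config)
        if not rec.passed:
            continue
        hit = roc_level2(rec, P[i], O[i], config=config)
        if hit is not None:
            hits.append(hit)
    return hits


def screen_all(
    blocks: list[BlockSpec],
    net: pd.DataFrame,
    config: RunConfig | None = None,
) -> list[ScreenHit]:
    config = config or RunConfig()
    hits: list[ScreenHit] = []
    for block in blocks:
        hits.extend(screen_block(block, net, config))
    return hits


def hits_to_frame(hits: list[ScreenHit]) -> pd.DataFrame:
    """Flatten hits into the tabular report (one row per hit)."""
    rows = []
    for h in hits:
        row = h.block.describe()
        rows.append(
            {
                "feature_id": h.feature_id,
                "annotation": h.annotation,
                "AUC": h.auc,
                "P1": h.p1,
                "LogFCh": h.log_fch,
                "P2": h.p2,
                "endpoint": row["endpoint"],
                "cryo": row["cryo"],
                "breed": row["breed"],
                "culture": row["culture"],
                "stage0h": row["stage0h"],
                "stage24h": row["stage24h"],
                "age": row["age"],
                "N_P": row["n_pregnant"],
                "N_O": row["n_open"],
                "significance": h.significance,
                "small_n_exception": int(h.small_n_exception),
            }
        )
    columns = [
        "feature_id", "annotation", "AUC", "P1", "LogFCh", "P2", "endpoint",
        "cryo", "breed", "culture", "stage0h", "stage24h", "age",
        "N_P", "N_O", "significance", "small_n_exception",
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Annotation against a user-supplied spectral reference library
# ---------------------------------------------------------------------------

@dataclass
class AnnotationRecord:
    feature_id: str
    compound: str
    precursor_ppm: float
    matched_ms2: int
    validated: bool


def _ppm(measured: float, reference: float) -> float:
    return abs(measured - reference) / reference * 1e6


def annotate_features(
    features: pd.DataFrame,
    library: pd.DataFrame,
    precursor_ppm: float = 10.0,
    ms2_ppm: float = 5.0,
    min_ms2: int = 3,
) -> list[AnnotationRecord]:
    """Match features to a reference library by precursor mass and MS2 ions.

    ``features`` needs columns ``feature_id``, ``mz`` and optionally
    ``ms2`` (a semicolon-separated m/z list).  ``library`` needs
    ``compound``, ``exact_mass`` and ``ms2_mz_list`` (semicolon-separated).
    An identification is validated only when the precursor mass agrees
    within ``precursor_ppm`` and at least ``min_ms2`` library MS2 ions
    match within ``ms2_ppm``.
    """
    records: list[AnnotationRecord] = []
    if library is None or len(library) == 0:
        return records
    lib = library.reset_index(drop=True)
    lib_ms2 = [
        [float(x) for x in str(row).split(";") if str(x).strip()]
        for row in lib["ms2_mz_list"]
    ]
    for _, feat in features.iterrows():
        mz = float(feat["mz"])
        feat_ms2 = []
        if "ms2" in features.columns and isinstance(feat.get("ms2"), str) and feat["ms2"]:
            feat_ms2 = [float(x) for x in feat["ms2"].split(";") if x.strip()]
        best: AnnotationRecord | None = None
        for k, librow in lib.iterrows():
            err = _ppm(mz, float(librow["exact_mass"]))
            if err >= precursor_ppm:
                continue
            matched = sum(
                any(_ppm(f, ion) < ms2_ppm for f in feat_ms2) for ion in lib_ms2[k]
            )
            validated = err < precursor_ppm and matched >= min_ms2
            rec = AnnotationRecord(
                feature_id=str(feat["feature_id"]),
                compound=str(librow["compound"]),
                precursor_ppm=err,
                matched_ms2=matched,
                validated=validated,
            )
            if best is None or (rec.validated, rec.matched_ms2, -rec.precursor_ppm) > (
                best.validated, best.matched_ms2, -best.precursor_ppm
            ):
                best = rec
        if best is not None:
            records.append(best)
    return records


def annotations_to_frame(records: list[AnnotationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "compound": r.compound,
                "precursor_ppm": r.precursor_ppm,
                "matched_ms2": r.matched_ms2,
                "validated": int(r.validated),
            }
            for r in records
        ],
        columns=["feature_id", "compound", "precursor_ppm", "matched_ms2", "validated"],
    )
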