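"""Synthetic spent-culture-medium cohorts with planted biomarker effects.

Real spent-medium metabolomics cohorts of transferred embryos are rarely
public, so every downstream stage of this pipeline is exercised on
synthetic bundles that reproduce the statistical structure the analysis
assumes:

* log-normal feature intensities measured in duplicate injections;
* medium-constituent features whose blank-subtracted net signal is
  negative when the embryo consumes them and positive when it releases
  them, with one blank medium record per (transfer round x culture) batch;
* a random bull intercept on a subset of features;
* per-stratum planted pregnancy effects, either a log2 shift of the net
  signal or a "qualitative" regime in which one outcome class sits at
  blank level (net ~ 0) so the downstream +/-99 fold-change sentinel fires;
* detection-limit (left-censoring) missingness plus a small MCAR rate;
* a stage-abundance ("impact") table derived from a larger virtual
  metapopulation of embryos.

A planted-truth ledger records, per planted feature, the exact block in
which it is differential, so recovery can be scored without ambiguity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .config import ENDPOINTS, STAGE0H_LEVELS, STAGE24H_LEVELS, STAGE_ORDER

FACTOR_COLUMNS = ("cryo", "breed", "culture", "bull", "stage0h", "stage24h", "age")

#: Transfer-design margins emulating a two-breed, two-culture cohort of 84
#: embryos: 28 fresh (Day-7) and 56 frozen (48 Day-7 + 8 Day-8).
DEFAULT_DESIGN = (
    {"cryo": "fresh", "culture": "BSA", "age": 7, "n": 17},
    {"cryo": "fresh", "culture": "FCS", "age": 7, "n": 11},
    {"cryo": "frozen", "culture": "BSA", "age": 7, "n": 30},
    {"cryo": "frozen", "culture": "BSA", "age": 8, "n": 8},
    {"cryo": "frozen", "culture": "FCS", "age": 7, "n": 18},
)

DEFAULT_FACTOR_LEVELS = {
    "cryo": ("fresh", "frozen"),
    "breed": ("AV", "H"),
    "culture": ("BSA", "FCS"),
    "bull": tuple(f"bull{i}" for i in range(1, 8)),
    "stage0h": STAGE0H_LEVELS,
    "stage24h": STAGE24H_LEVELS,
    "age": (7, 8),
}


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass
class PlantedEffect:
    """A pregnancy-differential signal planted in one fixed-factor stratum.

    ``stratum`` constrains any subset of cryo/breed/culture/stage0h/
    stage24h/age (stage constraints may be sets of levels).  ``mode`` is
    ``"shift"`` (a log2 offset of the net-signal magnitude) or
    ``"qualitative"`` (one outcome class at blank level, the other with a
    clear net signal, so the fold change is undefined on the ratio scale).
    ``direction`` is the sign of the pregnant-minus-open net contrast.
    """

    feature: str
    stratum: Mapping[str, object] = field(default_factory=dict)
    endpoints: tuple[str, ...] = ENDPOINTS
    mode: str = "shift"
    log2_effect: float = 2.0
    direction: int = -1

    def __post_init__(self) -> None:
        if self.mode not in ("shift", "qualitative"):
            raise ConfigurationError(f"unknown planted mode {self.mode!r}")
        if self.direction not in (-1, 1):
            raise ConfigurationError("direction must be -1 or +1")
        for ep in self.endpoints:
            if ep not in ENDPOINTS:
                raise ConfigurationError(f"unknown endpoint {ep!r}")


@dataclass
class GeneratorConfig:
    """Everything the cohort generator needs, seed included."""

    design: Sequence[Mapping[str, object]] = DEFAULT_DESIGN
    factor_levels: Mapping[str, Sequence] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_LEVELS)
    )
    # Baseline pregnancy process: P(Day-40), P(Day-62 | Day-40),
    # P(birth | Day-62).  Conditioning guarantees monotone endpoints.
    p_day40: float = 0.60
    p_day62_given_day40: float = 0.95
    p_birth_given_day62: float = 0.80

    n_features: int = 80
    constituent_fraction: float = 0.3   # features present in blank medium
    planted: Sequence[PlantedEffect] = ()

    noise_sd: float = 0.5               # log2-scale biological SD
    bull_sd: float = 0.5                # log2-scale bull random intercept SD
    bull_feature_fraction: float = 0.25
    injection_cv: float = 0.02          # analytical CV of duplicate injections
    blank_batch_sd: float = 0.10        # log2-scale batch wobble of blank levels
    detection_quantile: float = 0.02    # left-censoring quantile (MNAR)
    mcar_rate: float = 0.01
    round_size: int = 4                 # embryos per transfer round
    metapopulation_n: int = 1114        # virtual embryos behind the impact table
    stage0h_probs: tuple[float, float, float] = (0.2, 0.4, 0.4)
    stage24h_probs: tuple[float, float] = (0.4, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (
            ("p_day40", self.p_day40),
            ("p_day62_given_day40", self.p_day62_given_day40),
            ("p_birth_given_day62", self.p_birth_given_day62),
            ("constituent_fraction", self.constituent_fraction),
            ("detection_quantile", self.detection_quantile),
            ("mcar_rate", self.mcar_rate),
        ):
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        for name, levels in self.factor_levels.items():
            if len(levels) == 0:
                raise ConfigurationError(f"empty level list for factor {name!r}")
        for row in self.design:
            for key in ("cryo", "culture", "age"):
                if row[key] not in self.factor_levels[key]:
                    raise ConfigurationError(
                        f"design level {row[key]!r} not in factor_levels[{key!r}]"
                    )
            if row["n"] < 0:
                raise ConfigurationError("design counts must be non-negative")
        for eff in self.planted:
            self._check_stratum(eff.stratum)

    def _check_stratum(self, stratum: Mapping[str, object]) -> None:
        for key, value in stratum.items():
            if key not in FACTOR_COLUMNS:
                raise ConfigurationError(f"unknown stratum factor {key!r}")
            levels = set(self.factor_levels[key])
            values = value if isinstance(value, (set, frozenset, list, tuple)) else [value]
            for v in values:
                if v not in levels:
                    raise ConfigurationError(
                        f"planted stratum references unknown level {v!r} of {key!r}"
                    )

    @property
    def n_samples(self) -> int:
        return int(sum(row["n"] for row in self.design))


@dataclass
class SyntheticBundle:
    """The complete input set for one synthetic study."""

    raw: pd.DataFrame          # feature_id, rt_min, mz + <sample>_r<k> columns
    blanks: pd.DataFrame       # feature_id + one column per culture batch
    samples: pd.DataFrame      # one row per embryo/sample
    impact: pd.DataFrame       # culture, stage0h, stage24h, n, percent
    truth: pd.DataFrame        # planted-effect ledger
    config: GeneratorConfig

    @property
    def feature_ids(self) -> list[str]:
        return list(self.raw["feature_id"])


def _stratum_mask(samples: pd.DataFrame, stratum: Mapping[str, object]) -> np.ndarray:
    mask = np.ones(len(samples), dtype=bool)
    for key, value in stratum.items():
        values = value if isinstance(value, (set, frozenset, list, tuple)) else [value]
        mask &= samples[key].isin(list(values)).to_numpy()
    return mask


def generate_cohort(config: GeneratorConfig) -> SyntheticBundle:
    """Generate a full synthetic bundle; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)

    samples = _generate_samples(config, rng)
    features = _generate_feature_metadata(config, rng)
    blanks, raw, truth = _generate_intensities(config, rng, samples, features)
    impact = _generate_impact_table(config, rng)
    return SyntheticBundle(
        raw=raw, blanks=blanks, samples=samples, impact=impact, truth=truth,
        config=config,
    )


def _generate_samples(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    levels = config.factor_levels
    rows = []
    for design_row in config.design:
        for _ in range(int(design_row["n"])):
            stage0h = rng.choice(levels["stage0h"], p=config.stage0h_probs)
            stage24h = rng.choice(levels["stage24h"], p=config.stage24h_probs)
            if STAGE_ORDER[stage24h] < STAGE_ORDER[stage0h]:  # cannot regress
                raise AssertionError("stage ordering violated")
            rows.append(
                {
                    "cryo": design_row["cryo"],
                    "culture": design_row["culture"],
                    "age": design_row["age"],
                    "breed": rng.choice(levels["breed"]),
                    "bull": rng.choice(levels["bull"]),
                    "stage0h": stage0h,
                    "stage24h": stage24h,
                    "sex": rng.choice(["F", "M"]),
                }
            )
    samples = pd.DataFrame(rows)
    n = len(samples)
    samples.insert(0, "sample_id", [f"S{i + 1:03d}" for i in range(n)])

    # Transfer rounds of round_size embryos; one culture batch (and hence
    # one blank medium record) per (round, culture).
    order = rng.permutation(n)
    rounds = np.empty(n, dtype=int)
    rounds[order] = np.arange(n) // config.round_size + 1
    samples["round"] = rounds
    samples["batch"] = [
        f"R{r:02d}_{c}" for r, c in zip(samples["round"], samples["culture"])
    ]
    samples["recipient"] = [f"rec{i + 1:03d}" for i in range(n)]

    d40 = rng.random(n) < config.p_day40
    d62 = d40 & (rng.random(n) < config.p_day62_given_day40)
    birth = d62 & (rng.random(n) < config.p_birth_given_day62)
    samples["D40"] = d40.astype(int)
    samples["D62"] = d62.astype(int)
    samples["Birth"] = birth.astype(int)
    samples["exclude_birth"] = 0
    return samples


def _generate_feature_metadata(
    config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    m = config.n_features
    n_planted = len(config.planted)
    if n_planted > m:
        raise ConfigurationError("more planted effects than features")
    features = pd.DataFrame(
        {
            "feature_id": [f"F{i + 1:04d}" for i in range(m)],
            "rt_min": np.round(rng.uniform(0.5, 12.0, m), 3),
            "mz": np.round(rng.uniform(100.0, 1500.0, m), 4),
        }
    )
    n_const = int(round(config.constituent_fraction * m))
    constituent = np.zeros(m, dtype=bool)
    constituent[rng.choice(m, size=n_const, replace=False)] = True
    features["constituent"] = constituent
    # Constituents are consumed (net negative after blank subtraction);
    # everything else is released by the embryo (net positive).
    features["net_sign"] = np.where(constituent, -1, 1)
    return features


def _planted_feature_map(config: GeneratorConfig, features: pd.DataFrame) -> dict[str, int]:
    index = {fid: i for i, fid in enumerate(features["feature_id"])}
    out = {}
    for eff in config.planted:
        if eff.feature not in index:
            raise ConfigurationError(f"planted feature {eff.feature!r} not generated")
        out[eff.feature] = index[eff.feature]
    return out


def _generate_intensities(
    config: GeneratorConfig,
    rng: np.random.Generator,
    samples: pd.DataFrame,
    features: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    n, m = len(samples), len(features)
    fmap = _planted_feature_map(config, features)

    base_mag = rng.uniform(8.0, 14.0, m)          # log2 net-signal magnitude
    blank_base = np.where(
        features["constituent"], 2.0 ** rng.uniform(14.0, 18.0, m), 0.0
    )
    # An embryo consumes a modest fraction (~2-18%) of a constituent's
    # medium pool, so consumption magnitude is tied to the blank level;
    # even a 4-fold planted boost then stays below the blank and the
    # measured signal never floors at zero.
    constituent = features["constituent"].to_numpy()
    base_mag[constituent] = np.log2(blank_base[constituent]) - rng.uniform(
        2.5, 5.5, int(constituent.sum())
    )
    net_sign = features["net_sign"].to_numpy(dtype=float)

    # Bull random intercept on a feature subset.
    bulls = sorted(samples["bull"].unique())
    bull_effects = {b: rng.normal(0.0, config.bull_sd) for b in bulls}
    n_bull_feat = int(round(config.bull_feature_fraction * m))
    bull_feat = np.zeros(m, dtype=bool)
    if n_bull_feat:
        bull_feat[rng.choice(m, size=n_bull_feat, replace=False)] = True

    log2mag = np.tile(base_mag, (n, 1))
    bull_col = samples["bull"].map(bull_effects).to_numpy()
    log2mag[:, bull_feat] += bull_col[:, None]
    log2mag += rng.normal(0.0, config.noise_sd, size=(n, m))

    net = net_sign[None, :] * 2.0 ** log2mag

    truth_rows = []
    for eff in config.planted:
        j = fmap[eff.feature]
        in_stratum = _stratum_mask(samples, eff.stratum)
        endpoint = eff.endpoints[0]
        pregnant = samples[endpoint].to_numpy(dtype=bool)
        s = net_sign[j]
        if eff.mode == "shift":
            # Apply the log2 offset to whichever class makes the net
            # pregnant-minus-open contrast carry the requested sign.
            boost_pregnant = eff.direction * s > 0
            target = in_stratum & (pregnant if boost_pregnant else ~pregnant)
            net[target, j] *= 2.0 ** abs(eff.log2_effect)  # scales the magnitude
        else:  # qualitative: the low class sits at blank level (net <~ 0)
            if blank_base[j] == 0.0:
                # A qualitative (absent-in-one-class) signal is only
                # observable against a nonzero blank level, i.e. on a
                # medium-constituent feature.
                blank_base[j] = 2.0 ** 16
                features.loc[j, "constituent"] = True
            low_is_pregnant = eff.direction < 0
            low = in_stratum & (pregnant if low_is_pregnant else ~pregnant)
            high = in_stratum & ~(pregnant if low_is_pregnant else ~pregnant)
            eps = 2.0 ** (base_mag[j] - 6.0)
            net[low, j] = -np.abs(rng.normal(0.0, eps, size=int(low.sum()))) - eps
            # High class released regardless of the feature's default sign,
            # so the two group means have opposite signs.
            net[high, j] = np.abs(net[high, j])
        truth_rows.append(
            {
                "feature_id": eff.feature,
                "mode": eff.mode,
                "direction": eff.direction,
                "log2_effect": eff.log2_effect if eff.mode == "shift" else np.nan,
                "endpoints": ";".join(eff.endpoints),
                "stratum": _encode_stratum(eff.stratum),
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["feature_id", "mode", "direction", "log2_effect", "endpoints", "stratum"],
    )

    # Blank records, one per culture batch, with mild batch wobble.
    batches = sorted(samples["batch"].unique())
    blank_values = {}
    for b in batches:
        wobble = 2.0 ** rng.normal(0.0, config.blank_batch_sd, m)
        blank_values[b] = blank_base * wobble
    blanks = pd.DataFrame({"feature_id": features["feature_id"]})
    for b in batches:
        blanks[b] = blank_values[b]

    # Measured raw signal = batch blank + net, floored at zero.
    batch_of = samples["batch"].to_numpy()
    blank_matrix = np.stack([blank_values[b] for b in batch_of])
    raw_true = np.maximum(blank_matrix + net, 0.0)

    # Duplicate injections with multiplicative analytical noise, then
    # detection-limit censoring plus MCAR dropout.
    raw = pd.DataFrame(
        {
            "feature_id": features["feature_id"],
            "rt_min": features["rt_min"],
            "mz": features["mz"],
        }
    )
    inj = np.empty((2, n, m))
    for k in range(2):
        inj[k] = raw_true * (1.0 + rng.normal(0.0, config.injection_cv, size=(n, m)))
    positive = inj[inj > 0]
    lod = np.quantile(positive, config.detection_quantile) if positive.size else 0.0
    for k in range(2):
        vals = inj[k]
        censored = vals < lod
        mcar = rng.random((n, m)) < config.mcar_rate
        inj[k] = np.where(censored | mcar, np.nan, vals)
    inj_cols = {}
    for i, sid in enumerate(samples["sample_id"]):
        inj_cols[f"{sid}_r1"] = inj[0][i]
        inj_cols[f"{sid}_r2"] = inj[1][i]
    raw = pd.concat([raw, pd.DataFrame(inj_cols)], axis=1)
    return blanks, raw, truth


def _encode_stratum(stratum: Mapping[str, object]) -> str:
    parts = []
    for key in FACTOR_COLUMNS:
        if key in stratum:
            value = stratum[key]
            if isinstance(value, (set, frozenset, list, tuple)):
                parts.append(f"{key}={'|'.join(str(v) for v in sorted(value, key=str))}")
            else:
                parts.append(f"{key}={value}")
    return ";".join(parts)


def decode_stratum(text: str) -> dict[str, object]:
    """Inverse of the truth ledger's stratum encoding."""
    out: dict[str, object] = {}
    if not text:
        return out
    for part in text.split(";"):
        key, value = part.split("=", 1)
        vals = value.split("|")
        parsed = [int(v) if v.isdigit() else v for v in vals]
        out[key] = parsed[0] if len(parsed) == 1 else frozenset(parsed)
    return out


def _generate_impact_table(
    config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Stage-abundance table from a larger virtual metapopulation.

    Cell counts are multinomial draws of ``metapopulation_n`` embryos per
    culture over the (stage0h x stage24h) grid, with percentages computed
    within culture so they sum to exactly 100.
    """
    p0 = np.asarray(config.stage0h_probs, dtype=float)
    p24 = np.asarray(config.stage24h_probs, dtype=float)
    cell_p = np.outer(p0, p24).ravel()
    cell_p /= cell_p.sum()
    cultures = list(config.factor_levels["culture"])
    per_culture = config.metapopulation_n // len(cultures)
    rows = []
    for culture in cultures:
        counts = rng.multinomial(per_culture, cell_p)
        total = counts.sum()
        k = 0
        for s0 in config.factor_levels["stage0h"]:
            for s24 in config.factor_levels["stage24h"]:
                rows.append(
                    {
                        "culture": culture,
                        "stage0h": s0,
                        "stage24h": s24,
                        "n": int(counts[k]),
                        "percent": 100.0 * counts[k] / total,
                    }
                )
                k += 1
    return pd.DataFrame(rows)


def default_planted_effects(n: int) -> tuple[PlantedEffect, ...]:
    """A standard set of planted effects cycling over well-filled strata
    of the default transfer design, alternating log2-shift and
    qualitative modes and both contrast directions."""
    strata = (
        {"cryo": "frozen", "culture": "BSA"},
        {"cryo": "frozen", "culture": "FCS"},
        {"cryo": "fresh"},
        {},
    )
    effects = []
    for i in range(n):
        effects.append(
            PlantedEffect(
                feature=f"F{i + 1:04d}",
                stratum=strata[i % len(strata)],
                mode="shift" if i % 2 == 0 else "qualitative",
                log2_effect=2.0,
                direction=-1 if i % 3 else 1,
            )
        )
    return tuple(effects)


def vectors_with_discordance(
    n_pos: int, n_neg: int, n_discordant: int, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Two value vectors with an exact number of discordant cross-pairs.

    Returns ``(positive, negative)`` vectors of distinct values such that
    exactly ``n_discordant`` of the ``n_pos * n_neg`` cross-pairs have the
    positive value below the negative one and none are tied, so the
    empirical rank ROC-AUC is exactly
    ``1 - n_discordant / (n_pos * n_neg)``.  If ``rng`` is given the
    entries are shuffled (the AUC is order-invariant).
    """
    if not 0 <= n_discordant <= n_pos * n_neg:
        raise ValueError("n_discordant outside [0, n_pos*n_neg]")
    negative = np.arange(1.0, n_neg + 1)
    positive = np.full(n_pos, float(n_neg)) + np.arange(1.0, n_pos + 1)
    remaining = n_discordant
    i = 0
    while remaining > 0:
        k = min(remaining, n_neg)
        positive[i] = n_neg - k + 0.5   # below exactly k negatives
        remaining -= k
        i += 1
    if rng is not None:
        rng.shuffle(positive)
        rng.shuffle(negative)
    return positive, negative


def write_fixtures(bundle: SyntheticBundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle as TSV fixtures + a YAML config snapshot."""
    from . import io as eio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": directory / "features.tsv",
        "blanks": directory / "blanks.tsv",
        "samples": directory / "samples.tsv",
        "impact": directory / "impact.tsv",
        "truth": directory / "truth.tsv",
        "config": directory / "generator.yaml",
    }
    eio.write_table(bundle.raw, paths["features"])
    eio.write_table(bundle.blanks, paths["blanks"])
    eio.write_table(bundle.samples, paths["samples"])
    eio.write_table(bundle.impact, paths["impact"])
    eio.write_table(bundle.truth, paths["truth"])
    cfg = dataclasses.asdict(bundle.config)
    cfg["design"] = [dict(r) for r in bundle.config.design]
    cfg["factor_levels"] = {k: list(v) for k, v in bundle.config.factor_levels.items()}
    cfg["planted"] = [
        {
            "feature": e.feature,
            "stratum": _encode_stratum(e.stratum),
            "endpoints": list(e.endpoints),
            "mode": e.mode,
            "log2_effect": e.log2_effect,
            "direction": e.direction,
        }
        for e in bundle.config.planted
    ]
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths
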