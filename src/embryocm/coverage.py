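"""Impact-weighted biomarker coverage and series combination.

A biomarker's practical value depends not only on its ROC-AUC but on how
many embryos its block represents.  The *impact* of a block is the
percentage of the embryo population (from a larger reference
metapopulation) falling in the block's culture x stage stratum; the
*predicted coverage* of a single biomarker is AUC x impact.  A *series*
is a set of stage-disjoint blocks sharing endpoint, cryopreservation,
breed, culture and age; its *combined coverage* is the sum of the member
coverages, exploiting that disjoint strata partition the population.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .screen import BlockSpec, ScreenHit


class ImpactLookupError(KeyError):
    """A block references a stratum missing from the impact table."""


@dataclass
class CoverageResult:
    hit: ScreenHit
    impact: float      # percent of the population in the block's stratum
    predicted: float   # AUC x impact, percent

    @property
    def feature_id(self) -> str:
        return self.hit.feature_id


@dataclass
class SeriesResult:
    """Stage-disjoint member blocks under one factor signature."""

    signature: tuple   # (endpoint, cryo, breed, culture, age)
    members: list[CoverageResult]
    combined: float

    @property
    def endpoint(self) -> str:
        return self.signature[0]


def _stage_cells(block: BlockSpec, all0: frozenset, all24: frozenset) -> frozenset:
    """The (stage0h, stage24h) grid cells a block's constraints cover."""
    s0 = block.stage0h if block.stage0h is not None else all0
    s24 = block.stage24h if block.stage24h is not None else all24
    return frozenset(itertools.product(sorted(s0), sorted(s24)))


def impact_lookup(block: BlockSpec, impact_table: pd.DataFrame) -> float:
    """Percent of the reference population in the block's stratum.

    Blocks free of both culture and stage constraints cover the whole
    population (100.000).  With a culture constraint the percentage is
    taken within that culture; with a free culture the counts are pooled
    across cultures, which requires the ``n`` count column.
    """
    t = impact_table
    stage_free = block.stage0h is None and block.stage24h is None
    if block.culture is None and stage_free:
        return 100.0
    if block.culture is not None:
        scope = t[t["culture"] == block.culture]
        if scope.empty:
            raise ImpactLookupError(f"culture {block.culture!r} absent from impact table")
    else:
        scope = t
    if stage_free:
        return 100.0
    sel = scope
    if block.stage0h is not None:
        known = set(scope["stage0h"])
        missing = set(block.stage0h) - known
        if missing:
            raise ImpactLookupError(f"stage0h levels absent from impact table: {sorted(missing)}")
        sel = sel[sel["stage0h"].isin(block.stage0h)]
    if block.stage24h is not None:
        known = set(scope["stage24h"])
        missing = set(block.stage24h) - known
        if missing:
            raise ImpactLookupError(f"stage24h levels absent from impact table: {sorted(missing)}")
        sel = sel[sel["stage24h"].isin(block.stage24h)]
    if block.culture is not None and "percent" in t.columns and "n" not in t.columns:
        return float(sel["percent"].sum())
    if "n" not in t.columns:
        raise ImpactLookupError(
            "impact table needs an 'n' count column to pool across cultures"
        )
    total = scope["n"].sum()
    if total <= 0:
        raise ImpactLookupError("empty impact scope")
    return float(100.0 * sel["n"].sum() / total)


def predicted_coverage(auc: float, impact: float) -> float:
    """Coverage (percent) = AUC x impact."""
    if not 0.5 <= auc <= 1.0:
        raise ValueError("auc must lie in [0.5, 1]")
    if not 0.0 <= impact <= 100.0:
        raise ValueError("impact must lie in [0, 100]")
    return auc * impact


def cover(hit: ScreenHit, impact_table: pd.DataFrame) -> CoverageResult:
    impact = impact_lookup(hit.block, impact_table)
    return CoverageResult(hit=hit, impact=impact, predicted=predicted_coverage(hit.auc, impact))


def select_single_biomarkers(
    hits: list[ScreenHit],
    impact_table: pd.DataFrame,
    min_predicted: float = 70.0,
) -> list[CoverageResult]:
    """Single biomarkers with predicted coverage >= ``min_predicted``,
    sorted by descending coverage (ties: larger block, then feature id)."""
    results = [cover(h, impact_table) for h in hits]
    kept = [r for r in results if r.predicted >= min_predicted]
    kept.sort(
        key=lambda r: (
            -r.predicted,
            -(r.hit.block.n_pregnant + r.hit.block.n_open),
            r.feature_id,
        )
    )
    return kept


def _signature(block: BlockSpec) -> tuple:
    return (block.endpoint, block.cryo, block.breed, block.culture, block.age)


def build_series(
    hits: list[ScreenHit],
    impact_table: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    max_strata: int = 24,
) -> list[tuple[tuple, list[list[CoverageResult]]]]:
    """Enumerate candidate series: for each (endpoint, cryo, breed,
    culture, age) signature, every set of stage-disjoint member strata,
    with each member carrying all its candidate metabolite coverages.

    Returns ``[(signature, [member_candidates, ...]), ...]`` — one entry
    per (signature, disjoint stratum set); the member order inside an
    entry is the stratum order.
    """
    if samples is not None:
        all0 = frozenset(samples["stage0h"].unique())
        all24 = frozenset(samples["stage24h"].unique())
    else:
        all0 = frozenset({"M", "EB", "B"})
        all24 = frozenset({"ExB", "FEB"})
    by_sig: dict[tuple, dict[frozenset, list[CoverageResult]]] = {}
    for h in hits:
        sig = _signature(h.block)
        cells = _stage_cells(h.block, all0, all24)
        by_sig.setdefault(sig, {}).setdefault(cells, []).append(cover(h, impact_table))
    out = []
    for sig, strata in sorted(by_sig.items(), key=lambda kv: str(kv[0])):
        keys = sorted(strata, key=lambda c: sorted(c))
        if len(keys) > max_strata:
            raise ValueError(f"too many strata ({len(keys)}) under signature {sig}")

        # Depth-first enumeration of disjoint stratum sets, pruning any
        # branch as soon as an overlap occurs.
        def extend(start: int, chosen: list[frozenset], union: frozenset) -> None:
            for idx in range(start, len(keys)):
                cells = keys[idx]
                if cells & union:
                    continue
                nxt = chosen + [cells]
                out.append((sig, [strata[c] for c in nxt]))
                extend(idx + 1, nxt, union | cells)

        extend(0, [], frozenset())
    return out


def combined_coverage(members: list[CoverageResult], all0=None, all24=None) -> float:
    """Sum of member coverages; raises if member strata overlap."""
    all0 = all0 or frozenset({"M", "EB", "B"})
    all24 = all24 or frozenset({"ExB", "FEB"})
    cells = [_stage_cells(m.hit.block, all0, all24) for m in members]
    for a, b in itertools.combinations(cells, 2):
        if a & b:
            raise ValueError("series members have overlapping stage strata")
    return float(sum(m.predicted for m in members))


def best_combination_per_series(
    candidates: list[tuple[tuple, list[list[CoverageResult]]]],
    combined_gate: float = 80.0,
) -> list[SeriesResult]:
    """Per signature, the member-metabolite assignment maximizing combined
    coverage, keeping series above the combined-coverage gate.

    Ties are broken toward fewer members, then lexicographic metabolite
    ids.  Within a member block the best metabolite is the one with the
    highest predicted coverage (same tie-break).
    """
    best: dict[tuple, tuple] = {}
    for sig, member_candidates in candidates:
        chosen = []
        for cands in member_candidates:
            pick = min(cands, key=lambda r: (-r.predicted, r.feature_id))
            chosen.append(pick)
        total = float(sum(r.predicted for r in chosen))
        ids = tuple(sorted(r.feature_id for r in chosen))
        key = (-total, len(chosen), ids)
        if sig not in best or key < best[sig][0]:
            best[sig] = (key, chosen, total)
    results = []
    for sig, (_, chosen, total) in sorted(best.items(), key=lambda kv: str(kv[0])):
        if total > combined_gate:
            results.append(SeriesResult(signature=sig, members=chosen, combined=total))
    results.sort(key=lambda s: (-s.combined, str(s.signature)))
    return results


def singles_to_frame(results: list[CoverageResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = r.hit.block.describe()
        rows.append(
            {
                "feature_id": r.feature_id,
                "AUC": r.hit.auc,
                "P1": r.hit.p1,
                "LogFCh": r.hit.log_fch,
                "P2": r.hit.p2,
                "endpoint": d["endpoint"],
                "cryo": d["cryo"],
                "breed": d["breed"],
                "culture": d["culture"],
                "stage0h": d["stage0h"],
                "stage24h": d["stage24h"],
                "age": d["age"],
                "N_P": d["n_pregnant"],
                "N_O": d["n_open"],
                "impact": r.impact,
                "predicted": r.predicted,
            }
        )
    columns = [
        "feature_id", "AUC", "P1", "LogFCh", "P2", "endpoint", "cryo", "breed",
        "culture", "stage0h", "stage24h", "age", "N_P", "N_O", "impact", "predicted",
    ]
    return pd.DataFrame(rows, columns=columns)


def series_to_frame(series: list[SeriesResult]) -> pd.DataFrame:
    rows = []
    for k, s in enumerate(series, start=1):
        for r in s.members:
            d = r.hit.block.describe()
            rows.append(
                {
                    "series": k,
                    "feature_id": r.feature_id,
                    "endpoint": d["endpoint"],
                    "cryo": d["cryo"],
                    "breed": d["breed"],
                    "culture": d["culture"],
                    "stage0h": d["stage0h"],
                    "stage24h": d["stage24h"],
                    "age": d["age"],
                    "N_P": d["n_pregnant"],
                    "N_O": d["n_open"],
                    "impact": r.impact,
                    "predicted": r.predicted,
                    "combined": s.combined,
                }
            )
    columns = [
        "series", "feature_id", "endpoint", "cryo", "breed", "culture",
        "stage0h", "stage24h", "age", "N_P", "N_O", "impact", "predicted", "combined",
    ]
    return pd.DataFrame(rows, columns=columns)
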