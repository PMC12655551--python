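"""Ligand-enrichment metrics for actives-seeded-in-decoys screens.

A ranked list of N_total compounds contains Hits_total known actives mixed
into decoys. Ranking power is summarised by:

* ROC AUC — the probability that a random active outranks a random decoy
  (ties count one half).
* The classical enrichment factor
  ``EF(f) = (Hits_sampled / Hits_total) / (N_sampled / N_total)``, the fold
  over-representation of actives in the top fraction ``f``.
* The modified enrichment factor
  ``EF'(f) = (50% / APR) × (Hits_sampled / Hits_total)``, where APR is the
  average percentile rank of all actives (percentile of rank r is
  ``100·r/N_total``, rank 1 best). EF' rewards actives sitting high in the
  list, not merely inside the window.
* The enhanced factor EF*(f), the mean of EF over the fraction grid
  ``{f/10, 2f/10, …, f}`` — enrichment integrated over a widening window —
  and the difference family DEF/DEF*/DEF' comparing two protocols on the
  same library.

Windows use ``N_sampled = ceil(f · N_total)`` so that a 1% window on a
7,100-compound library is never empty. Ties in score get average ranks for
AUC and APR; window membership breaks ties by compound id so reruns are
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score, roc_curve

from .exceptions import AlignmentError, DataError, UndefinedMetricError
from .io import HIGHER, LOWER, ScreeningRecord

EF_FAMILY_NOTE = (
    "EF*/DEF/DEF*/DEF' defined by this package: EF*(f) = mean EF over the "
    "grid {f/10,...,f}; DEF variants are pairwise differences between lists."
)


@dataclass
class RankedList:
    """Screening records ordered best-first with average-rank bookkeeping."""

    records: list[ScreeningRecord]
    ranks: np.ndarray  # average rank per record, rank 1 = best

    @classmethod
    def from_records(cls, records, direction: str = LOWER) -> "RankedList":
        if direction not in (LOWER, HIGHER):
            raise DataError(f"unknown score direction {direction!r}")
        records = list(records)
        ids = [r.compound_id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate compound ids: {dupes}")
        sign = 1.0 if direction == LOWER else -1.0
        # stable deterministic order: oriented score, then compound id
        order = sorted(range(len(records)),
                       key=lambda i: (sign * records[i].score,
                                      records[i].compound_id))
        ordered = [records[i] for i in order]
        oriented = np.array([sign * r.score for r in ordered])
        ranks = rankdata(oriented, method="average")
        return cls(ordered, ranks)

    @property
    def n_total(self) -> int:
        return len(self.records)

    @property
    def hits_total(self) -> int:
        return sum(r.label == "active" for r in self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    def percentile_ranks(self) -> np.ndarray:
        """Percentile rank of every record: 100 · average-rank / N_total."""
        return 100.0 * self.ranks / self.n_total


def roc_auc(ranked: RankedList):
    """ROC AUC and curve points; ties contribute half a concordant pair.

    Returns ``(auc, points)`` with points as (FPR, TPR) tuples.
    """
    labels = ranked.labels
    mask = labels != "unknown"
    y = (labels[mask] == "active").astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise UndefinedMetricError(
            "ROC undefined: list must contain at least one active and one decoy"
        )
    # higher "goodness" = better rank; negate average rank
    goodness = -ranked.ranks[mask]
    auc = float(roc_auc_score(y, goodness))
    fpr, tpr, _ = roc_curve(y, goodness)
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def window_size(fraction: float, n_total: int) -> int:
    if not (0 < fraction <= 1):
        raise DataError(f"fraction must be in (0, 1], got {fraction}")
    return math.ceil(fraction * n_total)


def hits_in_window(ranked: RankedList, fraction: float) -> tuple[int, int]:
    """(n_sampled, hits_sampled) for the top-fraction window."""
    n_sampled = window_size(fraction, ranked.n_total)
    hits = sum(r.label == "active" for r in ranked.records[:n_sampled])
    return n_sampled, hits


def enrichment_factor(ranked: RankedList, fraction: float) -> dict:
    """Classical EF at a sampled fraction."""
    if ranked.hits_total < 1:
        raise UndefinedMetricError("EF undefined with no actives in the list")
    n_sampled, hits_sampled = hits_in_window(ranked, fraction)
    ef = (hits_sampled / ranked.hits_total) / (n_sampled / ranked.n_total)
    return {"fraction": fraction, "n_sampled": n_sampled,
            "hits_sampled": hits_sampled, "ef": ef}


def average_percentile_rank(ranked: RankedList) -> float:
    """APR: mean percentile rank over ALL actives (Hits_total of them)."""
    if ranked.hits_total < 1:
        raise UndefinedMetricError("APR undefined with no actives")
    pct = ranked.percentile_ranks()
    active = ranked.labels == "active"
    return float(pct[active].mean())


def modified_enrichment_factor(ranked: RankedList, fraction: float) -> dict:
    """EF'(f) = (50 / APR) × (Hits_sampled / Hits_total).

    Reported as 0 when the window holds no actives, even though the APR
    term is global.
    """
    apr = average_percentile_rank(ranked)
    n_sampled, hits_sampled = hits_in_window(ranked, fraction)
    if hits_sampled == 0 or apr <= 0:
        ef_prime = 0.0
    else:
        ef_prime = (50.0 / apr) * (hits_sampled / ranked.hits_total)
    return {"fraction": fraction, "n_sampled": n_sampled,
            "hits_sampled": hits_sampled, "apr": apr, "ef_prime": ef_prime}


def enhanced_enrichment_factor(ranked: RankedList, fraction: float) -> float:
    """EF*(f): mean of EF over the fraction grid {f/10, 2f/10, ..., f}."""
    grid = [fraction * i / 10.0 for i in range(1, 11)]
    return float(np.mean([enrichment_factor(ranked, g)["ef"] for g in grid]))


def ef_family(ranked_a: RankedList, ranked_b: RankedList, fraction: float) -> dict:
    """EF* for list A plus the difference family DEF/DEF*/DEF' (A minus B).

    Both lists must rank the same compound set.
    """
    ids_a = {r.compound_id for r in ranked_a.records}
    ids_b = {r.compound_id for r in ranked_b.records}
    if ids_a != ids_b:
        diff = sorted(ids_a.symmetric_difference(ids_b))
        raise AlignmentError(f"compound sets differ; symmetric difference: {diff}")
    ef_star_a = enhanced_enrichment_factor(ranked_a, fraction)
    ef_star_b = enhanced_enrichment_factor(ranked_b, fraction)
    def_ = (enrichment_factor(ranked_a, fraction)["ef"]
            - enrichment_factor(ranked_b, fraction)["ef"])
    def_prime = (modified_enrichment_factor(ranked_a, fraction)["ef_prime"]
                 - modified_enrichment_factor(ranked_b, fraction)["ef_prime"])
    return {
        "fraction": fraction,
        "ef_star": ef_star_a,
        "ef_star_b": ef_star_b,
        "def": def_,
        "def_star": ef_star_a - ef_star_b,
        "def_prime": def_prime,
        "note": EF_FAMILY_NOTE,
    }


def top_n_hit_rate(ranked: RankedList, n: int) -> float:
    """Percent of true actives among the top ``n`` ranked compounds."""
    if not (1 <= n <= ranked.n_total):
        raise DataError(f"n must be in [1, {ranked.n_total}], got {n}")
    hits = sum(r.label == "active" for r in ranked.records[:n])
    return 100.0 * hits / n


@dataclass(frozen=True)
class HitCall:
    compound_id: str
    ic50: float | None
    is_hit: bool
    overridden: bool = False


def classify_hits(ic50_table, threshold: float = 100.0, overrides=()) -> tuple[list[HitCall], float]:
    """Classify assayed compounds as hits by IC50 < threshold (µM).

    ``ic50_table`` is an iterable of (compound_id, ic50-or-None); ``None``
    marks compounds inactive at the top tested concentration. Ids listed in
    ``overrides`` are forced to hits regardless of value (borderline calls
    the assay team accepted, e.g. an IC50 a few percent over threshold) and
    flagged in the output. Returns the calls and the hit rate in percent,
    rounded to two decimals.
    """
    overrides = set(overrides)
    calls = []
    for cid, ic50 in ic50_table:
        if ic50 is not None and ic50 <= 0:
            raise DataError(f"non-positive IC50 for {cid!r}: {ic50}")
        forced = cid in overrides
        is_hit = forced or (ic50 is not None and ic50 < threshold)
        calls.append(HitCall(cid, ic50, is_hit, overridden=forced and not (
            ic50 is not None and ic50 < threshold)))
    if not calls:
        raise DataError("empty IC50 table")
    rate = round(100.0 * sum(c.is_hit for c in calls) / len(calls), 2)
    return calls, rate


def enrichment_report(ranked: RankedList, fractions) -> list[dict]:
    """EF and EF' at each fraction plus AUC, as write_report-ready rows."""
    auc, _ = roc_auc(ranked)
    rows = []
    for f in fractions:
        ef = enrichment_factor(ranked, f)
        efp = modified_enrichment_factor(ranked, f)
        rows.append({
            "fraction": f,
            "n_sampled": ef["n_sampled"],
            "hits_sampled": ef["hits_sampled"],
            "ef": ef["ef"],
            "ef_prime": efp["ef_prime"],
            "apr": efp["apr"],
            "auc": auc,
        })
    return rows
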