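"""Evaluation statistics: recall, stoichiometry correlation, FPR and FDR.

All four statistics exist at per-read and/or per-site resolution.  The FDR
is the IVT-normalized surrogate: the fraction of positives in a
modification-free in-vitro-transcribed (IVT) sample divided by the fraction
of positives in the wild-type sample — a lower bound on the true FDR,
optionally capped at 1.  Undefined statistics (empty denominators, too few
common sites, zero variance, the minimum-positives guard) are returned as
``None``, never coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .aggregate import (
    DEFAULT_MIN_COVERAGE,
    DEFAULT_RATIO_CUTOFF,
    SiteProbTable,
    call_modified_sites,
    filter_by_coverage,
)
from .records import (
    ConfusionCounts,
    GroundTruthSite,
    PerReadCall,
    SiteAggregate,
    SiteKey,
    ThresholdPolicy,
    exact_fraction,
)
from .reference import CandidateSiteSet

DEFAULT_MIN_POSITIVES = 10


def per_site_recall(
    predicted_modified: set[SiteKey],
    truth: Iterable[GroundTruthSite],
    assessed_sites: set[SiteKey] | None = None,
) -> tuple[float | None, ConfusionCounts]:
    """Fraction of ground-truth modified sites also called modified.

    Both inputs are expected to be restricted beforehand to one candidate
    universe (coverage-filtered exonic sites).  ``assessed_sites`` — the
    sites where the caller made any assessment — splits false negatives
    into never-assessed vs assessed-but-below-cutoff.
    """
    truth_sites = {t.site for t in truth}
    tp = len(predicted_modified & truth_sites)
    fn_sites = truth_sites - predicted_modified
    fn_no_pred = (
        sum(1 for s in fn_sites if s not in assessed_sites)
        if assessed_sites is not None
        else 0
    )
    counts = ConfusionCounts(
        tp=tp,
        fp=len(predicted_modified - truth_sites),
        fn=len(fn_sites),
        fn_no_prediction=fn_no_pred,
    )
    if not truth_sites:
        return None, counts
    return tp / len(truth_sites), counts


def spearman(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Spearman rank correlation (average ranks on ties); None if undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return None
    rho = stats.spearmanr(x, y).statistic
    return None if np.isnan(rho) else float(rho)


def stoichiometry_correlation(
    a: Mapping[SiteKey, float],
    b: Mapping[SiteKey, float],
    restrict_to: set[SiteKey] | None = None,
) -> tuple[float | None, int]:
    """Spearman correlation of two site->ratio mappings on their common sites.

    ``restrict_to`` further limits the comparison, e.g. to true-positive
    sites.  Undefined (None) below 3 common sites or at zero variance.
    """
    common = sorted(a.keys() & b.keys())
    if restrict_to is not None:
        common = [s for s in common if s in restrict_to]
    rho = spearman([a[s] for s in common], [b[s] for s in common])
    return rho, len(common)


def per_read_fpr(
    ivt_calls: Iterable[PerReadCall] | np.ndarray, policy: ThresholdPolicy
) -> float | None:
    """Fraction of IVT per-read predictions with probability above t.

    Every IVT call is a prediction on an unmodified base, so every call
    above the threshold is a false positive.
    """
    if isinstance(ivt_calls, np.ndarray):
        probs = ivt_calls.astype(float)
    else:
        probs = np.fromiter((c.prob for c in ivt_calls), dtype=float)
    if probs.size == 0:
        return None
    return float(np.count_nonzero(probs > policy.t) / probs.size)


def per_site_fpr(
    ivt_aggregates: Iterable[SiteAggregate],
    ratio_cutoff: float = DEFAULT_RATIO_CUTOFF,
    n_candidate_sites: int | None = None,
) -> float | None:
    """Fraction of IVT sites whose modification ratio reaches the cutoff.

    The denominator is the number of aggregated (coverage-filtered) IVT
    sites; pass ``n_candidate_sites`` to use the full candidate universe
    as the denominator instead.
    """
    aggs = list(ivt_aggregates)
    denom = n_candidate_sites if n_candidate_sites is not None else len(aggs)
    if not denom:
        return None
    n_pos = len(call_modified_sites(aggs, ratio_cutoff))
    return n_pos / denom


def fdr_ratio(
    ivt_pos: int,
    ivt_total: int,
    wt_pos: int,
    wt_total: int,
    cap: bool = True,
    min_positives: int = 0,
) -> float | None:
    """IVT-normalized FDR: (ivt_pos/ivt_total) / (wt_pos/wt_total).

    Positive counts are normalized to fractions of each sample's candidate
    total before taking the ratio, so unequal sample sizes cancel.  With
    ``cap`` the value is clipped at 1.  Undefined when either total is 0,
    when wt_pos is 0, or when either positive count is <= min_positives
    (the guard against unstable points at stringent thresholds).
    """
    if ivt_total == 0 or wt_total == 0 or wt_pos == 0:
        return None
    if min_positives and (wt_pos <= min_positives or ivt_pos <= min_positives):
        return None
    value = (ivt_pos / ivt_total) / (wt_pos / wt_total)
    return min(value, 1.0) if cap else value


# ---------------------------------------------------------------------------
# Threshold sweeps


@dataclass
class MetricPoint:
    """All statistics at one per-read probability threshold (None = undefined)."""

    t: float
    recall: float | None = None
    spearman: float | None = None
    fpr_read: float | None = None
    fpr_site: float | None = None
    fdr_read: float | None = None
    fdr_site: float | None = None
    counts: ConfusionCounts | None = None


@dataclass
class MetricCurve:
    points: list[MetricPoint]

    def __post_init__(self) -> None:
        ts = [p.t for p in self.points]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("threshold grid must be strictly increasing")

    def __iter__(self):
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def to_rows(self) -> list[dict]:
        return [
            {
                "threshold": p.t,
                "recall": p.recall,
                "spearman": p.spearman,
                "fpr_read": p.fpr_read,
                "fpr_site": p.fpr_site,
                "fdr_read": p.fdr_read,
                "fdr_site": p.fdr_site,
                "tp": p.counts.tp if p.counts else None,
                "fp": p.counts.fp if p.counts else None,
                "fn": p.counts.fn if p.counts else None,
                "fn_no_prediction": p.counts.fn_no_prediction if p.counts else None,
            }
            for p in self.points
        ]


def default_threshold_grid(recommended: Iterable[float] = ()) -> list[float]:
    """101 evenly spaced thresholds in [0,1] plus any recommended cutoffs."""
    grid = {round(i / 100, 2) for i in range(101)}
    grid.update(float(t) for t in recommended)
    return sorted(grid)


def _positives_mask(n_mod: np.ndarray, cov: np.ndarray, ratio_cutoff) -> np.ndarray:
    # exact rational comparison n_mod/cov >= p/q  <=>  n_mod*q >= p*cov
    q = exact_fraction(ratio_cutoff)
    return n_mod * q.denominator >= cov * q.numerator


def _obj_array(items: list) -> np.ndarray:
    # object array of site keys; plain np.array would unpack the tuples
    arr = np.empty(len(items), dtype=object)
    for i, x in enumerate(items):
        arr[i] = x
    return arr


def sweep_thresholds(
    wt_calls: Iterable[PerReadCall] | SiteProbTable,
    ivt_calls: Iterable[PerReadCall] | SiteProbTable,
    truth: Iterable[GroundTruthSite],
    grid: Sequence[float] | None = None,
    ratio_cutoff: float = DEFAULT_RATIO_CUTOFF,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    min_positives: int = DEFAULT_MIN_POSITIVES,
    candidate_sites: CandidateSiteSet | None = None,
    truth_universe: set[SiteKey] | None = None,
    tp_restricted_correlation: bool = True,
    cap_fdr: bool = True,
) -> MetricCurve:
    """Evaluate all statistics over a sweep of per-read thresholds.

    Ground truth is restricted to ``truth_universe`` when given, otherwise
    to the WT sites passing the coverage filter (mirroring the restriction
    of chemical ground truth to positions with adequate ONT coverage).
    The correlation is computed at true-positive sites by default.  FDR
    points with positive counts at or below ``min_positives`` are undefined.
    """
    grid = list(grid) if grid is not None else default_threshold_grid()
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("threshold grid must be strictly increasing")
    if not all(0.0 <= t <= 1.0 for t in grid):
        raise ValueError("thresholds must lie in [0,1]")

    wt = (
        wt_calls
        if isinstance(wt_calls, SiteProbTable)
        else SiteProbTable.from_calls(wt_calls, candidate_sites)
    )
    ivt = (
        ivt_calls
        if isinstance(ivt_calls, SiteProbTable)
        else SiteProbTable.from_calls(ivt_calls, candidate_sites)
    )

    wt_cov = wt.coverages()
    ivt_cov = ivt.coverages()
    wt_keep = wt_cov >= min_coverage
    ivt_keep = ivt_cov >= min_coverage
    wt_sites = _obj_array([k[0] for k in wt.keys])
    ivt_sites = _obj_array([k[0] for k in ivt.keys])
    covered_wt = {s for s, keep in zip(wt_sites, wt_keep) if keep}

    universe = truth_universe if truth_universe is not None else covered_wt
    truth_list = [t for t in truth if t.site in universe]
    truth_map = {t.site: t.level for t in truth_list}

    wt_probs_all = np.sort(np.concatenate(wt.probs)) if wt.probs else np.empty(0)
    ivt_probs_all = np.sort(np.concatenate(ivt.probs)) if ivt.probs else np.empty(0)

    points: list[MetricPoint] = []
    for t in grid:
        policy = ThresholdPolicy(t)
        wt_nmod = wt.n_modified_at(t)
        ivt_nmod = ivt.n_modified_at(t)

        wt_pos_mask = _positives_mask(wt_nmod, wt_cov, ratio_cutoff) & wt_keep
        ivt_pos_mask = _positives_mask(ivt_nmod, ivt_cov, ratio_cutoff) & ivt_keep
        predicted = set(wt_sites[wt_pos_mask])

        recall, counts = per_site_recall(predicted, truth_list, assessed_sites=covered_wt)

        wt_ratio = {
            s: float(m / c)
            for s, m, c, keep in zip(wt_sites, wt_nmod, wt_cov, wt_keep)
            if keep
        }
        restrict = predicted & set(truth_map) if tp_restricted_correlation else None
        rho, _ = stoichiometry_correlation(wt_ratio, truth_map, restrict_to=restrict)

        n_wt_reads = wt_probs_all.size
        n_ivt_reads = ivt_probs_all.size
        wt_reads_pos = int(n_wt_reads - np.searchsorted(wt_probs_all, t, side="right"))
        ivt_reads_pos = int(n_ivt_reads - np.searchsorted(ivt_probs_all, t, side="right"))

        fpr_read = ivt_reads_pos / n_ivt_reads if n_ivt_reads else None
        n_ivt_sites = int(np.count_nonzero(ivt_keep))
        fpr_site = int(np.count_nonzero(ivt_pos_mask)) / n_ivt_sites if n_ivt_sites else None

        fdr_read = fdr_ratio(
            ivt_reads_pos, n_ivt_reads, wt_reads_pos, n_wt_reads,
            cap=cap_fdr, min_positives=min_positives,
        )
        fdr_site = fdr_ratio(
            int(np.count_nonzero(ivt_pos_mask)), n_ivt_sites,
            int(np.count_nonzero(wt_pos_mask)), int(np.count_nonzero(wt_keep)),
            cap=cap_fdr, min_positives=min_positives,
        )
        points.append(
            MetricPoint(
                t=t, recall=recall, spearman=rho, fpr_read=fpr_read,
                fpr_site=fpr_site, fdr_read=fdr_read, fdr_site=fdr_site,
                counts=counts,
            )
        )
    return MetricCurve(points)


def fdr_vs_ratio_curve(
    wt_aggregates: Iterable[SiteAggregate],
    ivt_aggregates: Iterable[SiteAggregate],
    ratio_grid: Sequence[float],
    min_positives: int = DEFAULT_MIN_POSITIVES,
    cap: bool = True,
) -> list[tuple[float, float | None]]:
    """Per-site FDR as a function of the ratio cutoff, at a fixed per-read t."""
    wt = list(wt_aggregates)
    ivt = list(ivt_aggregates)
    out = []
    for cutoff in ratio_grid:
        wt_pos = sum(1 for a in wt if a.ratio_at_least(cutoff))
        ivt_pos = sum(1 for a in ivt if a.ratio_at_least(cutoff))
        out.append(
            (
                float(cutoff),
                fdr_ratio(ivt_pos, len(ivt), wt_pos, len(wt), cap=cap, min_positives=min_positives),
            )
        )
    return out


@dataclass
class ConcordanceResult:
    rho: float | None
    n_common: int
    frac_a: float | None
    frac_b: float | None


def cross_sample_concordance(
    a_aggregates: Iterable[SiteAggregate], b_aggregates: Iterable[SiteAggregate]
) -> ConcordanceResult:
    """Spearman of per-site ratios on the sites common to two samples."""
    a = {x.site: x.ratio for x in a_aggregates}
    b = {x.site: x.ratio for x in b_aggregates}
    rho, n_common = stoichiometry_correlation(a, b)
    return ConcordanceResult(
        rho=rho,
        n_common=n_common,
        frac_a=n_common / len(a) if a else None,
        frac_b=n_common / len(b) if b else None,
    )


def intermediate_band_fraction(
    a_aggregates: Iterable[SiteAggregate],
    b_aggregates: Iterable[SiteAggregate],
    lo: float = 0.05,
    hi: float = 0.40,
) -> float | None:
    """Fraction of common sites with both ratios inside [lo, hi].

    Sites with intermediate ratios in both a wild-type and an IVT sample
    point at systematic model biases rather than biology.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    a = {x.site: x.ratio_exact for x in a_aggregates}
    b = {x.site: x.ratio_exact for x in b_aggregates}
    common = a.keys() & b.keys()
    if not common:
        return None
    qlo, qhi = exact_fraction(lo), exact_fraction(hi)
    n_band = sum(1 for s in common if qlo <= a[s] <= qhi and qlo <= b[s] <= qhi)
    return n_band / len(common)
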