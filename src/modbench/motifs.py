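"""Motif-stratified evaluation.

Sequence context strongly shapes caller behavior: recall, stoichiometry
correlation, per-site FPR and FDR all vary across the 18 DRACH 5-mers.
This module partitions sites by their reference-derived sense-strand
context and recomputes each per-site statistic within the partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .aggregate import DEFAULT_RATIO_CUTOFF, call_modified_sites
from .metrics import fdr_ratio, per_site_recall, stoichiometry_correlation
from .records import ConfusionCounts, GroundTruthSite, SiteAggregate, SiteKey
from .reference import CandidateSiteSet, context_of

UNRESOLVED_MOTIF = "NNNNN"


@dataclass
class MotifMetrics:
    """Per-site statistics restricted to sites sharing one 5-mer context."""

    motif: str
    count: int
    correlation: float | None
    recall: float | None
    fpr_site: float | None
    fdr_site: float | None
    counts: ConfusionCounts
    n_truth: int = 0
    n_ivt: int = 0


def _motif_lookup(
    sites: Iterable[SiteKey],
    candidate_sites: CandidateSiteSet | None,
    reference: Mapping[str, object] | None,
) -> dict[SiteKey, str]:
    out: dict[SiteKey, str] = {}
    for site in sites:
        motif = None
        if candidate_sites is not None:
            motif = candidate_sites.sites.get(site)
        if motif is None and reference is not None:
            try:
                motif = context_of(site, reference)
            except Exception:
                motif = None
        out[site] = motif if motif is not None else UNRESOLVED_MOTIF
    return out


def motif_stratified_metrics(
    wt_aggregates: Iterable[SiteAggregate],
    ivt_aggregates: Iterable[SiteAggregate],
    truth: Iterable[GroundTruthSite],
    candidate_sites: CandidateSiteSet | None = None,
    ratio_cutoff: float = DEFAULT_RATIO_CUTOFF,
    reference: Mapping[str, object] | None = None,
    min_positives: int = 0,
    cap_fdr: bool = True,
) -> list[MotifMetrics]:
    """Partition sites by 5-mer context and evaluate each partition.

    Inputs are expected to be coverage-filtered already.  Sites whose
    context cannot be resolved through the candidate set or the reference
    fall into an ``NNNNN`` bucket, which is reported like any motif.
    Output is sorted alphabetically by motif.  ``count`` is the number of
    distinct stratified sites (WT, IVT or truth) carrying the motif, so
    counts sum to the total number of stratified sites.
    """
    wt = list(wt_aggregates)
    ivt = list(ivt_aggregates)
    truth = list(truth)

    all_sites = {a.site for a in wt} | {a.site for a in ivt} | {t.site for t in truth}
    motif_of = _motif_lookup(all_sites, candidate_sites, reference)
    motifs = sorted({motif_of[s] for s in all_sites})

    wt_ratio = {a.site: a.ratio for a in wt}
    predicted_all = call_modified_sites(wt, ratio_cutoff)
    ivt_pos_all = call_modified_sites(ivt, ratio_cutoff)

    out: list[MotifMetrics] = []
    for motif in motifs:
        sites = {s for s in all_sites if motif_of[s] == motif}
        wt_m = [a for a in wt if a.site in sites]
        ivt_m = [a for a in ivt if a.site in sites]
        truth_m = [t for t in truth if t.site in sites]
        truth_map = {t.site: t.level for t in truth_m}

        predicted = predicted_all & sites
        assessed = {a.site for a in wt_m}
        recall, counts = per_site_recall(predicted, truth_m, assessed_sites=assessed)

        rho, _ = stoichiometry_correlation(
            {s: wt_ratio[s] for s in assessed},
            truth_map,
            restrict_to=predicted & set(truth_map),
        )

        n_ivt = len(ivt_m)
        ivt_pos = len(ivt_pos_all & sites)
        fpr_site = ivt_pos / n_ivt if n_ivt else None
        fdr_site = fdr_ratio(
            ivt_pos, n_ivt, len(predicted), len(wt_m),
            cap=cap_fdr, min_positives=min_positives,
        )
        out.append(
            MotifMetrics(
                motif=motif,
                count=len(sites),
                correlation=rho,
                recall=recall,
                fpr_site=fpr_site,
                fdr_site=fdr_site,
                counts=counts,
                n_truth=len(truth_m),
                n_ivt=n_ivt,
            )
        )
    return out


def pooled_confusion(motif_metrics: Iterable[MotifMetrics]) -> ConfusionCounts:
    """Sum per-motif confusion counts; equals the global counts exactly."""
    total = ConfusionCounts()
    for m in motif_metrics:
        total = total + m.counts
    return total
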