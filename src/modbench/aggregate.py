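"""Per-read threshold classification and per-site ratio aggregation.

A per-read call is classified modified iff its probability strictly exceeds
the threshold.  The per-site modification ratio is the number of modified
classifications divided by all assessments at the site — no intermediate
probabilities are discarded, unlike Modkit's dual-threshold pileup.
Boundary semantics: strict ``>`` for the per-read threshold, inclusive
``>=`` for the ratio cutoff and coverage filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .records import PerReadCall, SiteAggregate, SiteKey, ThresholdPolicy
from .reference import CandidateSiteSet

DEFAULT_RATIO_CUTOFF = 0.10
DEFAULT_MIN_COVERAGE = 10


def classify_call(call: PerReadCall, policy: ThresholdPolicy) -> str:
    """'modified' iff prob > t (strict), else 'unmodified'."""
    return "modified" if policy.is_modified(call.prob) else "unmodified"


@dataclass
class SiteProbTable:
    """Per-site sorted probability arrays after per-molecule deduplication.

    Intermediate form shared by single-threshold aggregation and threshold
    sweeps: deduplicate and group once, count at any threshold cheaply.
    """

    keys: list[tuple[SiteKey, str]]
    probs: list[np.ndarray]
    n_calls: int = 0
    n_outside_candidates: int = 0

    @classmethod
    def from_calls(
        cls,
        calls: Iterable[PerReadCall],
        candidate_sites: CandidateSiteSet | None = None,
    ) -> "SiteProbTable":
        # A read assessed more than once at one site (e.g. supplementary
        # alignments) is collapsed to its maximum-probability call.
        best: dict[tuple[SiteKey, str], dict[str, float]] = {}
        n_calls = 0
        n_outside = 0
        for call in calls:
            n_calls += 1
            if candidate_sites is not None and call.site not in candidate_sites:
                n_outside += 1
                continue
            reads = best.setdefault((call.site, call.mod_code), {})
            prev = reads.get(call.read_id)
            if prev is None or call.prob > prev:
                reads[call.read_id] = call.prob
        keys = sorted(best, key=lambda k: (k[0].chrom, k[0].pos, k[0].strand, k[1]))
        probs = [np.sort(np.fromiter(best[k].values(), dtype=float)) for k in keys]
        return cls(keys=keys, probs=probs, n_calls=n_calls, n_outside_candidates=n_outside)

    def coverages(self) -> np.ndarray:
        return np.fromiter((p.size for p in self.probs), dtype=np.int64, count=len(self.probs))

    def n_modified_at(self, t: float) -> np.ndarray:
        """Per-site count of calls with prob strictly above t."""
        return np.fromiter(
            (p.size - np.searchsorted(p, t, side="right") for p in self.probs),
            dtype=np.int64,
            count=len(self.probs),
        )

    def aggregates_at(self, policy: ThresholdPolicy) -> list[SiteAggregate]:
        n_mod = self.n_modified_at(policy.t)
        return [
            SiteAggregate(
                site=key[0],
                mod_code=key[1],
                coverage=int(p.size),
                n_modified=int(m),
                threshold_used=policy.t,
            )
            for key, p, m in zip(self.keys, self.probs, n_mod)
        ]


def aggregate_sites(
    calls: Iterable[PerReadCall],
    policy: ThresholdPolicy,
    candidate_sites: CandidateSiteSet | None = None,
) -> list[SiteAggregate]:
    """One SiteAggregate per distinct (site, mod_code) in the calls.

    When a candidate set is given, calls outside it are discarded (their
    count is available through :class:`SiteProbTable`).
    """
    return SiteProbTable.from_calls(calls, candidate_sites).aggregates_at(policy)


def filter_by_coverage(
    aggregates: Iterable[SiteAggregate], min_coverage: int = DEFAULT_MIN_COVERAGE
) -> list[SiteAggregate]:
    """Keep aggregates with coverage >= min_coverage (inclusive)."""
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    return [a for a in aggregates if a.coverage >= min_coverage]


def call_modified_sites(
    aggregates: Iterable[SiteAggregate], ratio_cutoff: float = DEFAULT_RATIO_CUTOFF
) -> set[SiteKey]:
    """Sites whose exact modification ratio is >= the cutoff (inclusive)."""
    if not 0.0 <= float(ratio_cutoff) <= 1.0:
        raise ValueError("ratio_cutoff must be in [0,1]")
    return {a.site for a in aggregates if a.ratio_at_least(ratio_cutoff)}
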