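"""Recurrent false-positive blacklist built from modification-free samples.

Sites recurrently called modified across independent IVT samples are very
likely systematic artifacts (sequence-context biases, signal noise) rather
than biology.  Each site observed in the IVT panel gets a posterior score
from a Beta-Binomial model over "called positive in an IVT sample":

    score = (alpha + n_positive) / (alpha + beta + n_observed)

with a Beta(alpha, beta) prior (default uniform).  The closed form keeps
single-sample behavior graceful — one positive observation under the
uniform prior scores 2/3, not 1 — and the model is an extension point:
coverage-weighted or sequence-aware scores would slot in here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .aggregate import DEFAULT_RATIO_CUTOFF
from .errors import FormatError
from .records import SiteAggregate, SiteKey

DEFAULT_PRIOR = (1.0, 1.0)


@dataclass(frozen=True)
class BlacklistEntry:
    site: SiteKey
    n_samples_observed: int
    n_samples_positive: int
    mean_ivt_ratio: float
    score: float

    def __post_init__(self) -> None:
        if self.n_samples_positive > self.n_samples_observed:
            raise ValueError("positive samples cannot exceed observed samples")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0,1]")


def blacklist_score(
    n_positive: int, n_observed: int, prior: tuple[float, float] = DEFAULT_PRIOR
) -> float:
    """Posterior mean probability that a site is a recurrent false positive."""
    alpha, beta = prior
    if alpha <= 0 or beta <= 0:
        raise ValueError("prior parameters must be positive")
    if not 0 <= n_positive <= n_observed:
        raise ValueError("need 0 <= n_positive <= n_observed")
    return (alpha + n_positive) / (alpha + beta + n_observed)


def build_blacklist(
    ivt_sample_aggregates: Sequence[Iterable[SiteAggregate]],
    ratio_cutoff: float = DEFAULT_RATIO_CUTOFF,
    prior: tuple[float, float] = DEFAULT_PRIOR,
) -> list[BlacklistEntry]:
    """Score every site observed in a panel of coverage-filtered IVT samples.

    A site is "observed" in a sample when it has an aggregate there (i.e.
    had coverage), and "positive" when its ratio reaches the cutoff.
    Entries are sorted by descending score, then by site for stability.
    """
    observed: dict[SiteKey, int] = {}
    positive: dict[SiteKey, int] = {}
    ratio_sum: dict[SiteKey, float] = {}
    for sample in ivt_sample_aggregates:
        for agg in sample:
            s = agg.site
            observed[s] = observed.get(s, 0) + 1
            ratio_sum[s] = ratio_sum.get(s, 0.0) + agg.ratio
            if agg.ratio_at_least(ratio_cutoff):
                positive[s] = positive.get(s, 0) + 1
    entries = [
        BlacklistEntry(
            site=s,
            n_samples_observed=n_obs,
            n_samples_positive=positive.get(s, 0),
            mean_ivt_ratio=ratio_sum[s] / n_obs,
            score=blacklist_score(positive.get(s, 0), n_obs, prior),
        )
        for s, n_obs in observed.items()
    ]
    entries.sort(key=lambda e: (-e.score, e.site.chrom, e.site.pos, e.site.strand))
    return entries


def apply_blacklist(
    predicted_sites: set[SiteKey],
    blacklist: Iterable[BlacklistEntry],
    score_cutoff: float = 0.9,
) -> tuple[set[SiteKey], set[SiteKey]]:
    """Split predictions into (kept, removed) by blacklist score >= cutoff.

    The two sets partition the input; filtering never adds sites.
    """
    if not 0.0 <= score_cutoff <= 1.0:
        raise ValueError("score_cutoff must lie in [0,1]")
    flagged = {e.site for e in blacklist if e.score >= score_cutoff}
    removed = predicted_sites & flagged
    return predicted_sites - removed, removed


BLACKLIST_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "n_samples_observed", "n_samples_positive", "mean_ivt_ratio",
]


def write_blacklist(entries: Iterable[BlacklistEntry], path: str | Path) -> None:
    rows = [
        (
            e.site.chrom, e.site.pos, e.site.pos + 1, "ivt_recurrent",
            repr(e.score), e.site.strand, e.n_samples_observed,
            e.n_samples_positive, repr(e.mean_ivt_ratio),
        )
        for e in entries
    ]
    pd.DataFrame(rows, columns=BLACKLIST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_blacklist(path: str | Path) -> list[BlacklistEntry]:
    df = pd.read_csv(path, sep="\t")
    for needed in BLACKLIST_COLUMNS:
        if needed not in df.columns:
            raise FormatError(f"{path}: missing column {needed!r} in blacklist")
    return [
        BlacklistEntry(
            site=SiteKey(str(r.chrom), int(r.start), str(r.strand)),
            n_samples_observed=int(r.n_samples_observed),
            n_samples_positive=int(r.n_samples_positive),
            mean_ivt_ratio=float(r.mean_ivt_ratio),
            score=float(r.score),
        )
        for r in df.itertuples(index=False)
    ]
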