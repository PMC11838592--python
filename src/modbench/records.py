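"""Core records shared across the benchmarking pipeline.

All genomic coordinates are 0-based, half-open, and strand-explicit.
Modification chemistry is strand-specific, so a position assessed on both
strands yields two distinct sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import NamedTuple

MOD_CODES = frozenset({"m6A", "pseU", "m5C", "inosine"})

#: Genomic coordinate space (default for Modkit-extract style calls).
GENOME = "genome"
#: Transcript coordinate space (m6Anet per-read output before lifting).
TRANSCRIPT = "transcript"


class SiteKey(NamedTuple):
    """One strand-specific reference position."""

    chrom: str
    pos: int
    strand: str

    def validate(self) -> "SiteKey":
        if self.pos < 0:
            raise ValueError(f"negative position: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-': {self!r}")
        return self


class PerReadCall(NamedTuple):
    """One caller assessment of one base on one read.

    ``context`` is the sense-strand 5-mer centered on the called base
    (``NNNNN`` when unknown).  ``coord_space`` distinguishes genomic calls
    from transcript-coordinate calls that still need lifting.
    """

    read_id: str
    sample_id: str
    site: SiteKey
    mod_code: str
    prob: float
    context: str = "NNNNN"
    coord_space: str = GENOME

    def validate(self) -> "PerReadCall":
        self.site.validate()
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError(f"probability out of [0,1]: {self.prob}")
        if len(self.context) != 5:
            raise ValueError(f"context must be a 5-mer: {self.context!r}")
        if self.mod_code not in MOD_CODES:
            raise ValueError(f"unknown modification code: {self.mod_code!r}")
        return self


class GroundTruthSite(NamedTuple):
    """Chemically determined per-site stoichiometry (replicate-averaged)."""

    site: SiteKey
    level: float
    source: str = ""

    def validate(self) -> "GroundTruthSite":
        self.site.validate()
        if not 0.0 <= self.level <= 1.0:
            raise ValueError(f"stoichiometry out of [0,1]: {self.level}")
        return self


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of one transcript.

    ``exons`` are genomic half-open ``[start, end)`` intervals sorted by
    genomic start and non-overlapping, regardless of strand; transcription
    order on the minus strand runs through them backwards.
    """

    tx_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-': {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.tx_id}: transcript needs at least one exon")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for start, end in exons:
            if start < 0 or end <= start:
                raise ValueError(f"{self.tx_id}: bad exon interval ({start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.tx_id}: exons overlap or are unsorted")
            prev_end = end

    @property
    def length(self) -> int:
        return sum(end - start for start, end in self.exons)


def exact_fraction(x: float | int | str | Fraction) -> Fraction:
    """Interpret a numeric cutoff as the exact decimal it was written as.

    Per-site boundary semantics are inclusive and must hold exactly on
    rational ratios (e.g. 3 modified reads of 30 is *at* a 10% cutoff), so
    float cutoffs are read back through their shortest decimal repr rather
    than their binary expansion.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(str(x))


@dataclass(frozen=True)
class SiteAggregate:
    """Per-site read counts and modification ratio at one per-read threshold.

    The ratio is kept as an exact integer pair; ``ratio`` is the float view.
    """

    site: SiteKey
    mod_code: str
    coverage: int
    n_modified: int
    threshold_used: float

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError(f"{self.site}: coverage must be positive")
        if not 0 <= self.n_modified <= self.coverage:
            raise ValueError(f"{self.site}: n_modified outside [0, coverage]")

    @property
    def ratio(self) -> float:
        return self.n_modified / self.coverage

    @property
    def ratio_exact(self) -> Fraction:
        return Fraction(self.n_modified, self.coverage)

    def ratio_at_least(self, cutoff: float | Fraction) -> bool:
        """Inclusive comparison of the exact ratio against a decimal cutoff."""
        return self.ratio_exact >= exact_fraction(cutoff)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Per-read probability threshold; a call is modified iff prob > t.

    The comparison is strictly greater: a probability exactly at the
    threshold is classified unmodified.
    """

    t: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.t <= 1.0:
            raise ValueError(f"threshold out of [0,1]: {self.t}")

    def is_modified(self, prob: float) -> bool:
        return prob > self.t


#: Recommended per-read thresholds shipped as overridable defaults: the
#: m6Anet default cutoff, and the Modkit-estimated Dorado cutoff typically
#: obtained by sampling the probability distribution.
RECOMMENDED_THRESHOLDS = {"m6anet": 0.033, "dorado": 0.61}


@dataclass
class ConfusionCounts:
    """Site-level confusion counts against a positives-only ground truth.

    ``fn_no_prediction`` separates truth sites where the caller made no
    assessment at all from those assessed but left below the ratio cutoff.
    True negatives are not identifiable against a positives-only truth and
    are reported as 0.
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    fn_no_prediction: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn, self.fn_no_prediction) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.fn_no_prediction > self.fn:
            raise ValueError("fn_no_prediction cannot exceed fn")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
            tn=self.tn + other.tn,
            fn_no_prediction=self.fn_no_prediction + other.fn_no_prediction,
        )
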