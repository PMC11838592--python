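"""Candidate modification sites on the reference and coordinate lifting.

m6A candidates are exonic adenosines in a DRACH context; pseudouridine
candidates are exonic uridines (T on the DNA alphabet).  Contexts are
sense-strand 5-mers: for minus-strand sites the genomic window is
reverse-complemented.  Transcript coordinates (m6Anet output) are lifted
to genomic coordinates by walking exon blocks in transcription order.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import CoordinateError
from .records import GENOME, PerReadCall, SiteKey, TranscriptModel

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# DRACH on the DNA alphabet: D={A,G,T}, R={A,G}, A, C, H={A,C,T}.
_DRACH_RE = re.compile(r"[AGT][AG]AC[ACT]")
DRACH_MOTIFS: frozenset[str] = frozenset(
    "".join(m) for m in itertools.product("AGT", "AG", "A", "C", "ACT")
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_drach(kmer: str) -> bool:
    return len(kmer) == 5 and _DRACH_RE.fullmatch(kmer) is not None


def _chrom_seq(reference: Mapping[str, object], chrom: str) -> str:
    try:
        seq = reference[chrom]
    except KeyError:
        raise CoordinateError(f"unknown sequence {chrom!r}") from None
    return str(seq).upper().replace("U", "T")


def context_of(site: SiteKey, reference: Mapping[str, object], flank: int = 2) -> str:
    """Sense-strand k-mer around a site, N-padded at sequence edges."""
    seq = _chrom_seq(reference, site.chrom)
    if not 0 <= site.pos < len(seq):
        raise CoordinateError(f"{site} outside sequence of length {len(seq)}")
    lo, hi = site.pos - flank, site.pos + flank + 1
    window = (
        "N" * max(0, -lo) + seq[max(0, lo) : min(len(seq), hi)] + "N" * max(0, hi - len(seq))
    )
    return reverse_complement(window) if site.strand == "-" else window


@dataclass
class CandidateSiteSet:
    """Candidate sites for one modification, mapped to sense-strand 5-mers."""

    mod_code: str
    sites: dict[SiteKey, str] = field(default_factory=dict)

    def __contains__(self, site: SiteKey) -> bool:
        return site in self.sites

    def __len__(self) -> int:
        return len(self.sites)

    def context(self, site: SiteKey) -> str:
        return self.sites.get(site, "NNNNN")


def enumerate_candidate_sites(
    reference: Mapping[str, object],
    models: Iterable[TranscriptModel],
    mod_code: str = "m6A",
) -> CandidateSiteSet:
    """Enumerate exonic candidate positions for one modification.

    For m6A every returned context matches DRACH; for pseU every sense-strand
    center is T.  Overlapping transcripts are deduplicated; the same genomic
    position on both strands yields two distinct sites.  N-containing
    contexts never match DRACH.
    """
    out = CandidateSiteSet(mod_code=mod_code)
    center = "A" if mod_code == "m6A" else "T"
    for model in models:
        seq = _chrom_seq(reference, model.chrom)
        for start, end in model.exons:
            if start < 0 or end > len(seq):
                raise CoordinateError(
                    f"{model.tx_id}: exon ({start},{end}) outside {model.chrom!r} "
                    f"of length {len(seq)}"
                )
            for pos in range(start, end):
                site = SiteKey(model.chrom, pos, model.strand)
                if site in out.sites:
                    continue
                ctx = context_of(site, reference)
                if ctx[2] != center:
                    continue
                if mod_code == "m6A" and not is_drach(ctx):
                    continue
                out.sites[site] = ctx
    return out


# ---------------------------------------------------------------------------
# Transcript <-> genome coordinate lifting


def transcript_to_genome(tx_pos: int, model: TranscriptModel) -> SiteKey:
    """Map a 0-based transcript offset to its genomic site.

    Exons are walked in transcription order: ascending genomic order on the
    plus strand, descending with within-exon reversal on the minus strand.
    """
    if not 0 <= tx_pos < model.length:
        raise CoordinateError(
            f"{model.tx_id}: transcript position {tx_pos} outside [0, {model.length})"
        )
    remaining = tx_pos
    exons = model.exons if model.strand == "+" else model.exons[::-1]
    for start, end in exons:
        size = end - start
        if remaining < size:
            pos = start + remaining if model.strand == "+" else end - 1 - remaining
            return SiteKey(model.chrom, pos, model.strand)
        remaining -= size
    raise AssertionError("unreachable: tx_pos checked against transcript length")


def genome_to_transcript(site: SiteKey, model: TranscriptModel) -> int | None:
    """Inverse of :func:`transcript_to_genome`; None off-exon or off-strand."""
    if site.chrom != model.chrom or site.strand != model.strand:
        return None
    offset = 0
    exons = model.exons if model.strand == "+" else model.exons[::-1]
    for start, end in exons:
        if start <= site.pos < end:
            within = site.pos - start if model.strand == "+" else end - 1 - site.pos
            return offset + within
        offset += end - start
    return None


def lift_calls(
    calls: Iterable[PerReadCall],
    models: Mapping[str, TranscriptModel],
    reference: Mapping[str, object] | None = None,
) -> tuple[list[PerReadCall], int]:
    """Lift transcript-coordinate calls to genomic coordinates.

    Transcript predictions sharing a genomic site are pooled per site; a
    read assessed at the same genomic site through several transcripts is
    collapsed to its maximum-probability call, keeping one assessment per
    molecule.  Returns the lifted calls and the count of calls dropped for
    referencing unknown transcripts.
    """
    best: dict[tuple[str, SiteKey], PerReadCall] = {}
    n_unmapped = 0
    order: list[tuple[str, SiteKey]] = []
    for call in calls:
        model = models.get(call.site.chrom)
        if model is None:
            n_unmapped += 1
            continue
        gsite = transcript_to_genome(call.site.pos, model)
        key = (call.read_id, gsite)
        ctx = call.context
        if ctx == "NNNNN" and reference is not None:
            ctx = context_of(gsite, reference)
        lifted = call._replace(site=gsite, context=ctx, coord_space=GENOME)
        prev = best.get(key)
        if prev is None:
            best[key] = lifted
            order.append(key)
        elif lifted.prob > prev.prob:
            best[key] = lifted
    return [best[k] for k in order], n_unmapped
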