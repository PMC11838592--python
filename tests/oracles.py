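"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is deliberately naive — plain loops, regex scans,
rank-then-Pearson — and shares no code with the implementation paths it
checks.
"""

from __future__ import annotations

import re

import numpy as np


def brute_aggregate(calls, t):
    """Naive per-site recount: {(site, mod): (coverage, n_modified)}.

    Duplicate (read, site) assessments keep the maximum probability.
    """
    per_site: dict = {}
    for c in calls:
        key = (c.site, c.mod_code)
        reads = per_site.setdefault(key, {})
        if c.read_id not in reads or c.prob > reads[c.read_id]:
            reads[c.read_id] = c.prob
    return {
        key: (len(reads), sum(1 for p in reads.values() if p > t))
        for key, reads in per_site.items()
    }


def brute_recall(predicted: set, truth_sites: set):
    if not truth_sites:
        return None
    return len(predicted & truth_sites) / len(truth_sites)


def brute_per_read_fpr(probs, t):
    probs = list(probs)
    if not probs:
        return None
    return sum(1 for p in probs if p > t) / len(probs)


def brute_per_site_fpr(ratios, cutoff):
    from fractions import Fraction

    # cutoffs are decimals by contract (0.1 means exactly 1/10)
    ratios = list(ratios)
    if not ratios:
        return None
    exact = Fraction(str(cutoff))
    return sum(1 for r in ratios if r >= exact) / len(ratios)


def brute_fdr(ivt_pos, ivt_total, wt_pos, wt_total, cap=True):
    if 0 in (ivt_total, wt_total) or wt_pos == 0:
        return None
    v = (ivt_pos / ivt_total) / (wt_pos / wt_total)
    return min(v, 1.0) if cap else v


def average_ranks(values):
    """Average ranks on ties, computed by explicit tie-group walking."""
    order = np.argsort(values, kind="stable")
    values = np.asarray(values, dtype=float)
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def rank_then_pearson(x, y):
    """Spearman via explicit ranking followed by the Pearson formula."""
    rx, ry = average_ranks(x), average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return None
    return float((rx * ry).sum() / denom)


DRACH_REGEX = re.compile(r"(?=([AGT][AG]AC[ACT]))")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def regex_drach_sites(seq: str, exons, strand: str):
    """Brute-force DRACH centers: scan the (reverse-complemented) sequence.

    Returns 0-based genomic positions of the central A for sites on
    ``strand``, restricted to the exonic positions given.
    """
    exonic = {p for s, e in exons for p in range(s, e)}
    scan = seq if strand == "+" else revcomp(seq)
    positions = []
    for m in DRACH_REGEX.finditer(scan):
        center_scan = m.start(1) + 2
        pos = center_scan if strand == "+" else len(seq) - 1 - center_scan
        if pos in exonic:
            positions.append(pos)
    return sorted(positions)
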