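from __future__ import annotations

import numpy as np
import pytest

from modbench.records import GroundTruthSite, PerReadCall, SiteKey, TranscriptModel


@pytest.fixture
def two_exon_plus():
    return TranscriptModel(tx_id="txp", chrom="chr1", strand="+", exons=((100, 200), (300, 400)))


@pytest.fixture
def one_exon_minus():
    return TranscriptModel(tx_id="txm", chrom="chr1", strand="-", exons=((100, 200),))


def make_call(
    chrom="chr1", pos=10, strand="+", prob=0.5, read_id="r1",
    sample_id="s", mod_code="m6A", context="NNNNN",
):
    return PerReadCall(
        read_id=read_id, sample_id=sample_id, site=SiteKey(chrom, pos, strand),
        mod_code=mod_code, prob=prob, context=context,
    )


@pytest.fixture
def call_factory():
    return make_call


def random_instance(rng: np.random.Generator, max_sites=100, max_reads=50):
    """A random small call set + truth table for oracle-equivalence checks."""
    n_sites = int(rng.integers(2, max_sites + 1))
    wt_calls, ivt_calls = [], []
    sites = []
    for i in range(n_sites):
        site = SiteKey(f"chr{int(rng.integers(1, 4))}", int(rng.integers(0, 500)), "+-"[int(rng.integers(2))])
        sites.append(site)
        for sample, bucket in (("wt", wt_calls), ("ivt", ivt_calls)):
            n_reads = int(rng.integers(1, max_reads + 1))
            for j in range(n_reads):
                bucket.append(
                    PerReadCall(
                        read_id=f"{sample}:{i}:{j}", sample_id=sample, site=site,
                        mod_code="m6A", prob=float(np.round(rng.random(), 3)),
                    )
                )
    uniq = sorted(set(sites), key=lambda s: (s.chrom, s.pos, s.strand))
    n_truth = int(rng.integers(1, max(2, len(uniq) // 2)))
    idx = rng.choice(len(uniq), size=min(n_truth, len(uniq)), replace=False)
    truth = [
        GroundTruthSite(site=uniq[i], level=float(0.1 + 0.9 * rng.random()))
        for i in sorted(idx)
    ]
    return wt_calls, ivt_calls, truth
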