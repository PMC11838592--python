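"""Synthetic paired WT/IVT call sets with the structure the pipeline assumes.

The generator emulates what the evaluation needs from real data:

* a zero-inflated per-site stoichiometry landscape — most candidate sites
  carry no modification; truly modified sites draw a stoichiometry from a
  Beta law rescaled to [0.1, 1], matching the convention that chemical
  ground truth only reports sites with at least 10% stoichiometry;
* read-level Bernoulli modification states at each wild-type site, and
  all-unmodified states in the in-vitro-transcribed (IVT) controls;
* caller probability emissions as Beta mixtures: a well-separated bimodal
  regime (mass near 0 and near 1) and a unimodal regime with a single peak
  near zero, the two qualitative shapes real callers display;
* motif-dependent false-positive heterogeneity — unmodified reads at
  weighted 5-mer contexts mix a high-probability component into their
  emission, producing recurrent per-site false positives shared across
  IVT samples;
* optional 3'-positional inflation of the false-positive tail.

Everything is deterministic under the seed, and closed-form expected
statistics are provided as an independent oracle for the Monte-Carlo
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import ConfigurationError
from .io import write_fasta, write_gtf, write_ground_truth, write_per_read_calls
from .records import (
    GroundTruthSite,
    PerReadCall,
    SiteKey,
    ThresholdPolicy,
    TranscriptModel,
    exact_fraction,
)
from .reference import CandidateSiteSet, enumerate_candidate_sites

#: Emission Beta parameters per qualitative regime: (modified, unmodified).
EMISSION_SHAPES = {
    "bimodal": ((9.0, 1.0), (1.0, 9.0)),
    "unimodal": ((2.0, 5.0), (1.0, 15.0)),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the WT/IVT generator.

    Defaults are the desk-scale study conditions: 2000 candidate sites of
    which 10% are truly modified, stoichiometries Beta(1.2, 1.8) rescaled
    to [0.1, 1] (median ~0.44, matching ground-truth medians near 40-48%),
    negative-binomial coverage with mean 30 and dispersion 8 floored at
    one read, and well-separated bimodal emissions.
    """

    seed: int = 7
    n_sites: int = 2000
    modified_fraction: float = 0.10
    stoichiometry_beta: tuple[float, float] = (1.2, 1.8)
    stoichiometry_floor: float = 0.10
    coverage_mean: float = 30.0
    coverage_dispersion: float = 8.0
    emission_shape: str = "bimodal"
    emission_modified: tuple[float, float] | None = None
    emission_unmodified: tuple[float, float] | None = None
    fp_tail_weight: float = 0.0
    motif_fp_weights: Mapping[str, float] = field(default_factory=dict)
    three_prime_bias: float = 0.0
    n_ivt_samples: int = 1
    mod_code: str = "m6A"

    def __post_init__(self) -> None:
        if self.emission_shape not in EMISSION_SHAPES:
            raise ConfigurationError(
                f"emission_shape must be one of {sorted(EMISSION_SHAPES)}"
            )
        if not 0.0 <= self.modified_fraction <= 1.0:
            raise ConfigurationError("modified_fraction must lie in [0,1]")
        if not 0.0 <= self.fp_tail_weight <= 1.0:
            raise ConfigurationError("fp_tail_weight must lie in [0,1]")
        if self.three_prime_bias < 0:
            raise ConfigurationError("three_prime_bias must be >= 0")
        if self.n_ivt_samples < 1 or self.n_sites < 1:
            raise ConfigurationError("need n_sites >= 1 and n_ivt_samples >= 1")

    @property
    def beta_modified(self) -> tuple[float, float]:
        return self.emission_modified or EMISSION_SHAPES[self.emission_shape][0]

    @property
    def beta_unmodified(self) -> tuple[float, float]:
        return self.emission_unmodified or EMISSION_SHAPES[self.emission_shape][1]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["motif_fp_weights"] = dict(self.motif_fp_weights)
        return d


@dataclass
class SyntheticDataset:
    """A generated reference, truth table and paired WT/IVT call tables."""

    reference: dict[str, str]
    models: list[TranscriptModel]
    candidates: CandidateSiteSet
    truth: list[GroundTruthSite]
    theta: dict[SiteKey, float]
    wt_calls: list[PerReadCall]
    ivt_samples: list[list[PerReadCall]]
    config: SyntheticConfig

    @property
    def ivt_calls(self) -> list[PerReadCall]:
        return self.ivt_samples[0]


# ---------------------------------------------------------------------------
# Reference generation


def generate_reference(
    seed: int,
    n_transcripts: int = 80,
    exons_per_transcript: tuple[int, int] = (2, 4),
    exon_length: tuple[int, int] = (300, 900),
    intron_length: tuple[int, int] = (50, 200),
) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Random multi-exon transcripts on both strands, one gene per contig.

    Uniform base composition gives an expected DRACH-center density of
    18/1024 per exonic base, so the defaults (~80 transcripts x ~1.8 kb
    exonic) comfortably exceed the default 2000-site demand.
    """
    if n_transcripts < 1:
        raise ConfigurationError("n_transcripts must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    reference: dict[str, str] = {}
    models: list[TranscriptModel] = []
    for i in range(n_transcripts):
        chrom = f"chr{i + 1}"
        n_exons = int(rng.integers(exons_per_transcript[0], exons_per_transcript[1] + 1))
        pos = int(rng.integers(5, 30))
        exons = []
        for j in range(n_exons):
            size = int(rng.integers(exon_length[0], exon_length[1] + 1))
            exons.append((pos, pos + size))
            pos += size + int(rng.integers(intron_length[0], intron_length[1] + 1))
        seq_len = exons[-1][1] + int(rng.integers(5, 30))
        reference[chrom] = "".join(rng.choice(bases, size=seq_len))
        strand = "+" if i % 2 == 0 else "-"
        models.append(
            TranscriptModel(tx_id=f"tx{i + 1}", chrom=chrom, strand=strand, exons=tuple(exons))
        )
    return reference, models


# ---------------------------------------------------------------------------
# Dataset simulation


def _tail_weight(config: SyntheticConfig, motif: str) -> float:
    return min(1.0, config.fp_tail_weight * float(config.motif_fp_weights.get(motif, 1.0)))


def _emit_probs(
    rng: np.random.Generator,
    states: np.ndarray,
    tail_weight: float,
    config: SyntheticConfig,
) -> np.ndarray:
    """Per-read caller probabilities given modification states (bool array)."""
    a1, b1 = config.beta_modified
    a0, b0 = config.beta_unmodified
    n = states.size
    # unmodified reads mix the high-probability component in with weight
    # tail_weight, optionally inflated linearly toward the 3' end
    w = np.full(n, tail_weight)
    if config.three_prime_bias > 0:
        u = rng.random(n)
        w = np.minimum(1.0, w * (1.0 + config.three_prime_bias * u))
    from_tail = rng.random(n) < w
    high = states | from_tail
    probs = np.empty(n)
    n_high = int(high.sum())
    probs[high] = rng.beta(a1, b1, size=n_high)
    probs[~high] = rng.beta(a0, b0, size=n - n_high)
    return probs


def simulate_dataset(
    config: SyntheticConfig,
    reference: dict[str, str] | None = None,
    models: Sequence[TranscriptModel] | None = None,
) -> SyntheticDataset:
    """Draw a paired WT/IVT dataset from the generative model.

    Sites are sampled from the exonic candidate universe; a fraction are
    truly modified with stoichiometry theta; WT read states are
    Bernoulli(theta) while IVT reads are unmodified by construction, so
    every IVT call above threshold is a false positive.  The truth table
    records theta for modified sites only (no true negatives), mirroring
    the structure of chemical ground-truth resources.
    """
    if reference is None or models is None:
        reference, models = generate_reference(config.seed)
    candidates = enumerate_candidate_sites(reference, models, config.mod_code)
    all_sites = sorted(candidates.sites, key=lambda s: (s.chrom, s.pos, s.strand))
    if len(all_sites) < config.n_sites:
        raise ConfigurationError(
            f"reference provides {len(all_sites)} candidate sites; "
            f"config demands {config.n_sites}"
        )
    rng = np.random.default_rng(config.seed)
    chosen_idx = rng.choice(len(all_sites), size=config.n_sites, replace=False)
    chosen = [all_sites[i] for i in sorted(chosen_idx)]

    n_mod = int(round(config.modified_fraction * config.n_sites))
    mod_idx = set(rng.choice(config.n_sites, size=n_mod, replace=False).tolist())
    a, b = config.stoichiometry_beta
    floor = config.stoichiometry_floor
    theta_draws = iter(floor + (1.0 - floor) * rng.beta(a, b, size=n_mod))
    theta = {
        site: (float(next(theta_draws)) if i in mod_idx else 0.0)
        for i, site in enumerate(chosen)
    }

    r = config.coverage_dispersion
    p_nb = r / (r + config.coverage_mean)

    def sample_calls(sample_id: str, wildtype: bool) -> list[PerReadCall]:
        calls: list[PerReadCall] = []
        coverages = np.maximum(1, rng.negative_binomial(r, p_nb, size=len(chosen)))
        for i, site in enumerate(chosen):
            c = int(coverages[i])
            states = (
                rng.random(c) < theta[site] if wildtype else np.zeros(c, dtype=bool)
            )
            motif = candidates.context(site)
            probs = _emit_probs(rng, states, _tail_weight(config, motif), config)
            calls.extend(
                PerReadCall(
                    read_id=f"{sample_id}:s{i}:r{j}",
                    sample_id=sample_id,
                    site=site,
                    mod_code=config.mod_code,
                    prob=float(probs[j]),
                    context=motif,
                )
                for j in range(c)
            )
        return calls

    wt_calls = sample_calls("wt", wildtype=True)
    ivt_samples = [
        sample_calls(f"ivt{k + 1}", wildtype=False) for k in range(config.n_ivt_samples)
    ]
    truth = [
        GroundTruthSite(site=site, level=theta[site], source="synthetic")
        for site in chosen
        if theta[site] > 0.0
    ]
    return SyntheticDataset(
        reference=reference,
        models=list(models),
        candidates=candidates,
        truth=truth,
        theta=theta,
        wt_calls=wt_calls,
        ivt_samples=ivt_samples,
        config=config,
    )


# ---------------------------------------------------------------------------
# Closed-form expected statistics (independent oracle)


@dataclass
class ExpectedStatistics:
    per_read_fpr: float
    per_site_fpr: float
    recall: float


def _mean_tail_weight(config: SyntheticConfig) -> float:
    """Average emission-mixing weight over reads (3'-bias integrated out)."""
    w = config.fp_tail_weight
    bias = config.three_prime_bias
    if w == 0.0 or bias == 0.0:
        return w
    if w * (1.0 + bias) <= 1.0:
        return w * (1.0 + bias / 2.0)
    # the linear inflation saturates at 1 beyond u* = (1/w - 1)/bias
    u_star = (1.0 / w - 1.0) / bias
    return w * u_star + w * bias * u_star**2 / 2.0 + (1.0 - u_star)


def _coverage_pmf(config: SyntheticConfig, min_coverage: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Support and pmf of max(1, NB) coverage, conditioned on >= min_coverage."""
    r = config.coverage_dispersion
    p_nb = r / (r + config.coverage_mean)
    cmax = int(stats.nbinom.ppf(1.0 - 1e-9, r, p_nb)) + 1
    c = np.arange(1, cmax + 1)
    pmf = stats.nbinom.pmf(c, r, p_nb)
    pmf[0] += stats.nbinom.pmf(0, r, p_nb)
    keep = c >= min_coverage
    c, pmf = c[keep], pmf[keep]
    return c, pmf / pmf.sum()


def _min_positive_count(c: int, cutoff: Fraction) -> int:
    """Smallest integer k with k/c >= cutoff (exact rational arithmetic)."""
    return -((-cutoff.numerator * c) // cutoff.denominator)


def expected_statistics(
    config: SyntheticConfig,
    policy: ThresholdPolicy,
    ratio_cutoff: float = 0.10,
    min_coverage: int = 1,
    n_theta_nodes: int = 96,
) -> ExpectedStatistics:
    """Analytic expectations under the generative model.

    The per-read FPR is the upper-tail mass of the (tail-mixed) unmodified
    emission beyond the threshold.  Per-site expectations integrate
    Binomial tail probabilities over the coverage law (exact pmf sum) and
    the stoichiometry law (Gauss-Legendre quadrature), using the fact that
    a read is called modified with marginal probability
    q = theta*pi1 + (1-theta)*pi0.
    """
    t = policy.t
    a1, b1 = config.beta_modified
    a0, b0 = config.beta_unmodified
    w = _mean_tail_weight(config)
    pi1 = float(stats.beta.sf(t, a1, b1))
    pi0 = float((1.0 - w) * stats.beta.sf(t, a0, b0) + w * stats.beta.sf(t, a1, b1))

    cutoff = exact_fraction(ratio_cutoff)
    c_vals, c_pmf = _coverage_pmf(config, min_coverage)
    k_vals = np.array([_min_positive_count(int(c), cutoff) for c in c_vals])

    def site_positive_prob(q: float) -> float:
        # P(Binom(c, q) >= k(c)) averaged over the coverage law
        return float(np.sum(c_pmf * stats.binom.sf(k_vals - 1, c_vals, q)))

    fpr_site = site_positive_prob(pi0)

    # theta = floor + (1-floor) * Beta(a,b); Gauss-Legendre on [0,1]
    x, wq = np.polynomial.legendre.leggauss(n_theta_nodes)
    x = 0.5 * (x + 1.0)
    wq = 0.5 * wq
    sa, sb = config.stoichiometry_beta
    dens = stats.beta.pdf(x, sa, sb)
    theta = config.stoichiometry_floor + (1.0 - config.stoichiometry_floor) * x
    q_theta = theta * pi1 + (1.0 - theta) * pi0
    detect = np.array([site_positive_prob(float(q)) for q in q_theta])
    recall = float(np.sum(wq * dens * detect) / np.sum(wq * dens))

    return ExpectedStatistics(per_read_fpr=pi0, per_site_fpr=fpr_site, recall=recall)


def emission_crossing_threshold(config: SyntheticConfig) -> float:
    """Threshold where the modified and unmodified emission densities cross.

    For the default shapes the density ratio is monotone, so the crossing
    is unique; it is the natural operating point for separated emissions.
    """
    a1, b1 = config.beta_modified
    a0, b0 = config.beta_unmodified
    if (a1, b1) == (a0, b0):
        return 0.5

    def logdiff(x: float) -> float:
        return stats.beta.logpdf(x, a1, b1) - stats.beta.logpdf(x, a0, b0)

    lo, hi = 1e-9, 1.0 - 1e-9
    if logdiff(lo) * logdiff(hi) > 0:
        return 0.5
    return float(optimize.brentq(logdiff, lo, hi))


# ---------------------------------------------------------------------------
# Fixture bundle on disk


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle the readers consume: FASTA, GTF, truth, call tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "annotation": outdir / "annotation.gtf",
        "truth": outdir / "truth.tsv",
        "wt_calls": outdir / "wt_calls.tsv",
    }
    write_fasta(dataset.reference, paths["reference"])
    write_gtf(dataset.models, paths["annotation"])
    write_ground_truth(dataset.truth, paths["truth"])
    write_per_read_calls(dataset.wt_calls, paths["wt_calls"])
    for k, sample in enumerate(dataset.ivt_samples):
        key = f"ivt{k + 1}_calls"
        paths[key] = outdir / f"{key}.tsv"
        write_per_read_calls(sample, paths[key])
    return paths
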