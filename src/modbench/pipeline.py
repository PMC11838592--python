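"""End-to-end orchestration: configured, logged, reproducible runs.

The benchmark run wires the stages together: parse per-read call tables
(lifting transcript coordinates where needed), restrict to the exonic
candidate universe, sweep per-read thresholds, evaluate all statistics at
the recommended threshold, stratify by motif, and optionally build and
apply an IVT blacklist.  Record counts are logged at every filter so each
denominator in each statistic is auditable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import io as mio
from .aggregate import SiteProbTable, call_modified_sites, filter_by_coverage
from .blacklist import apply_blacklist, build_blacklist, write_blacklist
from .errors import ConfigurationError
from .metrics import (
    MetricCurve,
    default_threshold_grid,
    fdr_vs_ratio_curve,
    intermediate_band_fraction,
    per_site_fpr,
    per_site_recall,
    stoichiometry_correlation,
    sweep_thresholds,
)
from .motifs import motif_stratified_metrics
from .records import RECOMMENDED_THRESHOLDS, ThresholdPolicy
from .reference import enumerate_candidate_sites, lift_calls
from .simulate import SyntheticConfig, simulate_dataset, write_dataset


@dataclass
class SampleSpec:
    path: str
    dialect: str = "modkit_extract"
    sample_id: str = "sample"


@dataclass
class RunConfig:
    """Declarative description of one benchmark run."""

    wt: SampleSpec
    ivt: list[SampleSpec]
    truth_path: str
    reference_path: str
    annotation_path: str
    outdir: str
    replicate_columns: Sequence[str] = ("level_rep1",)
    mod_code: str = "m6A"
    recommended_threshold: float = RECOMMENDED_THRESHOLDS["dorado"]
    threshold_grid: Sequence[float] | None = None
    ratio_cutoff: float = 0.10
    min_coverage: int = 10
    min_positives: int = 10
    blacklist_score_cutoff: float | None = 0.9
    blacklist_prior: tuple[float, float] = (1.0, 1.0)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        try:
            raw["wt"] = SampleSpec(**raw["wt"])
            raw["ivt"] = [SampleSpec(**s) for s in raw["ivt"]]
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"bad sample declarations in {path}: {exc}") from exc
        return cls(**raw)


def _load_calls(spec: SampleSpec, models_by_id, reference, stage_log: dict) -> list:
    parsed = mio.read_per_read_calls(spec.path, spec.dialect, sample_id=spec.sample_id)
    entry = {"rows_parsed": len(parsed.calls), "rows_skipped": parsed.n_skipped}
    calls = parsed.calls
    if parsed.needs_lifting:
        calls, n_unmapped = lift_calls(calls, models_by_id, reference)
        entry["lifted"] = len(calls)
        entry["unmapped_transcripts"] = n_unmapped
    stage_log[spec.sample_id] = entry
    return calls


def _round(x: float | None, nd: int = 6) -> float | None:
    return None if x is None else round(float(x), nd)


def run_benchmark(config: RunConfig) -> dict:
    """Execute the full evaluation; returns the summary written to disk."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"samples": {}}

    reference = mio.read_fasta(config.reference_path)
    models = mio.read_transcript_models(config.annotation_path)
    models_by_id = {m.tx_id: m for m in models}
    candidates = enumerate_candidate_sites(reference, models, config.mod_code)
    log["n_candidate_sites"] = len(candidates)

    wt_calls = _load_calls(config.wt, models_by_id, reference, log["samples"])
    ivt_calls = [
        _load_calls(spec, models_by_id, reference, log["samples"]) for spec in config.ivt
    ]
    if not ivt_calls:
        raise ConfigurationError("benchmark requires at least one IVT sample")

    truth_table = mio.read_ground_truth(
        config.truth_path,
        replicate_columns=list(config.replicate_columns),
        exonic_only=True,
        exon_models=models,
    )
    log["truth"] = {
        "sites": len(truth_table.sites),
        "dropped_missing": truth_table.n_dropped_missing,
        "dropped_intronic": truth_table.n_dropped_intronic,
    }

    wt_table = SiteProbTable.from_calls(wt_calls, candidates)
    ivt_tables = [SiteProbTable.from_calls(c, candidates) for c in ivt_calls]
    log["samples"][config.wt.sample_id]["outside_candidates"] = wt_table.n_outside_candidates
    for spec, table in zip(config.ivt, ivt_tables):
        log["samples"][spec.sample_id]["outside_candidates"] = table.n_outside_candidates

    grid = (
        sorted(set(config.threshold_grid) | {float(config.recommended_threshold)})
        if config.threshold_grid is not None
        else default_threshold_grid([config.recommended_threshold])
    )
    curve = sweep_thresholds(
        wt_table,
        ivt_tables[0],
        truth_table.sites,
        grid=grid,
        ratio_cutoff=config.ratio_cutoff,
        min_coverage=config.min_coverage,
        min_positives=config.min_positives,
    )
    _write_curve(curve, outdir / "metric_curve.tsv")

    # everything below is evaluated at the recommended per-read threshold
    policy = ThresholdPolicy(config.recommended_threshold)
    wt_aggs = filter_by_coverage(wt_table.aggregates_at(policy), config.min_coverage)
    ivt_aggs_all = [
        filter_by_coverage(t.aggregates_at(policy), config.min_coverage) for t in ivt_tables
    ]
    ivt_aggs = ivt_aggs_all[0]
    log["coverage_filter"] = {
        "wt_sites_kept": len(wt_aggs),
        "ivt_sites_kept": [len(a) for a in ivt_aggs_all],
        "min_coverage": config.min_coverage,
    }
    mio.write_site_table(wt_aggs, outdir / "wt_sites.tsv")
    for spec, aggs in zip(config.ivt, ivt_aggs_all):
        mio.write_site_table(aggs, outdir / f"{spec.sample_id}_sites.tsv")

    covered = {a.site for a in wt_aggs}
    truth_eval = [t for t in truth_table.sites if t.site in covered]
    predicted = call_modified_sites(wt_aggs, config.ratio_cutoff)
    recall, counts = per_site_recall(predicted, truth_eval, assessed_sites=covered)
    truth_map = {t.site: t.level for t in truth_eval}
    rho, n_common = stoichiometry_correlation(
        {a.site: a.ratio for a in wt_aggs},
        truth_map,
        restrict_to=predicted & set(truth_map),
    )
    point = next(p for p in curve if p.t == config.recommended_threshold)

    ratio_grid = [round(i / 20, 2) for i in range(21)]
    fdr_curve = fdr_vs_ratio_curve(
        wt_aggs, ivt_aggs, ratio_grid, min_positives=config.min_positives
    )
    _write_fdr_curve(fdr_curve, outdir / "fdr_vs_ratio.tsv")

    motif_rows = motif_stratified_metrics(
        wt_aggs, ivt_aggs, truth_eval, candidates, config.ratio_cutoff, reference
    )
    _write_motif_table(motif_rows, outdir / "motif_metrics.tsv")

    summary = {
        "recommended_threshold": config.recommended_threshold,
        "ratio_cutoff": config.ratio_cutoff,
        "min_coverage": config.min_coverage,
        "recall": _round(recall),
        "spearman": _round(rho),
        "spearman_n_sites": n_common,
        "fpr_read": _round(point.fpr_read),
        "fpr_site": _round(per_site_fpr(ivt_aggs, config.ratio_cutoff)),
        "fdr_read": _round(point.fdr_read),
        "fdr_site": _round(point.fdr_site),
        "confusion": {
            "tp": counts.tp, "fp": counts.fp, "fn": counts.fn,
            "fn_no_prediction": counts.fn_no_prediction,
        },
        "intermediate_band_fraction": _round(
            intermediate_band_fraction(wt_aggs, ivt_aggs)
        ),
        "n_predicted_sites": len(predicted),
        "n_truth_sites_evaluated": len(truth_eval),
    }

    if config.blacklist_score_cutoff is not None:
        entries = build_blacklist(
            ivt_aggs_all, config.ratio_cutoff, prior=config.blacklist_prior
        )
        write_blacklist(entries, outdir / "blacklist.tsv")
        kept, removed = apply_blacklist(predicted, entries, config.blacklist_score_cutoff)
        recall_post, _ = per_site_recall(kept, truth_eval, assessed_sites=covered)
        ivt_pos = call_modified_sites(ivt_aggs, config.ratio_cutoff)
        ivt_kept, _ = apply_blacklist(ivt_pos, entries, config.blacklist_score_cutoff)
        summary["blacklist"] = {
            "score_cutoff": config.blacklist_score_cutoff,
            "n_entries": len(entries),
            "n_removed_from_predictions": len(removed),
            "recall_after_filter": _round(recall_post),
            "fpr_site_after_filter": _round(
                len(ivt_kept) / len(ivt_aggs) if ivt_aggs else None
            ),
        }

    summary["log"] = log
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def run_simulate(
    seed: int,
    outdir: str | Path,
    **config_overrides,
) -> dict[str, Path]:
    """Generate a synthetic fixture bundle consumable by run_benchmark."""
    config = SyntheticConfig(seed=seed, **config_overrides)
    dataset = simulate_dataset(config)
    paths = write_dataset(dataset, outdir)
    with open(Path(outdir) / "sim_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def benchmark_config_for_bundle(
    bundle_dir: str | Path, outdir: str | Path, **overrides
) -> RunConfig:
    """RunConfig pointing at a simulated fixture bundle's files."""
    bundle = Path(bundle_dir)
    ivt_paths = sorted(bundle.glob("ivt*_calls.tsv"))
    defaults = dict(
        wt=SampleSpec(path=str(bundle / "wt_calls.tsv"), sample_id="wt"),
        ivt=[
            SampleSpec(path=str(p), sample_id=p.name.replace("_calls.tsv", ""))
            for p in ivt_paths
        ],
        truth_path=str(bundle / "truth.tsv"),
        reference_path=str(bundle / "reference.fa"),
        annotation_path=str(bundle / "annotation.gtf"),
        outdir=str(outdir),
    )
    defaults.update(overrides)
    return RunConfig(**defaults)


# ---------------------------------------------------------------------------
# Table writers (stable formatting so reruns are byte-identical)


def _fmt(x) -> str:
    return "NA" if x is None else repr(x) if isinstance(x, float) else str(x)


def _write_curve(curve: MetricCurve, path: Path) -> None:
    rows = curve.to_rows()
    with open(path, "w") as fh:
        cols = list(rows[0].keys()) if rows else ["threshold"]
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row[c]) for c in cols) + "\n")


def _write_fdr_curve(points, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ratio_cutoff\tfdr_site\n")
        for cutoff, fdr in points:
            fh.write(f"{_fmt(cutoff)}\t{_fmt(fdr)}\n")


def _write_motif_table(rows, path: Path) -> None:
    cols = ["motif", "count", "n_truth", "n_ivt", "correlation", "recall", "fpr_site", "fdr_site"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for m in rows:
            fh.write(
                "\t".join(
                    _fmt(v)
                    for v in (
                        m.motif, m.count, m.n_truth, m.n_ivt,
                        m.correlation, m.recall, m.fpr_site, m.fdr_site,
                    )
                )
                + "\n"
            )
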