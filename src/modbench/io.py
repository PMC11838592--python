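"""Readers and writers for the interchange formats.

Per-read call tables come in two dialects: a Modkit-"extract"-style genomic
TSV and an m6Anet-style per-read table in transcript coordinates.  Ground
truth arrives as a replicate-level TSV/CSV; per-site aggregates are written
as BED-like TSV.  Internal coordinates are 0-based half-open throughout;
GTF's 1-based starts are converted on ingest.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError
from .records import (
    GENOME,
    TRANSCRIPT,
    GroundTruthSite,
    PerReadCall,
    SiteAggregate,
    SiteKey,
    TranscriptModel,
)

# Raw caller codes mapped onto canonical modification names.  Modkit emits
# single-letter or ChEBI-numbered codes; m6Anet only calls m6A.
DEFAULT_MOD_CODE_MAP: Mapping[str, str] = {
    "a": "m6A",
    "m6A": "m6A",
    "17802": "pseU",
    "psi": "pseU",
    "pseU": "pseU",
    "m": "m5C",
    "m5C": "m5C",
    "17596": "inosine",
    "inosine": "inosine",
}


@dataclass(frozen=True)
class Dialect:
    """Column layout of one per-read call table flavor.

    ``columns`` maps logical fields (read_id, chrom, pos, prob, and
    optionally strand, mod_code, context) onto the file's column names.
    Column layouts drift between caller versions, so dialects are data,
    not code: derive a variant with :meth:`with_columns`.
    """

    name: str
    columns: Mapping[str, str]
    coord_space: str = GENOME
    default_mod_code: str = "m6A"
    mod_code_map: Mapping[str, str] = field(default_factory=lambda: DEFAULT_MOD_CODE_MAP)

    REQUIRED = ("read_id", "chrom", "pos", "prob")

    def __post_init__(self) -> None:
        missing = [f for f in self.REQUIRED if f not in self.columns]
        if missing:
            raise ConfigurationError(
                f"dialect {self.name!r} lacks a column mapping for {missing[0]!r}"
            )

    def with_columns(self, **overrides: str) -> "Dialect":
        cols = dict(self.columns)
        cols.update(overrides)
        return dataclasses.replace(self, columns=cols)


MODKIT_EXTRACT = Dialect(
    name="modkit_extract",
    columns={
        "read_id": "read_id",
        "chrom": "chrom",
        "pos": "ref_position",
        "strand": "ref_strand",
        "prob": "call_prob",
        "mod_code": "call_code",
        "context": "ref_kmer",
    },
)

M6ANET_PER_READ = Dialect(
    name="m6anet_per_read",
    columns={
        "read_id": "read_index",
        "chrom": "transcript_id",
        "pos": "transcript_position",
        "prob": "probability_modified",
    },
    coord_space=TRANSCRIPT,
)

DIALECTS: Mapping[str, Dialect] = {
    MODKIT_EXTRACT.name: MODKIT_EXTRACT,
    M6ANET_PER_READ.name: M6ANET_PER_READ,
}


def get_dialect(name: str) -> Dialect:
    try:
        return DIALECTS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown dialect {name!r}; known: {sorted(DIALECTS)}"
        ) from None


def normalize_context(kmer: object) -> str:
    """Uppercase, U->T; anything that is not a clean 5-mer becomes NNNNN."""
    if not isinstance(kmer, str):
        return "NNNNN"
    kmer = kmer.strip().upper().replace("U", "T")
    if len(kmer) != 5 or any(b not in "ACGTN" for b in kmer):
        return "NNNNN"
    return kmer


@dataclass
class ParsedCalls:
    """Materialized per-read calls plus parse bookkeeping.

    Row counts are conserved: input data rows == len(calls) + n_skipped.
    """

    calls: list[PerReadCall]
    n_skipped: int = 0
    needs_lifting: bool = False

    def __iter__(self):
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)


def read_per_read_calls(
    path: str | Path,
    dialect: Dialect | str,
    sample_id: str,
    sep: str = "\t",
) -> ParsedCalls:
    """Parse one per-read call table.

    Probabilities are parsed to [0,1]; rows whose probability is missing,
    unparseable or out of range are skipped and counted, never clamped.
    m6anet_per_read rows carry transcript coordinates and the result is
    flagged as needing lifting.
    """
    if isinstance(dialect, str):
        dialect = get_dialect(dialect)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for logical in dialect.REQUIRED:
        col = dialect.columns[logical]
        if col not in df.columns:
            raise FormatError(
                f"{path}: missing column {col!r} required by dialect {dialect.name!r}"
            )

    col = dialect.columns
    prob = pd.to_numeric(df[col["prob"]], errors="coerce")
    pos = pd.to_numeric(df[col["pos"]], errors="coerce")
    ok = prob.notna() & (prob >= 0.0) & (prob <= 1.0) & pos.notna() & (pos >= 0)
    n_skipped = int((~ok).sum())

    strand_col = col.get("strand")
    mod_col = col.get("mod_code")
    ctx_col = col.get("context")
    transcript = dialect.coord_space == TRANSCRIPT

    calls: list[PerReadCall] = []
    sub = df.loc[ok]
    probs = prob.loc[ok].to_numpy(dtype=float)
    poss = pos.loc[ok].to_numpy(dtype=np.int64)
    chroms = sub[col["chrom"]].to_numpy(dtype=object)
    reads = sub[col["read_id"]].to_numpy(dtype=object)
    strands = sub[strand_col].to_numpy(dtype=object) if strand_col else None
    mods = sub[mod_col].to_numpy(dtype=object) if mod_col else None
    ctxs = sub[ctx_col].to_numpy(dtype=object) if ctx_col else None

    for i in range(len(sub)):
        strand = str(strands[i]) if strands is not None else "+"
        if strand not in ("+", "-"):
            n_skipped += 1
            continue
        raw_mod = str(mods[i]) if mods is not None else dialect.default_mod_code
        mod_code = dialect.mod_code_map.get(raw_mod, raw_mod)
        calls.append(
            PerReadCall(
                read_id=str(reads[i]),
                sample_id=sample_id,
                site=SiteKey(str(chroms[i]), int(poss[i]), strand),
                mod_code=mod_code,
                prob=float(probs[i]),
                context=normalize_context(ctxs[i]) if ctxs is not None else "NNNNN",
                coord_space=TRANSCRIPT if transcript else GENOME,
            )
        )
    return ParsedCalls(calls=calls, n_skipped=n_skipped, needs_lifting=transcript)


def write_per_read_calls(calls: Iterable[PerReadCall], path: str | Path) -> None:
    """Write calls as a modkit_extract-style TSV (the genomic dialect)."""
    rows = [
        (
            c.read_id,
            c.site.chrom,
            c.site.pos,
            c.site.strand,
            repr(float(c.prob)),
            c.mod_code,
            c.context,
        )
        for c in calls
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "chrom",
            "ref_position",
            "ref_strand",
            "call_prob",
            "call_code",
            "ref_kmer",
        ],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ground truth


class _ExonIndex:
    """Merged exon intervals per (chrom, strand) with bisect membership."""

    def __init__(self, models: Iterable[TranscriptModel]):
        raw: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for m in models:
            raw.setdefault((m.chrom, m.strand), []).extend(m.exons)
        self._merged: dict[tuple[str, str], tuple[list[int], list[int]]] = {}
        for key, ivals in raw.items():
            ivals.sort()
            merged: list[list[int]] = []
            for s, e in ivals:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._merged[key] = ([s for s, _ in merged], [e for _, e in merged])

    def __contains__(self, site: SiteKey) -> bool:
        entry = self._merged.get((site.chrom, site.strand))
        if entry is None:
            return False
        starts, ends = entry
        i = bisect_right(starts, site.pos) - 1
        return i >= 0 and site.pos < ends[i]


@dataclass
class GroundTruthTable:
    sites: list[GroundTruthSite]
    n_dropped_missing: int = 0
    n_dropped_intronic: int = 0

    def __iter__(self):
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)


def read_ground_truth(
    path: str | Path,
    replicate_columns: Sequence[str],
    exonic_only: bool = False,
    exon_models: Iterable[TranscriptModel] | None = None,
    source: str = "",
    sep: str = "\t",
) -> GroundTruthTable:
    """Read a replicate-level stoichiometry table.

    The site level is the arithmetic mean of the non-missing replicate
    values; rows with every replicate missing are dropped and counted.
    With ``exonic_only``, sites outside the provided exon models (same
    strand) are dropped and counted separately.
    """
    if not replicate_columns:
        raise ConfigurationError("need at least one replicate column")
    df = pd.read_csv(path, sep=sep)
    for needed in ("chrom", "pos", "strand", *replicate_columns):
        if needed not in df.columns:
            raise FormatError(f"{path}: missing column {needed!r} in ground truth")
    levels = df[list(replicate_columns)].apply(pd.to_numeric, errors="coerce")
    mean_level = levels.mean(axis=1, skipna=True)
    keep = mean_level.notna()
    n_missing = int((~keep).sum())

    index = None
    if exonic_only:
        if exon_models is None:
            raise ConfigurationError("exonic_only requires exon models")
        index = _ExonIndex(exon_models)

    sites: list[GroundTruthSite] = []
    n_intronic = 0
    for chrom, pos, strand, level in zip(
        df.loc[keep, "chrom"], df.loc[keep, "pos"], df.loc[keep, "strand"], mean_level[keep]
    ):
        site = SiteKey(str(chrom), int(pos), str(strand)).validate()
        if index is not None and site not in index:
            n_intronic += 1
            continue
        sites.append(GroundTruthSite(site=site, level=float(level), source=source))
    return GroundTruthTable(
        sites=sites, n_dropped_missing=n_missing, n_dropped_intronic=n_intronic
    )


def write_ground_truth(truth: Iterable[GroundTruthSite], path: str | Path) -> None:
    rows = [
        (t.site.chrom, t.site.pos, t.site.strand, repr(float(t.level)), t.source)
        for t in truth
    ]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "level_rep1", "source"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Per-site aggregate tables (BED-like TSV)

SITE_TABLE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "ratio",
    "strand",
    "coverage",
    "n_modified",
    "threshold",
]


def write_site_table(aggregates: Iterable[SiteAggregate], path: str | Path) -> None:
    """Write per-site aggregates as BED-like TSV, sorted by (chrom, pos, strand)."""
    aggs = sorted(aggregates, key=lambda a: (a.site.chrom, a.site.pos, a.site.strand))
    rows = [
        (
            a.site.chrom,
            a.site.pos,
            a.site.pos + 1,
            a.mod_code,
            repr(a.ratio),
            a.site.strand,
            a.coverage,
            a.n_modified,
            repr(float(a.threshold_used)),
        )
        for a in aggs
    ]
    pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> list[SiteAggregate]:
    df = pd.read_csv(path, sep="\t")
    for needed in SITE_TABLE_COLUMNS:
        if needed not in df.columns:
            raise FormatError(f"{path}: missing column {needed!r} in site table")
    return [
        SiteAggregate(
            site=SiteKey(str(r.chrom), int(r.start), str(r.strand)),
            mod_code=str(r.name),
            coverage=int(r.coverage),
            n_modified=int(r.n_modified),
            threshold_used=float(r.threshold),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Reference sequence and annotation


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into plain uppercase strings (U normalized to T)."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), sequence_always_upper=True)
    return {name: str(fa[name][:]).replace("U", "T") for name in fa.keys()}


def write_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write exon models as GTF (1-based, closed intervals on output)."""
    with open(path, "w") as fh:
        for m in models:
            gene = f"{m.tx_id}_gene"
            attrs = f'gene_id "{gene}"; transcript_id "{m.tx_id}";'
            tx_start = m.exons[0][0] + 1
            tx_end = m.exons[-1][1]
            fh.write(
                f"{m.chrom}\tmodbench\ttranscript\t{tx_start}\t{tx_end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for start, end in m.exons:
                fh.write(
                    f"{m.chrom}\tmodbench\texon\t{start + 1}\t{end}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def read_transcript_models(path: str | Path) -> list[TranscriptModel]:
    """Load transcript exon models from a GTF (1-based starts converted)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    models = []
    by_tx: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        tx_id = exon.attributes["transcript_id"][0]
        entry = by_tx.setdefault(
            tx_id, {"chrom": exon.seqid, "strand": exon.strand, "exons": []}
        )
        entry["exons"].append((exon.start - 1, exon.end))
    for tx_id in sorted(by_tx):
        entry = by_tx[tx_id]
        models.append(
            TranscriptModel(
                tx_id=tx_id,
                chrom=entry["chrom"],
                strand=entry["strand"],
                exons=tuple(sorted(entry["exons"])),
            )
        )
    return models
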