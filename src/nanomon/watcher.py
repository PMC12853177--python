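"""Real-time orchestration: watch a run directory, process each batch once.

The sequencer writes finished FASTQ batches into a run directory; the
monitor polls it, picks up files whose size is stable, and pushes each one
through filter -> classify -> store exactly once.  A JSON manifest keyed by
(path, content digest) survives restarts, so re-watching the same directory
never reprocesses a batch, while a genuinely new file under an old name
(different digest) becomes a new sample.

The reference k-mer index is built once per session and held in memory so
new batches are scored immediately.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

from .classify import (
    EMSettings,
    ReferenceIndex,
    aggregate_to_rank,
    build_kmer_index,
    load_references,
    profile_sample,
)
from .reads import (
    AMPLICON_16S_PRESET,
    WGS_PRESET,
    FastqParseError,
    FilterPolicy,
    filter_reads,
    qc_summary,
    read_fastq,
)
from .store import (
    SampleRecord,
    SampleStore,
    TimeSeriesTable,
    build_counts_table,
    export_table,
    normalize_counts,
)
from .stats import alpha_diversity_table
from .taxonomy import Taxonomy

__all__ = [
    "RunConfig",
    "ProcessedManifest",
    "Monitor",
    "process_fastq",
    "export_project",
]

logger = logging.getLogger("nanomon.watcher")

_TIMESTAMP_IN_NAME = re.compile(r"_(\d{8}T\d{6})$")
_FASTQ_SUFFIXES = (".fastq", ".fq", ".fastq.gz", ".fq.gz")


@dataclass
class RunConfig:
    """Configuration for one monitored run (flat key = value file)."""

    project_id: str
    mode: str = "16s"  # selects the matching filter preset unless overridden
    watch_dir: str = "."
    output_dir: str = "nanomon_out"
    reference_fasta: str = ""
    taxonomy_tsv: str = ""
    seq2tax_tsv: str = ""
    k: int = 15
    min_length: int | None = None
    max_length: int | None = None
    min_quality: float | None = None
    poll_seconds: float = 5.0
    em_tol: float = 1e-6
    em_max_iter: int = 100
    em_prune_floor: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("16s", "wgs"):
            raise ValueError(f"mode must be '16s' or 'wgs', got {self.mode!r}")

    @property
    def filter_policy(self) -> FilterPolicy:
        preset = AMPLICON_16S_PRESET if self.mode == "16s" else WGS_PRESET
        return FilterPolicy(
            min_length=self.min_length if self.min_length is not None else preset.min_length,
            max_length=self.max_length if self.max_length is not None else preset.max_length,
            min_mean_quality=self.min_quality
            if self.min_quality is not None
            else preset.min_mean_quality,
        )

    @property
    def em_settings(self) -> EMSettings:
        return EMSettings(
            tol=self.em_tol, max_iter=self.em_max_iter, prune_floor=self.em_prune_floor
        )

    def to_file(self, path: str | Path, force: bool = False) -> None:
        path = Path(path)
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists (use force to overwrite)")
        lines = []
        for key, value in asdict(self).items():
            if value is None:
                continue
            if isinstance(value, str):
                lines.append(f'{key} = "{value}"')
            else:
                lines.append(f"{key} = {value}")
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as handle:
            data = tomllib.load(handle)
        return cls(**data)


@dataclass
class ManifestEntry:
    size: int
    digest: str
    processed_at: str
    sample_id: str
    status: str  # "done" or "failed"


class ProcessedManifest:
    """Exactly-once ledger: path -> (size, digest, timestamp, sample, status)."""

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path else None
        self.entries: dict[str, ManifestEntry] = {}
        if self.path and self.path.exists():
            self.load()

    def is_processed(self, path: Path, digest: str) -> bool:
        entry = self.entries.get(str(path))
        return entry is not None and entry.digest == digest

    def mark(self, path: Path, size: int, digest: str, sample_id: str, status: str) -> None:
        self.entries[str(path)] = ManifestEntry(
            size=size,
            digest=digest,
            processed_at=datetime.now(timezone.utc).isoformat(),
            sample_id=sample_id,
            status=status,
        )

    def save(self, path: str | Path | None = None) -> None:
        target = Path(path) if path else self.path
        if target is None:
            return
        target.write_text(
            json.dumps({k: asdict(v) for k, v in sorted(self.entries.items())}, indent=1)
        )

    def load(self, path: str | Path | None = None) -> None:
        source = Path(path) if path else self.path
        self.entries = {
            k: ManifestEntry(**v) for k, v in json.loads(source.read_text()).items()
        }


def sample_identity(path: Path) -> tuple[str, datetime]:
    """Sample id (filename stem) and timestamp (encoded in the name, else
    file mtime, treated as UTC)."""
    stem = path.name
    for suffix in _FASTQ_SUFFIXES:
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    match = _TIMESTAMP_IN_NAME.search(stem)
    if match:
        ts = datetime.strptime(match.group(1), "%Y%m%dT%H%M%S").replace(
            tzinfo=timezone.utc
        )
    else:
        ts = datetime.fromtimestamp(path.stat().st_mtime, tz=timezone.utc)
    return stem, ts


def process_fastq(
    path: Path,
    config: RunConfig,
    index: ReferenceIndex,
    tree: Taxonomy,
) -> SampleRecord:
    """Run one FASTQ batch through filter -> classify -> profile.

    QC statistics are computed on the raw input reads; profiling uses only
    the reads that pass the filter.  Species profiles are aggregated to
    genus and phylum at ingest so any rank is directly queryable.
    """
    started = time.monotonic()
    raw = list(read_fastq(path))
    qc = qc_summary(raw)
    kept, report = filter_reads(raw, config.filter_policy)
    result = profile_sample(kept, index, tree, config.em_settings)
    profiles = {"species": result.profile}
    for rank in ("genus", "phylum"):
        profiles[rank] = aggregate_to_rank(result.profile, tree, rank)
    sample_id, timestamp = sample_identity(path)
    logger.info(
        "processed %s: reads in=%d kept=%d unclassified=%.3f elapsed=%.2fs",
        path.name,
        report.n_input,
        report.n_kept,
        result.profile.unclassified_fraction,
        time.monotonic() - started,
    )
    return SampleRecord(
        sample_id=sample_id,
        project_id=config.project_id,
        timestamp=timestamp,
        qc=qc,
        profiles=profiles,
        aligned_bases=result.aligned_bases,
        aligned_bases_kind="classified",
        n_classified=result.n_classified,
    )


def export_project(
    store: SampleStore,
    project_id: str,
    out_dir: str | Path,
    ranks: Sequence[str] = ("species", "genus", "phylum"),
) -> list[Path]:
    """Write the project's dashboard tables: raw and normalized counts per
    rank plus per-sample alpha diversity.  Deterministic output given the
    same store contents."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    aligned = {
        rec.sample_id: rec.aligned_bases for rec in store.samples(project_id)
    }
    diversity = None
    for rank in ranks:
        table = build_counts_table(store, project_id, rank)
        path = out_dir / f"counts_{rank}.csv"
        export_table(table, path)
        written.append(path)
        normalized = normalize_counts(table, aligned)
        path = out_dir / f"normalized_{rank}.csv"
        export_table(normalized, path)
        written.append(path)
        if rank == ranks[0]:
            diversity = alpha_diversity_table(normalized)
    if diversity is not None:
        path = out_dir / "alpha_diversity.csv"
        diversity.to_csv(path, float_format="%.12g")
        written.append(path)
    return written


class Monitor:
    """Polling watcher over a run directory.

    A file is ingested when its size is unchanged between the stat before
    and the stat after reading (still-growing batches are deferred to the
    next poll).  Unreadable files are logged and skipped; malformed FASTQ is
    quarantined in the manifest as failed so it is not retried forever.
    """

    def __init__(
        self,
        config: RunConfig,
        store: SampleStore | None = None,
        manifest: ProcessedManifest | None = None,
    ):
        self.config = config
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.store = store if store is not None else SampleStore(out_dir / "samples.jsonl")
        self.manifest = (
            manifest if manifest is not None else ProcessedManifest(out_dir / "manifest.json")
        )
        references = load_references(config.reference_fasta, config.seq2tax_tsv)
        self.index = build_kmer_index(references, k=config.k)  # held for the session
        self.tree = Taxonomy.from_tsv(config.taxonomy_tsv)

    def scan_once(self) -> list[str]:
        """One poll: ingest every new, stable FASTQ; returns new sample ids."""
        watch_dir = Path(self.config.watch_dir)
        if not watch_dir.is_dir():
            raise FileNotFoundError(f"watch directory {watch_dir} does not exist")
        new_samples: list[str] = []
        for path in sorted(watch_dir.iterdir()):
            if not path.name.endswith(_FASTQ_SUFFIXES) or not path.is_file():
                continue
            try:
                size_before = path.stat().st_size
                digest = hashlib.sha256(path.read_bytes()).hexdigest()
                size_after = path.stat().st_size
            except OSError as exc:
                logger.warning("skipping unreadable %s: %s", path, exc)
                continue
            if size_before != size_after:
                logger.info("deferring still-growing file %s", path.name)
                continue
            if self.manifest.is_processed(path, digest):
                continue
            try:
                record = process_fastq(path, self.config, self.index, self.tree)
            except FastqParseError as exc:
                logger.error("quarantining malformed %s: %s", path, exc)
                self.manifest.mark(path, size_after, digest, "", "failed")
                continue
            self.store.upsert_sample(record)
            self.manifest.mark(path, size_after, digest, record.sample_id, "done")
            new_samples.append(record.sample_id)
        if new_samples:
            if self.store.path:
                self.store.save()
            self.manifest.save()
            export_project(self.store, self.config.project_id, self.config.output_dir)
        return new_samples

    def watch(self, max_scans: int | None = None) -> None:
        """Run :meth:`scan_once` every ``poll_seconds`` until interrupted
        (or ``max_scans`` polls); state is persisted after each poll."""
        scans = 0
        try:
            while max_scans is None or scans < max_scans:
                self.scan_once()
                scans += 1
                if max_scans is not None and scans >= max_scans:
                    break
                time.sleep(self.config.poll_seconds)
        except KeyboardInterrupt:
            logger.info("interrupted; persisting state")
        finally:
            if self.store.path:
                self.store.save()
            self.manifest.save()
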