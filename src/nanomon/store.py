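"""Sample management: a persistent time-series store of profiled samples.

Each profiled FASTQ batch becomes a :class:`SampleRecord` keyed by
(project_id, sample_id).  The store assembles samples x taxa count tables,
normalizes them by sequencing effort, applies the dashboard's top-N/"Other"
display reduction, and round-trips everything through CSV/JSON.

Count normalization divides raw counts by each sample's aligned bases and
rescales by the project-mean aligned bases, so samples sequenced for
different durations become comparable while counts stay on their original
magnitude:

    c_n = c_r / b * f,   f = mean(b) over the table's samples
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import AbundanceProfile
from .reads import ReadQCSummary

__all__ = [
    "SampleRecord",
    "SampleStore",
    "TimeSeriesTable",
    "MAGQualityRecord",
    "build_counts_table",
    "normalize_counts",
    "top_n_with_other",
    "filter_mag_quality",
    "filter_mags_pipeline",
    "filter_mags_mimag",
    "read_mag_table",
    "export_table",
    "import_table",
]

OTHER_LABEL = "Other"


def _parse_timestamp(value: str | datetime) -> datetime:
    if isinstance(value, datetime):
        ts = value
    else:
        try:
            ts = datetime.fromisoformat(value)
        except ValueError as exc:
            raise ValueError(f"malformed timestamp {value!r}") from exc
    if ts.tzinfo is None:  # naive timestamps are treated as UTC
        ts = ts.replace(tzinfo=timezone.utc)
    return ts


@dataclass
class SampleRecord:
    """One timestamped, profiled sample."""

    sample_id: str
    project_id: str
    timestamp: datetime
    metadata: dict[str, float | str] = field(default_factory=dict)
    qc: ReadQCSummary | None = None
    profiles: dict[str, AbundanceProfile] = field(default_factory=dict)
    aligned_bases: int = 0
    aligned_bases_kind: str = "classified"  # or "filtered": which b this is
    n_classified: int = 0

    def __post_init__(self) -> None:
        self.timestamp = _parse_timestamp(self.timestamp)
        if self.aligned_bases < 0:
            raise ValueError("aligned_bases must be >= 0")

    @property
    def key(self) -> tuple[str, str]:
        return (self.project_id, self.sample_id)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "project_id": self.project_id,
            "timestamp": self.timestamp.isoformat(),
            "metadata": self.metadata,
            "qc": asdict(self.qc) if self.qc else None,
            "profiles": {
                rank: json.loads(p.to_json()) for rank, p in self.profiles.items()
            },
            "aligned_bases": self.aligned_bases,
            "aligned_bases_kind": self.aligned_bases_kind,
            "n_classified": self.n_classified,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SampleRecord":
        qc = ReadQCSummary(**{
            **data["qc"],
            "quality_quartiles": tuple(data["qc"]["quality_quartiles"])
            if data["qc"]["quality_quartiles"] is not None else None,
        }) if data.get("qc") else None
        profiles = {}
        for rank, pdata in data.get("profiles", {}).items():
            profiles[rank] = AbundanceProfile(
                rank=pdata["rank"],
                abundances={int(t["taxid"]): t["abundance"] for t in pdata["taxa"]},
                unclassified_fraction=pdata["unclassified_fraction"],
                unclassified_at_rank=pdata.get("unclassified_at_rank", 0.0),
                names={int(t["taxid"]): t["name"] for t in pdata["taxa"]},
            )
        return cls(
            sample_id=data["sample_id"],
            project_id=data["project_id"],
            timestamp=data["timestamp"],
            metadata=data.get("metadata", {}),
            qc=qc,
            profiles=profiles,
            aligned_bases=data.get("aligned_bases", 0),
            aligned_bases_kind=data.get("aligned_bases_kind", "classified"),
            n_classified=data.get("n_classified", 0),
        )


class SampleStore:
    """In-memory sample registry with JSON-lines persistence.

    Upserts are idempotent and last-write-wins per (project_id, sample_id),
    so replaying the same batches in any order converges to the same state.
    """

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path else None
        self._records: dict[tuple[str, str], SampleRecord] = {}
        if self.path and self.path.exists():
            self.load()

    def __len__(self) -> int:
        return len(self._records)

    def upsert_sample(self, record: SampleRecord) -> None:
        self._records[record.key] = record

    def get(self, project_id: str, sample_id: str) -> SampleRecord:
        return self._records[(project_id, sample_id)]

    def projects(self) -> list[str]:
        return sorted({p for p, _ in self._records})

    def samples(self, project_id: str) -> list[SampleRecord]:
        """Project samples in chronological order (ties broken by sample_id)."""
        records = [r for r in self._records.values() if r.project_id == project_id]
        if not records:
            raise KeyError(f"unknown project {project_id!r}")
        return sorted(records, key=lambda r: (r.timestamp, r.sample_id))

    def save(self, path: str | Path | None = None) -> None:
        target = Path(path) if path else self.path
        if target is None:
            raise ValueError("no path configured for store persistence")
        with open(target, "wt", encoding="utf-8") as out:
            for key in sorted(self._records):
                out.write(json.dumps(self._records[key].to_dict()) + "\n")

    def load(self, path: str | Path | None = None) -> None:
        source = Path(path) if path else self.path
        if source is None:
            raise ValueError("no path configured for store persistence")
        self._records.clear()
        with open(source, "rt", encoding="utf-8") as handle:
            for line in handle:
                if line.strip():
                    record = SampleRecord.from_dict(json.loads(line))
                    self._records[record.key] = record


@dataclass
class TimeSeriesTable:
    """Samples x taxa count matrix with aligned timestamps.

    ``data`` rows are chronologically ordered samples, columns taxa (by
    display name).  ``scaling_factor`` records f when the table holds
    normalized counts.
    """

    data: pd.DataFrame
    timestamps: pd.Series
    normalized: bool = False
    scaling_factor: float | None = None

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.normalized and not (self.scaling_factor and self.scaling_factor > 0):
            raise ValueError("normalized table requires scaling_factor > 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    def subset_taxa(self, taxa: Sequence[str]) -> "TimeSeriesTable":
        return TimeSeriesTable(
            data=self.data[list(taxa)].copy(),
            timestamps=self.timestamps.copy(),
            normalized=self.normalized,
            scaling_factor=self.scaling_factor,
        )

    def proportions(self) -> pd.DataFrame:
        """Row-normalized relative abundances."""
        totals = self.data.sum(axis=1)
        return self.data.div(totals, axis=0)


def build_counts_table(
    store: SampleStore,
    project_id: str,
    rank: str,
    include_unclassified: bool = False,
) -> TimeSeriesTable:
    """Raw count table c_r: profile abundance x classified-read count.

    Taxa are the union over samples (missing taxa filled with 0).  With
    ``include_unclassified`` an extra "Unclassified" column holds the reads
    the classifier could not place.
    """
    records = store.samples(project_id)
    rows: list[dict[str, float]] = []
    index = []
    timestamps = []
    for rec in records:
        if rank not in rec.profiles:
            raise KeyError(f"sample {rec.sample_id!r} has no profile at rank {rank!r}")
        profile = rec.profiles[rank]
        # reads represented per unit of classified profile mass, so row sums
        # equal each sample's classified-read count
        mass = profile.classified_mass()
        per_mass = rec.n_classified / mass if mass > 0 else 0.0
        row = {
            profile.names.get(taxid, str(taxid)): p * per_mass
            for taxid, p in profile.abundances.items()
        }
        if profile.unclassified_at_rank > 0:
            row[f"Unclassified at {rank}"] = profile.unclassified_at_rank * per_mass
        if include_unclassified:
            row["Unclassified"] = profile.unclassified_fraction * per_mass
        rows.append(row)
        index.append(rec.sample_id)
        timestamps.append(rec.timestamp)
    data = pd.DataFrame(rows, index=index).fillna(0.0)
    data = data[sorted(data.columns)]
    data.index.name = "sample_id"
    return TimeSeriesTable(
        data=data, timestamps=pd.Series(timestamps, index=index, name="timestamp")
    )


def normalize_counts(
    table: TimeSeriesTable, aligned_bases: Mapping[str, int]
) -> TimeSeriesTable:
    """Sequencing-effort normalization: c_n = c_r / b * f with f = mean(b).

    ``aligned_bases`` maps each of the table's sample ids to its b; any
    missing or zero b is an error naming the sample.
    """
    if table.normalized:
        raise ValueError("table is already normalized")
    b = []
    for sample_id in table.sample_ids:
        if sample_id not in aligned_bases:
            raise KeyError(f"no aligned-base count for sample {sample_id!r}")
        value = aligned_bases[sample_id]
        if value == 0:
            raise ValueError(f"sample {sample_id!r} has zero aligned bases")
        b.append(float(value))
    b_arr = np.array(b)
    f = float(b_arr.mean())
    data = table.data.div(b_arr, axis=0) * f
    return TimeSeriesTable(
        data=data,
        timestamps=table.timestamps.copy(),
        normalized=True,
        scaling_factor=f,
    )


def top_n_with_other(table: TimeSeriesTable, n: int) -> TimeSeriesTable:
    """Keep the N taxa with the largest totals; sum the rest into "Other".

    Mirrors the dashboard legend convention (e.g. top 14 taxa in stacked-bar
    views, top 10 with "Other" in heatmaps).  Row sums are preserved; ties
    in the ranking break lexicographically by taxon name.  An existing
    "Unclassified" column competes like any taxon and otherwise folds into
    "Other".
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    totals = table.data.sum(axis=0)
    ranked = sorted(table.taxa, key=lambda t: (-totals[t], t))
    top = ranked[:n]
    rest = ranked[n:]
    data = table.data[top].copy()
    data[OTHER_LABEL] = table.data[rest].sum(axis=1) if rest else 0.0
    return TimeSeriesTable(
        data=data,
        timestamps=table.timestamps.copy(),
        normalized=table.normalized,
        scaling_factor=table.scaling_factor,
    )


# --- MAG quality filtering ---


@dataclass(frozen=True)
class MAGQualityRecord:
    """Quality row for one metagenome-assembled genome (MAG)."""

    mag_id: str
    completeness: float  # percent
    contamination: float  # percent
    genome_size: int = 0  # bp
    classification: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise ValueError("completeness must be in [0, 100]")
        if self.contamination < 0:
            raise ValueError("contamination must be >= 0")


def filter_mag_quality(
    records: Iterable[MAGQualityRecord],
    min_completeness: float,
    max_contamination: float,
    boundary_mode: str = "strict",
) -> list[MAGQualityRecord]:
    """Retain bins passing completeness/contamination thresholds.

    ``boundary_mode='strict'`` requires completeness strictly above the
    minimum (the pipeline's retention rule, > 80 and < 10);
    ``'inclusive'`` accepts equality (the MIMAG high-quality rule, >= 90 and
    < 5).  Contamination is strictly below the maximum in both modes.
    """
    if not 0 <= min_completeness <= 100 or not 0 <= max_contamination <= 100:
        raise ValueError("thresholds must be in [0, 100]")
    if boundary_mode not in ("strict", "inclusive"):
        raise ValueError(f"unknown boundary_mode {boundary_mode!r}")
    out = []
    for rec in records:
        if boundary_mode == "strict":
            ok = rec.completeness > min_completeness
        else:
            ok = rec.completeness >= min_completeness
        if ok and rec.contamination < max_contamination:
            out.append(rec)
    return out


def filter_mags_pipeline(records: Iterable[MAGQualityRecord]) -> list[MAGQualityRecord]:
    """Assembly-pipeline retention rule: completeness > 80, contamination < 10."""
    return filter_mag_quality(records, 80.0, 10.0, boundary_mode="strict")


def filter_mags_mimag(records: Iterable[MAGQualityRecord]) -> list[MAGQualityRecord]:
    """MIMAG "high-quality draft" rule: completeness >= 90, contamination < 5."""
    return filter_mag_quality(records, 90.0, 5.0, boundary_mode="inclusive")


_MAG_COLUMNS = {
    "MAG ID": "mag_id",
    "Completeness (%)": "completeness",
    "Contamination (%)": "contamination",
    "Genome size (bp)": "genome_size",
    "GTDB classification": "classification",
}


def read_mag_table(path: str | Path) -> list[MAGQualityRecord]:
    """Read a MAG quality CSV with the conventional report column names."""
    frame = pd.read_csv(path)
    missing = set(_MAG_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"MAG table missing columns: {sorted(missing)}")
    return [
        MAGQualityRecord(
            mag_id=str(row["MAG ID"]),
            completeness=float(row["Completeness (%)"]),
            contamination=float(row["Contamination (%)"]),
            genome_size=int(row["Genome size (bp)"]),
            classification=str(row["GTDB classification"]),
        )
        for _, row in frame.iterrows()
    ]


# --- import/export ---


def export_table(table: TimeSeriesTable, path: str | Path, format: str = "csv") -> None:
    """Write a table to CSV (12-significant-digit counts) or JSON.

    The CSV form leads with a comment line carrying the normalization state
    so a round-trip restores the scaling factor f.
    """
    path = Path(path)
    if format == "csv":
        with open(path, "wt", encoding="utf-8", newline="") as out:
            out.write(
                f"# normalized={str(table.normalized).lower()}"
                + (f" f={table.scaling_factor:.12g}" if table.normalized else "")
                + "\n"
            )
            frame = table.data.copy()
            frame.insert(0, "timestamp", [ts.isoformat() for ts in table.timestamps])
            frame.to_csv(out, float_format="%.12g", index_label="sample_id")
    elif format == "json":
        payload = {
            "normalized": table.normalized,
            "scaling_factor": table.scaling_factor,
            "sample_ids": table.sample_ids,
            "timestamps": [ts.isoformat() for ts in table.timestamps],
            "taxa": table.taxa,
            "counts": table.data.to_numpy().tolist(),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown format {format!r}")


def import_table(path: str | Path, format: str = "csv") -> TimeSeriesTable:
    path = Path(path)
    if format == "csv":
        with open(path, "rt", encoding="utf-8") as handle:
            header = handle.readline().strip()
            if not header.startswith("#"):
                raise ValueError("missing normalization comment line")
            fields = dict(
                item.split("=") for item in header.lstrip("# ").split() if "=" in item
            )
            frame = pd.read_csv(handle, index_col="sample_id")
        timestamps = pd.Series(
            [datetime.fromisoformat(t) for t in frame.pop("timestamp")],
            index=frame.index,
            name="timestamp",
        )
        normalized = fields.get("normalized") == "true"
        return TimeSeriesTable(
            data=frame,
            timestamps=timestamps,
            normalized=normalized,
            scaling_factor=float(fields["f"]) if normalized else None,
        )
    elif format == "json":
        payload = json.loads(path.read_text())
        data = pd.DataFrame(
            payload["counts"], index=payload["sample_ids"], columns=payload["taxa"]
        )
        data.index.name = "sample_id"
        return TimeSeriesTable(
            data=data,
            timestamps=pd.Series(
                [datetime.fromisoformat(t) for t in payload["timestamps"]],
                index=payload["sample_ids"],
                name="timestamp",
            ),
            normalized=payload["normalized"],
            scaling_factor=payload["scaling_factor"],
        )
    raise ValueError(f"unknown format {format!r}")
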