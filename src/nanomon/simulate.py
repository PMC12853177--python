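"""Deterministic synthetic data: references, reads, time series, fixture runs.

Everything needed to exercise the pipeline without downloading databases:
random reference "genomes" organised into a small taxonomy, nanopore-like
reads drawn from an abundance profile with substitution errors and a
two-level quality model, abundance time series with a changepoint (the kind
of community shift a reactor perturbation produces), and timestamped FASTQ
fixture runs for the directory watcher.

All randomness flows through one integer seed; identical :class:`SimSpec`
inputs give byte-identical outputs.  The error model is substitution-only —
no indels, homopolymer artefacts, or quality autocorrelation — which keeps
the k-mer classifier's hit statistics analyzable.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import canonical_kmers
from .reads import ReadRecord, write_fastq
from .taxonomy import Taxonomy, TaxonNode

__all__ = [
    "SimSpec",
    "ReferenceSet",
    "make_reference_set",
    "simulate_reads",
    "simulate_time_series",
    "emit_fixture_run",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: read-length ranges per sequencing mode (bp): full-length 16S amplicons
#: sit between the 1 kb / 2 kb filter bounds; WGS reads start at the 2 kb
#: minimum.
READ_LENGTH_RANGES = {"16s": (1200, 1600), "wgs": (2000, 10000)}


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic study; ``seed`` is mandatory.

    Defaults emulate a small full-length 16S amplicon time series: a
    handful of genera at ~1.6 kb reference length, 2% substitution errors,
    a two-level quality model averaging ~Q14, mild compositional
    (Dirichlet) noise, and one community shift at ``changepoint``.
    """

    seed: int
    mode: str = "16s"
    n_genera: int = 3
    species_per_genus: int = 2
    reference_length: int = 1600
    read_length_range: tuple[int, int] | None = None  # None -> mode default
    quality_high: int = 18
    quality_low: int = 7
    low_quality_fraction: float = 0.1
    substitution_rate: float = 0.02
    n_reads: int = 500
    timepoints: int = 6
    changepoint: int = 3           # 0-based timepoint where the shift starts
    effect_taxa: tuple[int, ...] = (0,)  # species indices that shift
    effect_multiplier: float = 4.0
    metadata_taxon: int = 0        # species index driving the metadata variable
    metadata_slope: float = 100.0
    metadata_noise_sd: float = 0.0
    dirichlet_concentration: float = 200.0
    k: int = 15                    # k-mer size for the cross-reference check

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.low_quality_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.mode not in READ_LENGTH_RANGES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.effect_multiplier <= 0:
            raise ValueError("effect_multiplier must be > 0")
        if self.timepoints >= 2 and not 1 <= self.changepoint <= self.timepoints:
            raise ValueError("changepoint must lie within the timepoints")

    @property
    def n_taxa(self) -> int:
        return self.n_genera * self.species_per_genus

    @property
    def lengths(self) -> tuple[int, int]:
        return self.read_length_range or READ_LENGTH_RANGES[self.mode]


@dataclass
class ReferenceSet:
    """Synthetic references plus their taxonomy and species taxids."""

    sequences: dict[int, str]  # species taxid -> sequence
    tree: Taxonomy
    species_taxids: list[int]

    def write(self, fasta_path: str | Path, taxonomy_path: str | Path,
              seq2tax_path: str | Path) -> None:
        with open(fasta_path, "wt", encoding="ascii") as out:
            for taxid in self.species_taxids:
                out.write(f">ref_{taxid}\n{self.sequences[taxid]}\n")
        self.tree.to_tsv(taxonomy_path)
        with open(seq2tax_path, "wt", encoding="ascii") as out:
            for taxid in self.species_taxids:
                out.write(f"ref_{taxid}\t{taxid}\n")


def _rng(spec: SimSpec, stream: int) -> np.random.Generator:
    # independent, platform-stable streams per generator stage
    return np.random.Generator(np.random.PCG64([spec.seed, stream]))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def make_reference_set(spec: SimSpec, max_retries: int = 50) -> ReferenceSet:
    """Generate per-species references sharing no canonical k-mers.

    Each candidate sequence is rejection-checked against the k-mer pool of
    the already-accepted references so every species is unambiguous at
    ``spec.k``; after ``max_retries`` rejections an error is raised.
    """
    rng = _rng(spec, stream=1)
    nodes = [TaxonNode(1, 1, "domain", "Bacteria")]
    species_taxids: list[int] = []
    taxid = 2
    phylum_id = taxid
    nodes.append(TaxonNode(phylum_id, 1, "phylum", "Phylum_1"))
    taxid += 1
    for g in range(spec.n_genera):
        genus_id = taxid
        nodes.append(TaxonNode(genus_id, phylum_id, "genus", f"Genus_{g + 1}"))
        taxid += 1
        for s in range(spec.species_per_genus):
            nodes.append(
                TaxonNode(taxid, genus_id, "species", f"Genus_{g + 1} species_{s + 1}")
            )
            species_taxids.append(taxid)
            taxid += 1

    sequences: dict[int, str] = {}
    pool: set[str] = set()
    for sp in species_taxids:
        for attempt in range(max_retries + 1):
            candidate = _random_sequence(rng, spec.reference_length)
            kmers = set(canonical_kmers(candidate, spec.k))
            if pool.isdisjoint(kmers):
                sequences[sp] = candidate
                pool |= kmers
                break
        else:
            raise RuntimeError(
                f"could not draw a k-mer-disjoint reference after {max_retries} tries"
            )
    return ReferenceSet(sequences=sequences, tree=Taxonomy(nodes), species_taxids=species_taxids)


def simulate_reads(
    profile: Mapping[int, float],
    references: ReferenceSet,
    spec: SimSpec,
    stream: int = 2,
    read_prefix: str = "read",
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Draw ``spec.n_reads`` reads from an abundance profile.

    Each read is a substring of its source reference with i.i.d.
    substitution errors; qualities are drawn from the two-level model.
    Returns the reads and a ground-truth sidecar (read_id, taxid) whose
    per-taxon counts are exactly the multinomial draw.
    """
    taxids = sorted(profile)
    p = np.array([profile[t] for t in taxids], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("profile must sum to 1")
    lo, hi = spec.lengths
    for t in taxids:
        if len(references.sequences[t]) < hi:
            raise ValueError(
                f"reference {t} shorter ({len(references.sequences[t])}) than "
                f"maximum read length {hi}"
            )
    rng = _rng(spec, stream=stream)
    counts = rng.multinomial(spec.n_reads, p)
    sources = np.repeat(taxids, counts)
    rng.shuffle(sources)
    reads: list[ReadRecord] = []
    truth_rows = []
    for i, taxid in enumerate(sources):
        ref = references.sequences[int(taxid)]
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(ref) - length + 1))
        seq = np.frombuffer(ref[start : start + length].encode("ascii"), dtype=np.uint8).copy()
        err = rng.random(length) < spec.substitution_rate
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum()))
            base_idx = np.searchsorted(_BASES, seq[err])
            seq[err] = _BASES[(base_idx + shift) % 4]
        quality = np.where(
            rng.random(length) < spec.low_quality_fraction,
            spec.quality_low,
            spec.quality_high,
        )
        read_id = f"{read_prefix}_{i:06d}"
        reads.append(
            ReadRecord(read_id, seq.tobytes().decode("ascii"), tuple(int(q) for q in quality))
        )
        truth_rows.append({"read_id": read_id, "taxid": int(taxid)})
    truth = pd.DataFrame(truth_rows, columns=["read_id", "taxid"])
    return reads, truth


def simulate_time_series(spec: SimSpec) -> tuple[list[dict[int, float]], pd.DataFrame]:
    """Per-timepoint species profiles with a changepoint, plus metadata.

    A baseline composition is drawn once; from ``changepoint`` on the
    ``effect_taxa`` are multiplied by ``effect_multiplier`` and the profile
    renormalized.  Dirichlet noise (concentration x expected profile) is
    applied per timepoint, and one numeric metadata variable follows the
    ``metadata_taxon`` abundance linearly with optional Gaussian noise.
    """
    if spec.timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    refs_rng = _rng(spec, stream=3)
    species = list(range(spec.n_taxa))
    baseline = refs_rng.dirichlet(np.full(spec.n_taxa, 5.0))
    shifted = baseline.copy()
    for idx in spec.effect_taxa:
        shifted[idx] *= spec.effect_multiplier
    shifted /= shifted.sum()

    profiles: list[dict[int, float]] = []
    meta_rows = []
    taxids = None
    for t in range(spec.timepoints):
        expected = shifted if t >= spec.changepoint else baseline
        if spec.dirichlet_concentration > 0 and not np.isinf(spec.dirichlet_concentration):
            drawn = refs_rng.dirichlet(spec.dirichlet_concentration * expected)
        else:
            drawn = expected.copy()
        profiles.append({i: float(v) for i, v in enumerate(drawn)})
        value = spec.metadata_slope * drawn[spec.metadata_taxon]
        if spec.metadata_noise_sd > 0:
            value += refs_rng.normal(0.0, spec.metadata_noise_sd)
        meta_rows.append({"timepoint": t, "variable": float(value)})
    metadata = pd.DataFrame(meta_rows)
    return profiles, metadata


def emit_fixture_run(
    directory: str | Path,
    spec: SimSpec,
    references: ReferenceSet | None = None,
    start_time: datetime | None = None,
    interval: timedelta = timedelta(hours=1),
    force: bool = False,
) -> list[Path]:
    """Write one timestamped FASTQ per timepoint (backdated mtimes).

    Filenames encode the sample id and timestamp
    (``sample_t00_20240101T000000.fastq``) so the watcher can recover both.
    Ground-truth sidecars (per-read taxid, per-timepoint true profile) are
    written alongside.  Refuses to reuse a non-empty directory unless
    ``force``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if any(directory.iterdir()) and not force:
        raise FileExistsError(f"{directory} is not empty (use force=True)")
    if references is None:
        references = make_reference_set(spec)
    if start_time is None:
        start_time = datetime(2024, 1, 1, tzinfo=timezone.utc)
    index_profiles, metadata = simulate_time_series(spec)
    paths: list[Path] = []
    truth_profiles = []
    for t, index_profile in enumerate(index_profiles):
        profile = {
            references.species_taxids[i]: p for i, p in index_profile.items()
        }
        reads, truth = simulate_reads(
            profile, references, spec, stream=100 + t, read_prefix=f"t{t:02d}"
        )
        ts = start_time + t * interval
        stamp = ts.strftime("%Y%m%dT%H%M%S")
        path = directory / f"sample_t{t:02d}_{stamp}.fastq"
        write_fastq(reads, path)
        epoch = ts.timestamp()
        os.utime(path, (epoch, epoch))
        truth.to_csv(path.with_suffix(".truth.csv"), index=False)
        for taxid, p in profile.items():
            truth_profiles.append(
                {"timepoint": t, "taxid": taxid, "abundance": p}
            )
        paths.append(path)
    pd.DataFrame(truth_profiles).to_csv(
        directory / "true_profiles.csv", index=False
    )
    metadata.insert(0, "sample_id", [p.stem.split(".")[0] for p in paths])
    metadata.to_csv(directory / "metadata.csv", index=False)
    return paths
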