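"""Taxonomic read classification and EM abundance refinement.

The shipped classifier is a deliberately simple canonical k-mer counter kept
entirely in memory, so that new read batches can be scored the moment they
arrive.  It is pluggable: any external profiler can be substituted by
handing :func:`em_abundance` a pre-built :class:`CompatibilityMatrix`, or by
storing a finished :class:`AbundanceProfile` directly.

Ambiguously mapping reads (e.g. conserved 16S regions shared between taxa)
are resolved by a multinomial-mixture EM: the community abundance vector
``a`` is the mixture weight, a read's k-mer hit counts ``w_rt`` act as
compatibility weights, and reads are fractionally redistributed among their
candidate taxa until the abundances stop moving.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .reads import ReadRecord
from .taxonomy import RANKS, Taxonomy

__all__ = [
    "ReferenceIndex",
    "CompatibilityMatrix",
    "AbundanceProfile",
    "EMSettings",
    "ProfileResult",
    "build_kmer_index",
    "load_references",
    "canonical_kmers",
    "score_read",
    "em_abundance",
    "profile_sample",
    "aggregate_to_rank",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmers(sequence: str, k: int) -> list[str]:
    """All canonical k-mers of a sequence; k-mers containing N are skipped.

    The canonical form of a k-mer is the lexicographic minimum of the k-mer
    and its reverse complement, so reads match regardless of strand.
    """
    sequence = sequence.upper()
    out = []
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i : i + k]
        if "N" in kmer:
            continue
        rc = _revcomp(kmer)
        out.append(kmer if kmer <= rc else rc)
    return out


@dataclass
class ReferenceIndex:
    """In-memory map from canonical k-mer to the set of source taxids."""

    k: int
    kmers: dict[str, frozenset[int]]
    reference_lengths: dict[int, int]

    @property
    def taxids(self) -> frozenset[int]:
        return frozenset(self.reference_lengths)


def build_kmer_index(
    references: Iterable[tuple[str, int]], k: int = 15
) -> ReferenceIndex:
    """Index every canonical k-mer of every reference sequence.

    ``references`` yields (sequence, taxid) pairs; several sequences may
    share a taxid (their k-mer sets are unioned).  Emits a warning condition
    via an empty index when every reference is shorter than k.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    kmers: dict[str, set[int]] = {}
    lengths: dict[int, int] = {}
    for sequence, taxid in references:
        lengths[taxid] = lengths.get(taxid, 0) + len(sequence)
        for kmer in canonical_kmers(sequence, k):
            kmers.setdefault(kmer, set()).add(taxid)
    return ReferenceIndex(
        k=k,
        kmers={kmer: frozenset(taxids) for kmer, taxids in kmers.items()},
        reference_lengths=lengths,
    )


def load_references(
    fasta_path: str | Path, seq2tax_path: str | Path
) -> list[tuple[str, int]]:
    """Read reference sequences (FASTA) plus a seq-id -> taxid TSV."""
    seq2tax: dict[str, int] = {}
    with open(seq2tax_path, "rt", encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            seq_id, taxid = line.split("\t")
            seq2tax[seq_id] = int(taxid)
    references = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id not in seq2tax:
            raise KeyError(f"reference {record.id!r} missing from {seq2tax_path}")
        references.append((str(record.seq).upper(), seq2tax[record.id]))
    return references


def score_read(read: ReadRecord, index: ReferenceIndex) -> dict[int, int]:
    """Count how many of the read's canonical k-mers each taxon's references
    contain.  Reads shorter than k score zero everywhere."""
    scores: dict[int, int] = {}
    for kmer in canonical_kmers(read.sequence, index.k):
        taxids = index.kmers.get(kmer)
        if taxids is None:
            continue
        for taxid in taxids:
            scores[taxid] = scores.get(taxid, 0) + 1
    return scores


@dataclass
class CompatibilityMatrix:
    """Sparse read x taxon weight matrix.

    ``weights[read_id]`` maps candidate taxids to nonnegative weights; an
    absent or empty entry marks an unclassified read.  ``read_ids`` fixes the
    row universe so the unclassified fraction is well defined.
    """

    read_ids: list[str]
    weights: dict[str, dict[int, float]]

    def __post_init__(self) -> None:
        for read_id, row in self.weights.items():
            for taxid, w in row.items():
                if w < 0:
                    raise ValueError(
                        f"negative weight {w} for read {read_id!r}, taxon {taxid}"
                    )

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    def classified_rows(self) -> list[str]:
        return [
            rid
            for rid in self.read_ids
            if any(w > 0 for w in self.weights.get(rid, {}).values())
        ]

    @classmethod
    def from_reads(
        cls, reads: Sequence[ReadRecord], index: ReferenceIndex
    ) -> "CompatibilityMatrix":
        weights = {}
        read_ids = []
        for read in reads:
            read_ids.append(read.read_id)
            row = score_read(read, index)
            if row:
                weights[read.read_id] = {t: float(w) for t, w in row.items()}
        return cls(read_ids=read_ids, weights=weights)


@dataclass
class AbundanceProfile:
    """Relative abundances p_i per taxon at one rank.

    ``sum(abundances) + unclassified_at_rank + unclassified_fraction == 1``:
    ``unclassified_fraction`` is the share of reads the classifier could not
    place at all, while ``unclassified_at_rank`` is classified mass whose
    lineage has no node at this profile's rank (only nonzero after
    aggregation).  ``names`` is an optional taxid -> display-name map.
    """

    rank: str
    abundances: dict[int, float]
    unclassified_fraction: float = 0.0
    unclassified_at_rank: float = 0.0
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.abundances.values()):
            raise ValueError("abundances must be nonnegative")

    @property
    def n_taxa(self) -> int:
        """S: number of taxa with positive abundance."""
        return sum(1 for p in self.abundances.values() if p > 0)

    def classified_mass(self) -> float:
        return sum(self.abundances.values()) + self.unclassified_at_rank

    def renormalized(self) -> dict[int, float]:
        """Abundances renormalized over classified mass at this rank."""
        total = sum(self.abundances.values())
        if total <= 0:
            raise ValueError("profile has no classified mass")
        return {t: p / total for t, p in self.abundances.items()}

    def to_json(self) -> str:
        return json.dumps(
            {
                "rank": self.rank,
                "unclassified_fraction": self.unclassified_fraction,
                "unclassified_at_rank": self.unclassified_at_rank,
                "taxa": [
                    {
                        "taxid": taxid,
                        "name": self.names.get(taxid, str(taxid)),
                        "abundance": p,
                    }
                    for taxid, p in sorted(self.abundances.items())
                ],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "wt", encoding="utf-8") as out:
            out.write("taxid,name,rank,abundance\n")
            for taxid, p in sorted(self.abundances.items()):
                out.write(f"{taxid},{self.names.get(taxid, taxid)},{self.rank},{p:.12g}\n")


@dataclass(frozen=True)
class EMSettings:
    tol: float = 1e-6       # max absolute abundance change at convergence
    max_iter: int = 100
    prune_floor: float = 1e-5  # taxa below this final abundance are dropped

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


def em_abundance(
    matrix: CompatibilityMatrix,
    settings: EMSettings = EMSettings(),
    rank: str = "species",
    return_trace: bool = False,
):
    """Multinomial-mixture EM over the compatibility matrix.

    E-step: responsibilities gamma_rt ~ a_t * w_rt, normalized per read.
    M-step: a_t = mean responsibility over classified reads.
    Iterates until ``max |delta a| < tol`` or ``max_iter``; taxa ending below
    ``prune_floor`` are removed and the remaining mass renormalized.

    Returns the :class:`AbundanceProfile`; with ``return_trace=True`` also
    the per-iteration log-likelihood, which is non-decreasing.
    """
    classified = matrix.classified_rows()
    n_total = matrix.n_reads
    if not classified:
        profile = AbundanceProfile(
            rank=rank, abundances={}, unclassified_fraction=1.0 if n_total else 0.0
        )
        return (profile, []) if return_trace else profile

    taxids = sorted({t for rid in classified for t in matrix.weights[rid]})
    t_index = {t: j for j, t in enumerate(taxids)}
    # dense R x T weight matrix; instances are small after k-mer screening
    W = np.zeros((len(classified), len(taxids)))
    for i, rid in enumerate(classified):
        for taxid, w in matrix.weights[rid].items():
            W[i, t_index[taxid]] = w

    a = np.full(len(taxids), 1.0 / len(taxids))
    loglik: list[float] = []
    for _ in range(settings.max_iter):
        mix = W * a  # (R, T)
        row_sums = mix.sum(axis=1)
        loglik.append(float(np.log(row_sums).sum()))
        gamma = mix / row_sums[:, None]
        a_new = gamma.mean(axis=0)
        delta = float(np.max(np.abs(a_new - a)))
        a = a_new
        if delta < settings.tol:
            break
    loglik.append(float(np.log((W * a).sum(axis=1)).sum()))

    keep = a >= settings.prune_floor
    if not keep.any():  # degenerate floor; keep everything rather than lose mass
        keep = np.ones_like(keep)
    a = np.where(keep, a, 0.0)
    a = a / a.sum()
    unclassified = (n_total - len(classified)) / n_total
    abundances = {
        taxids[j]: float(a[j] * (1.0 - unclassified)) for j in np.nonzero(keep)[0]
    }
    profile = AbundanceProfile(
        rank=rank, abundances=abundances, unclassified_fraction=unclassified
    )
    return (profile, loglik) if return_trace else profile


@dataclass
class ProfileResult:
    """Profile plus per-read bookkeeping from :func:`profile_sample`."""

    profile: AbundanceProfile
    assignments: dict[str, int | None]  # read_id -> LCA taxid (None = unclassified)
    n_reads: int
    n_classified: int
    aligned_bases: int   # total bases of classified reads (normalization proxy b)
    total_bases: int     # total bases of all input reads
    read_fraction_profile: AbundanceProfile  # alternative: LCA read-count fractions


def profile_sample(
    reads: Sequence[ReadRecord],
    index: ReferenceIndex,
    tree: Taxonomy,
    settings: EMSettings = EMSettings(),
) -> ProfileResult:
    """Score reads, run the EM, and assign each read to the LCA of its
    top-scoring taxa (assignments are reporting-only; abundances come from
    the EM posterior).

    Reads whose top scores tie within one k-mer are assigned conservatively
    to the LCA of all near-maximal taxa.
    """
    matrix = CompatibilityMatrix.from_reads(reads, index)
    profile = em_abundance(matrix, settings)
    lengths = {r.read_id: len(r) for r in reads}

    assignments: dict[str, int | None] = {}
    lca_counts: dict[int, int] = {}
    aligned_bases = 0
    for rid in matrix.read_ids:
        row = matrix.weights.get(rid, {})
        positive = {t: w for t, w in row.items() if w > 0}
        if not positive:
            assignments[rid] = None
            continue
        best = max(positive.values())
        candidates = [t for t, w in positive.items() if w >= best - 1]
        taxid = tree.lca(candidates)
        assignments[rid] = taxid
        lca_counts[taxid] = lca_counts.get(taxid, 0) + 1
        aligned_bases += lengths[rid]

    n_classified = sum(1 for t in assignments.values() if t is not None)
    names = {t: tree.name(t) for t in set(profile.abundances) | set(lca_counts)}
    profile.names = {t: names[t] for t in profile.abundances}
    unclassified = profile.unclassified_fraction
    read_fraction = AbundanceProfile(
        rank="species",
        abundances={
            t: (1.0 - unclassified) * c / n_classified for t, c in lca_counts.items()
        }
        if n_classified
        else {},
        unclassified_fraction=unclassified,
        names={t: names[t] for t in lca_counts},
    )
    return ProfileResult(
        profile=profile,
        assignments=assignments,
        n_reads=len(reads),
        n_classified=n_classified,
        aligned_bases=aligned_bases,
        total_bases=sum(lengths.values()),
        read_fraction_profile=read_fraction,
    )


def aggregate_to_rank(
    profile: AbundanceProfile, tree: Taxonomy, target_rank: str
) -> AbundanceProfile:
    """Sum abundances up the taxonomy to a broader rank.

    Mass on lineages with no node at the target rank accumulates in
    ``unclassified_at_rank``; total mass is preserved.
    """
    ranks = list(RANKS)
    if target_rank not in ranks:
        raise ValueError(f"unknown rank {target_rank!r}")
    if profile.rank in ranks and ranks.index(target_rank) > ranks.index(profile.rank):
        raise ValueError(
            f"cannot aggregate {profile.rank} profile down to {target_rank}"
        )
    if target_rank == profile.rank:
        return profile
    out: dict[int, float] = {}
    names: dict[int, str] = {}
    orphan = profile.unclassified_at_rank
    for taxid, p in profile.abundances.items():
        ancestor = tree.ancestor_at_rank(taxid, target_rank)
        if ancestor is None:
            orphan += p
        else:
            out[ancestor] = out.get(ancestor, 0.0) + p
            names[ancestor] = tree.name(ancestor)
    return AbundanceProfile(
        rank=target_rank,
        abundances=out,
        unclassified_fraction=profile.unclassified_fraction,
        unclassified_at_rank=orphan,
        names=names,
    )
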