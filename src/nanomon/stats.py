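"""Dashboard analytics: diversity, ordination, correlation, horizon series.

Alpha diversity uses Shannon entropy H = -sum p_i log2 p_i and the
Gini-Simpson index D = 1 - sum p_i^2 on relative abundances renormalized
over classified mass.  Beta diversity is the Bray-Curtis dissimilarity

    d(u, v) = sum_i |u_i - v_i| / sum_i |u_i + v_i|

and sample configurations are embedded by classical principal coordinates
analysis (Gower double-centering of -1/2 d^2 followed by an
eigendecomposition).  Taxonomy-metadata association offers Pearson's rho,
Kendall's tau, and Spearman's rank correlation, all computed natively from
their defining sums so the coefficients stay inspectable (concordant and
discordant pair counts, rank vectors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import AbundanceProfile
from .store import TimeSeriesTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "CorrelationResult",
    "CorrelationMatrix",
    "HorizonSeries",
    "shannon",
    "simpson",
    "alpha_diversity_table",
    "bray_curtis",
    "beta_diversity_matrix",
    "pcoa",
    "correlate",
    "taxon_metadata_correlations",
    "horizon_series",
]


def _as_proportions(values) -> np.ndarray:
    if isinstance(values, AbundanceProfile):
        values = list(values.renormalized().values())
    p = np.asarray(values, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    return p / total


def shannon(values) -> float:
    """Shannon entropy H = -sum p_i log2(p_i), with 0*log(0) := 0 (bits)."""
    p = _as_proportions(values)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def simpson(values) -> float:
    """Gini-Simpson index D = 1 - sum p_i^2."""
    p = _as_proportions(values)
    return float(1.0 - (p * p).sum())


def alpha_diversity_table(table: TimeSeriesTable) -> pd.DataFrame:
    """Per-sample Shannon and Simpson indices from a count table."""
    rows = {
        sample_id: {
            "shannon": shannon(table.data.loc[sample_id].to_numpy()),
            "simpson": simpson(table.data.loc[sample_id].to_numpy()),
        }
        for sample_id in table.sample_ids
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def bray_curtis(u: Sequence[float], v: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity: sum|u_i - v_i| / sum|u_i + v_i|."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    denom = np.abs(u + v).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(u - v).sum() / denom)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with sample labels."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="sample_id", float_format="%.12g")


def beta_diversity_matrix(table: TimeSeriesTable) -> DistanceMatrix:
    """All pairwise Bray-Curtis distances between the table's samples."""
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    X = table.data.to_numpy(dtype=float)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = bray_curtis(X[i], X[j])
    return DistanceMatrix(values=D, ids=table.sample_ids)


@dataclass
class OrdinationResult:
    """PCoA embedding: coordinates, eigenvalues, variance explained."""

    coordinates: pd.DataFrame       # samples x axes
    eigenvalues: np.ndarray         # non-increasing; negatives clamped to 0
    proportion_explained: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        frame = self.coordinates.copy()
        frame.to_csv(path, index_label="sample_id", float_format="%.12g")


def pcoa(distance: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers B = -1/2 J D^2 J and eigendecomposes.  Coordinates are
    eigenvector * sqrt(eigenvalue) for positive eigenvalues; negative
    eigenvalues (non-Euclidean input) are clamped to zero and reported.
    """
    D = distance.values
    n = D.shape[0]
    if n_axes is None:
        n_axes = n
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    clamped = np.clip(eigvals, 0.0, None)
    coords = eigvecs * np.sqrt(clamped)
    n_axes = min(n_axes, n)
    positive_sum = clamped.sum()
    proportion = clamped / positive_sum if positive_sum > 0 else np.zeros(n)
    axes = [f"PC{i + 1}" for i in range(n_axes)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords[:, :n_axes], index=distance.ids, columns=axes),
        eigenvalues=clamped[:n_axes],
        proportion_explained=proportion[:n_axes],
    )


# --- correlation ---


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties sharing the average of their positions."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


@dataclass
class CorrelationResult:
    """One coefficient with the ingredients of its defining formula.

    ``coefficient`` is NaN (flagged missing) when either series has zero
    variance.  For Kendall, ``concordant``/``discordant`` are the pair
    counts C and D; ``tie_mode`` records whether ties were handled as tau-b
    or excluded ("printed" mode, tau = (C-D)/(C+D)).  For Spearman the
    average-rank vectors are retained.
    """

    method: str
    coefficient: float
    n: int
    concordant: int | None = None
    discordant: int | None = None
    tie_mode: str | None = None
    ranks_x: np.ndarray | None = None
    ranks_y: np.ndarray | None = None

    @property
    def missing(self) -> bool:
        return math.isnan(self.coefficient)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    sx = math.sqrt((xd * xd).sum())
    sy = math.sqrt((yd * yd).sum())
    if sx == 0 or sy == 0:
        return math.nan
    return float((xd * yd).sum() / (sx * sy))


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
    kendall_tie_mode: str = "tau-b",
) -> CorrelationResult:
    """Pearson, Kendall, or Spearman correlation of two aligned series.

    Paired missing values (NaN in either series) are dropped first.  Zero
    variance in either series yields a flagged-missing coefficient rather
    than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")

    if method == "pearson":
        return CorrelationResult("pearson", _pearson(x, y), n)

    if method == "spearman":
        rx = _average_ranks(x)
        ry = _average_ranks(y)
        return CorrelationResult(
            "spearman", _pearson(rx, ry), n, ranks_x=rx, ranks_y=ry
        )

    if method == "kendall":
        if kendall_tie_mode not in ("tau-b", "printed"):
            raise ValueError(f"unknown kendall_tie_mode {kendall_tie_mode!r}")
        concordant = discordant = ties_x = ties_y = 0
        for i in range(n):
            for j in range(i + 1, n):
                dx = x[i] - x[j]
                dy = y[i] - y[j]
                if dx == 0 and dy == 0:
                    continue
                elif dx == 0:
                    ties_x += 1
                elif dy == 0:
                    ties_y += 1
                elif dx * dy > 0:
                    concordant += 1
                else:
                    discordant += 1
        if kendall_tie_mode == "printed":
            denom = concordant + discordant
        else:
            denom = math.sqrt(
                (concordant + discordant + ties_x)
                * (concordant + discordant + ties_y)
            )
        tau = (concordant - discordant) / denom if denom else math.nan
        return CorrelationResult(
            "kendall",
            float(tau),
            n,
            concordant=concordant,
            discordant=discordant,
            tie_mode=kendall_tie_mode,
        )

    raise ValueError(f"unknown method {method!r}")


@dataclass
class CorrelationMatrix:
    """Taxa x metadata-variable grid of correlation results."""

    method: str
    coefficients: pd.DataFrame  # taxa rows, variable columns
    results: dict[tuple[str, str], CorrelationResult]

    def to_csv(self, path: str | Path) -> None:
        self.coefficients.to_csv(path, index_label="taxon", float_format="%.12g")


def taxon_metadata_correlations(
    table: TimeSeriesTable,
    metadata: pd.DataFrame,
    method: str = "pearson",
    **kwargs,
) -> CorrelationMatrix:
    """Correlate every taxon's count series with every numeric metadata
    variable, aligned by sample id.  Constant series are flagged missing."""
    shared = [s for s in table.sample_ids if s in metadata.index]
    if not shared:
        raise ValueError("no shared samples between table and metadata")
    numeric = metadata.loc[shared].select_dtypes(include=[np.number])
    counts = table.data.loc[shared]
    coefficients = pd.DataFrame(index=table.taxa, columns=numeric.columns, dtype=float)
    results: dict[tuple[str, str], CorrelationResult] = {}
    for taxon in table.taxa:
        for variable in numeric.columns:
            res = correlate(
                counts[taxon].to_numpy(),
                numeric[variable].to_numpy(),
                method=method,
                **kwargs,
            )
            results[(taxon, variable)] = res
            coefficients.loc[taxon, variable] = res.coefficient
    return CorrelationMatrix(method=method, coefficients=coefficients, results=results)


# --- horizon plots ---


@dataclass
class HorizonSeries:
    """Signed deviations for a banded (horizon) time-series chart.

    ``vs_mean`` deviations are x_t - mean(x) (red above, blue below the
    mean); ``vs_previous`` uses successive differences with the first point
    at 0.  ``band_boundaries`` slice [0, max|dev|] into equal bands;
    ``band_index`` gives each point's signed band (0 for zero deviation).
    """

    deviations: np.ndarray
    mode: str
    band_boundaries: np.ndarray
    band_index: np.ndarray

    def to_frame(
        self, timestamps: Sequence | None = None, taxon: str | None = None
    ) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "timestamp": list(timestamps)
                if timestamps is not None
                else np.arange(len(self.deviations)),
                "deviation": self.deviations,
                "band": self.band_index,
            }
        )
        if taxon is not None:
            frame.insert(0, "taxon", taxon)
        return frame


def horizon_series(
    values: Sequence[float], mode: str = "vs_mean", n_bands: int = 4
) -> HorizonSeries:
    """Transform one taxon's time series into horizon-plot deviations."""
    x = np.asarray(values, dtype=float)
    if len(x) < 1:
        raise ValueError("need at least one timepoint")
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if mode == "vs_mean":
        dev = x - x.mean()
    elif mode == "vs_previous":
        dev = np.concatenate([[0.0], np.diff(x)])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    peak = float(np.abs(dev).max())
    boundaries = (
        np.linspace(peak / n_bands, peak, n_bands) if peak > 0 else np.zeros(n_bands)
    )
    if peak > 0:
        band = np.sign(dev) * np.ceil(np.abs(dev) / (peak / n_bands))
    else:
        band = np.zeros_like(dev)
    return HorizonSeries(
        deviations=dev,
        mode=mode,
        band_boundaries=boundaries,
        band_index=band.astype(int),
    )
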