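"""Structural-variant evidence suite built on windowed local PCA.

A chromosomal inversion suppresses recombination in heterokaryotypes, so
windows inside it share a relatedness structure distinct from the rest of
the chromosome.  The suite mirrors the standard local-PCA workflow:

1. per-window PCA summaries (top-2 eigenpairs of the sample covariance),
2. pairwise distances between window summaries,
3. classical (Torgerson) MDS of the distance matrix,
4. silhouette-selected k-means on the MDS plane,
5. z-score outlier windows on MDS1 and consecutive-run region calling,
6. PCA + 3-cluster genotyping of called regions with heterozygosity
   contrasts, and
7. LD heatmaps in all samples vs putative inversion homozygotes (elevated
   LD across the region is expected only in the former).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from hybridscan.aim import AimMatrix, individual_heterozygosity

logger = logging.getLogger(__name__)


@dataclass
class WindowSummary:
    """Top-2 eigenpairs of one genomic window's sample covariance."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    ordinal: int  # start // window_bp, used for genomic adjacency
    eigenvalues: np.ndarray  # (2,), descending
    eigenvectors: np.ndarray  # (n_individuals, 2), unit columns
    n_loci: int


def _impute_center(states: np.ndarray) -> np.ndarray:
    """Mean-impute missing states per locus, then mean-center per locus."""
    x = states.astype(float).copy()
    mu = np.nanmean(x, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(x))
    x[nan_rows, nan_cols] = mu[nan_cols]
    return x - x.mean(axis=0)


def window_summaries(
    matrix: AimMatrix,
    chrom: str,
    window_bp: int = 100_000,
    min_loci: int = 5,
) -> list[WindowSummary]:
    """Local PCA summaries in non-overlapping windows along one chromosome.

    Missing states are mean-imputed per locus (for PCA only); the window
    covariance is ``C = X X^T / L_w`` over the window's ``L_w`` centred
    loci.  Windows with fewer than ``min_loci`` usable loci, or with zero
    covariance, are skipped with a log message.
    """
    if matrix.n_individuals < 2:
        raise ValueError("need at least two individuals for local PCA")
    on_chrom = matrix.loci["chrom"].to_numpy() == chrom
    positions = matrix.loci["pos"].to_numpy()[on_chrom]
    states = matrix.states[:, on_chrom]
    summaries = []
    for ordinal in range(0, (int(positions.max()) - 1) // window_bp + 1 if positions.size else 0):
        lo = ordinal * window_bp + 1
        hi = lo + window_bp - 1
        cols = np.flatnonzero((positions >= lo) & (positions <= hi))
        usable = cols[~np.isnan(states[:, cols]).all(axis=0)]
        if usable.size < min_loci:
            logger.debug("window %s:%d-%d skipped: %d loci", chrom, lo, hi, usable.size)
            continue
        x = _impute_center(states[:, usable])
        cov = (x @ x.T) / usable.size
        if not np.any(cov):
            logger.debug("window %s:%d-%d skipped: zero variance", chrom, lo, hi)
            continue
        n = cov.shape[0]
        lam, vec = eigh(cov, subset_by_index=(n - 2, n - 1))
        order = np.argsort(lam)[::-1]
        lam = np.maximum(lam[order], 0.0)
        vec = vec[:, order]
        summaries.append(
            WindowSummary(
                chrom=chrom,
                start=lo,
                end=hi,
                ordinal=ordinal,
                eigenvalues=lam,
                eigenvectors=vec,
                n_loci=int(usable.size),
            )
        )
    return summaries


def window_distance(a: WindowSummary, b: WindowSummary) -> float:
    """Frobenius distance between rank-2 covariance reconstructions.

    With ``P_w = sum_k lam_k v_k v_k^T`` the distance is ``||P_a - P_b||_F``,
    evaluated through the inner-product identity
    ``d^2 = sum lam_a^2 + sum lam_b^2 - 2 sum_{k,l} lam_ak lam_bl (v_ak . v_bl)^2``.
    """
    if a.eigenvectors.shape[0] != b.eigenvectors.shape[0]:
        raise ValueError("window summaries cover different individual sets")
    la, lb = a.eigenvalues, b.eigenvalues
    cross = (a.eigenvectors.T @ b.eigenvectors) ** 2
    scale = float(la @ la + lb @ lb)
    d2 = scale - 2.0 * float(la @ cross @ lb)
    if d2 < 1e-12 * max(scale, 1.0):  # numerical cancellation, e.g. d(A, A)
        return 0.0
    return float(np.sqrt(d2))


def window_distance_matrix(summaries: list[WindowSummary]) -> np.ndarray:
    n = len(summaries)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = window_distance(summaries[i], summaries[j])
    return d


def classical_mds(distances: np.ndarray, n_axes: int = 2) -> np.ndarray:
    """Torgerson multidimensional scaling (R's ``cmdscale``).

    Double-centres the squared distance matrix, takes the top eigenpairs,
    clamps negative eigenvalues to zero, and fixes each axis's sign so its
    first non-zero loading is positive.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    lam, vec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(lam)[::-1][:n_axes]
    lam = np.maximum(lam[order], 0.0)
    coords = vec[:, order] * np.sqrt(lam)
    for k in range(coords.shape[1]):
        nz = np.flatnonzero(np.abs(coords[:, k]) > 1e-12)
        if nz.size and coords[nz[0], k] < 0:
            coords[:, k] = -coords[:, k]
    return coords


def choose_k_silhouette(
    coords: np.ndarray,
    k_range: range = range(2, 9),
    seed: int = 0,
    n_init: int = 25,
) -> tuple[int, np.ndarray]:
    """Pick the k-means k maximising the mean silhouette on the MDS plane.

    Ties go to the smaller k.  Raises when the points cannot support the
    requested range (too few, or all duplicates).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[1] == 1 or coords.ndim == 1:
        coords = coords.reshape(len(coords), -1)
    n = coords.shape[0]
    if n < max(k_range) + 1:
        raise ValueError(f"need at least {max(k_range) + 1} points for k_range {k_range}")
    if np.all(coords == coords[0]):
        raise ValueError("silhouette undefined: all points identical")
    best = None
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(coords)
        if len(np.unique(km.labels_)) < 2:
            continue
        score = silhouette_score(coords, km.labels_)
        if best is None or score > best[0] + 1e-12:
            best = (score, k, km.labels_)
    if best is None:
        raise ValueError("no k in range produced two or more distinct clusters")
    return best[1], best[2]


@dataclass
class OutlierRegion:
    """Run of >= ``min_run`` consecutive windows with |MDS1 z| above threshold."""

    chrom: str
    start: int
    end: int
    window_ordinals: list[int]
    mean_z: float
    cluster_label: int | None = None


def outlier_regions(
    mds1: np.ndarray,
    windows: list[WindowSummary],
    z_threshold: float = 1.0,
    min_run: int = 10,
    signed: bool = False,
) -> list[OutlierRegion]:
    """Call outlier regions from per-window MDS1 scores.

    z-scores use the mean and standard deviation of all windows.  A window
    is an outlier when ``|z| > z_threshold`` (or ``z > z_threshold`` with
    ``signed=True``; the absolute default reflects the arbitrary sign of an
    MDS axis).  Maximal runs of at least ``min_run`` genomically adjacent
    outlier windows (skipped windows break runs) become regions.
    """
    scores = np.asarray(mds1, dtype=float)
    if scores.size != len(windows):
        raise ValueError("one MDS1 score per window required")
    if scores.size < 2:
        raise ValueError("need at least two windows")
    sd = scores.std()
    if sd == 0:
        logger.warning("outlier_regions: zero variance in MDS1 scores; no regions")
        return []
    z = (scores - scores.mean()) / sd
    is_out = (z > z_threshold) if signed else (np.abs(z) > z_threshold)

    regions: list[OutlierRegion] = []
    run: list[int] = []

    def flush(run_idx: list[int]) -> None:
        if len(run_idx) >= min_run:
            ws = [windows[i] for i in run_idx]
            regions.append(
                OutlierRegion(
                    chrom=ws[0].chrom,
                    start=ws[0].start,
                    end=ws[-1].end,
                    window_ordinals=[w.ordinal for w in ws],
                    mean_z=float(z[run_idx].mean()),
                )
            )

    for i, w in enumerate(windows):
        if is_out[i] and run and (
            windows[run[-1]].chrom == w.chrom
            and w.ordinal == windows[run[-1]].ordinal + 1
        ):
            run.append(i)
        elif is_out[i]:
            flush(run)
            run = [i]
        else:
            flush(run)
            run = []
    flush(run)
    return regions


@dataclass
class RegionGenotype:
    """PCA-based 3-cluster karyotype call for one candidate SV region."""

    pcs: np.ndarray  # (n_individuals, 2)
    labels: np.ndarray  # cluster 0/1/2 ordered by mean PC1
    summary: pd.DataFrame  # per-cluster sizes and heterozygosity means
    collapsed: bool  # True when k-means found < 3 distinguishable clusters


def region_pca_genotype(
    matrix: AimMatrix,
    chrom: str,
    start: int,
    end: int,
    seed: int = 0,
    n_init: int = 25,
) -> RegionGenotype:
    """Genotype individuals for a putative inversion by PCA + 3-means.

    PCA is run on the region's mean-imputed, centred genotypes; k-means
    with k=3 on PC1 assigns clusters, relabelled in order of increasing
    mean PC1 so the ends are putative homokaryotypes and the middle the
    putative heterokaryotypes.  The summary reports, per cluster, the mean
    genome-wide heterozygosity and the mean heterozygosity restricted to
    the region (elevated in the central cluster for a real inversion).
    """
    idx = matrix.loci_in(chrom, start, end)
    region_states = matrix.states[:, idx]
    poly = [
        j
        for j in range(region_states.shape[1])
        if np.unique(region_states[~np.isnan(region_states[:, j]), j]).size > 1
    ]
    if len(poly) < 2:
        raise ValueError("region must contain at least two polymorphic loci")
    if matrix.n_individuals < 6:
        raise ValueError("need at least six individuals to genotype a region")
    x = _impute_center(region_states[:, poly])
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    pcs = u[:, :2] * s[:2]
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # cluster collapse is detected and flagged below
        warnings.simplefilter("ignore", ConvergenceWarning)
        km = KMeans(n_clusters=3, n_init=n_init, random_state=seed).fit(pcs[:, :1])
    raw = km.labels_
    occupied = np.unique(raw)
    collapsed = occupied.size < 3 or np.unique(km.cluster_centers_.round(10)).size < 3
    if collapsed:
        logger.warning("region_pca_genotype: k-means found <3 distinguishable clusters")
    # PC sign is arbitrary; anchor the cluster order (0 -> 2) by the mean
    # ancestry dosage in the region so 0 = coastal-like homokaryotypes
    with np.errstate(invalid="ignore"):
        dosage = np.nanmean(region_states, axis=1)
    order = np.argsort([np.nanmean(dosage[raw == c]) for c in occupied])
    relabel = {int(occupied[o]): rank for rank, o in enumerate(order)}
    labels = np.array([relabel[int(c)] for c in raw])

    genome_h = individual_heterozygosity(matrix)
    region_is_het = (region_states == 1).astype(float)
    region_is_het[np.isnan(region_states)] = np.nan
    with np.errstate(invalid="ignore"):
        region_h = np.nanmean(region_is_het, axis=1)
    rows = []
    for c in sorted(set(labels)):
        m = labels == c
        rows.append(
            {
                "cluster": c,
                "n": int(m.sum()),
                "mean_pc1": float(pcs[m, 0].mean()),
                "genome_heterozygosity": float(np.nanmean(genome_h[m])),
                "region_heterozygosity": float(np.nanmean(region_h[m])),
            }
        )
    return RegionGenotype(
        pcs=pcs, labels=labels, summary=pd.DataFrame(rows), collapsed=collapsed
    )


def ld_heatmap(
    matrix: AimMatrix,
    individuals: np.ndarray | None = None,
    maf_min: float = 0.05,
    thin_bp: int | None = None,
    max_missing: float = 0.5,
) -> pd.DataFrame:
    """Pairwise dosage r^2 over filtered, optionally thinned loci.

    ``individuals`` restricts the sample set (e.g. the major-homokaryotype
    cluster from :func:`region_pca_genotype`); loci are filtered on
    minor-state frequency (>= ``maf_min``) and missingness within that
    subset, then thinned to the first locus per ``thin_bp`` bin.  Returns a
    long table (chrom_i, pos_i, chrom_j, pos_j, r2) over all retained pairs.
    """
    if individuals is not None:
        individuals = np.asarray(individuals)
        if individuals.dtype == bool:
            individuals = np.flatnonzero(individuals)
        if individuals.size == 0:
            raise ValueError("empty individual subset")
        matrix = matrix.subset_individuals(individuals)
    from hybridscan.aim import _pairwise_r2, minor_state_frequency

    maf = minor_state_frequency(matrix)
    missing_frac = np.isnan(matrix.states).mean(axis=0)
    keep = ~np.isnan(maf) & (maf >= maf_min) & (missing_frac <= max_missing)
    idx = np.flatnonzero(keep)
    if thin_bp is not None:
        chosen = []
        seen: set[tuple[str, int]] = set()
        for i in idx:
            key = (matrix.loci["chrom"].iloc[i], int(matrix.loci["pos"].iloc[i] - 1) // thin_bp)
            if key not in seen:
                seen.add(key)
                chosen.append(i)
        idx = np.array(chosen, dtype=int)
    sub = matrix.subset_loci(idx)
    r2 = _pairwise_r2(sub.states)
    rows = []
    for i in range(sub.n_loci):
        for j in range(i + 1, sub.n_loci):
            rows.append(
                {
                    "chrom_i": sub.loci["chrom"].iloc[i],
                    "pos_i": int(sub.loci["pos"].iloc[i]),
                    "chrom_j": sub.loci["chrom"].iloc[j],
                    "pos_j": int(sub.loci["pos"].iloc[j]),
                    "r2": r2[i, j],
                }
            )
    return pd.DataFrame(rows, columns=["chrom_i", "pos_i", "chrom_j", "pos_j", "r2"])
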