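"""Gene-overlap enrichment and the recombination-rate contrast.

Outlier AIMs from the viability scan are expanded into linkage blocks (all
same-chromosome loci with r^2 above a threshold against the focal locus),
genes are assigned to blocks by interval overlap, and the overlap between
viability-associated genes and an external candidate list is tested against
the random-draw expectation e = (a/b)*c with a 1-df chi-square
goodness-of-fit (an exact binomial tail is reported as a cross-check).
Recombination rates in outlier vs non-outlier windows are contrasted with a
two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from hybridscan.aim import AimMatrix, dosage_r2

logger = logging.getLogger(__name__)


@dataclass
class LdBlock:
    """Linkage block around one focal locus.

    The interval spans the positions of all same-chromosome loci whose
    dosage r^2 with the focal locus strictly exceeds the threshold (the
    focal locus itself included).  Coordinates are 1-based closed.
    """

    focal_index: int
    chrom: str
    start: int
    end: int
    member_indices: list[int]
    monomorphic: bool = False
    genes: set[str] = field(default_factory=set)


def ld_blocks(
    matrix: AimMatrix, focal_loci: np.ndarray, r2_threshold: float = 0.5
) -> list[LdBlock]:
    """Build linkage blocks around each focal locus (strict r^2 > threshold)."""
    chroms = matrix.loci["chrom"].to_numpy()
    positions = matrix.loci["pos"].to_numpy()
    blocks = []
    for f in np.asarray(focal_loci, dtype=int):
        col = matrix.states[:, f]
        obs = col[~np.isnan(col)]
        mono = obs.size == 0 or obs.min() == obs.max()
        members = [int(f)]
        if not mono:
            for j in np.flatnonzero(chroms == chroms[f]):
                if j == f:
                    continue
                r2 = dosage_r2(matrix, int(f), int(j))
                if not np.isnan(r2) and r2 > r2_threshold:
                    members.append(int(j))
        pos = positions[members]
        blocks.append(
            LdBlock(
                focal_index=int(f),
                chrom=str(chroms[f]),
                start=int(pos.min()),
                end=int(pos.max()),
                member_indices=sorted(members),
                monomorphic=mono,
            )
        )
    return blocks


def genes_in_blocks(
    blocks: list[LdBlock], annotation: pd.DataFrame
) -> tuple[list[set[str]], set[str]]:
    """Assign genes to blocks by >= 1 bp overlap on the same chromosome.

    ``annotation`` needs columns ``chrom``, ``start``, ``end`` (1-based
    closed, GFF convention) and ``gene``.  Returns per-block gene sets and
    their union.  Chromosome names present in blocks but absent from the
    annotation are reported in a warning.
    """
    bad = annotation["start"] > annotation["end"]
    if bad.any():
        raise ValueError("annotation intervals must satisfy start <= end")
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in annotation.groupby("chrom"):
        # half-open tree coordinates; +1 makes the 1-based closed end inclusive
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e) + 1, g)
            for s, e, g in zip(sub["start"], sub["end"], sub["gene"])
        )
    unmatched = {b.chrom for b in blocks} - set(trees)
    if unmatched:
        logger.warning(
            "genes_in_blocks: %d block chromosome(s) absent from annotation: %s",
            len(unmatched),
            sorted(unmatched),
        )
    per_block: list[set[str]] = []
    for b in blocks:
        tree = trees.get(b.chrom)
        hits = {iv.data for iv in tree.overlap(b.start, b.end + 1)} if tree else set()
        b.genes = hits
        per_block.append(hits)
    union = set().union(*per_block) if per_block else set()
    return per_block, union


@dataclass
class OverlapTest:
    """Random-draw overlap expectation and chi-square test."""

    n_viability_genes: int
    n_block_genes_total: int
    n_candidates: int
    observed_overlap: int
    expected_overlap: float
    expected_overlap_rounded: int
    chi2: float
    p_value: float
    p_binomial: float


def overlap_expectation(a: int, b: int, c: int) -> tuple[float, int]:
    """Expected overlap e = (a/b) * c under random draws.

    ``a`` viability-associated genes out of ``b`` total linkage-block genes,
    ``c`` candidate genes drawn.  Returns the real value and its nearest
    integer (the conventionally reported figure).
    """
    if b <= 0:
        raise ValueError("total block gene count b must be positive")
    if not (0 <= a <= b) or c < 0:
        raise ValueError("require 0 <= a <= b and c >= 0")
    e = (a / b) * c
    return e, int(round(e))


def overlap_chisq(observed: int, a: int, b: int, c: int) -> OverlapTest:
    """1-df chi-square goodness-of-fit for candidate/viability gene overlap.

    The ``c`` candidates are split into overlap vs non-overlap with expected
    proportions ``(a/b, 1 - a/b)``; the statistic is
    ``(o-e)^2/e + ((c-o)-(c-e))^2/(c-e)``.  An exact binomial two-sided
    p-value on the same split is included as a cross-check.
    """
    e, e_round = overlap_expectation(a, b, c)
    if not (0 <= observed <= c):
        raise ValueError("observed overlap must lie in [0, c]")
    if e == 0 or c - e == 0:
        raise ValueError("degenerate expectation (e = 0 or c - e = 0)")
    chi2 = (observed - e) ** 2 / e + ((c - observed) - (c - e)) ** 2 / (c - e)
    p = float(stats.chi2.sf(chi2, df=1))
    p_binom = float(stats.binomtest(observed, c, a / b).pvalue)
    return OverlapTest(
        n_viability_genes=a,
        n_block_genes_total=b,
        n_candidates=c,
        observed_overlap=observed,
        expected_overlap=e,
        expected_overlap_rounded=e_round,
        chi2=float(chi2),
        p_value=p,
        p_binomial=p_binom,
    )


def read_gene_annotation(path) -> pd.DataFrame:
    """Read gene intervals from BED or GFF3 into 1-based closed coordinates.

    BED (0-based half-open) is converted on read; GFF3 keeps only ``gene``
    features and takes the gene name from the ``Name=`` or ``ID=``
    attribute.  Returns columns ``chrom``, ``start``, ``end``, ``gene``.
    """
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                name = attrs.get("Name", attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"))
                rows.append(
                    {"chrom": f[0], "start": int(f[3]), "end": int(f[4]), "gene": name}
                )
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene"],
    )
    df["start"] = df["start"] + 1  # BED 0-based half-open -> 1-based closed
    return df


def _rank_sum_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration (midranks for ties)."""
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0
    count = 0
    total = 0
    for comb in itertools.combinations(range(n + m), n):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


def recomb_contrast(
    rates: np.ndarray, outlier_flags: np.ndarray, exact_max: int = 10
) -> tuple[float, float]:
    """Wilcoxon rank-sum contrast of outlier vs non-outlier window rates.

    Two-sided; midrank ties.  Exact enumeration when both groups have at
    most ``exact_max`` members, otherwise the normal approximation with tie
    correction (no continuity correction).  Returns ``(W, p)`` where W is
    the rank-sum-based Mann-Whitney U of the outlier group.
    """
    rates = np.asarray(rates, dtype=float)
    flags = np.asarray(outlier_flags, dtype=bool)
    x = rates[flags]
    y = rates[~flags]
    if x.size == 0 or y.size == 0:
        raise ValueError("both outlier and non-outlier groups must be non-empty")
    u = float(stats.mannwhitneyu(x, y, alternative="two-sided").statistic)
    if x.size <= exact_max and y.size <= exact_max:
        p = _rank_sum_exact(x, y)
    else:
        p = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            ).pvalue
        )
    return u, p
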