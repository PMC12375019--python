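"""Ancestry-informative-marker (AIM) data model and core summaries.

Ancestry states are coded per locus and individual as

* ``0`` — homozygous coastal ancestry,
* ``1`` — interspecific heterozygote (one coastal and one inland allele),
* ``2`` — homozygous inland ancestry,

with ``NaN`` for missing calls.  Genome-wide ancestry ``q`` is the mean
state across non-missing loci divided by two, so a pure coastal bird has
``q = 0``, an F1 hybrid ``q = 0.5`` and a pure inland bird ``q = 1``.
Individual heterozygosity ``h`` is the proportion of non-missing loci in
state 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan

_LOCI_COLUMNS = ("chrom", "pos", "is_z")


def _as_loci_frame(loci: pd.DataFrame, z_chrom: str | None = None) -> pd.DataFrame:
    loci = loci.copy().reset_index(drop=True)
    if "is_z" not in loci.columns:
        if z_chrom is None:
            loci["is_z"] = False
        else:
            loci["is_z"] = loci["chrom"].astype(str) == z_chrom
    missing = [c for c in ("chrom", "pos") if c not in loci.columns]
    if missing:
        raise ValueError(f"locus table lacks required columns: {missing}")
    loci["pos"] = loci["pos"].astype(np.int64)
    if (loci["pos"] < 1).any():
        raise ValueError("locus positions must be 1-based (>= 1)")
    return loci[list(_LOCI_COLUMNS)]


@dataclass
class AimMatrix:
    """Individuals x loci ancestry-state matrix with locus metadata.

    Parameters
    ----------
    states
        Float array of shape ``(n_individuals, n_loci)`` with values in
        ``{0, 1, 2}`` or ``NaN`` for missing.
    loci
        Locus table with columns ``chrom``, ``pos`` (1-based) and ``is_z``;
        sorted by (chrom, pos) with unique positions per chromosome.
    individual_ids
        Unique individual identifiers, one per matrix row.
    """

    states: np.ndarray
    loci: pd.DataFrame
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2:
            raise ValueError("states must be a 2-D (individuals x loci) array")
        self.loci = _as_loci_frame(self.loci)
        self.individual_ids = [str(i) for i in self.individual_ids]
        n_ind, n_loci = self.states.shape
        if len(self.individual_ids) != n_ind:
            raise ValueError("individual_ids length does not match states rows")
        if len(self.loci) != n_loci:
            raise ValueError("locus table length does not match states columns")
        if len(set(self.individual_ids)) != n_ind:
            raise ValueError("individual_ids must be unique")
        obs = self.states[~np.isnan(self.states)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("ancestry states must be 0, 1, 2 or missing")
        order = self.loci.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
        if not np.array_equal(order, np.arange(n_loci)):
            self.states = self.states[:, order]
            self.loci = self.loci.iloc[order].reset_index(drop=True)
        dup = self.loci.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate (chrom, pos) in locus table")

    @property
    def n_individuals(self) -> int:
        return self.states.shape[0]

    @property
    def n_loci(self) -> int:
        return self.states.shape[1]

    def subset_loci(self, index: np.ndarray) -> "AimMatrix":
        """Return a new matrix restricted to the given locus indices."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return AimMatrix(
            self.states[:, index], self.loci.iloc[index], list(self.individual_ids)
        )

    def subset_individuals(self, index: np.ndarray) -> "AimMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        ids = [self.individual_ids[i] for i in index]
        return AimMatrix(self.states[index, :], self.loci, ids)

    def loci_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of loci with ``pos`` in the closed interval [start, end]."""
        m = (
            (self.loci["chrom"].to_numpy() == chrom)
            & (self.loci["pos"].to_numpy() >= start)
            & (self.loci["pos"].to_numpy() <= end)
        )
        return np.flatnonzero(m)

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path) -> None:
        """Write the matrix as TSV: chrom, pos, then one column per individual."""
        df = self.loci[["chrom", "pos"]].copy()
        for j, ind in enumerate(self.individual_ids):
            col = self.states[j, :]
            df[ind] = pd.array(col, dtype="Int64") if not np.isnan(col).any() else col
        with open(path, "w") as fh:
            fh.write("# ancestry states: 0=coastal hom, 1=het, 2=inland hom, NA=missing\n")
            df.to_csv(fh, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path, z_chrom: str = "chrZ") -> "AimMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
        loci = df[["chrom", "pos"]]
        ids = [c for c in df.columns if c not in ("chrom", "pos")]
        states = df[ids].to_numpy(dtype=float).T
        return cls(states, _as_loci_frame(loci, z_chrom=z_chrom), ids)


@dataclass
class SampleMeta:
    """Per-individual metadata table.

    Wraps a DataFrame indexed by individual id with columns ``age``
    (ordinal 0=HY, 1=SY, 2=ASY), ``sex`` ('F', 'M' or 'unknown'),
    ``ancestry_q`` and ``heterozygosity_h`` (both fractions in [0, 1]).
    """

    table: pd.DataFrame

    AGE_LABELS = {"HY": 0, "SY": 1, "ASY": 2}

    def __post_init__(self) -> None:
        t = self.table
        required = {"age", "sex"}
        if not required.issubset(t.columns):
            raise ValueError(f"sample table lacks columns {required - set(t.columns)}")
        if not t["age"].isin([0, 1, 2]).all():
            raise ValueError("age must be ordinal 0 (HY), 1 (SY) or 2 (ASY)")
        if not t["sex"].isin(["F", "M", "unknown"]).all():
            raise ValueError("sex must be 'F', 'M' or 'unknown'")
        for col in ("ancestry_q", "heterozygosity_h"):
            if col in t.columns:
                v = t[col].dropna()
                if ((v < 0) | (v > 1)).any():
                    raise ValueError(f"{col} must lie in [0, 1]")

    @classmethod
    def from_tsv(cls, path) -> "SampleMeta":
        t = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=["NA"])
        if t["age"].dtype == object:
            t["age"] = t["age"].map(cls.AGE_LABELS)
        return cls(t)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="individual_id", na_rep="NA")

    def with_summaries(self, matrix: AimMatrix) -> "SampleMeta":
        """Return a copy with ancestry_q and heterozygosity_h recomputed."""
        t = self.table.copy()
        t = t.loc[matrix.individual_ids]
        t["ancestry_q"] = genome_wide_ancestry(matrix)
        t["heterozygosity_h"] = individual_heterozygosity(matrix)
        return SampleMeta(t)


@dataclass
class PanelCounts:
    """Parental reference-panel allele counts per candidate locus.

    ``table`` holds one row per locus with columns ``chrom``, ``pos``,
    ``coastal_ref``, ``coastal_alt``, ``inland_ref``, ``inland_alt``.
    """

    table: pd.DataFrame

    COUNT_COLS = ("coastal_ref", "coastal_alt", "inland_ref", "inland_alt")

    def __post_init__(self) -> None:
        missing = [c for c in ("chrom", "pos", *self.COUNT_COLS) if c not in self.table.columns]
        if missing:
            raise ValueError(f"panel table lacks columns: {missing}")
        counts = self.table[list(self.COUNT_COLS)]
        if (counts.to_numpy() < 0).any():
            raise ValueError("allele counts must be non-negative")

    @classmethod
    def from_tsv(cls, path) -> "PanelCounts":
        return cls(pd.read_csv(path, sep="\t", comment="#"))


# ---------------------------------------------------------------- operations

def harden_posteriors(
    posteriors: np.ndarray,
    loci: pd.DataFrame,
    individual_ids: list[str],
    threshold: float = 0.9,
) -> AimMatrix:
    """Convert per-site ancestry posteriors to hard genotype calls.

    Parameters
    ----------
    posteriors
        Array of shape ``(n_individuals, n_loci, 3)`` holding the posterior
        probability of states 0, 1 and 2.  Each triple must sum to 1 within
        1e-6 and contain no negative entries.
    threshold
        A state is called only when its posterior strictly exceeds this
        value; otherwise the call is missing.

    Returns
    -------
    AimMatrix with hard calls, missing where no state passes the threshold.
    """
    post = np.asarray(posteriors, dtype=float)
    if post.ndim != 3 or post.shape[2] != 3:
        raise ValueError("posteriors must have shape (n_individuals, n_loci, 3)")
    bad = (post < 0).any(axis=2) | (np.abs(post.sum(axis=2) - 1.0) > 1e-6)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"malformed posterior triple for individual {individual_ids[i]!r} "
            f"at locus index {j} (negative entry or sum far from 1)"
        )
    best = post.argmax(axis=2).astype(float)
    best_p = post.max(axis=2)
    best[best_p <= threshold] = MISSING
    return AimMatrix(best, loci, individual_ids)


def select_aims(panel: PanelCounts, min_diff: float = 0.5) -> np.ndarray:
    """Select ancestry-informative markers from parental panel counts.

    A locus is retained iff the absolute difference of alternate-allele
    frequencies between the coastal and inland panels strictly exceeds
    ``min_diff``.  Loci with zero observed alleles in either panel are
    dropped with a warning.

    Returns a boolean retention mask over the panel's locus rows.
    """
    t = panel.table
    c_tot = (t["coastal_ref"] + t["coastal_alt"]).to_numpy(dtype=float)
    i_tot = (t["inland_ref"] + t["inland_alt"]).to_numpy(dtype=float)
    valid = (c_tot > 0) & (i_tot > 0)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("select_aims: dropping %d loci with empty panel counts", n_bad)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = t["coastal_alt"].to_numpy(dtype=float) / c_tot
        fi = t["inland_alt"].to_numpy(dtype=float) / i_tot
    keep = valid & (np.abs(fc - fi) > min_diff)
    return keep


def genome_wide_ancestry(matrix: AimMatrix, individual: str | None = None):
    """Genome-wide inland ancestry q = mean state over non-missing loci / 2.

    With ``individual=None`` returns the full per-individual vector (NaN for
    individuals missing at every locus, with a warning); otherwise the scalar
    for one individual.
    """
    q = _row_nanmean(matrix.states) / 2.0
    if individual is None:
        return q
    return float(q[matrix.individual_ids.index(individual)])


def _row_nanmean(states: np.ndarray) -> np.ndarray:
    all_missing = np.isnan(states).all(axis=1)
    if all_missing.any():
        logger.warning(
            "%d individual(s) missing at every locus; summary set to NaN",
            int(all_missing.sum()),
        )
    out = np.full(states.shape[0], np.nan)
    ok = ~all_missing
    if ok.any():
        out[ok] = np.nanmean(states[ok], axis=1)
    return out


def individual_heterozygosity(matrix: AimMatrix, individual: str | None = None):
    """Proportion of non-missing loci in state 1, per individual."""
    is_het = (matrix.states == 1).astype(float)
    is_het[np.isnan(matrix.states)] = np.nan
    h = _row_nanmean(is_het)
    if individual is None:
        return h
    return float(h[matrix.individual_ids.index(individual)])


def interspecific_het_vector(matrix: AimMatrix, locus: int) -> np.ndarray:
    """Binary per-individual heterozygosity at one locus (NaN propagated)."""
    col = matrix.states[:, locus]
    out = (col == 1).astype(float)
    out[np.isnan(col)] = np.nan
    return out


def dosage_r2(matrix: AimMatrix, locus_a: int, locus_b: int) -> float:
    """Squared Pearson correlation of ancestry states at two loci.

    Computed over pairwise-complete individuals; returns NaN (with a debug
    log) when fewer than two complete pairs remain or either locus is
    monomorphic in the complete subset.
    """
    a = matrix.states[:, locus_a]
    b = matrix.states[:, locus_b]
    ok = ~np.isnan(a) & ~np.isnan(b)
    return _r2(a[ok], b[ok])


def _r2(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2:
        return float("nan")
    va = a - a.mean()
    vb = b - b.mean()
    den = (va @ va) * (vb @ vb)
    if den == 0:
        return float("nan")
    r = (va @ vb) / np.sqrt(den)
    return float(r * r)


def _pairwise_r2(states: np.ndarray) -> np.ndarray:
    """Pairwise dosage r^2 over columns with pairwise-complete individuals."""
    n_loci = states.shape[1]
    out = np.full((n_loci, n_loci), np.nan)
    complete = ~np.isnan(states).any(axis=1)
    if complete.all():
        x = states - states.mean(axis=0)
        sd = x.std(axis=0)
        poly = sd > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (x.T @ x) / (states.shape[0] * np.outer(sd, sd))
        r2 = corr**2
        r2[~poly, :] = np.nan
        r2[:, ~poly] = np.nan
        return r2
    for i in range(n_loci):
        out[i, i] = 0.0 if np.isnan(states[:, i]).all() else 1.0
        for j in range(i + 1, n_loci):
            ok = ~np.isnan(states[:, i]) & ~np.isnan(states[:, j])
            out[i, j] = out[j, i] = _r2(states[ok, i], states[ok, j])
    return out


def minor_state_frequency(matrix: AimMatrix) -> np.ndarray:
    """Per-locus minor allele frequency on the ancestry-dosage scale."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(matrix.states, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def ld_prune(
    matrix: AimMatrix,
    window_snps: int = 200,
    step_snps: int = 20,
    r2_max: float = 0.2,
    maf_min: float = 0.05,
) -> np.ndarray:
    """Sliding-window LD pruning of loci (plink ``--indep-pairwise`` style).

    Loci with minor-state frequency below ``maf_min`` are removed first.
    Windows of ``window_snps`` loci advance by ``step_snps`` along each
    chromosome; within a window, while any retained pair has dosage r^2
    greater than ``r2_max``, the member with the lower minor-state frequency
    (ties: the later locus by position) is removed.

    Returns a boolean retention mask over the matrix loci.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    if step_snps < 1:
        raise ValueError("step_snps must be >= 1")
    if not (0.0 < r2_max < 1.0):
        raise ValueError("r2_max must be in (0, 1)")

    maf = minor_state_frequency(matrix)
    keep = ~np.isnan(maf) & (maf >= maf_min)

    for chrom in matrix.loci["chrom"].unique():
        idx = np.flatnonzero(matrix.loci["chrom"].to_numpy() == chrom)
        for start in range(0, len(idx), step_snps):
            win = idx[start : start + window_snps]
            live = [i for i in win if keep[i]]
            changed = True
            while changed and len(live) > 1:
                changed = False
                for ai in range(len(live)):
                    for bi in range(ai + 1, len(live)):
                        a, b = live[ai], live[bi]
                        r2 = dosage_r2(matrix, a, b)
                        if np.isnan(r2) or r2 <= r2_max:
                            continue
                        # lower-MAF member goes; equal MAF -> later position
                        drop = a if maf[a] < maf[b] else b
                        if maf[a] == maf[b]:
                            drop = max(a, b)
                        keep[drop] = False
                        live.remove(drop)
                        changed = True
                        break
                    if changed:
                        break
            if len(win) < window_snps:
                break
    return keep
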