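"""Hi-C contact-matrix processing and between-genome comparison.

The pipeline compares chromatin contact maps from two parental genomes to
find interactions present in only one of them (e.g. the long-range contacts
an inversion breakpoint creates).  Order of operations: coverage-based bin
masking -> ICE balancing -> normalisation to common coverage -> bin
merging -> entrywise log2 ratio.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ContactMatrix:
    """Symmetric binned Hi-C contact matrix.

    ``counts`` is a dense symmetric ``(n_bins, n_bins)`` array of
    non-negative values; ``mask`` flags bins excluded from all downstream
    totals and comparisons.
    """

    counts: np.ndarray
    bin_bp: int
    chrom: str = "chr"
    mask: np.ndarray = field(default=None)  # True = masked bin

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (self.counts < 0).any():
            raise ValueError("contact counts must be non-negative")
        if not np.allclose(self.counts, self.counts.T, rtol=1e-8, atol=1e-8):
            raise ValueError("contact matrix must be symmetric")
        if self.mask is None:
            self.mask = np.zeros(self.n_bins, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.n_bins,):
            raise ValueError("mask length must equal n_bins")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> float:
        """Total contact count over unmasked bin pairs."""
        ok = ~self.mask
        return float(self.counts[np.ix_(ok, ok)].sum())

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path) -> None:
        """Write upper-triangle COO TSV with a JSON header line."""
        header = {"bin_bp": self.bin_bp, "n_bins": self.n_bins, "chrom": self.chrom,
                  "masked_bins": np.flatnonzero(self.mask).tolist()}
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            fh.write("bin_i\tbin_j\tcount\n")
            iu = np.triu_indices(self.n_bins)
            for i, j in zip(*iu):
                v = self.counts[i, j]
                if v != 0:
                    fh.write(f"{i}\t{j}\t{v:.10g}\n")

    @classmethod
    def from_tsv(cls, path) -> "ContactMatrix":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise ValueError("missing JSON header line")
            header = json.loads(first[1:])
            n = int(header["n_bins"])
            counts = np.zeros((n, n))
            fh.readline()  # column header
            for line in fh:
                i_s, j_s, v_s = line.split("\t")
                i, j, v = int(i_s), int(j_s), float(v_s)
                counts[i, j] = v
                counts[j, i] = v
        mask = np.zeros(n, dtype=bool)
        mask[header.get("masked_bins", [])] = True
        return cls(counts, int(header["bin_bp"]), header.get("chrom", "chr"), mask)


def mask_bins_by_coverage(
    m: ContactMatrix, z_low: float = -1.5, z_high: float = 5.0
) -> ContactMatrix:
    """Mask bins whose log coverage is extreme.

    Per-bin coverage (full row sum) is transformed as ``log(1 + coverage)``
    and z-scored over all bins in a single pass; bins with z below
    ``z_low`` or above ``z_high`` are masked, unioned with any existing
    mask.  Because the statistics ignore the incoming mask, applying the
    operation twice equals applying it once.
    """
    if m.n_bins < 2:
        raise ValueError("need at least two bins")
    logcov = np.log1p(m.counts.sum(axis=1))
    sd = logcov.std()
    z = (logcov - logcov.mean()) / sd if sd > 0 else np.zeros_like(logcov)
    new_mask = m.mask | (z < z_low) | (z > z_high)
    if new_mask.all():
        raise ValueError("coverage masking removed every bin")
    n_new = int(new_mask.sum() - m.mask.sum())
    if n_new:
        logger.info("mask_bins_by_coverage: masked %d additional bins", n_new)
    return replace(m, counts=m.counts.copy(), mask=new_mask)


def ice_balance(
    m: ContactMatrix, tol: float = 1e-5, max_iter: int = 200
) -> ContactMatrix:
    """Iterative correction (ICE) so all unmasked bins have equal visibility.

    Rows and columns are repeatedly divided by their marginal sums
    (normalised to mean 1 over unmasked bins) until the maximum relative
    deviation of the marginals drops below ``tol``.  Masked bins are left
    untouched and excluded from the marginals.  Non-convergence within
    ``max_iter`` returns the partial result with a warning.
    """
    ok = ~m.mask
    idx = np.flatnonzero(ok)
    sub = m.counts[np.ix_(idx, idx)].copy()
    rowsum = sub.sum(axis=1)
    if (rowsum == 0).any():
        raise ValueError(
            "unmasked bin with zero contacts; run mask_bins_by_coverage first"
        )
    for _ in range(max_iter):
        rowsum = sub.sum(axis=1)
        scale = rowsum / rowsum.mean()
        if np.max(np.abs(scale - 1.0)) < tol:
            break
        sub /= np.sqrt(np.outer(scale, scale))
    else:
        logger.warning("ice_balance: not converged after %d iterations", max_iter)
    counts = m.counts.copy()
    counts[np.ix_(idx, idx)] = sub
    return replace(m, counts=counts, mask=m.mask.copy())


def normalize_to_common_coverage(
    a: ContactMatrix, b: ContactMatrix
) -> tuple[ContactMatrix, ContactMatrix]:
    """Scale the higher-coverage matrix down so both totals match."""
    if a.n_bins != b.n_bins or a.bin_bp != b.bin_bp:
        raise ValueError("matrices must share the same bin grid")
    ta, tb = a.total, b.total
    if ta == 0 or tb == 0:
        raise ValueError("zero total coverage")
    low = min(ta, tb)
    a2 = replace(a, counts=a.counts * (low / ta), mask=a.mask.copy())
    b2 = replace(b, counts=b.counts * (low / tb), mask=b.mask.copy())
    return a2, b2


def merge_bins(m: ContactMatrix, factor: int = 100) -> ContactMatrix:
    """Sum counts over ``factor`` x ``factor`` blocks of bins.

    The last partial block is kept.  A merged bin is masked only when all
    of its constituent bins were masked.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return replace(m, counts=m.counts.copy(), mask=m.mask.copy())
    n = m.n_bins
    n_out = (n + factor - 1) // factor
    counts = np.zeros((n_out, n_out))
    for i in range(n_out):
        si = slice(i * factor, min((i + 1) * factor, n))
        for j in range(n_out):
            sj = slice(j * factor, min((j + 1) * factor, n))
            counts[i, j] = m.counts[si, sj].sum()
    mask = np.array(
        [m.mask[i * factor : min((i + 1) * factor, n)].all() for i in range(n_out)]
    )
    return ContactMatrix(counts, m.bin_bp * factor, m.chrom, mask)


def log2_ratio(
    a: ContactMatrix, b: ContactMatrix, pseudocount: float = 0.0
) -> np.ndarray:
    """Entrywise ``log2((a + pc) / (b + pc))`` over the shared grid.

    Entries involving a masked bin in either matrix, or where either side
    is zero at pseudocount 0, are NaN.
    """
    if a.n_bins != b.n_bins or a.bin_bp != b.bin_bp:
        raise ValueError("matrices must share the same bin grid")
    num = a.counts + pseudocount
    den = b.counts + pseudocount
    out = np.full(a.counts.shape, np.nan)
    valid = (num > 0) & (den > 0)
    bad = a.mask | b.mask
    valid[bad, :] = False
    valid[:, bad] = False
    out[valid] = np.log2(num[valid] / den[valid])
    return out


def compare_pipeline(
    a: ContactMatrix,
    b: ContactMatrix,
    z_low: float = -1.5,
    z_high: float = 5.0,
    merge_factor: int = 100,
    pseudocount: float = 0.0,
) -> np.ndarray:
    """Full comparison: mask -> balance -> normalise -> merge -> log2 ratio."""
    a = mask_bins_by_coverage(a, z_low, z_high)
    b = mask_bins_by_coverage(b, z_low, z_high)
    shared = a.mask | b.mask
    a = replace(a, counts=a.counts.copy(), mask=shared.copy())
    b = replace(b, counts=b.counts.copy(), mask=shared.copy())
    a = ice_balance(a)
    b = ice_balance(b)
    a, b = normalize_to_common_coverage(a, b)
    a = merge_bins(a, merge_factor)
    b = merge_bins(b, merge_factor)
    return log2_ratio(a, b, pseudocount)
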