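"""Per-locus viability-selection scan.

For every AIM, interspecific heterozygosity (a 0/1 response) is modelled as

    het ~ ancestry_q * age + sex,    binomial(logit)

across cross-sectionally sampled age classes (HY=0, SY=1, ASY=2).  A
significant age or ancestry-by-age term indicates that the frequency of
heterozygotes changes with survival to later age classes, i.e. viability
selection on that locus.  Multiple testing is corrected with
Benjamini-Hochberg FDR separately for autosomes and the Z chromosome,
because the Z has its own effective population size and missingness
profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from hybridscan.aim import AimMatrix, SampleMeta, interspecific_het_vector

logger = logging.getLogger(__name__)

SEPARATION_BOUND = 30.0  # |beta| beyond this on the logit scale => separation

SCAN_TERMS = ("ancestry", "age", "sex", "ancestry_age")


@dataclass
class GlmFit:
    """Result of a single GLM fit.

    Coefficients for aliased (rank-deficient) columns are NaN and flagged in
    ``aliased``.  A non-converged fit (including detected separation) keeps
    its last coefficients but reports NaN p-values.
    """

    params: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    loglik: float
    converged: bool
    n_used: int
    term_names: list[str]
    aliased: np.ndarray
    n_iter: int = 0

    def __getitem__(self, term: str) -> dict:
        i = self.term_names.index(term)
        return {
            "beta": self.params[i],
            "se": self.bse[i],
            "z": self.zvalues[i],
            "p": self.pvalues[i],
        }


def _logit_mu(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))


def fit_glm_irls(
    y: np.ndarray,
    X: np.ndarray,
    family: str = "binomial",
    term_names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GlmFit:
    """Fit a GLM by iteratively reweighted least squares, dispersion fixed at 1.

    Parameters
    ----------
    y
        Response vector.  Binomial: values in [0, 1].  Poisson (log link):
        non-negative reals; non-integer responses are accepted and fitted by
        the same estimating equations (quasi-likelihood), matching R's
        coefficient and Wald-test behaviour on continuous responses.
    X
        Dense design matrix including the intercept column; rows with
        missing data must be dropped by the caller.
    family
        ``"binomial"`` (logit link) or ``"poisson"`` (log link).

    Notes
    -----
    Convergence is declared when the largest absolute coefficient change
    falls below ``tol``.  Rank-deficient columns are dropped (NaN
    coefficients, ``aliased`` flag).  Perfect separation in the binomial
    family is detected as a coefficient exceeding 30 on the logit scale:
    the fit is returned with ``converged=False`` and missing p-values.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("X rows must match the length of y")
    if y.size == 0:
        raise ValueError("empty response vector")
    if family not in ("binomial", "poisson"):
        raise ValueError(f"unknown family {family!r}")
    n, p = X.shape
    if term_names is None:
        term_names = [f"x{i}" for i in range(p)]

    # detect aliased columns once, on the unweighted design
    _, R, piv = _pivoted_qr(X)
    rank_tol = np.abs(R[0, 0]) * max(n, p) * np.finfo(float).eps if R.size else 0.0
    rank = int((np.abs(np.diag(R)) > rank_tol).sum())
    keep = np.sort(piv[:rank])
    aliased = np.ones(p, dtype=bool)
    aliased[keep] = False
    Xk = X[:, keep]
    pk = Xk.shape[1]

    beta = np.zeros(pk)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xk @ beta
        if family == "binomial":
            mu = _logit_mu(eta)
            w = mu * (1.0 - mu)
        else:
            mu = np.exp(np.clip(eta, -500, 500))
            w = mu
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(Xk * sw[:, None], z * sw, rcond=None)
        delta = np.max(np.abs(beta_new - beta)) if pk else 0.0
        beta = beta_new
        if delta < tol:
            converged = True
            break

    separated = family == "binomial" and np.any(np.abs(beta) > SEPARATION_BOUND)
    if separated:
        converged = False

    eta = Xk @ beta
    if family == "binomial":
        mu = _logit_mu(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        mu_c = np.clip(mu, 1e-12, 1 - 1e-12)
        loglik = float(np.sum(y * np.log(mu_c) + (1 - y) * np.log(1 - mu_c)))
    else:
        mu = np.exp(np.clip(eta, -500, 500))
        w = np.maximum(mu, 1e-10)
        with np.errstate(divide="ignore", invalid="ignore"):
            ylogmu = np.where(y > 0, y * np.log(np.maximum(mu, 1e-300)), 0.0)
        loglik = float(np.sum(ylogmu - mu))  # up to the y! constant

    info = (Xk * w[:, None]).T @ Xk
    try:
        cov = np.linalg.inv(info)
        se_k = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_k = np.full(pk, np.nan)
        converged = False

    params = np.full(p, np.nan)
    bse = np.full(p, np.nan)
    params[keep] = beta
    bse[keep] = se_k
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = params / bse
    pval = 2.0 * stats.norm.sf(np.abs(zval))
    if not converged:
        pval = np.full(p, np.nan)
    return GlmFit(
        params=params,
        bse=bse,
        zvalues=zval,
        pvalues=pval,
        loglik=loglik,
        converged=converged,
        n_used=n,
        term_names=list(term_names),
        aliased=aliased,
        n_iter=it,
    )


def _pivoted_qr(X: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, np.atleast_2d(R), piv


def build_design(
    meta: SampleMeta, individual_ids: list[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Build the scan design matrix (intercept, ancestry, age, sex, ancestry*age).

    Individuals of unknown sex or with missing ancestry are excluded.
    Returns ``(X, row_index, term_names)`` where ``row_index`` maps design
    rows back to positions in ``individual_ids``.
    """
    t = meta.table.loc[individual_ids]
    q = t["ancestry_q"].to_numpy(dtype=float)
    age = t["age"].to_numpy(dtype=float)
    sex = t["sex"].to_numpy()
    usable = (sex != "unknown") & ~np.isnan(q)
    rows = np.flatnonzero(usable)
    sex01 = (sex[rows] == "M").astype(float)
    X = np.column_stack(
        [
            np.ones(rows.size),
            q[rows],
            age[rows],
            sex01,
            q[rows] * age[rows],
        ]
    )
    return X, rows, ["intercept", *SCAN_TERMS]


@dataclass
class ScanResult:
    """Per-locus (or per-pair) scan table with per-term p- and q-values.

    ``table`` has one row per tested unit with columns ``beta_<term>``,
    ``p_<term>``, ``q_<term>`` for each term plus bookkeeping columns
    (``n_used``, ``converged``, ``skipped``, ``skip_reason``).
    """

    table: pd.DataFrame
    terms: list[str] = field(default_factory=lambda: list(SCAN_TERMS))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def fdr_adjust(pvals: np.ndarray, strata: np.ndarray | None = None) -> np.ndarray:
    """Benjamini-Hochberg q-values computed within each stratum.

    Missing p-values are ignored (their q is NaN).  Raises on p outside
    [0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if strata is None:
        strata = np.zeros(p.shape, dtype=int)
    strata = np.asarray(strata)
    for s in pd.unique(strata):
        m = (strata == s) & finite
        if m.any():
            q[m] = multipletests(p[m], method="fdr_bh")[1]
    return q


def het_scan(
    matrix: AimMatrix,
    meta: SampleMeta,
    min_cases: int = 20,
    alpha: float = 0.05,
) -> ScanResult:
    """Scan every locus for viability selection on interspecific heterozygosity.

    Fits ``het ~ ancestry * age + sex`` (binomial-logit) per locus on
    complete cases.  Loci with fewer than ``min_cases`` complete cases or a
    monomorphic response are skipped with a reason.  q-values are BH-FDR
    within two strata: pooled autosomes, and the Z chromosome.
    """
    X_full, rows, names = build_design(meta, matrix.individual_ids)
    terms = list(SCAN_TERMS)
    records = []
    for j in range(matrix.n_loci):
        y_all = interspecific_het_vector(matrix, j)[rows]
        ok = ~np.isnan(y_all)
        rec = {
            "chrom": matrix.loci["chrom"].iloc[j],
            "pos": int(matrix.loci["pos"].iloc[j]),
            "is_z": bool(matrix.loci["is_z"].iloc[j]),
            "n_used": int(ok.sum()),
            "converged": False,
            "skipped": False,
            "skip_reason": "",
        }
        y = y_all[ok]
        if y.size < min_cases:
            rec.update(skipped=True, skip_reason="too_few_cases")
        elif y.min() == y.max():
            rec.update(skipped=True, skip_reason="monomorphic")
        else:
            fit = fit_glm_irls(y, X_full[ok], family="binomial", term_names=names)
            rec["converged"] = fit.converged
            if not fit.converged:
                rec["skip_reason"] = "separation_or_nonconvergence"
            for t in terms:
                cell = fit[t]
                rec[f"beta_{t}"] = cell["beta"]
                rec[f"p_{t}"] = cell["p"]
        for t in terms:
            rec.setdefault(f"beta_{t}", np.nan)
            rec.setdefault(f"p_{t}", np.nan)
        records.append(rec)
    if not records or all(r["skipped"] for r in records):
        raise ValueError("no valid loci to scan")
    table = pd.DataFrame.from_records(records)
    strata = table["is_z"].to_numpy()
    for t in terms:
        table[f"q_{t}"] = fdr_adjust(table[f"p_{t}"].to_numpy(), strata)
        table[f"outlier_{t}"] = table[f"q_{t}"] < alpha
    n_skipped = int(table["skipped"].sum())
    if n_skipped:
        logger.info("het_scan: skipped %d of %d loci", n_skipped, len(table))
    return ScanResult(table, terms)


def outlier_loci(scan: ScanResult, term: str, alpha: float = 0.05) -> pd.DataFrame:
    """Loci with FDR-adjusted q strictly below ``alpha`` for one model term."""
    if term not in scan.terms:
        raise ValueError(f"unknown term {term!r}; have {scan.terms}")
    col = f"q_{term}"
    out = scan.table[scan.table[col] < alpha]
    return out.sort_values(col, kind="mergesort").reset_index(drop=True)
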