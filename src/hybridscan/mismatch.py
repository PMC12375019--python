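"""Pairwise ancestry-mismatch statistic and its per-pair GLM scan.

For a pair of loci, each individual's two-locus genotype is a point
``(s_i, s_j)`` on the 0-2 ancestry-state grid.  The parental panels define
anchor points ``c`` (coastal means) and ``u`` (inland means); ancestry
mismatch is the perpendicular Euclidean distance of the genotype point from
the line through the anchors.  Individuals whose two loci carry concordant
ancestry lie on (or near) the parental line and score ~0; discordant
ancestry combinations score high.

The per-pair scan mirrors the heterozygosity scan's design
(``mismatch ~ ancestry * age + sex``) but with a Poisson log link.  The
response is a continuous non-negative distance, so the Poisson fit is used
as a quasi-likelihood estimating equation; coefficients and Wald tests
match R's ``glm`` behaviour on such data (modulo its non-integer warning),
and the caveat is logged once per scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hybridscan.aim import AimMatrix, SampleMeta
from hybridscan.glm import SCAN_TERMS, ScanResult, build_design, fdr_adjust, fit_glm_irls

logger = logging.getLogger(__name__)


def mismatch_distance(
    g: np.ndarray, c: tuple[float, float], u: tuple[float, float]
) -> np.ndarray:
    """Perpendicular distance of genotype points from the parental line.

    Parameters
    ----------
    g
        Genotype point(s) ``(state_i, state_j)``; either a single pair or an
        ``(n, 2)`` array.  Missing states propagate NaN.
    c, u
        Coastal and inland anchor points (mean panel states at the two
        loci).  Must differ.

    Returns the distance(s) ``|cross(u - c, g - c)| / ||u - c||``.
    """
    c = np.asarray(c, dtype=float)
    u = np.asarray(u, dtype=float)
    d = u - c
    norm = np.hypot(d[0], d[1])
    if norm == 0:
        raise ValueError("degenerate anchors: coastal and inland points coincide")
    g = np.asarray(g, dtype=float)
    single = g.ndim == 1
    g2 = np.atleast_2d(g)
    rel = g2 - c
    cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
    dist = np.abs(cross) / norm
    return float(dist[0]) if single else dist


@dataclass
class MismatchPair:
    """One locus pair with its anchors and per-individual distances."""

    locus_i: int
    locus_j: int
    c: tuple[float, float]
    u: tuple[float, float]
    distances: np.ndarray


def panel_anchor_means(
    matrix: AimMatrix,
    meta: SampleMeta,
    coastal_q_max: float = 0.05,
    inland_q_min: float = 0.95,
) -> pd.DataFrame:
    """Per-locus coastal/inland mean states from proxy parental individuals.

    Individuals with genome-wide ancestry below ``coastal_q_max`` act as the
    coastal panel, above ``inland_q_min`` as the inland panel.  Used when no
    designated reference panel is available.
    """
    q = meta.table.loc[matrix.individual_ids, "ancestry_q"].to_numpy(dtype=float)
    coastal = q <= coastal_q_max
    inland = q >= inland_q_min
    if coastal.sum() == 0 or inland.sum() == 0:
        raise ValueError(
            "no proxy parental individuals at the requested ancestry thresholds"
        )
    with np.errstate(invalid="ignore"):
        cmean = np.nanmean(matrix.states[coastal], axis=0)
        umean = np.nanmean(matrix.states[inland], axis=0)
    return pd.DataFrame(
        {
            "chrom": matrix.loci["chrom"],
            "pos": matrix.loci["pos"],
            "coastal_mean": cmean,
            "inland_mean": umean,
        }
    )


def pair_scan(
    matrix: AimMatrix,
    meta: SampleMeta,
    pairs: np.ndarray,
    panel_means: pd.DataFrame | None = None,
    min_cases: int = 20,
    alpha: float = 0.05,
) -> ScanResult:
    """Scan locus pairs for viability selection on ancestry mismatch.

    Parameters
    ----------
    pairs
        Integer array of shape ``(n_pairs, 2)`` of locus indices into the
        matrix.  Scanning all ~n^2/2 pairs of a genome-scale matrix is
        deliberately not the default; callers supply (or subsample) a pair
        list.
    panel_means
        Optional per-locus table with ``coastal_mean``/``inland_mean``
        columns aligned to the matrix loci.  Defaults to proxy panels from
        near-parental individuals (see :func:`panel_anchor_means`).

    Pairs with degenerate anchors or a constant distance response are
    skipped with a reason.  q-values are BH within two strata (pair on
    autosomes only vs pair touching the Z).
    """
    pairs = np.asarray(pairs, dtype=int)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] == 0:
        raise ValueError("pairs must be a non-empty (n_pairs, 2) index array")
    if panel_means is None:
        panel_means = panel_anchor_means(matrix, meta)
    cmean = panel_means["coastal_mean"].to_numpy(dtype=float)
    umean = panel_means["inland_mean"].to_numpy(dtype=float)

    logger.warning(
        "pair_scan: Poisson log-link applied to a continuous distance response "
        "(quasi-likelihood estimating equations)"
    )
    X_full, rows, names = build_design(meta, matrix.individual_ids)
    terms = list(SCAN_TERMS)
    chroms = matrix.loci["chrom"].to_numpy()
    positions = matrix.loci["pos"].to_numpy()
    is_z = matrix.loci["is_z"].to_numpy()

    records = []
    n_degenerate = 0
    for a, b in pairs:
        rec = {
            "chrom_i": chroms[a],
            "pos_i": int(positions[a]),
            "chrom_j": chroms[b],
            "pos_j": int(positions[b]),
            "locus_i": int(a),
            "locus_j": int(b),
            "touches_z": bool(is_z[a] or is_z[b]),
            "c_i": cmean[a],
            "c_j": cmean[b],
            "u_i": umean[a],
            "u_j": umean[b],
            "converged": False,
            "skipped": False,
            "skip_reason": "",
        }
        c = (cmean[a], cmean[b])
        u = (umean[a], umean[b])
        if np.isnan(c).any() or np.isnan(u).any() or np.hypot(u[0] - c[0], u[1] - c[1]) == 0:
            n_degenerate += 1
            rec.update(skipped=True, skip_reason="degenerate_anchors", n_used=0)
        else:
            g = matrix.states[:, [a, b]][rows]
            d = mismatch_distance(g, c, u)
            ok = ~np.isnan(d)
            rec["n_used"] = int(ok.sum())
            y = d[ok]
            if y.size < min_cases:
                rec.update(skipped=True, skip_reason="too_few_cases")
            elif y.min() == y.max():
                rec.update(skipped=True, skip_reason="constant_response")
            else:
                fit = fit_glm_irls(y, X_full[ok], family="poisson", term_names=names)
                rec["converged"] = fit.converged
                for t in terms:
                    cell = fit[t]
                    rec[f"beta_{t}"] = cell["beta"]
                    rec[f"p_{t}"] = cell["p"]
        for t in terms:
            rec.setdefault(f"beta_{t}", np.nan)
            rec.setdefault(f"p_{t}", np.nan)
        records.append(rec)
    if n_degenerate:
        logger.info("pair_scan: skipped %d degenerate pairs", n_degenerate)
    table = pd.DataFrame.from_records(records)
    strata = table["touches_z"].to_numpy()
    for t in terms:
        table[f"q_{t}"] = fdr_adjust(table[f"p_{t}"].to_numpy(), strata)
        table[f"outlier_{t}"] = table[f"q_{t}"] < alpha
    return ScanResult(table, terms)


def interchrom_report(
    scan: ScanResult, term: str = "ancestry_age", alpha_raw: float = 0.05
) -> pd.DataFrame:
    """Cross-chromosome pairs with raw p below ``alpha_raw`` for one term.

    Returns the filtered pair table with a ``pair_count`` column giving the
    number of reported pairs for each chromosome pair.
    """
    if term not in scan.terms:
        raise ValueError(f"unknown term {term!r}")
    t = scan.table
    sel = (t["chrom_i"] != t["chrom_j"]) & (t[f"p_{term}"] < alpha_raw)
    out = t[sel].copy().reset_index(drop=True)
    if len(out):
        key = out[["chrom_i", "chrom_j"]].agg("|".join, axis=1)
        out["pair_count"] = key.map(key.value_counts())
    else:
        out["pair_count"] = pd.Series(dtype=int)
    return out
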