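"""Marker-level statistics for bulked-segregant allele counts.

Implements the G test on the 2x2 allele-by-bulk read-count table, its
tricube-smoothed version G' computed over a genetic-distance window,
coverage normalization and dispersion QC for target-enriched data,
replicate heterogeneity testing and pooling via repeated G tests, the
log-normal empirical null for G' with Benjamini-Hochberg FDR control, and
the broad-sense heritability estimator from accession phenotype tables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DEFAULT_WINDOW_CM = 36.0


# ---------------------------------------------------------------------------
# G test
# ---------------------------------------------------------------------------

def g_test_tables(a1, b1, a2, b2):
    """Vectorized G test on 2x2 tables ``[[a1, b1], [a2, b2]]``.

    G = 2 * sum O * ln(O / E) with expected counts from the margins; the
    p-value is the chi-square upper tail with 1 df.  Tables with a zero row
    or column margin (monomorphic marker or empty bulk) are untestable and
    return NaN for both G and p.

    Returns ``(G, p)`` as float arrays (or scalars for scalar input).
    """
    a1, b1, a2, b2 = (np.asarray(x, dtype=float) for x in (a1, b1, a2, b2))
    if np.any(a1 < 0) or np.any(b1 < 0) or np.any(a2 < 0) or np.any(b2 < 0):
        raise ValueError("counts must be nonnegative")
    r1, r2 = a1 + b1, a2 + b2
    ca, cb = a1 + a2, b1 + b2
    n = r1 + r2
    testable = (r1 > 0) & (r2 > 0) & (ca > 0) & (cb > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 2.0 * (
            xlogy(a1, a1 * n / (r1 * ca))
            + xlogy(b1, b1 * n / (r1 * cb))
            + xlogy(a2, a2 * n / (r2 * ca))
            + xlogy(b2, b2 * n / (r2 * cb))
        )
    g = np.where(testable, np.maximum(g, 0.0), np.nan)
    p = np.where(testable, stats.chi2.sf(g, df=1), np.nan)
    if np.isscalar(a1) or g.ndim == 0:
        return float(g), float(p)
    return g, p


def g_test_2x2(a1, b1, a2, b2):
    """Scalar G test; raises on an untestable (zero-margin) table."""
    g, p = g_test_tables(a1, b1, a2, b2)
    if np.isnan(g):
        raise ValueError("untestable 2x2 table: zero row or column margin")
    return g, p


def bh_adjust(pvalues, alpha=0.01):
    """Benjamini-Hochberg adjusted p-values and rejection flags.

    NaN p-values (untestable markers) are excluded from the correction and
    come back as NaN / not significant.
    """
    p = np.asarray(pvalues, dtype=float)
    qv = np.full(p.shape, np.nan)
    sig = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        rej, q, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        qv[ok] = q
        sig[ok] = rej
    return qv, sig


def detect_markers(counts: pd.DataFrame, alpha: float = 0.01):
    """G test each marker of a wide BulkCounts table and flag those whose
    BH-adjusted p-value is below ``alpha``.  Returns a boolean mask."""
    g, p = g_test_tables(
        counts["countA_bulk1"], counts["countB_bulk1"],
        counts["countA_bulk2"], counts["countB_bulk2"],
    )
    if not np.isfinite(p).any():
        raise ValueError("no testable markers")
    _, sig = bh_adjust(p, alpha=alpha)
    return sig


# ---------------------------------------------------------------------------
# Tricube smoothing (G')
# ---------------------------------------------------------------------------

def tricube_weights(distances, halfwidth: float):
    """Tricube kernel ``w(d) = (1 - |d/h|^3)^3`` for ``|d| < h``, else 0."""
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    u = np.abs(np.asarray(distances, dtype=float)) / halfwidth
    w = np.where(u < 1.0, (1.0 - u**3) ** 3, 0.0)
    return w


def smoothing_matrix(positions_cm, window_cm: float) -> np.ndarray:
    """Row-normalized tricube smoothing matrix for one chromosome.

    ``window_cm`` is the full window width; the tricube halfwidth is
    ``window_cm / 2``.  Windows truncate at chromosome ends and the weights
    renormalize over the markers present (the focal marker always carries
    weight 1, so rows are never empty).
    """
    if window_cm <= 0:
        raise ValueError("window must be positive")
    x = np.asarray(positions_cm, dtype=float)
    d = np.abs(x[:, None] - x[None, :])
    w = tricube_weights(d, window_cm / 2.0)
    return w / w.sum(axis=1, keepdims=True)


def smooth_gprime(g_values, positions_cm, window_cm: float = DEFAULT_WINDOW_CM):
    """Tricube-weighted moving average of G over a genetic window (one
    chromosome): ``G'(x) = sum_j w_j G_j / sum_j w_j``."""
    g = np.asarray(g_values, dtype=float)
    if g.size == 0:
        raise ValueError("need at least one marker")
    return smoothing_matrix(positions_cm, window_cm) @ g


def smooth_profile(df: pd.DataFrame, window_cm: float, g_col: str = "G",
                   pos_col: str = "pos_cm") -> np.ndarray:
    """Per-chromosome G' for a multi-chromosome marker table."""
    out = np.empty(len(df), dtype=float)
    for _, idx in df.groupby("chrom", sort=False).indices.items():
        out[idx] = smooth_gprime(
            df[g_col].to_numpy()[idx], df[pos_col].to_numpy()[idx], window_cm
        )
    return out


# ---------------------------------------------------------------------------
# Coverage normalization and dispersion QC
# ---------------------------------------------------------------------------

def normalize_coverage(counts: pd.DataFrame, threshold: int):
    """Normalize per-marker sequencing depth to a fixed threshold.

    Markers where every bulk reaches the threshold are downscaled
    proportionally so each bulk's (A, B) pair sums exactly to the threshold
    (A rounded to nearest, B = threshold - A); markers where any bulk falls
    below the threshold are discarded, keeping the 2x2 table balanced.

    Returns ``(normalized table, number of markers dropped)``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    a1 = counts["countA_bulk1"].to_numpy(dtype=float)
    b1 = counts["countB_bulk1"].to_numpy(dtype=float)
    a2 = counts["countA_bulk2"].to_numpy(dtype=float)
    b2 = counts["countB_bulk2"].to_numpy(dtype=float)
    cov1, cov2 = a1 + b1, a2 + b2
    keep = (cov1 >= threshold) & (cov2 >= threshold)
    out = counts.loc[keep].copy()
    na1 = np.round(a1[keep] * threshold / cov1[keep]).astype(np.int64)
    na2 = np.round(a2[keep] * threshold / cov2[keep]).astype(np.int64)
    out["countA_bulk1"] = na1
    out["countB_bulk1"] = threshold - na1
    out["countA_bulk2"] = na2
    out["countB_bulk2"] = threshold - na2
    return out.reset_index(drop=True), int((~keep).sum())


def poisson_iqr(mean: float) -> int:
    """Interquartile range of a Poisson distribution with the given mean,
    using the standard left-continuous integer quantile function."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    return int(stats.poisson.ppf(0.75, mean) - stats.poisson.ppf(0.25, mean))


def coverage_dispersion(counts: pd.DataFrame, ratio: float = 2.0):
    """Compare observed per-marker coverage IQR against the Poisson IQR at
    the observed mean, per bulk.

    Target-enrichment coverage is typically grossly over-dispersed relative
    to the Poisson expectation of shotgun sequencing; the flag trips when
    the observed IQR exceeds ``ratio`` times the Poisson IQR in any bulk.

    Returns a DataFrame indexed by bulk with columns ``mean``,
    ``iqr_observed``, ``iqr_poisson``, ``overdispersed``.
    """
    if len(counts) < 4:
        raise ValueError("need at least 4 markers to assess dispersion")
    rows = {}
    for bulk, (ca, cb) in {
        "bulk1": ("countA_bulk1", "countB_bulk1"),
        "bulk2": ("countA_bulk2", "countB_bulk2"),
    }.items():
        cov = counts[ca].to_numpy(float) + counts[cb].to_numpy(float)
        mean = cov.mean()
        obs = float(np.percentile(cov, 75) - np.percentile(cov, 25))
        pois = poisson_iqr(mean) if mean > 0 else 0
        rows[bulk] = dict(
            mean=mean, iqr_observed=obs, iqr_poisson=pois,
            overdispersed=bool(pois > 0 and obs > ratio * pois),
        )
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Replicate heterogeneity (repeated G tests) and pooling
# ---------------------------------------------------------------------------

def replicate_heterogeneity(replicates, alpha: float = 0.01):
    """Repeated G tests across biological replicates of a bulk pair.

    For each marker: ``G_total`` is the sum of the per-replicate G values,
    ``G_pooled`` is the G of the summed count table, and the heterogeneity
    component ``G_het = G_total - G_pooled`` has ``R - 1`` df.  Markers with
    heterogeneity p-value below ``alpha`` (or untestable in any replicate)
    are dropped; survivors' counts are summed across replicates.

    Parameters
    ----------
    replicates : sequence of wide BulkCounts DataFrames sharing a marker map.
    alpha : per-marker heterogeneity significance level.

    Returns
    -------
    (stats_table, pooled_counts) : per-marker statistics with a ``keep``
        flag, and the pooled wide table of the kept markers.
    """
    if len(replicates) < 2:
        raise ValueError("need at least two replicates")
    base = replicates[0]
    for rep in replicates[1:]:
        if len(rep) != len(base) or not rep["pos_cm" if "pos_cm" in rep else "pos_bp"].reset_index(drop=True).equals(
            base["pos_cm" if "pos_cm" in base else "pos_bp"].reset_index(drop=True)
        ):
            raise ValueError("replicate marker maps do not match")
    cols = ["countA_bulk1", "countB_bulk1", "countA_bulk2", "countB_bulk2"]
    stacks = {c: np.stack([r[c].to_numpy(dtype=np.int64) for r in replicates]) for c in cols}
    g_rep = np.stack([
        g_test_tables(r["countA_bulk1"], r["countB_bulk1"],
                      r["countA_bulk2"], r["countB_bulk2"])[0]
        for r in replicates
    ])
    g_total = g_rep.sum(axis=0)
    sums = {c: stacks[c].sum(axis=0) for c in cols}
    g_pooled, _ = g_test_tables(
        sums["countA_bulk1"], sums["countB_bulk1"],
        sums["countA_bulk2"], sums["countB_bulk2"],
    )
    r = len(replicates)
    g_het = g_total - g_pooled
    p_het = stats.chi2.sf(np.maximum(g_het, 0.0), df=r - 1)
    keep = np.isfinite(p_het) & (p_het >= alpha)
    stats_tab = base[[c for c in ("chrom", "pos_cm", "pos_bp") if c in base]].copy()
    stats_tab["G_pooled"] = g_pooled
    stats_tab["G_total"] = g_total
    stats_tab["G_het"] = g_het
    stats_tab["df_het"] = r - 1
    stats_tab["p_het"] = p_het
    stats_tab["keep"] = keep
    pooled = stats_tab.loc[keep, [c for c in ("chrom", "pos_cm", "pos_bp") if c in base]].copy()
    for c in cols:
        pooled[c] = sums[c][keep]
    return stats_tab, pooled.reset_index(drop=True)


def replicate_null_gprime(replicates, window_cm: float = DEFAULT_WINDOW_CM,
                          pos_col: str = "pos_cm"):
    """Empirical null sample of G' from between-replicate comparisons.

    For every unordered pair of replicates and each bulk, the G test is run
    between the two replicates' counts of the *same* bulk (no biological
    signal), smoothed to G' with the standard window; all pairs are pooled
    into one null sample.
    """
    if len(replicates) < 2:
        raise ValueError("need at least two replicates to form a null")
    vals = []
    for i in range(len(replicates)):
        for j in range(i + 1, len(replicates)):
            ri, rj = replicates[i], replicates[j]
            for ca, cb in (("countA_bulk1", "countB_bulk1"),
                           ("countA_bulk2", "countB_bulk2")):
                g, _ = g_test_tables(ri[ca], ri[cb], rj[ca], rj[cb])
                tmp = ri[["chrom", pos_col]].copy()
                tmp["G"] = g
                tmp = tmp.dropna(subset=["G"])
                vals.append(smooth_profile(tmp, window_cm, pos_col=pos_col))
    return np.concatenate(vals)


# ---------------------------------------------------------------------------
# Log-normal null and significance calls
# ---------------------------------------------------------------------------

def fit_lognormal_null(sample):
    """Maximum-likelihood log-normal fit to a null G' sample.

    Returns ``(meanlog, sdlog)`` — the mean and (population) SD of the log
    values.  Zeros and negatives are excluded with a logged count.
    """
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    pos = x[x > 0]
    if pos.size < x.size:
        log.warning("fit_lognormal_null: excluded %d nonpositive values",
                    x.size - pos.size)
    if pos.size == 0:
        raise ValueError("no positive values in null sample")
    lx = np.log(pos)
    return float(lx.mean()), float(lx.std(ddof=0))


def call_significant(gprime, null_params, q: float = 0.01):
    """One-sided upper-tail test of G' against a fitted log-normal null,
    with Benjamini-Hochberg FDR control at level ``q``.

    Returns ``(qvalues, significant flags)``.
    """
    meanlog, sdlog = null_params
    g = np.asarray(gprime, dtype=float)
    if sdlog <= 0:
        p = np.where(g > np.exp(meanlog), 0.0, 1.0)
    else:
        with np.errstate(divide="ignore"):
            z = (np.log(np.maximum(g, 1e-300)) - meanlog) / sdlog
        p = np.where(g > 0, stats.norm.sf(z), 1.0)
    return bh_adjust(p, alpha=q)


def gprime_threshold(null_params, q: float = 0.01) -> float:
    """G' value whose upper-tail null probability equals ``q`` (the dashed
    significance line of a QTL map plot, before BH adjustment)."""
    meanlog, sdlog = null_params
    return float(np.exp(meanlog + sdlog * stats.norm.isf(q)))


# ---------------------------------------------------------------------------
# Broad-sense heritability
# ---------------------------------------------------------------------------

def broad_sense_h2(table: pd.DataFrame, accession_col: str = "accession",
                   value_col: str = "value") -> float:
    """Broad-sense heritability from an accession x replicate phenotype
    table: ``H2 = 1 - Ve / Vp`` with Ve the mean within-accession variance
    and Vp the variance of the full sample.  Clamped to [0, 1] with a
    warning when the raw estimate falls outside.
    """
    groups = table.groupby(accession_col)[value_col]
    if groups.ngroups < 2:
        raise ValueError("need at least two accessions")
    if (groups.count() < 2).any():
        raise ValueError("every accession needs at least two replicates")
    ve = groups.var(ddof=1).mean()
    vp = table[value_col].var(ddof=1)
    if vp == 0:
        raise ValueError("degenerate phenotype table: zero total variance")
    h2 = 1.0 - ve / vp
    if not 0.0 <= h2 <= 1.0:
        log.warning("H2 estimate %.3f outside [0, 1]; clamping", h2)
        h2 = min(max(h2, 0.0), 1.0)
    return float(h2)
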