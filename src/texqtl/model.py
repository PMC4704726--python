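"""Model/Results interface for a bulked-segregant QTL scan.

:class:`QTLScan` is built from a BulkCounts table (optionally with
replicates) and owns the whole mapping pipeline; :meth:`QTLScan.fit`
returns a :class:`QTLScanResults` carrying the G' profile, the fitted
multi-QTL models with support intervals, marker attrition accounting, and
``summary()`` / ``plot()`` views.

Pipeline order follows the mapping workflow: replicate heterogeneity
filtering and pooling (repeated G tests) -> depth normalization to a fixed
threshold -> per-marker G and tricube-smoothed G' -> log-normal empirical
null from between-replicate G' -> Benjamini-Hochberg FDR calls ->
recombination-aware model-selection peak calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gstat, peaks
from .genome import RecombMap
from .io import default_recomb_map, read_counts

log = logging.getLogger(__name__)


class QTLScan:
    """A QTL mapping scan over bulked-segregant allele counts.

    Parameters
    ----------
    counts : DataFrame
        Wide BulkCounts table (``chrom``, ``pos_bp`` and/or ``pos_cm``,
        ``countA_bulk1`` ... ``countB_bulk2``), optionally with a
        ``replicate`` column for biological replicates sharing the marker
        map.
    recomb_map : RecombMap, optional
        bp <-> cM map; defaults to uniform 4 cM/Mb when bp coordinates are
        present without genetic ones.
    design : 'one_tailed' or 'two_tailed'
        Bulk design: high vs random control, or high vs low.
    window_cm : float
        Full width of the tricube G' smoothing window (default 36 cM,
        equivalent to 9 Mb at the default map).
    norm_threshold : int, optional
        Depth-normalization threshold; markers below it in any bulk are
        discarded, the rest downscaled to exactly this coverage.
    fdr : float
        Benjamini-Hochberg FDR level for significant markers.
    het_alpha : float
        Per-marker replicate-heterogeneity significance level.
    """

    def __init__(self, counts: pd.DataFrame, recomb_map: RecombMap | None = None,
                 design: str = "one_tailed", window_cm: float = 36.0,
                 norm_threshold: int | None = None, fdr: float = 0.01,
                 het_alpha: float = 0.01, marker_blacklist=None):
        if design not in ("one_tailed", "two_tailed"):
            raise ValueError(f"unknown design {design!r}")
        if counts.empty:
            raise ValueError("empty count table")
        self.counts = counts.reset_index(drop=True)
        self.recomb_map = recomb_map
        self.design = design
        self.window_cm = float(window_cm)
        self.norm_threshold = norm_threshold
        self.fdr = float(fdr)
        self.het_alpha = float(het_alpha)
        self.marker_blacklist = marker_blacklist

    @classmethod
    def from_table(cls, path, schema=None, **kwargs):
        """Build a scan from a native (or schema-mapped) TSV count table."""
        from .io import NATIVE_SCHEMA
        counts = read_counts(path, schema or NATIVE_SCHEMA)
        return cls(counts, **kwargs)

    # ------------------------------------------------------------------

    def _with_cm(self, df: pd.DataFrame) -> pd.DataFrame:
        if "pos_cm" in df.columns:
            return df
        if "pos_bp" not in df.columns:
            raise ValueError("counts need pos_cm or pos_bp coordinates")
        rmap = self.recomb_map
        if rmap is None:
            extents = df.groupby("chrom")["pos_bp"].max().to_dict()
            rmap = default_recomb_map(extents)
            self.recomb_map = rmap
        df = df.copy()
        parts = [
            pd.Series(rmap.bp_to_cm(chrom, sub["pos_bp"].to_numpy()),
                      index=sub.index)
            for chrom, sub in df.groupby("chrom", sort=False)
        ]
        df["pos_cm"] = pd.concat(parts).reindex(df.index)
        return df

    def fit(self, null_gprime=None, gprime_threshold: float | None = None,
            interval_alpha: float = 0.05) -> "QTLScanResults":
        """Run the full pipeline and return a results object.

        ``null_gprime`` supplies an explicit null G' sample when the count
        table has no replicates; alternatively pass ``gprime_threshold``
        directly.  With replicates, the null is built from between-replicate
        G' automatically.
        """
        counts = self._with_cm(self.counts)
        if self.marker_blacklist is not None:
            before = len(counts)
            counts = counts.loc[~counts["pos_bp"].isin(self.marker_blacklist)]
            log.info("blacklist removed %d markers", before - len(counts))
        attrition = {"markers_in": 0, "dropped_heterogeneity": 0,
                     "dropped_normalization": 0, "untestable": 0, "kept": 0}

        reps = None
        if "replicate" in counts.columns and counts["replicate"].nunique() > 1:
            reps = [sub.drop(columns="replicate").reset_index(drop=True)
                    for _, sub in counts.groupby("replicate", sort=True)]
            attrition["markers_in"] = len(reps[0])
            het_tab, pooled = gstat.replicate_heterogeneity(reps, self.het_alpha)
            attrition["dropped_heterogeneity"] = int((~het_tab["keep"]).sum())
            work = pooled
        else:
            work = counts.drop(columns=["replicate"], errors="ignore")
            attrition["markers_in"] = len(work)
            het_tab = None

        if self.norm_threshold is not None:
            work, n_drop = gstat.normalize_coverage(work, self.norm_threshold)
            attrition["dropped_normalization"] = n_drop
            coverage = float(self.norm_threshold)
        else:
            coverage = float(np.mean(
                work["countA_bulk1"] + work["countB_bulk1"]))

        g, p = gstat.g_test_tables(
            work["countA_bulk1"], work["countB_bulk1"],
            work["countA_bulk2"], work["countB_bulk2"])
        testable = np.isfinite(g)
        attrition["untestable"] = int((~testable).sum())
        work = work.loc[testable].reset_index(drop=True)
        g = g[testable]
        attrition["kept"] = len(work)

        profile = work[[c for c in ("chrom", "pos_bp", "pos_cm") if c in work]].copy()
        profile["G"] = g
        profile["Gprime"] = gstat.smooth_profile(profile, self.window_cm)
        cov1 = work["countA_bulk1"] + work["countB_bulk1"]
        cov2 = work["countA_bulk2"] + work["countB_bulk2"]
        profile["coverage_bulk1"] = cov1
        profile["coverage_bulk2"] = cov2
        profile["af_diff"] = (work["countA_bulk1"] / cov1
                              - work["countA_bulk2"] / cov2)

        null_params = None
        if null_gprime is None and reps is not None:
            reps_cm = [self._with_cm(r) for r in reps]
            null_gprime = gstat.replicate_null_gprime(reps_cm, self.window_cm)
        if null_gprime is not None:
            null_params = gstat.fit_lognormal_null(null_gprime)
            qv, sig = gstat.call_significant(profile["Gprime"], null_params,
                                             q=self.fdr)
            profile["qvalue"] = qv
            profile["significant"] = sig
            if gprime_threshold is None:
                if sig.any():
                    gprime_threshold = float(profile.loc[sig, "Gprime"].min())
                else:
                    gprime_threshold = float(np.inf)
        elif gprime_threshold is not None:
            profile["significant"] = profile["Gprime"] >= gprime_threshold
            profile["qvalue"] = np.nan
        else:
            raise ValueError(
                "no replicates, null_gprime sample or gprime_threshold: "
                "cannot determine significance")

        fits = peaks.call_qtl(profile, self.design, coverage, self.window_cm,
                              gprime_threshold=gprime_threshold,
                              alpha=interval_alpha)
        return QTLScanResults(
            model=self, profile=profile, fits=fits, null_params=null_params,
            gprime_threshold=float(gprime_threshold), coverage=coverage,
            attrition=attrition, heterogeneity=het_tab,
        )


@dataclass
class QTLScanResults:
    """Results of a fitted :class:`QTLScan`."""

    model: QTLScan
    profile: pd.DataFrame
    fits: list
    null_params: tuple | None
    gprime_threshold: float
    coverage: float
    attrition: dict
    heterogeneity: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def qtl(self) -> pd.DataFrame:
        """All called QTL as one table."""
        rows = []
        for fit in self.fits:
            q = fit.qtl.copy()
            q.insert(0, "chrom", fit.chrom)
            q["rmse"] = fit.rmse
            q["bic"] = fit.bic
            rows.append(q)
        if not rows:
            return pd.DataFrame(columns=["chrom", "pos_cm", "freq"])
        return pd.concat(rows, ignore_index=True)

    @property
    def n_significant(self) -> int:
        return int(self.profile["significant"].sum())

    def summary(self) -> str:
        lines = []
        lines.append("QTL scan summary")
        lines.append("=" * 64)
        lines.append(f"design: {self.model.design}    window: "
                     f"{self.model.window_cm:g} cM    coverage: {self.coverage:g}x")
        if self.null_params is not None:
            lines.append(f"null G' ~ LogNormal(meanlog={self.null_params[0]:.3f}, "
                         f"sdlog={self.null_params[1]:.3f}); FDR {self.model.fdr:g}"
                         f" -> G' threshold {self.gprime_threshold:.2f}")
        else:
            lines.append(f"G' threshold (user supplied): {self.gprime_threshold:.2f}")
        a = self.attrition
        lines.append(
            f"markers: {a['markers_in']} in; dropped {a['dropped_heterogeneity']}"
            f" (heterogeneity) + {a['dropped_normalization']} (coverage) + "
            f"{a['untestable']} (untestable); {a['kept']} analysed; "
            f"{self.n_significant} significant")
        lines.append("-" * 64)
        qtl = self.qtl
        if qtl.empty:
            lines.append("no QTL called")
        else:
            cols = [c for c in ("chrom", "pos_cm", "pos_bp", "freq",
                                "fitted_gprime", "ci_lo_cm", "ci_hi_cm") if c in qtl]
            lines.append(qtl[cols].round(3).to_string(index=False))
        return "\n".join(lines)

    def plot(self, ax=None):
        """QTL map: observed G' (dots), fitted G' (line), support intervals
        (bars) and the significance threshold (dashed)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        offset = 0.0
        ticks, labels = [], []
        for chrom, sub in self.profile.groupby("chrom", sort=False):
            x = sub["pos_cm"].to_numpy() + offset
            ax.plot(x, sub["Gprime"], ".", ms=2, color="black", alpha=0.6)
            for fit in self.fits:
                if fit.chrom != chrom:
                    continue
                ax.plot(x, fit.fitted_gprime, "-", color="red", lw=1)
                for _, q in fit.qtl.iterrows():
                    ax.plot([q["ci_lo_cm"] + offset, q["ci_hi_cm"] + offset],
                            [0, 0], lw=4, color="blue")
            ticks.append(offset + sub["pos_cm"].mean())
            labels.append(str(chrom))
            offset += sub["pos_cm"].max() + 5
        if np.isfinite(self.gprime_threshold):
            ax.axhline(self.gprime_threshold, ls="--", color="grey", lw=1)
        ax.set_xticks(ticks, labels)
        ax.set_ylabel("G'")
        return ax
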