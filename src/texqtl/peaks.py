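"""Resolving QTL peaks from a G' profile by model selection.

A chromosome's QTL model is a set of QTL markers with bulk allele
frequencies ``(p_1, ..., p_m)``.  The expected G' curve implied by a model
is computed from recombination: markers between two QTL take the
three-locus expected allele frequency given both flanks, markers distal to
the outermost QTL take the two-locus expectation, frequencies map to
expected G via the 2x2 expected-count table, and expected G is smoothed
with the same tricube window as the observed profile.  Model search is
stepwise backward elimination under BIC with coordinate-descent refinement
of positions and frequencies, and support intervals come from a chi-square
bound on the residual RMSE.

The three-locus flank joint uses the no-interference haplotype law tilted
by independent per-QTL selection weights, which preserves the haplotype
odds ratio ``((1-r12)/r12)^2`` and therefore has the closed Plackett form
for a 2x2 table with fixed margins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

from .gstat import smoothing_matrix

log = logging.getLogger(__name__)

RMSE_FLOOR = 1e-12
FREQ_GRID_STEP = 0.005


def recomb_fraction(d_cm):
    """Haldane recombination fraction ``r = (1 - exp(-2 d / 100)) / 2`` for a
    genetic distance in cM (no crossover interference)."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cm) else r


def expected_af_two_locus(p_q, r):
    """Expected marker allele frequency linked to a single selected locus at
    frequency ``p_q`` through recombination fraction ``r``:
    ``p_m = p_q (1 - r) + (1 - p_q) r``."""
    p_q = np.asarray(p_q, dtype=float)
    r = np.asarray(r, dtype=float)
    return p_q * (1.0 - r) + (1.0 - p_q) * r


def _plackett_joint(p1, p2, r12):
    """P(flank1 = A, flank2 = A) for marginals ``p1``, ``p2`` and haplotype
    odds ratio ``theta = ((1-r12)/r12)^2`` (2x2 Plackett table)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if r12 <= 0:
        h = np.minimum(p1, p2)
    elif r12 >= 0.5:
        h = p1 * p2
    else:
        theta = ((1.0 - r12) / r12) ** 2
        s = 1.0 + (p1 + p2) * (theta - 1.0)
        disc = s * s - 4.0 * theta * (theta - 1.0) * p1 * p2
        h = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * (theta - 1.0))
    lo = np.maximum(0.0, p1 + p2 - 1.0)
    hi = np.minimum(p1, p2)
    return np.clip(h, lo, hi)


def expected_af_three_locus(p1, p2, r1, r2):
    """Expected allele frequency at a marker between two selected loci.

    ``p1``/``p2`` are the bulk allele frequencies at the flanking loci and
    ``r1``/``r2`` the recombination fractions from the marker to each.  The
    four flank haplotype classes get joint frequencies from the tilted
    no-interference law (Plackett closed form with
    ``r12 = r1 + r2 - 2 r1 r2``); within each class the marker follows the
    flanks through independent crossover events in the two intervals.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    r12 = r1 + r2 - 2.0 * r1 * r2
    scalar = np.isscalar(r12) or r12.ndim == 0
    r12s = float(np.mean(r12)) if not scalar else float(r12)
    h_aa = _plackett_joint(p1, p2, r12s)
    h_ab = p1 - h_aa
    h_ba = p2 - h_aa
    h_bb = 1.0 - p1 - p2 + h_aa
    # P(marker = A | flank class), independent crossovers per interval
    den_same = (1.0 - r1) * (1.0 - r2) + r1 * r2
    den_diff = (1.0 - r1) * r2 + r1 * (1.0 - r2)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(den_same > 0, (1.0 - r1) * (1.0 - r2) / np.where(den_same > 0, den_same, 1.0), 1.0)
        beta = np.where(den_diff > 0, (1.0 - r1) * r2 / np.where(den_diff > 0, den_diff, 1.0), 0.5)
    pm = h_aa * alpha + h_bb * (1.0 - alpha) + h_ab * beta + h_ba * (1.0 - beta)
    return pm


def expected_g(p_high, p_other, coverage: float):
    """Expected G of the 2x2 allele-by-bulk table with expected counts
    ``coverage * p`` in each bulk."""
    p_high = np.asarray(p_high, dtype=float)
    p_other = np.asarray(p_other, dtype=float)
    a1, b1 = coverage * p_high, coverage * (1.0 - p_high)
    a2, b2 = coverage * p_other, coverage * (1.0 - p_other)
    r1, r2 = a1 + b1, a2 + b2
    ca, cb = a1 + a2, b1 + b2
    n = r1 + r2
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 2.0 * (
            xlogy(a1, np.where(ca > 0, a1 * n / (r1 * np.where(ca > 0, ca, 1.0)), 1.0))
            + xlogy(b1, np.where(cb > 0, b1 * n / (r1 * np.where(cb > 0, cb, 1.0)), 1.0))
            + xlogy(a2, np.where(ca > 0, a2 * n / (r2 * np.where(ca > 0, ca, 1.0)), 1.0))
            + xlogy(b2, np.where(cb > 0, b2 * n / (r2 * np.where(cb > 0, cb, 1.0)), 1.0))
        )
    return np.maximum(g, 0.0)


def rmse(observed, fitted) -> float:
    """Root mean squared error between observed and fitted G' curves, over
    all markers of the chromosome."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape:
        raise ValueError("curve length mismatch")
    if obs.size == 0:
        raise ValueError("empty curves")
    return float(np.sqrt(np.mean((obs - fit) ** 2)))


def bic(rmse_value: float, n: int, m: int) -> float:
    """Model-selection score ``BIC = 2 n ln(RMSE) + 2 m ln(n)`` for ``n``
    markers and ``m`` QTL; RMSE is floored at 1e-12 before the log."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if m < 0:
        raise ValueError("m must be >= 0")
    if rmse_value < RMSE_FLOOR:
        log.warning("RMSE %g floored at %g in BIC", rmse_value, RMSE_FLOOR)
        rmse_value = RMSE_FLOOR
    return float(2.0 * n * np.log(rmse_value) + 2.0 * m * np.log(n))


class GPrimeContext:
    """Expected-G' machinery for one chromosome.

    Holds the marker positions, per-bulk coverage, bulk design and smoothing
    window; precomputes the tricube smoothing matrix so that expected curves
    for candidate models are cheap to evaluate.

    Parameters
    ----------
    positions_cm : array
        Sorted marker positions (cM).
    coverage : float
        Reads per marker per bulk (after depth normalization this is the
        normalization threshold).
    design : 'one_tailed' or 'two_tailed'
        One-tailed compares the high bulk against an unselected control
        (expected frequency 0.5 everywhere); two-tailed assumes the
        symmetric response ``1 - p`` in the low bulk.
    window_cm : float
        Full width of the G' smoothing window.
    """

    def __init__(self, positions_cm, coverage: float, design: str = "one_tailed",
                 window_cm: float = 36.0):
        if design not in ("one_tailed", "two_tailed"):
            raise ValueError(f"unknown design {design!r}")
        self.pos = np.asarray(positions_cm, dtype=float)
        if self.pos.size < 1:
            raise ValueError("need at least one marker")
        self.coverage = float(coverage)
        self.design = design
        self.window_cm = float(window_cm)
        self.W = smoothing_matrix(self.pos, window_cm)
        self.n = self.pos.size

    # -- allele-frequency curves ------------------------------------------

    def af_curve(self, qtl_idx, freqs) -> np.ndarray:
        """Expected bulk allele frequency at every marker for a model.

        ``qtl_idx`` are sorted marker indices; ``freqs`` either a vector of
        per-QTL frequencies or a (K, m) batch.  Returns (n,) or (K, n).
        """
        qtl_idx = np.asarray(qtl_idx, dtype=int)
        P = np.atleast_2d(np.asarray(freqs, dtype=float))
        squeeze = np.asarray(freqs).ndim == 1
        K, mq = P.shape
        if mq != qtl_idx.size:
            raise ValueError("freqs do not match QTL count")
        if mq == 0:
            out = np.full((K, self.n), 0.5)
            return out[0] if squeeze else out
        qpos = self.pos[qtl_idx]
        out = np.empty((K, self.n))
        first, last = qtl_idx[0], qtl_idx[-1]
        if first > 0:
            r = recomb_fraction(qpos[0] - self.pos[:first])
            out[:, :first] = expected_af_two_locus(P[:, [0]], r[None, :])
        if last < self.n - 1:
            r = recomb_fraction(self.pos[last + 1:] - qpos[-1])
            out[:, last + 1:] = expected_af_two_locus(P[:, [-1]], r[None, :])
        for k in range(mq - 1):
            lo, hi = qtl_idx[k], qtl_idx[k + 1]
            if hi - lo < 2:
                continue
            mid = self.pos[lo + 1:hi]
            r1 = recomb_fraction(mid - qpos[k])[None, :]
            r2 = recomb_fraction(qpos[k + 1] - mid)[None, :]
            out[:, lo + 1:hi] = expected_af_three_locus(
                P[:, [k]], P[:, [k + 1]], r1, r2
            )
        out[:, qtl_idx] = P
        return out[0] if squeeze else out

    def expected_curve(self, qtl_idx, freqs) -> np.ndarray:
        """Expected G' at every marker for a model (vector or batch)."""
        af1 = self.af_curve(qtl_idx, freqs)
        if self.design == "two_tailed":
            freqs2 = 1.0 - np.asarray(freqs, dtype=float)
            af2 = self.af_curve(qtl_idx, freqs2)
        else:
            af2 = np.full_like(np.atleast_2d(af1), 0.5)
            if af1.ndim == 1:
                af2 = af2[0]
        g = expected_g(af1, af2, self.coverage)
        if g.ndim == 1:
            return self.W @ g
        return g @ self.W.T

    # -- frequency <-> G' mapping -----------------------------------------

    def af_to_gprime(self, p: float, marker_idx: int | None = None) -> float:
        """Expected G' at a lone QTL marker with bulk allele frequency ``p``
        (the one-to-one frequency-to-G' mapping for this coverage, window
        and design)."""
        if marker_idx is None:
            marker_idx = self.n // 2
        curve = self.expected_curve(np.array([marker_idx]), np.array([p]))
        return float(curve[marker_idx])

    def gprime_to_af(self, target: float, marker_idx: int | None = None,
                     tol: float = 1e-6) -> float:
        """Invert :meth:`af_to_gprime` on ``p in [0.5, 1]`` by bisection.

        Targets above the ``p = 1`` maximum clamp to 1 with a warning.
        """
        if target < 0:
            raise ValueError("G' target must be nonnegative")
        if marker_idx is None:
            marker_idx = self.n // 2
        if target <= 0:
            return 0.5
        hi_val = self.af_to_gprime(1.0, marker_idx)
        if target >= hi_val:
            if target > hi_val * (1.0 + 1e-9):
                log.warning("G' target %.3f above the p=1 maximum %.3f; clamping",
                            target, hi_val)
            return 1.0
        lo, hi = 0.5, 1.0
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if self.af_to_gprime(mid, marker_idx) < target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Candidate discovery
# ---------------------------------------------------------------------------

def local_slopes(values, positions_cm, window_cm: float) -> np.ndarray:
    """First derivative of a curve at each marker, as the slope of an
    ordinary linear regression over the markers within ``window_cm / 2``."""
    x = np.asarray(positions_cm, dtype=float)
    y = np.asarray(values, dtype=float)
    half = window_cm / 2.0
    out = np.empty(x.size)
    lo = np.searchsorted(x, x - half, side="left")
    hi = np.searchsorted(x, x + half, side="right")
    for i in range(x.size):
        xs = x[lo[i]:hi[i]]
        ys = y[lo[i]:hi[i]]
        xc = xs - xs.mean()
        den = (xc**2).sum()
        out[i] = (xc * (ys - ys.mean())).sum() / den if den > 0 else 0.0
    return out


def find_candidates(gprime, positions_cm, window_cm: float,
                    min_separation_cm: float | None = None) -> np.ndarray:
    """Candidate QTL markers: strict local maxima of G' plus local minima of
    |dG'/dx| (the shoulders of merged peaks), deduplicated to the smoothed
    profile's resolution floor.

    The derivative is the local-linear-regression slope over the same
    window as the G' test.  Candidates closer than ``min_separation_cm``
    (default: half the smoothing window, below which two QTL are not
    identifiable from the smoothed curve) are merged greedily, keeping the
    highest-G' member.  If the curve has no strict interior maximum the
    global argmax is nominated so the set is never empty.
    """
    g = np.asarray(gprime, dtype=float)
    if g.size < 3:
        return np.array([int(np.argmax(g))])
    if min_separation_cm is None:
        min_separation_cm = window_cm / 2.0
    x = np.asarray(positions_cm, dtype=float)
    interior = np.arange(1, g.size - 1)
    maxima = interior[(g[1:-1] > g[:-2]) & (g[1:-1] > g[2:])]
    cand = set(maxima.tolist())
    # shoulders of merged peaks show up as |slope| minima, not as maxima
    slope = np.abs(local_slopes(g, positions_cm, window_cm))
    s_minima = interior[(slope[1:-1] < slope[:-2]) & (slope[1:-1] < slope[2:])]
    cand.update(int(k) for k in s_minima)
    # perfectly symmetric curves can lack a strict interior maximum
    cand.add(int(np.argmax(g)))
    ranked = sorted(cand, key=lambda i: -g[i])
    kept = []
    for i in ranked:
        if all(abs(x[i] - x[j]) >= min_separation_cm for j in kept):
            kept.append(i)
    return np.array(sorted(kept), dtype=int)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

@dataclass
class ChromosomeModel:
    """A multi-QTL model on one chromosome: sorted marker indices, signed
    bulk-1 allele frequencies, and fit statistics."""

    idx: np.ndarray
    freqs: np.ndarray  # bulk-1 A-allele frequency at each QTL (may be < 0.5)
    rmse: float = np.nan
    bic: float = np.nan
    fitted: np.ndarray | None = field(default=None, repr=False)

    @property
    def m(self) -> int:
        return int(self.idx.size)


def _evaluate(ctx: GPrimeContext, observed, idx, freqs) -> ChromosomeModel:
    fitted = ctx.expected_curve(idx, freqs)
    e = rmse(observed, fitted)
    return ChromosomeModel(
        idx=np.asarray(idx, int), freqs=np.asarray(freqs, float), rmse=e,
        bic=bic(e, len(observed), len(idx)), fitted=fitted,
    )


def initial_model(ctx: GPrimeContext, observed, signs=None,
                  min_separation_cm: float | None = None) -> ChromosomeModel:
    """Step-1 model: every candidate marker, with frequency obtained by
    inverting the frequency-to-G' map at the observed G', oriented by the
    observed allele-frequency difference sign (``signs``; default +1)."""
    cand = find_candidates(observed, ctx.pos, ctx.window_cm, min_separation_cm)
    mags = np.array([ctx.gprime_to_af(max(observed[i], 0.0), i) for i in cand])
    if signs is None:
        s = np.ones(cand.size)
    else:
        s = np.where(np.asarray(signs, dtype=float)[cand] >= 0, 1.0, -1.0)
    freqs = 0.5 + s * (mags - 0.5)
    return _evaluate(ctx, observed, cand, freqs)


def backward_eliminate(ctx: GPrimeContext, observed, model: ChromosomeModel) -> ChromosomeModel:
    """Stepwise backward elimination under BIC: repeatedly remove the QTL
    whose removal most decreases BIC; stop at a fixed point.  Ties are
    broken toward the QTL with the lower fitted G'."""
    current = model
    while current.m > 0:
        best = None
        for k in range(current.m):
            idx = np.delete(current.idx, k)
            freqs = np.delete(current.freqs, k)
            trial = _evaluate(ctx, observed, idx, freqs)
            key = (trial.bic, current.fitted[current.idx[k]] if current.fitted is not None else 0.0)
            if best is None or key < best[0]:
                best = (key, trial)
        if best is not None and best[1].bic < current.bic:
            current = best[1]
        else:
            break
    return current


def _freq_grid(sign: float) -> np.ndarray:
    mags = np.arange(0.5, 1.0 + FREQ_GRID_STEP / 2, FREQ_GRID_STEP)
    return 0.5 + sign * (mags - 0.5)


def _eval_unsorted(ctx: GPrimeContext, obs, idx, freqs):
    order = np.argsort(idx)
    fitted = ctx.expected_curve(idx[order], freqs[order])
    return float(np.sqrt(np.mean((obs - fitted) ** 2))), fitted


def refine(ctx: GPrimeContext, observed, model: ChromosomeModel,
           max_passes: int = 50,
           min_separation_cm: float | None = None) -> ChromosomeModel:
    """Coordinate-descent refinement of QTL positions and frequencies.

    Per QTL (others fixed): scan the 0.005-step frequency grid at the
    current position, scan marker positions within half a smoothing window
    at the refined frequency, then jointly polish position (+-2 markers)
    x frequency grid.  Passes repeat until no adjustment lowers the RMSE,
    with a hard cap to guard against oscillation.
    """
    if model.m == 0:
        return model
    if min_separation_cm is None:
        min_separation_cm = ctx.window_cm / 2.0
    obs = np.asarray(observed, dtype=float)
    half = ctx.window_cm / 2.0
    idx = model.idx.copy()
    freqs = model.freqs.copy()
    best_e = model.rmse
    best_fit = model.fitted
    for _ in range(max_passes):
        changed = False
        for k in range(idx.size):
            sign = 1.0 if freqs[k] >= 0.5 else -1.0
            grid = _freq_grid(sign)
            taken = set(np.delete(idx, k).tolist())
            # frequency scan at fixed positions (batched over the grid)
            order = np.argsort(idx)
            F = np.tile(freqs, (grid.size, 1))
            F[:, k] = grid
            curves = ctx.expected_curve(idx[order], F[:, order])
            errs = np.sqrt(np.mean((curves - obs) ** 2, axis=1))
            j = int(np.argmin(errs))
            if errs[j] < best_e - 1e-12:
                freqs[k] = grid[j]
                best_e, best_fit = float(errs[j]), curves[j]
                changed = True
            # position scan at fixed frequencies; moves may not come closer
            # than the resolution floor to another QTL
            other_pos = ctx.pos[np.delete(idx, k)]
            near = np.flatnonzero(np.abs(ctx.pos - ctx.pos[idx[k]]) <= half)
            best_move = None
            for i in near:
                if i == idx[k] or i in taken:
                    continue
                if other_pos.size and np.min(np.abs(other_pos - ctx.pos[i])) < min_separation_cm:
                    continue
                trial = idx.copy()
                trial[k] = i
                e, fit = _eval_unsorted(ctx, obs, trial, freqs)
                if e < best_e - 1e-12 and (best_move is None or e < best_move[0]):
                    best_move = (e, i, fit)
            if best_move is not None:
                best_e, idx[k], best_fit = best_move[0], best_move[1], best_move[2]
                changed = True
            # joint polish: position +-2 markers x frequency grid
            for off in (-2, -1, 1, 2):
                i = idx[k] + off
                if not (0 <= i < ctx.n) or i in taken:
                    continue
                if other_pos.size and np.min(np.abs(other_pos - ctx.pos[i])) < min_separation_cm:
                    continue
                trial = idx.copy()
                trial[k] = i
                order = np.argsort(trial)
                F = np.tile(freqs, (grid.size, 1))
                F[:, k] = grid
                curves = ctx.expected_curve(trial[order], F[:, order])
                errs = np.sqrt(np.mean((curves - obs) ** 2, axis=1))
                j = int(np.argmin(errs))
                if errs[j] < best_e - 1e-12:
                    idx[k], freqs[k] = i, grid[j]
                    best_e, best_fit = float(errs[j]), curves[j]
                    changed = True
        if not changed:
            break
    else:
        log.warning("refine: pass cap (%d) reached without convergence", max_passes)
    order = np.argsort(idx)
    return ChromosomeModel(idx[order], freqs[order], best_e,
                           bic(best_e, ctx.n, idx.size), best_fit)


def select_model(ctx: GPrimeContext, observed, signs=None,
                 max_outer: int = 50,
                 min_separation_cm: float | None = None) -> ChromosomeModel:
    """Full model search: candidates -> frequencies -> backward elimination
    -> refinement, with the elimination/refinement pair repeated until the
    model stops changing."""
    current = refine(ctx, observed, backward_eliminate(
        ctx, observed, initial_model(ctx, observed, signs, min_separation_cm)),
        min_separation_cm=min_separation_cm)
    for _ in range(max_outer):
        nxt = refine(ctx, observed, backward_eliminate(ctx, observed, current),
                     min_separation_cm=min_separation_cm)
        if nxt.m == current.m and np.array_equal(nxt.idx, current.idx) and np.allclose(
            nxt.freqs, current.freqs
        ):
            break
        current = nxt
    else:
        log.warning("select_model: outer-loop cap (%d) reached", max_outer)
    return current


# ---------------------------------------------------------------------------
# Support intervals
# ---------------------------------------------------------------------------

def rmse_interval_multipliers(n: int, alpha: float = 0.05):
    """Multipliers on the best RMSE bounding its (1 - alpha) confidence
    interval for n residuals: ``[sqrt(n / chi2_{1-a/2, n}),
    sqrt(n / chi2_{a/2, n})]``."""
    lo = float(np.sqrt(n / stats.chi2.ppf(1.0 - alpha / 2.0, n)))
    hi = float(np.sqrt(n / stats.chi2.ppf(alpha / 2.0, n)))
    return lo, hi


def support_interval(ctx: GPrimeContext, observed, model: ChromosomeModel,
                     focal: int, alpha: float = 0.05):
    """Support interval of one QTL: slide the focal QTL to nearby markers
    (all other parameters fixed) and keep the maximal contiguous run around
    the peak whose RMSE stays below the chi-square upper bound of the best
    model's RMSE confidence interval.

    Returns ``(lo_idx, hi_idx, clipped)`` — inclusive marker indices and a
    flag set when the interval reaches a chromosome end.
    """
    if model.m == 0:
        raise ValueError("empty model has no support interval")
    _, hi_mult = rmse_interval_multipliers(ctx.n, alpha)
    bound = hi_mult * max(model.rmse, RMSE_FLOOR)
    taken = set(np.delete(model.idx, focal).tolist())
    obs = np.asarray(observed, dtype=float)

    def rmse_at(i):
        idx = model.idx.copy()
        idx[focal] = i
        order = np.argsort(idx)
        return _evaluate(ctx, obs, idx[order], model.freqs[order]).rmse

    peak = int(model.idx[focal])
    lo = peak
    i = peak - 1
    while i >= 0:
        if i in taken or rmse_at(i) > bound:
            break
        lo = i
        i -= 1
    hi = peak
    i = peak + 1
    while i < ctx.n:
        if i in taken or rmse_at(i) > bound:
            break
        hi = i
        i += 1
    clipped = lo == 0 or hi == ctx.n - 1
    if clipped:
        log.info("support interval reaches a chromosome end (clipped)")
    return lo, hi, clipped


# ---------------------------------------------------------------------------
# Top-level peak calling
# ---------------------------------------------------------------------------

@dataclass
class QTLFit:
    """Fitted multi-QTL model for one chromosome."""

    chrom: str
    qtl: pd.DataFrame  # marker_idx, pos_cm, pos_bp, freq, fitted_gprime, interval bounds
    fitted_gprime: np.ndarray = field(repr=False)
    rmse: float = np.nan
    bic: float = np.nan
    n_markers: int = 0

    @property
    def m(self) -> int:
        return len(self.qtl)


def call_qtl(profile: pd.DataFrame, design: str, coverage: float,
             window_cm: float = 36.0, gprime_threshold: float | None = None,
             alpha: float = 0.05, max_outer: int = 50,
             min_separation_cm: float | None = None):
    """Run the full model-selection peak caller on a G' profile.

    Parameters
    ----------
    profile : DataFrame
        Marker table with columns ``chrom``, ``pos_cm``, ``Gprime`` and
        optionally ``pos_bp`` and ``af_diff`` (observed bulk1 - bulk2 allele
        frequency difference, used to orient each QTL's allele).
    design, coverage, window_cm : expected-curve context parameters.
    gprime_threshold : float, optional
        Significance line on G'; chromosomes with no marker above it are
        skipped and fitted peaks below it are not reported.
    alpha : support-interval level (0.05 -> 95% intervals).

    Returns a list of :class:`QTLFit`, one per chromosome with >= 1 QTL.
    """
    fits = []
    for chrom, sub in profile.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        obs = sub["Gprime"].to_numpy(dtype=float)
        if gprime_threshold is not None and not np.any(obs >= gprime_threshold):
            log.info("%s: no marker above the G' threshold; no QTL called", chrom)
            continue
        ctx = GPrimeContext(sub["pos_cm"].to_numpy(dtype=float), coverage,
                            design, window_cm)
        signs = sub["af_diff"].to_numpy(dtype=float) if "af_diff" in sub else None
        model = select_model(ctx, obs, signs, max_outer=max_outer,
                             min_separation_cm=min_separation_cm)
        if model.m == 0:
            continue
        if gprime_threshold is not None:
            keep = model.fitted[model.idx] >= gprime_threshold
            if not keep.all():
                model = _evaluate(ctx, obs, model.idx[keep], model.freqs[keep])
            if model.m == 0:
                continue
        rows = []
        for k in range(model.m):
            lo, hi, clipped = support_interval(ctx, obs, model, k, alpha)
            row = dict(
                marker_idx=int(model.idx[k]),
                pos_cm=float(ctx.pos[model.idx[k]]),
                freq=float(model.freqs[k]),
                fitted_gprime=float(model.fitted[model.idx[k]]),
                ci_lo_cm=float(ctx.pos[lo]),
                ci_hi_cm=float(ctx.pos[hi]),
                ci_clipped=bool(clipped),
            )
            if "pos_bp" in sub:
                bp = sub["pos_bp"].to_numpy()
                row["pos_bp"] = int(bp[model.idx[k]])
                row["ci_lo_bp"] = int(bp[lo])
                row["ci_hi_bp"] = int(bp[hi])
            rows.append(row)
        fits.append(QTLFit(chrom=str(chrom), qtl=pd.DataFrame(rows),
                           fitted_gprime=model.fitted, rmse=model.rmse,
                           bic=model.bic, n_markers=ctx.n))
    return fits
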