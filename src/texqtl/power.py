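"""Detectability (power) simulations and smoothing-window calibration.

Two simulation families:

* **Power sweeps** — full forward chains (F2 meiosis -> phenotypes ->
  truncation bulks -> read sampling -> per-marker G test with
  Benjamini-Hochberg correction) scoring how often each QTL effect class
  is detected across replicates, over grids of population size, depth,
  marker density, heritability and bulk design.
* **Window calibration** — frequency-driven chromosomes (one or two QTL
  with a stated bulk allele frequency, binomial reads at a stated
  coverage) pushed through G' smoothing and the model-selection peak
  caller, to measure false-peak and peak-merging probabilities as a
  function of the smoothing window and inter-QTL distance.

The calibration generator imposes allele frequencies directly through the
expected-curve machinery rather than simulating selection, matching the
frequency-level framing of the calibration experiments.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import build_genome
from .gstat import (detect_markers, fit_lognormal_null, g_test_tables,
                    gprime_threshold, smooth_gprime)
from .peaks import GPrimeContext, call_qtl, recomb_fraction
from .simulate import QTLModelTruth, simulate_experiment, snap_to_markers, spawn_rngs

log = logging.getLogger(__name__)

#: default QTL effect scheme: one QTL per chromosome, fractions of Vg
EFFECTS_MIXED = (0.70, 0.10, 0.10, 0.05, 0.05)
EFFECTS_EQUAL = (0.20, 0.20, 0.20, 0.20, 0.20)


@dataclass
class PowerConfig:
    """Grid specification for a power sweep."""

    designs: tuple = ("two_tailed", "one_tailed")
    population_sizes: tuple = (10_000,)
    depths: tuple = (1000,)
    marker_densities: tuple = (5.0,)
    heritabilities: tuple = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))
    effects: tuple = EFFECTS_MIXED
    replicates: int = 100
    alpha: float = 0.01
    bulk_fraction: float = 0.1
    n_chr: int = 5
    chr_len_cm: float = 100.0
    detect_window_cm: float = 10.0
    genotyping: bool = False

    def __post_init__(self):
        for grid in (self.designs, self.population_sizes, self.depths,
                     self.marker_densities, self.heritabilities):
            if len(grid) == 0:
                raise ValueError("grids must be nonempty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def score_detection(sig_mask, marker_table: pd.DataFrame, truth: QTLModelTruth,
                    window_cm: float = 10.0) -> np.ndarray:
    """Per-QTL detected flags from a significant-marker mask.

    Each significant marker is assigned to the nearest QTL on its
    chromosome (so one marker cannot count for two QTL); a QTL is detected
    iff at least one of its assigned markers lies within ``window_cm``.
    """
    detected = np.zeros(len(truth.loci), dtype=bool)
    sig = marker_table.loc[np.asarray(sig_mask, bool), ["chrom", "pos_cm"]]
    if sig.empty:
        return detected
    for chrom, sub in sig.groupby("chrom", sort=False):
        loci = [(k, pos) for k, (c, pos, _e) in enumerate(truth.loci) if c == chrom]
        if not loci:
            continue
        qpos = np.array([p for _, p in loci])
        d = np.abs(sub["pos_cm"].to_numpy()[:, None] - qpos[None, :])
        nearest = np.argmin(d, axis=1)
        within = d[np.arange(len(sub)), nearest] <= window_cm
        for j in np.unique(nearest[within]):
            detected[loci[int(j)][0]] = True
    return detected


def run_power_cell(design: str, n: int, depth: int, h2: float, seed,
                   effects=EFFECTS_MIXED, marker_density: float = 5.0,
                   replicates: int = 100, alpha: float = 0.01,
                   bulk_fraction: float = 0.1, n_chr: int = 5,
                   chr_len_cm: float = 100.0, detect_window_cm: float = 10.0,
                   genotyping: bool = False) -> pd.DataFrame:
    """Detection frequency per QTL effect class for one parameter cell.

    Runs ``replicates`` independent simulate -> phenotype -> bulk ->
    sequence -> G-test/BH chains and scores each QTL.  Returns one row per
    effect class with columns ``effect``, ``n_qtl``, ``detection`` and the
    cell-wide ``false_marker_rate`` (significant markers farther than the
    detection window from every QTL).
    """
    genome = build_genome(n_chr, chr_len_cm, marker_density)
    truth = QTLModelTruth.one_per_chromosome(genome, effects)
    marker_tab = genome.marker_table()
    rngs = spawn_rngs(seed, replicates)
    det = np.zeros(len(truth.loci))
    false_rate = 0.0
    qidx, _ = snap_to_markers(genome, truth.loci)
    near_any = np.zeros(len(marker_tab), dtype=bool)
    for chrom, pos, _e in truth.loci:
        on_chr = marker_tab["chrom"] == chrom
        near_any |= on_chr & (np.abs(marker_tab["pos_cm"] - pos) <= detect_window_cm)
    for rng in rngs:
        counts, _pop = simulate_experiment(
            genome, truth, n, h2, design, depth, rng,
            bulk_fraction=bulk_fraction, genotyping=genotyping,
        )
        sig = detect_markers(counts, alpha=alpha)
        det += score_detection(sig, marker_tab, truth, detect_window_cm)
        false_rate += (sig & ~near_any).sum() / len(marker_tab)
    det /= replicates
    false_rate /= replicates
    eff = np.array([e for _, _, e in truth.loci])
    rows = []
    for e in np.unique(eff):
        sel = eff == e
        rows.append(dict(effect=float(e), n_qtl=int(sel.sum()),
                         detection=float(det[sel].mean()),
                         false_marker_rate=float(false_rate)))
    return pd.DataFrame(rows)


def power_grid(cfg: PowerConfig, seed) -> pd.DataFrame:
    """Run every cell of a :class:`PowerConfig` grid with independent
    derived seeds; long-format result, one row per cell x effect class."""
    cells = list(itertools.product(cfg.designs, cfg.population_sizes,
                                   cfg.depths, cfg.marker_densities,
                                   cfg.heritabilities))
    rngs = spawn_rngs(seed, len(cells))
    frames = []
    for (design, n, depth, dens, h2), rng in zip(cells, rngs):
        t0 = time.perf_counter()
        try:
            res = run_power_cell(
                design, n, depth, h2, rng, effects=cfg.effects,
                marker_density=dens, replicates=cfg.replicates,
                alpha=cfg.alpha, bulk_fraction=cfg.bulk_fraction,
                n_chr=cfg.n_chr, chr_len_cm=cfg.chr_len_cm,
                detect_window_cm=cfg.detect_window_cm,
                genotyping=cfg.genotyping,
            )
        except Exception:  # keep sweeping; a bad cell should not kill the grid
            log.exception("power cell failed: design=%s n=%d depth=%d dens=%g h2=%g",
                          design, n, depth, dens, h2)
            continue
        res.insert(0, "design", design)
        res.insert(1, "n", n)
        res.insert(2, "depth", depth)
        res.insert(3, "marker_density", dens)
        res.insert(4, "h2", h2)
        frames.append(res)
        log.info("cell design=%s n=%d depth=%d dens=%g h2=%g done in %.1fs",
                 design, n, depth, dens, h2, time.perf_counter() - t0)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Frequency-driven calibration simulations
# ---------------------------------------------------------------------------

def _calibration_genome(chr_len_cm=100.0, density=5.0):
    g = build_genome(1, chr_len_cm, density, names=("chr1",))
    return g.marker_pos_cm[0]


def sample_bulk_haplotype_freqs(pos_cm, qtl_idx, qtl_freqs, n_gametes: int, rng):
    """Allele frequencies of a finite bulk whose QTL alleles sit at stated
    frequencies.

    Gametes are drawn from the Haldane no-interference Markov chain along
    the markers, *conditioned* on their QTL alleles: QTL states are sampled
    sequentially with the tilted (Plackett) pairwise joint at the stated
    marginal frequencies, tails extend outward as unconditional chains, and
    markers between two QTL follow the exact two-state Markov bridge.  The
    returned per-marker frequencies therefore carry the linkage
    (haplotype-block) sampling noise of a real bulk, which independent
    binomial noise does not.
    """
    from .peaks import _plackett_joint

    pos = np.asarray(pos_cm, dtype=float)
    n = pos.size
    qtl_idx = np.asarray(qtl_idx, dtype=int)
    if qtl_idx.size == 0:
        from .simulate import _gametes
        g = _gametes(rng, n_gametes, pos, mu=0.0)
        return g.mean(axis=0)
    qf = np.asarray(qtl_freqs, dtype=float)
    states = np.empty((n_gametes, n), dtype=np.uint8)
    # QTL alleles: sequential sampling preserving marginals and the tilted
    # pairwise joint between neighbours
    q_states = np.empty((n_gametes, qtl_idx.size), dtype=np.uint8)
    q_states[:, 0] = rng.random(n_gametes) < qf[0]
    for k in range(1, qtl_idx.size):
        r12 = recomb_fraction(pos[qtl_idx[k]] - pos[qtl_idx[k - 1]])
        h11 = _plackett_joint(qf[k - 1], qf[k], float(r12))
        prev = q_states[:, k - 1].astype(bool)
        p_given1 = h11 / max(qf[k - 1], 1e-12)
        p_given0 = (qf[k] - h11) / max(1.0 - qf[k - 1], 1e-12)
        q_states[:, k] = rng.random(n_gametes) < np.where(prev, p_given1, p_given0)
    states[:, qtl_idx] = q_states
    # tails: unconditional outward chains
    for start, stop, step, anchor in ((qtl_idx[0] - 1, -1, -1, qtl_idx[0]),
                                      (qtl_idx[-1] + 1, n, 1, qtl_idx[-1])):
        cur = states[:, anchor].copy()
        prev_pos = pos[anchor]
        for j in range(start, stop, step):
            r = recomb_fraction(abs(pos[j] - prev_pos))
            cur = cur ^ (rng.random(n_gametes) < r).astype(np.uint8)
            states[:, j] = cur
            prev_pos = pos[j]
    # interior intervals: Markov bridge conditioned on both QTL states
    for k in range(qtl_idx.size - 1):
        a, b = qtl_idx[k], qtl_idx[k + 1]
        cur = states[:, a].copy()
        end = states[:, b]
        prev_pos = pos[a]
        for j in range(a + 1, b):
            r1 = recomb_fraction(pos[j] - prev_pos)
            r2 = recomb_fraction(pos[b] - pos[j])
            same = cur == end
            p_switch_same = r1 * r2 / ((1 - r1) * (1 - r2) + r1 * r2)
            p_switch_diff = r1 * (1 - r2) / (r1 * (1 - r2) + (1 - r1) * r2)
            p_switch = np.where(same, p_switch_same, p_switch_diff)
            cur = cur ^ (rng.random(n_gametes) < p_switch).astype(np.uint8)
            states[:, j] = cur
            prev_pos = pos[j]
    return states.mean(axis=0)


def simulate_freq_chromosome(pos_cm, qtl_pos_cm, qtl_freqs, coverage: int,
                             window_cm: float, rng,
                             design: str = "one_tailed",
                             n_bulk: int | None = None) -> pd.DataFrame:
    """Simulate one chromosome's G' profile with QTL imposed at stated bulk
    allele frequencies.

    The high bulk's allele-frequency curve comes from the two- and
    three-locus recombination models around the QTL; reads are binomial at
    the stated coverage per marker.  The comparison bulk sits at frequency
    0.5 (one-tailed control) or at the mirrored curve (two-tailed).  With
    ``n_bulk`` set, the deterministic curves are replaced by the frequencies
    of a finite pool of ``n_bulk`` individuals whose haplotypes are sampled
    conditional on the stated QTL frequencies (see
    :func:`sample_bulk_haplotype_freqs`), adding the linkage sampling noise
    of a finite bulk.
    """
    pos = np.asarray(pos_cm, dtype=float)
    qidx = np.array([int(np.argmin(np.abs(pos - q))) for q in qtl_pos_cm],
                    dtype=int)
    order = np.argsort(qidx)
    qidx, qfreq = qidx[order], np.asarray(qtl_freqs, float)[order]
    if n_bulk is None:
        ctx = GPrimeContext(pos, coverage, design, window_cm)
        af1 = ctx.af_curve(qidx, qfreq)
        if design == "two_tailed":
            af2 = ctx.af_curve(qidx, 1.0 - qfreq)
        else:
            af2 = np.full_like(af1, 0.5)
    else:
        af1 = sample_bulk_haplotype_freqs(pos, qidx, qfreq, 2 * n_bulk, rng)
        if design == "two_tailed":
            af2 = sample_bulk_haplotype_freqs(pos, qidx, 1.0 - qfreq,
                                              2 * n_bulk, rng)
        else:
            af2 = sample_bulk_haplotype_freqs(pos, np.array([], dtype=int), [],
                                              2 * n_bulk, rng)
    a1 = rng.binomial(coverage, af1)
    a2 = rng.binomial(coverage, af2)
    g, _ = g_test_tables(a1, coverage - a1, a2, coverage - a2)
    g = np.nan_to_num(g)
    prof = pd.DataFrame({
        "chrom": "chr1", "pos_cm": pos, "G": g,
        "Gprime": smooth_gprime(g, pos, window_cm),
        "af_diff": a1 / coverage - a2 / coverage,
    })
    return prof


def calibration_threshold(pos_cm, coverage: int, window_cm: float, seed,
                          n_null: int = 20, q: float = 0.01,
                          design: str = "one_tailed") -> float:
    """G' significance line for calibration runs: log-normal fit to G'
    from ``n_null`` null chromosomes (no QTL, frequency 0.5 everywhere),
    upper ``q`` tail quantile."""
    rng = np.random.default_rng(seed) if not hasattr(seed, "standard_normal") else seed
    sample = []
    for _ in range(n_null):
        prof = simulate_freq_chromosome(pos_cm, [], [], coverage, window_cm,
                                        rng, design)
        sample.append(prof["Gprime"].to_numpy())
    params = fit_lognormal_null(np.concatenate(sample))
    return gprime_threshold(params, q)


def _score_peaks(fits, truth_pos_cm, tol_cm: float):
    """(n_called, n_false) for one replicate: a called peak is false when it
    lies farther than ``tol_cm`` from every true QTL."""
    called = []
    for fit in fits:
        called.extend(fit.qtl["pos_cm"].tolist())
    truth = np.asarray(truth_pos_cm, dtype=float)
    n_false = 0
    for c in called:
        if truth.size == 0 or np.min(np.abs(truth - c)) > tol_cm:
            n_false += 1
    return len(called), n_false


def window_calibration_1qtl(window_sizes_cm, seed, replicates: int = 100,
                            coverage: int = 5000, qtl_freq: float = 0.6,
                            chr_len_cm: float = 100.0, density: float = 5.0,
                            design: str = "one_tailed") -> pd.DataFrame:
    """False-peak probability of the model-selection caller on single-QTL
    chromosomes (QTL mid-chromosome), per smoothing window size.

    The false-peak probability is total false peaks / replicates; a peak is
    false when it lies more than half the smoothing window from the true
    QTL.
    """
    pos = _calibration_genome(chr_len_cm, density)
    rows = []
    rngs = spawn_rngs(seed, len(window_sizes_cm))
    for w, rng in zip(window_sizes_cm, rngs):
        if w <= 0:
            raise ValueError("window sizes must be positive")
        thr = calibration_threshold(pos, coverage, w, rng, design=design)
        tol = w / 2.0
        n_false = 0
        for _ in range(replicates):
            prof = simulate_freq_chromosome(pos, [chr_len_cm / 2.0], [qtl_freq],
                                            coverage, w, rng, design)
            fits = call_qtl(prof, design, coverage, w, gprime_threshold=thr)
            _, nf = _score_peaks(fits, [chr_len_cm / 2.0], tol)
            n_false += nf
        rows.append(dict(window_cm=float(w), false_peak_prob=n_false / replicates,
                         gprime_threshold=thr))
    return pd.DataFrame(rows)


def window_calibration_2qtl(distances_cm, seed, window_cm: float = 36.0,
                            replicates: int = 100, coverage: int = 5000,
                            qtl_freq: float = 0.6, chr_len_cm: float = 100.0,
                            density: float = 5.0,
                            design: str = "one_tailed") -> pd.DataFrame:
    """Merge and false-peak probabilities for two equal-frequency QTL at a
    range of inter-QTL distances, at a fixed smoothing window.

    ``merge_prob`` is the fraction of replicates where model selection
    returns exactly one peak where the truth has two; ``false_peak_prob``
    counts called peaks farther than half a window from both true QTL.
    """
    pos = _calibration_genome(chr_len_cm, density)
    for d in distances_cm:
        if d <= 0 or d >= chr_len_cm:
            raise ValueError("distances must fit inside the chromosome")
    rngs = spawn_rngs(seed, len(distances_cm) + 1)
    thr = calibration_threshold(pos, coverage, window_cm, rngs[-1], design=design)
    tol = window_cm / 2.0
    rows = []
    for d, rng in zip(distances_cm, rngs[:-1]):
        centers = [chr_len_cm / 2.0 - d / 2.0, chr_len_cm / 2.0 + d / 2.0]
        n_merge = n_false = 0
        for _ in range(replicates):
            prof = simulate_freq_chromosome(pos, centers, [qtl_freq, qtl_freq],
                                            coverage, window_cm, rng, design)
            fits = call_qtl(prof, design, coverage, window_cm,
                            gprime_threshold=thr)
            n_called, nf = _score_peaks(fits, centers, tol)
            n_false += nf
            if n_called == 1:
                n_merge += 1
        rows.append(dict(distance_cm=float(d), merge_prob=n_merge / replicates,
                         false_peak_prob=n_false / replicates,
                         gprime_threshold=thr))
    return pd.DataFrame(rows)
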