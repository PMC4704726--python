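"""Forward simulation of F2 bulked-segregant experiments.

The simulator emulates the generation of an F2 mapping population from a
cross of two inbred parents (A and B), truncation selection of phenotypic
bulks, and sequencing of pooled DNA:

* meiosis follows the Haldane model — crossovers per gamete per chromosome
  are Poisson with mean length/100 cM, placed uniformly, no interference.
  Gametes are generated with the exact Markov-chain representation of this
  process evaluated at the marker positions: the parental origin switches
  between adjacent markers with probability equal to the Haldane
  recombination fraction of the spacing;
* a spontaneous mutation flips an allele at gamete formation with
  probability ``mu`` (default 7.0e-9) independently per locus;
* phenotypes are the sum of an additive genotypic value over the QTL and a
  normal environmental deviate scaled to a target broad-sense heritability;
* bulks are the top/bottom (two-tailed) or top/random-control (one-tailed)
  fractions of the phenotype distribution;
* sequencing draws ``countA ~ Binomial(depth, p)`` per marker per bulk,
  where ``p`` is the bulk's true parent-A allele frequency.

All randomness flows through a :class:`numpy.random.Generator`; every public
function accepts either a generator or an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSpec

MUTATION_RATE = 7.0e-9

COUNT_COLUMNS = ["countA_bulk1", "countB_bulk1", "countA_bulk2", "countB_bulk2"]


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rngs(seed, n: int):
    """Derive ``n`` independent child generators from a root seed.

    Children are reproducible in isolation, so pipeline stages and grid
    cells can be re-run independently.
    """
    if isinstance(seed, np.random.Generator):
        return [np.random.default_rng(int(s))
                for s in seed.integers(0, 2**31, size=n)]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def haldane_r(d_cm):
    """Haldane map function: recombination fraction for a distance in cM."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be nonnegative")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


@dataclass(frozen=True)
class QTLModelTruth:
    """Additive QTL truth model: loci as (chrom, pos_cm, effect fraction).

    Effect fractions are each locus's share of the genotypic variance; they
    must be positive and sum to 1.  No dominance, no epistasis.
    """

    loci: tuple  # of (chrom: str, pos_cm: float, effect: float)

    def __post_init__(self):
        effects = np.array([e for _, _, e in self.loci], dtype=float)
        if effects.size == 0:
            raise ValueError("truth model needs at least one QTL")
        if np.any(effects <= 0):
            raise ValueError("effect sizes must be positive")
        if not np.isclose(effects.sum(), 1.0, atol=1e-8):
            raise ValueError("effect sizes must sum to 1")

    @property
    def effects(self):
        return np.array([e for _, _, e in self.loci], dtype=float)

    @classmethod
    def one_per_chromosome(cls, genome: GenomeSpec, effects, positions_cm=None):
        """Place one QTL per chromosome (default: at the chromosome middle).

        ``effects`` is a sequence of per-chromosome variance fractions, e.g.
        ``(0.7, 0.1, 0.1, 0.05, 0.05)`` or five equal ``0.2``.
        """
        if len(effects) != genome.n_chromosomes:
            raise ValueError("need one effect per chromosome")
        if positions_cm is None:
            positions_cm = [L / 2.0 for L in genome.chrom_lengths_cm]
        loci = tuple(
            (c, float(p), float(e))
            for c, p, e in zip(genome.chrom_names, positions_cm, effects)
        )
        return cls(loci)


@dataclass
class F2Population:
    """Simulated F2 genotypes (and, once assigned, phenotypes).

    ``doses`` holds the parent-A allele count in {0,1,2} per individual and
    marker, markers ordered as in ``genome.marker_table()``.
    """

    genome: GenomeSpec
    doses: np.ndarray  # (n, n_markers) uint8
    phenotypes: np.ndarray | None = None
    heritability: float | None = None
    qtl_marker_idx: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.doses.shape[0]

    def marker_slice(self, chrom) -> slice:
        """Column slice of ``doses`` for one chromosome."""
        start = 0
        for name, pos in zip(self.genome.chrom_names, self.genome.marker_pos_cm):
            m = len(pos)
            if name == chrom:
                return slice(start, start + m)
            start += m
        raise KeyError(chrom)


def snap_to_markers(genome: GenomeSpec, loci):
    """Global marker index of the marker nearest each (chrom, pos_cm) locus.

    Returns (indices, snap_distances_cm)."""
    idx, dist = [], []
    offset = {}
    start = 0
    for name, pos in zip(genome.chrom_names, genome.marker_pos_cm):
        offset[name] = (start, np.asarray(pos))
        start += len(pos)
    for chrom, pos_cm, *_ in loci:
        base, pos = offset[chrom]
        j = int(np.argmin(np.abs(pos - pos_cm)))
        idx.append(base + j)
        dist.append(abs(pos[j] - pos_cm))
    return np.array(idx, dtype=int), np.array(dist, dtype=float)


def _gametes(rng, n_gametes, pos_cm, mu):
    """Parental-origin alleles (0/1) for n gametes at the given marker
    positions of one chromosome, under the Haldane model."""
    m = len(pos_cm)
    alle = np.empty((n_gametes, m), dtype=np.uint8)
    alle[:, 0] = rng.integers(0, 2, size=n_gametes, dtype=np.uint8)
    if m > 1:
        r = haldane_r(np.diff(pos_cm))
        u = rng.random((n_gametes, m - 1), dtype=np.float32)
        alle[:, 1:] = u < r.astype(np.float32)
        np.bitwise_xor.accumulate(alle, axis=1, out=alle)
    if mu > 0:
        n_flip = rng.poisson(mu * alle.size)
        if n_flip:
            flat = rng.integers(0, alle.size, size=n_flip)
            alle.flat[flat] ^= 1
    return alle


def simulate_f2(genome: GenomeSpec, n: int, seed, mu: float = MUTATION_RATE) -> F2Population:
    """Simulate ``n`` F2 individuals: each is the union of two independent
    F1 gametes per chromosome.

    Parameters
    ----------
    genome : GenomeSpec
    n : int
        Population size (>= 1).
    seed : int or numpy.random.Generator
    mu : float
        Per-locus mutation (allele flip) probability at gamete formation.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = as_rng(seed)
    blocks = []
    for pos in genome.marker_pos_cm:
        g = _gametes(rng, 2 * n, np.asarray(pos), mu)
        blocks.append(g[:n] + g[n:])
    return F2Population(genome=genome, doses=np.concatenate(blocks, axis=1))


def assign_phenotypes(
    pop: F2Population, qtl: QTLModelTruth, h2: float, seed
) -> np.ndarray:
    """Assign phenotypes = genotypic value + normal environmental effect.

    The genotypic value is additive over the QTL with per-locus effect
    ``sqrt(effect fraction)`` on centred allele dose, so each QTL contributes
    its stated fraction of the genotypic variance.  The environmental
    variance is scaled from the realized genotypic variance to hit the
    target broad-sense heritability: ``Ve = Vg * (1 - h2) / h2``.  ``h2 = 0``
    yields a pure-noise phenotype with unit variance.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("heritability must lie in [0, 1]")
    rng = as_rng(seed)
    n = pop.n
    if h2 == 0.0:
        phen = rng.normal(0.0, 1.0, size=n)
        pop.phenotypes, pop.heritability = phen, h2
        return phen
    idx, _ = snap_to_markers(pop.genome, qtl.loci)
    pop.qtl_marker_idx = idx
    a = np.sqrt(qtl.effects)
    g = (pop.doses[:, idx].astype(float) - 1.0) @ a
    vg = g.var()
    if vg == 0:
        raise ValueError("degenerate genotypic variance (monomorphic QTL)")
    if h2 == 1.0:
        phen = g
    else:
        ve = vg * (1.0 - h2) / h2
        phen = g + rng.normal(0.0, np.sqrt(ve), size=n)
    pop.phenotypes, pop.heritability = phen, h2
    return phen


def select_bulks(phenotypes, scheme: str, fraction: float, seed):
    """Select bulk index sets by truncation on the phenotype.

    ``two_tailed`` returns (high, low); ``one_tailed`` returns (high,
    random-control drawn uniformly from the whole population).  Ties are
    broken by a random shuffle under the run's seed so bulk sizes are exact.
    """
    phen = np.asarray(phenotypes, dtype=float)
    n = phen.size
    if n == 0:
        raise ValueError("empty population")
    if not 0.0 < fraction <= 0.5:
        raise ValueError("bulk fraction must lie in (0, 0.5]")
    if scheme not in ("one_tailed", "two_tailed"):
        raise ValueError(f"unknown bulk scheme {scheme!r}")
    rng = as_rng(seed)
    k = max(1, int(round(n * fraction)))
    perm = rng.permutation(n)
    order = perm[np.argsort(phen[perm], kind="stable")]
    high = order[-k:]
    if scheme == "two_tailed":
        other = order[:k]
    else:
        other = rng.choice(n, size=k, replace=False)
    return high, other


def bulk_allele_freq(pop: F2Population, indices) -> np.ndarray:
    """True parent-A allele frequency of the bulk at every marker."""
    indices = np.asarray(indices)
    if indices.size == 0:
        raise ValueError("empty bulk")
    return pop.doses[indices].mean(axis=0) / 2.0


def sequence_bulk(
    pop: F2Population, indices, depth: int, seed, depth_model: str = "fixed"
) -> pd.DataFrame:
    """Draw sequencing read counts for one bulk.

    Per marker the bulk's true allele frequency ``p`` is the mean allele
    dose / 2 over bulk members; ``countA ~ Binomial(D, p)`` with ``D`` the
    nominal depth (``depth_model='fixed'``) or ``Poisson(depth)`` per marker
    (``depth_model='poisson'``, for coverage-dispersion checks).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = as_rng(seed)
    p = bulk_allele_freq(pop, indices)
    if depth_model == "fixed":
        d = np.full(p.size, int(depth))
    elif depth_model == "poisson":
        d = rng.poisson(depth, size=p.size)
    else:
        raise ValueError(f"unknown depth model {depth_model!r}")
    count_a = rng.binomial(d, p)
    tab = pop.genome.marker_table()
    tab["countA"] = count_a
    tab["countB"] = d - count_a
    return tab


def tally_bulk(pop: F2Population, indices) -> pd.DataFrame:
    """Exact allele tallies of the bulk (individual-genotyping mode):
    countA is the summed parent-A dose over bulk members."""
    indices = np.asarray(indices)
    if indices.size == 0:
        raise ValueError("empty bulk")
    count_a = pop.doses[indices].sum(axis=0, dtype=np.int64)
    tab = pop.genome.marker_table()
    tab["countA"] = count_a
    tab["countB"] = 2 * indices.size - count_a
    return tab


def combine_bulks(bulk1: pd.DataFrame, bulk2: pd.DataFrame) -> pd.DataFrame:
    """Merge two per-bulk count tables into the canonical wide BulkCounts
    table (bulk1 = high; bulk2 = low or control)."""
    if not bulk1["pos_cm"].equals(bulk2["pos_cm"]) or not bulk1["chrom"].equals(
        bulk2["chrom"]
    ):
        raise ValueError("bulk tables do not share a marker map")
    out = bulk1[[c for c in ("chrom", "pos_cm", "pos_bp") if c in bulk1]].copy()
    out["countA_bulk1"] = bulk1["countA"].to_numpy()
    out["countB_bulk1"] = bulk1["countB"].to_numpy()
    out["countA_bulk2"] = bulk2["countA"].to_numpy()
    out["countB_bulk2"] = bulk2["countB"].to_numpy()
    return out


def downsample_reads(counts: pd.DataFrame, factor: float, seed) -> pd.DataFrame:
    """Subsample reads without replacement (hypergeometric) per marker and
    bulk, retaining a ``factor`` fraction of the original total depth."""
    if not 0.0 < factor <= 1.0:
        raise ValueError("retention factor must lie in (0, 1]")
    rng = as_rng(seed)
    out = counts.copy()
    pairs = [(a, b) for a, b in zip(COUNT_COLUMNS[::2], COUNT_COLUMNS[1::2]) if a in counts]
    if not pairs and {"countA", "countB"} <= set(counts.columns):
        pairs = [("countA", "countB")]
    for ca, cb in pairs:
        a = counts[ca].to_numpy(dtype=np.int64)
        b = counts[cb].to_numpy(dtype=np.int64)
        total = a + b
        keep = np.round(total * factor).astype(np.int64)
        new_a = np.where(
            total > 0, rng.hypergeometric(np.maximum(a, 0), np.maximum(b, 0), np.minimum(keep, total)), 0
        )
        out[ca] = new_a
        out[cb] = np.minimum(keep, total) - new_a
    return out


def simulate_experiment(
    genome: GenomeSpec,
    qtl: QTLModelTruth,
    n: int,
    h2: float,
    scheme: str,
    depth,
    seed,
    bulk_fraction: float = 0.1,
    genotyping: bool = False,
    mu: float = MUTATION_RATE,
):
    """One full simulate -> phenotype -> select -> sequence chain.

    Returns ``(counts, pop)`` where ``counts`` is the wide BulkCounts table.
    With ``genotyping=True`` counts are exact allele tallies of the bulks
    (the individual-genotyping mode of the population-size panel) and
    ``depth`` is ignored.
    """
    rng = as_rng(seed)
    pop = simulate_f2(genome, n, rng, mu=mu)
    assign_phenotypes(pop, qtl, h2, rng)
    high, other = select_bulks(pop.phenotypes, scheme, bulk_fraction, rng)
    if genotyping:
        b1, b2 = tally_bulk(pop, high), tally_bulk(pop, other)
    else:
        b1 = sequence_bulk(pop, high, depth, rng)
        b2 = sequence_bulk(pop, other, depth, rng)
    return combine_bulks(b1, b2), pop
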