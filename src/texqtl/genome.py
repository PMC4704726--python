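"""Genome layout and genetic/physical coordinate maps.

A :class:`GenomeSpec` describes the marker scaffold that both the forward
simulator and the mapping statistics operate on: a set of chromosomes with
lengths in centimorgans (cM) and, per chromosome, a sorted vector of marker
positions in cM.  Physical (bp) coordinates are optional and, when present,
are tied to the genetic coordinates through a :class:`RecombMap`.

The default recombination map is uniform at 4 cM/Mb, which makes a 9 Mb
physical window equivalent to a 36 cM genetic window — the smoothing window
used throughout the G' pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: default uniform conversion, cM per Mb (9 Mb window == 36 cM window)
DEFAULT_CM_PER_MB = 4.0


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome and marker layout in genetic coordinates.

    Parameters
    ----------
    chrom_names : tuple of str
        Chromosome names, e.g. ``("chr1", ..., "chr5")``.
    chrom_lengths_cm : tuple of float
        Length of each chromosome in cM.
    marker_pos_cm : tuple of np.ndarray
        Per-chromosome sorted marker positions in cM.
    """

    chrom_names: tuple
    chrom_lengths_cm: tuple
    marker_pos_cm: tuple = field(repr=False)

    def __post_init__(self):
        if len(self.chrom_names) != len(self.chrom_lengths_cm) or len(
            self.chrom_names
        ) != len(self.marker_pos_cm):
            raise ValueError("chromosome name/length/marker lists must align")
        for name, length, pos in zip(
            self.chrom_names, self.chrom_lengths_cm, self.marker_pos_cm
        ):
            if length <= 0:
                raise ValueError(f"nonpositive length for {name}")
            pos = np.asarray(pos, dtype=float)
            if pos.size and (np.any(np.diff(pos) <= 0)):
                raise ValueError(f"marker positions not strictly increasing on {name}")
            if pos.size and (pos[0] < 0 or pos[-1] > length):
                raise ValueError(f"marker positions outside [0, {length}] on {name}")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_names)

    @property
    def n_markers(self) -> int:
        return int(sum(len(p) for p in self.marker_pos_cm))

    def marker_table(self, recomb_map: "RecombMap | None" = None) -> pd.DataFrame:
        """Flat marker table with columns ``chrom``, ``pos_cm`` (and ``pos_bp``
        when a recombination map is supplied)."""
        frames = []
        for name, pos in zip(self.chrom_names, self.marker_pos_cm):
            frames.append(pd.DataFrame({"chrom": name, "pos_cm": np.asarray(pos)}))
        tab = pd.concat(frames, ignore_index=True)
        if recomb_map is not None:
            tab["pos_bp"] = np.concatenate(
                [
                    recomb_map.cm_to_bp(name, np.asarray(pos))
                    for name, pos in zip(self.chrom_names, self.marker_pos_cm)
                ]
            ).astype(np.int64)
        return tab


def build_genome(
    n_chr: int, chr_len_cm: float, marker_density: float, names=None
) -> GenomeSpec:
    """Build a genome of ``n_chr`` chromosomes of ``chr_len_cm`` cM with
    evenly spaced markers at ``marker_density`` markers per cM.

    Markers sit at interval midpoints ``(i + 0.5) / density`` so that no
    marker coincides with a chromosome end; the marker count per chromosome
    is ``floor(chr_len_cm * marker_density)``.

    Examples
    --------
    >>> g = build_genome(5, 100, 5)
    >>> g.n_markers
    2500
    """
    if n_chr < 1:
        raise ValueError("n_chr must be >= 1")
    if chr_len_cm <= 0:
        raise ValueError("chr_len_cm must be > 0")
    if marker_density <= 0:
        raise ValueError("marker_density must be > 0")
    m = int(np.floor(chr_len_cm * marker_density))
    if m < 1:
        raise ValueError("marker density too low: zero markers per chromosome")
    spacing = 1.0 / marker_density
    pos = (np.arange(m) + 0.5) * spacing
    if names is None:
        names = tuple(f"chr{i + 1}" for i in range(n_chr))
    return GenomeSpec(
        chrom_names=tuple(names),
        chrom_lengths_cm=tuple([float(chr_len_cm)] * n_chr),
        marker_pos_cm=tuple(pos.copy() for _ in range(n_chr)),
    )


class RecombMap:
    """Monotone piecewise-linear map between physical (bp) and genetic (cM)
    coordinates, one table per chromosome.

    Parameters
    ----------
    tables : dict of str -> (ndarray, ndarray)
        Per chromosome, a pair of strictly increasing vectors ``(bp, cm)``.
    """

    def __init__(self, tables: dict):
        self.tables = {}
        for chrom, (bp, cm) in tables.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.size < 2:
                raise ValueError(f"recombination map for {chrom} needs >= 2 rows")
            if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) <= 0):
                raise ValueError(f"recombination map for {chrom} is not monotone")
            self.tables[chrom] = (bp, cm)

    @classmethod
    def uniform(cls, chrom_extents_bp: dict, cm_per_mb: float = DEFAULT_CM_PER_MB):
        """Uniform-rate map: ``cm = bp / 1e6 * cm_per_mb`` on each chromosome.

        ``chrom_extents_bp`` maps chromosome name to its bp length.
        """
        tables = {
            c: (np.array([0.0, L]), np.array([0.0, L / 1e6 * cm_per_mb]))
            for c, L in chrom_extents_bp.items()
        }
        return cls(tables)

    @classmethod
    def uniform_for_genome(
        cls, genome: GenomeSpec, cm_per_mb: float = DEFAULT_CM_PER_MB
    ):
        extents = {
            c: L / cm_per_mb * 1e6
            for c, L in zip(genome.chrom_names, genome.chrom_lengths_cm)
        }
        return cls.uniform(extents, cm_per_mb)

    def _require(self, chrom):
        if chrom not in self.tables:
            raise KeyError(f"no recombination map for chromosome {chrom!r}")
        return self.tables[chrom]

    def bp_to_cm(self, chrom, bp):
        xb, xc = self._require(chrom)
        return np.interp(np.asarray(bp, dtype=float), xb, xc)

    def cm_to_bp(self, chrom, cm):
        xb, xc = self._require(chrom)
        return np.interp(np.asarray(cm, dtype=float), xc, xb)
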