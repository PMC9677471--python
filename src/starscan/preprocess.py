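"""Variant filtering and sliding-window construction.

Two site filters run before scoring:

* ``filter_fixed_derived`` removes variants whose derived allele is fixed in
  *both* the reference and the target population. Such sites are shared
  ancestral-state differences and carry no signal for introgression scanning.
* ``drop_monomorphic`` removes sites with no derived allele in reference and
  target combined; they only inflate per-window mutation counts.

Source-panel genotypes are never consulted by either filter.

Windows are 0-based half-open intervals. A site with 1-based position ``p``
belongs to window ``[start, end)`` iff ``start <= p - 1 < end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix, PopulationAssignment

__all__ = [
    "Window",
    "RecombMap",
    "filter_fixed_derived",
    "drop_monomorphic",
    "make_windows",
    "assign_sites",
    "windows_for_matrix",
    "local_recomb_rate",
]


@dataclass
class Window:
    """Half-open genomic interval plus the site rows it contains."""

    chrom: str
    start: int
    end: int
    site_indices: np.ndarray = field(default_factory=lambda: np.empty(0, np.intp))
    partial: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def filter_fixed_derived(gm: GenotypeMatrix,
                         assignment: PopulationAssignment) -> GenotypeMatrix:
    """Remove sites fixed for the derived allele in both reference and target.

    A site is removed iff its derived count equals ``2 * |reference|`` among
    reference individuals *and* ``2 * |target|`` among target individuals.
    Fixation in only one of the two panels retains the site. Order preserved.
    """
    if gm.n_sites == 0:
        return gm
    ref = gm.sample_indices(assignment.reference_ids)
    tgt = gm.sample_indices(assignment.target_ids)
    fixed_ref = gm.G[:, ref].sum(axis=1) == 2 * len(ref)
    fixed_tgt = gm.G[:, tgt].sum(axis=1) == 2 * len(tgt)
    return gm.take_sites(~(fixed_ref & fixed_tgt))


def drop_monomorphic(gm: GenotypeMatrix,
                     assignment: PopulationAssignment) -> GenotypeMatrix:
    """Remove sites with zero derived alleles across reference and target."""
    if gm.n_sites == 0:
        return gm
    idx = gm.sample_indices(assignment.reference_ids
                            + assignment.target_ids)
    return gm.take_sites(gm.G[:, idx].sum(axis=1) > 0)


def make_windows(chrom_length: int, window_size: int = 50_000,
                 step: int = 10_000, chrom: str = "1") -> list[Window]:
    """Sliding windows of length ``window_size`` at every ``step`` bp.

    Full-length windows are emitted at starts 0, step, 2*step, ... while
    ``start + window_size <= chrom_length``. If the chromosome tail is not
    covered (chrom_length not aligned to the step, or shorter than one
    window), one final partial window ``[next_start, chrom_length)`` is
    appended and flagged, so every base is covered by at least one window.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if step <= 0 or step > window_size:
        raise ValueError("step must satisfy 0 < step <= window_size "
                         "(larger steps would leave uncovered gaps)")
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    windows: list[Window] = []
    start = 0
    while start + window_size <= chrom_length:
        windows.append(Window(chrom, start, start + window_size))
        start += step
    covered = windows[-1].end if windows else 0
    if covered < chrom_length:
        windows.append(Window(chrom, start, chrom_length, partial=True))
    return windows


def assign_sites(windows: list[Window], gm: GenotypeMatrix) -> list[Window]:
    """Fill each window's ``site_indices`` from the matrix (per chromosome)."""
    for w in windows:
        mask = gm.chrom_mask(w.chrom)
        rows = np.flatnonzero(mask)
        p0 = gm.pos[rows] - 1  # 0-based
        lo = np.searchsorted(p0, w.start, side="left")
        hi = np.searchsorted(p0, w.end, side="left")
        w.site_indices = rows[lo:hi]
    return windows


def windows_for_matrix(gm: GenotypeMatrix, chrom_lengths: dict[str, int],
                       window_size: int = 50_000,
                       step: int = 10_000) -> list[Window]:
    """Build windows for every chromosome in the matrix and assign sites."""
    windows: list[Window] = []
    for chrom in gm.chromosomes():
        if chrom not in chrom_lengths:
            raise ValueError(f"no length given for chromosome {chrom!r}")
        windows.extend(make_windows(chrom_lengths[chrom], window_size, step,
                                    chrom=chrom))
    return assign_sites(windows, gm)


class RecombMap:
    """Piecewise-constant recombination map (per-bp per-generation rates).

    Built from non-overlapping 0-based half-open intervals per chromosome.
    A plain scalar rate can be used anywhere a map is accepted.
    """

    def __init__(self, intervals: dict[str, np.ndarray]):
        # intervals[chrom] is an (n, 3) float array of (start, end, rate)
        self.intervals = {}
        for chrom, arr in intervals.items():
            arr = np.asarray(arr, dtype=float)
            arr = arr[np.argsort(arr[:, 0])]
            if np.any(arr[:, 1] <= arr[:, 0]):
                raise ValueError(f"empty or inverted interval on {chrom}")
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError(f"overlapping intervals on {chrom}")
            if np.any(arr[:, 2] < 0):
                raise ValueError("negative recombination rate")
            self.intervals[chrom] = arr

    @classmethod
    def from_tsv(cls, path) -> "RecombMap":
        """Read a headerless TSV ``chrom<TAB>start<TAB>end<TAB>rate``."""
        intervals: dict[str, list] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns")
                chrom, start, end, rate = parts
                intervals.setdefault(chrom, []).append(
                    (float(start), float(end), float(rate)))
        return cls({c: np.array(v) for c, v in intervals.items()})

    def mean_rate(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean rate over ``[start, end)``."""
        if chrom not in self.intervals:
            raise ValueError(f"chromosome {chrom!r} not in recombination map")
        arr = self.intervals[chrom]
        if start < arr[0, 0] or end > arr[-1, 1]:
            raise ValueError(
                f"window [{start}, {end}) extends beyond map support "
                f"[{arr[0, 0]:.0f}, {arr[-1, 1]:.0f}) on {chrom}")
        overlap = np.minimum(arr[:, 1], end) - np.maximum(arr[:, 0], start)
        overlap = np.clip(overlap, 0, None)
        total = overlap.sum()
        if total < end - start:
            raise ValueError(
                f"window [{start}, {end}) not fully covered by map on {chrom}")
        return float((overlap * arr[:, 2]).sum() / total)


def local_recomb_rate(window: Window, recomb) -> float:
    """Mean recombination rate over a window; scalar maps return the scalar."""
    if isinstance(recomb, RecombMap):
        return recomb.mean_rate(window.chrom, window.start, window.end)
    rate = float(recomb)
    if rate < 0:
        raise ValueError("negative recombination rate")
    return rate
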