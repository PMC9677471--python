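"""The S* statistic: maximal-scoring chains of target-private derived variants.

S* searches a window for a chain of derived variants, private to one target
individual relative to the reference panel, that look like a single diverged
haplotype: mutually consistent genotypes spread over physical distance. Each
consecutive pair in a chain is scored (long matching pairs score high, small
genotype mismatches pay a fixed penalty, incompatible pairs are forbidden) and
S* is the best total over all increasing chains, floored at zero.

The dynamic program is exact: ``S(j) = max_{i<j} max(S(i) + s(i, j), s(i, j))``
with ``S* = max(0, max_j S(j))``. Ties between equal-scoring chains are broken
toward the lexicographically smallest position sequence so results are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PopulationAssignment
from .preprocess import Window

__all__ = [
    "ScoreFunctionParams",
    "CandidateSiteSet",
    "SStarWindowScore",
    "candidate_sites",
    "pair_score",
    "compute_sstar",
    "sstar_scan",
]

NEG_INF = -math.inf


@dataclass(frozen=True)
class ScoreFunctionParams:
    """Constants of the pairwise chain score.

    ``match_bonus`` is added to the bp distance for a genotype-identical pair
    at least ``min_bp_dist`` apart; identical pairs closer than that are
    forbidden (they carry no linkage information and would let dense clusters
    dominate). A pair differing by 1..``max_geno_dist`` derived copies pays
    ``mismatch_penalty``; larger differences are forbidden. The defaults are
    the long-standing S* convention; alternative conventions are configuration.
    """

    match_bonus: int = 5000
    mismatch_penalty: int = -10000
    min_bp_dist: int = 10
    max_geno_dist: int = 5

    def __post_init__(self) -> None:
        if self.match_bonus <= 0:
            raise ValueError("match_bonus must be positive")
        if self.mismatch_penalty >= 0:
            raise ValueError("mismatch_penalty must be negative")
        if self.min_bp_dist < 0:
            raise ValueError("min_bp_dist must be >= 0")


@dataclass
class CandidateSiteSet:
    """Candidate variants for one individual in one window.

    Candidates are sites where the focal target individual carries at least
    one derived allele and the reference panel carries none (optionally up to
    ``ref_max_daf`` as a frequency allowance).
    """

    individual: str
    window: Window
    site_indices: np.ndarray  # rows into the genotype matrix, position order
    positions: np.ndarray     # 1-based positions of those rows
    genotypes: np.ndarray     # focal individual's derived codes at those rows


@dataclass
class SStarWindowScore:
    """S* for one (individual, window) pair."""

    individual: str
    chrom: str
    start: int
    end: int
    sstar: float
    n_candidates: int
    chain: tuple[int, ...]          # 1-based positions attaining the maximum
    n_snps_window: int              # all surviving sites in the window


def candidate_sites(gm: GenotypeMatrix, assignment: PopulationAssignment,
                    window: Window, individual: str,
                    ref_max_daf: float = 0.0) -> CandidateSiteSet:
    """Select the focal individual's candidate variants within a window."""
    if individual not in assignment.target_ids:
        raise ValueError(f"{individual!r} is not in the target population")
    ref = gm.sample_indices(assignment.reference_ids)
    focal = gm.sample_index(individual)
    rows = window.site_indices
    ref_count = gm.G[rows][:, ref].sum(axis=1)
    max_ref = int(ref_max_daf * 2 * len(ref))
    keep = (gm.G[rows, focal] >= 1) & (ref_count <= max_ref)
    rows = rows[keep]
    return CandidateSiteSet(individual, window, rows, gm.pos[rows],
                            gm.G[rows, focal])


def pair_score(pos_i: int, pos_j: int, g_i: int, g_j: int,
               params: ScoreFunctionParams = ScoreFunctionParams()) -> float:
    """Score one ordered pair of candidate sites (-inf = forbidden)."""
    if pos_j <= pos_i:
        raise ValueError(f"positions must increase: {pos_i} !< {pos_j}")
    d = pos_j - pos_i
    gd = abs(int(g_i) - int(g_j))
    if gd == 0:
        return d + params.match_bonus if d >= params.min_bp_dist else NEG_INF
    if gd <= params.max_geno_dist:
        return params.mismatch_penalty
    return NEG_INF


def compute_sstar(candidates: CandidateSiteSet,
                  params: ScoreFunctionParams = ScoreFunctionParams(),
                  n_snps_window: int | None = None) -> SStarWindowScore:
    """Exact S* by dynamic programming over the candidate sites.

    Chains may start at any candidate; chains shorter than two sites score 0.
    Among equal-scoring maximal chains the lexicographically smallest position
    sequence is returned.
    """
    pos = candidates.positions
    gen = candidates.genotypes
    k = len(pos)
    w = candidates.window
    nsnps = len(w.site_indices) if n_snps_window is None else n_snps_window
    best_score = 0.0
    best_chain: tuple[int, ...] = ()
    if k >= 2:
        # ending[j] = (score, chain) of the best chain ending at candidate j
        ending: list[tuple[float, tuple[int, ...]] | None] = [None] * k
        for j in range(1, k):
            bj: tuple[float, tuple[int, ...]] | None = None
            for i in range(j):
                sij = pair_score(int(pos[i]), int(pos[j]), gen[i], gen[j], params)
                if sij == NEG_INF:
                    continue
                options = [(sij, (int(pos[i]), int(pos[j])))]
                if ending[i] is not None:
                    si, ci = ending[i]
                    options.append((si + sij, ci + (int(pos[j]),)))
                for sc, ch in options:
                    if bj is None or sc > bj[0] or (sc == bj[0] and ch < bj[1]):
                        bj = (sc, ch)
            ending[j] = bj
            if bj is not None and (bj[0] > best_score
                                   or (bj[0] == best_score and
                                       (not best_chain or bj[1] < best_chain))):
                best_score, best_chain = bj
    if best_score <= 0:
        best_score, best_chain = 0.0, ()
    return SStarWindowScore(candidates.individual, w.chrom, w.start, w.end,
                            float(best_score), k, best_chain, nsnps)


def sstar_scan(gm: GenotypeMatrix, assignment: PopulationAssignment,
               windows: list[Window],
               params: ScoreFunctionParams = ScoreFunctionParams(),
               ref_max_daf: float = 0.0) -> pd.DataFrame:
    """Score every target individual in every window.

    Returns a DataFrame with one row per (window, individual):
    chrom, start, end, sample, sstar, n_candidates, n_snps_window, chain
    (comma-joined 1-based positions). Deterministic given its inputs.
    """
    rows = []
    for w in windows:
        for ind in assignment.target_ids:
            cand = candidate_sites(gm, assignment, w, ind, ref_max_daf)
            sc = compute_sstar(cand, params)
            rows.append((sc.chrom, sc.start, sc.end, ind, sc.sstar,
                         sc.n_candidates, sc.n_snps_window,
                         ",".join(str(p) for p in sc.chain)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample",
                                       "sstar", "n_candidates",
                                       "n_snps_window", "chain"])
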