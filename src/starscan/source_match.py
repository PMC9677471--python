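"""Tract assembly and source-match-rate attribution of candidate fragments.

Flagged windows are merged into maximal candidate tracts per individual. When
one or two source genomes are available, each tract's *source match rate* is
the fraction of its informative sites — the focal individual's candidate
derived variants inside the tract — at which the source panel also carries at
least one derived allele. With two sources, the tract is attributed to the
source with the higher match rate (ties, or rates within the configured
margin, are ambiguous; an empty denominator is unknown).

Sources are exempt from the reference/target fixed-derived filter; since
informative sites are target-private candidates, they always survive the
standard preprocessing, so match rates can be computed on the filtered matrix
as long as source columns were carried along.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._intervals import merge_intervals
from .genotype_io import GenotypeMatrix, PopulationAssignment

__all__ = [
    "MatchRateRecord",
    "SourceAssignment",
    "merge_windows_to_tracts",
    "match_rate",
    "assign_source",
    "attribute_tracts",
]


@dataclass
class MatchRateRecord:
    individual: str
    chrom: str
    start: int
    end: int
    source: str
    n_informative: int
    n_matched: int

    @property
    def rate(self) -> float | None:
        if self.n_informative == 0:
            return None
        return self.n_matched / self.n_informative


@dataclass
class SourceAssignment:
    individual: str
    chrom: str
    start: int
    end: int
    rates: dict[str, float | None]
    verdict: str  # one of the source labels, "ambiguous", or "unknown"


def merge_windows_to_tracts(calls: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Union flagged windows into maximal candidate tracts per individual.

    ``calls`` is a `call_outliers` table; only rows with ``is_outlier`` are
    used. Overlapping or book-ended windows (gap <= ``gap``) merge. Returns a
    DataFrame (chrom, start, end, sample) sorted by sample then position.
    """
    flagged = calls.loc[calls["is_outlier"]]
    rows = []
    for (sample, chrom), grp in flagged.groupby(["sample", "chrom"], sort=True):
        for a, b in merge_intervals(zip(grp["start"], grp["end"]), gap=gap):
            rows.append((chrom, a, b, sample))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample"])


def _informative_mask(gm: GenotypeMatrix, assignment: PopulationAssignment,
                      individual: str, chrom: str, start: int, end: int,
                      ref_max_daf: float, chain_positions=None) -> np.ndarray:
    ref = gm.sample_indices(assignment.reference_ids)
    focal = gm.sample_index(individual)
    max_ref = int(ref_max_daf * 2 * len(ref))
    mask = (gm.chrom_mask(chrom) & (gm.pos - 1 >= start) & (gm.pos - 1 < end)
            & (gm.G[:, focal] >= 1)
            & (gm.G[:, ref].sum(axis=1) <= max_ref))
    if chain_positions is not None:
        mask &= np.isin(gm.pos, np.asarray(list(chain_positions)))
    return mask


def match_rate(gm: GenotypeMatrix, assignment: PopulationAssignment,
               individual: str, tract: tuple[str, int, int], source: str,
               site_policy: str = "candidates", ref_max_daf: float = 0.0,
               chain_positions=None) -> MatchRateRecord:
    """Source match rate of one tract for one source panel.

    ``site_policy`` selects the denominator: ``"candidates"`` (default) uses
    all candidate sites in the tract; ``"chain"`` restricts to the supplied
    S*-chain positions. A site is matched when *any* individual of the source
    panel carries a derived allele (presence semantics — archaic panels are
    typically a single genome).
    """
    if source not in assignment.sources:
        raise ValueError(f"unknown source population {source!r}")
    if site_policy not in ("candidates", "chain"):
        raise ValueError("site_policy must be 'candidates' or 'chain'")
    if site_policy == "chain" and chain_positions is None:
        raise ValueError("site_policy='chain' requires chain_positions")
    chrom, start, end = tract
    if end <= start:
        raise ValueError("empty tract")
    mask = _informative_mask(
        gm, assignment, individual, chrom, start, end, ref_max_daf,
        chain_positions if site_policy == "chain" else None)
    src_idx = gm.sample_indices(assignment.sources[source])
    rows = np.flatnonzero(mask)
    matched = int((gm.G[rows][:, src_idx].max(axis=1) >= 1).sum()) if len(rows) \
        else 0
    return MatchRateRecord(individual, chrom, start, end, source,
                           int(len(rows)), matched)


def assign_source(rec1: MatchRateRecord, rec2: MatchRateRecord,
                  margin: float = 0.0) -> SourceAssignment:
    """Attribute a tract by comparing two sources' match rates.

    Verdict is the source whose rate exceeds the other's by more than
    ``margin``; within the margin (including exact ties) → "ambiguous";
    either rate undefined → "unknown".
    """
    if (rec1.individual, rec1.chrom, rec1.start, rec1.end) != \
            (rec2.individual, rec2.chrom, rec2.start, rec2.end):
        raise ValueError("match-rate records refer to different tracts")
    rates = {rec1.source: rec1.rate, rec2.source: rec2.rate}
    if rec1.rate is None or rec2.rate is None:
        verdict = "unknown"
    elif rec1.rate > rec2.rate + margin:
        verdict = rec1.source
    elif rec2.rate > rec1.rate + margin:
        verdict = rec2.source
    else:
        verdict = "ambiguous"
    return SourceAssignment(rec1.individual, rec1.chrom, rec1.start, rec1.end,
                            rates, verdict)


def attribute_tracts(gm: GenotypeMatrix, assignment: PopulationAssignment,
                     tracts: pd.DataFrame, site_policy: str = "candidates",
                     ref_max_daf: float = 0.0,
                     margin: float = 0.0) -> pd.DataFrame:
    """Match rates (and verdicts when two sources exist) for a tract table.

    Returns one row per tract x source with columns chrom, start, end, sample,
    source, n_informative, n_matched, rate, verdict.
    """
    sources = list(assignment.sources)
    if not sources:
        raise ValueError("no source populations declared")
    rows = []
    for t in tracts.itertuples():
        tract = (t.chrom, int(t.start), int(t.end))
        recs = [match_rate(gm, assignment, t.sample, tract, s, site_policy,
                           ref_max_daf) for s in sources]
        if len(recs) == 2:
            verdict = assign_source(recs[0], recs[1], margin).verdict
        else:
            verdict = recs[0].source if recs[0].rate is not None else "unknown"
        for r in recs:
            rows.append((r.chrom, r.start, r.end, r.individual, r.source,
                         r.n_informative, r.n_matched,
                         np.nan if r.rate is None else r.rate, verdict))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample",
                                       "source", "n_informative", "n_matched",
                                       "rate", "verdict"])
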