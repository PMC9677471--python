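"""Simulation benchmark: introgression scenarios with recorded true tracts.

This module generates the study conditions used throughout the test suite and
the worked examples: a two-population null, a ghost-introgression scenario
(3% pulse from an unsampled donor that diverged an order of magnitude deeper
than the reference/target split), and a two-source scenario with two sampled
donor genomes. True introgressed segments are read off the simulator's
migration records (a lineage that sits in the donor population at the pulse
time), merged per diploid individual as the union of its two haplotype
tracts, and labeled by donor — the ground truth for base-pair-level
precision/recall.

All toy demographies use a constant effective size of 10,000 diploids, a
reference/target split 2,000 generations ago, donor splits 20,000 (ghost /
source 1) and 12,000 (source 2) generations ago, and recent pulses (50
generations) of a few percent — deliberately small models; full published
demographies can be supplied as Demes YAML files instead.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import demes

from ._intervals import intersect_length, merge_intervals, total_length
from ._simtools import load_graph, matrix_from_ts, score_matrix, simulate_ts
from .genotype_io import GenotypeMatrix, PopulationAssignment
from .null_model import ExpectedScoreModel, call_outliers
from .sstar_core import ScoreFunctionParams
from .source_match import merge_windows_to_tracts

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "PRPoint",
    "builtin_model",
    "BUILTIN_MODELS",
    "null_counterpart",
    "simulate_with_truth",
    "assignment_for",
    "score_simulation",
    "precision_recall",
    "f1",
    "baseline",
    "pr_curve",
    "make_fixture",
    "truth_to_bed",
    "tracts_to_bed",
]

_N = 10_000          # constant diploid effective size of every toy deme
_SPLIT_RT = 2_000    # reference/target split (generations ago)
_SPLIT_DEEP = 20_000  # ghost / source-1 divergence
_SPLIT_SRC2 = 12_000  # source-2 divergence
_PULSE_TIME = 50


def _two_pop_null() -> demes.Graph:
    b = demes.Builder(time_units="generations")
    b.add_deme("anc", epochs=[dict(start_size=_N, end_time=_SPLIT_RT)])
    b.add_deme("ref", ancestors=["anc"], epochs=[dict(start_size=_N)])
    b.add_deme("tgt", ancestors=["anc"], epochs=[dict(start_size=_N)])
    return b.resolve()


def _ghost(pulse_prop: float = 0.03) -> demes.Graph:
    # tgt bottlenecks at the split, so the constant-size approximate null is
    # a genuine approximation of this history rather than an exact match
    b = demes.Builder(time_units="generations")
    b.add_deme("anc", epochs=[dict(start_size=_N, end_time=_SPLIT_DEEP)])
    b.add_deme("ghost", ancestors=["anc"], epochs=[dict(start_size=_N)])
    b.add_deme("anc_rt", ancestors=["anc"],
               epochs=[dict(start_size=_N, end_time=_SPLIT_RT)])
    b.add_deme("ref", ancestors=["anc_rt"], epochs=[dict(start_size=_N)])
    b.add_deme("tgt", ancestors=["anc_rt"], epochs=[dict(start_size=_N // 2)])
    b.add_pulse(sources=["ghost"], dest="tgt", time=_PULSE_TIME,
                proportions=[pulse_prop])
    return b.resolve()


def _two_source(prop1: float = 0.03, prop2: float = 0.03) -> demes.Graph:
    b = demes.Builder(time_units="generations")
    b.add_deme("anc", epochs=[dict(start_size=_N, end_time=_SPLIT_DEEP)])
    b.add_deme("anc_src", ancestors=["anc"],
               epochs=[dict(start_size=_N, end_time=_SPLIT_SRC2)])
    b.add_deme("src1", ancestors=["anc_src"], epochs=[dict(start_size=_N)])
    b.add_deme("src2", ancestors=["anc_src"], epochs=[dict(start_size=_N)])
    b.add_deme("anc_rt", ancestors=["anc"],
               epochs=[dict(start_size=_N, end_time=_SPLIT_RT)])
    b.add_deme("ref", ancestors=["anc_rt"], epochs=[dict(start_size=_N)])
    b.add_deme("tgt", ancestors=["anc_rt"], epochs=[dict(start_size=_N)])
    b.add_pulse(sources=["src1"], dest="tgt", time=_PULSE_TIME + 10,
                proportions=[prop1])
    b.add_pulse(sources=["src2"], dest="tgt", time=_PULSE_TIME,
                proportions=[prop2])
    return b.resolve()


BUILTIN_MODELS = {
    "null": _two_pop_null,
    "ghost": _ghost,
    "two-source": _two_source,
}


def builtin_model(name: str, **kwargs) -> demes.Graph:
    """Return a built-in toy demography by id (see ``BUILTIN_MODELS``)."""
    try:
        return BUILTIN_MODELS[name](**kwargs)
    except KeyError:
        raise ValueError(
            f"unknown built-in model {name!r}; "
            f"available: {sorted(BUILTIN_MODELS)}") from None


def null_counterpart(model, keep_demes=None) -> demes.Graph:
    """Strip all pulses (and migrations into any deme) from a demography.

    With ``keep_demes``, additionally restrict the graph to those demes and
    their ancestors — the "only reference and target" approximate null.
    """
    graph = load_graph(model)
    d = graph.asdict_simplified()
    d.pop("pulses", None)
    d.pop("migrations", None)
    if keep_demes is not None:
        keep = set(keep_demes)
        changed = True
        while changed:  # close over ancestors
            changed = False
            for deme in d["demes"]:
                if deme["name"] in keep:
                    for a in deme.get("ancestors", []):
                        if a not in keep:
                            keep.add(a)
                            changed = True
        d["demes"] = [deme for deme in d["demes"] if deme["name"] in keep]
        for deme in d["demes"]:
            deme["ancestors"] = [a for a in deme.get("ancestors", [])
                                 if a in keep]
            if not deme["ancestors"]:
                deme.pop("ancestors", None)
                deme.pop("proportions", None)
                deme.pop("start_time", None)
                if deme["epochs"]:
                    deme["epochs"][0].pop("start_time", None)
    return demes.Graph.fromdict(d)


@dataclass
class SimulationConfig:
    """One introgression simulation: model, samples, genome, rates, seed."""

    model: object = "ghost"          # builtin id, demes.Graph, YAML path/string
    samples: dict[str, int] = field(default_factory=lambda: {"ref": 10,
                                                             "tgt": 10})
    seq_len: int = 1_000_000
    mu: float = 1.25e-8
    recomb_rate: float = 1e-8
    seed: int = 1
    tgt_pop: str = "tgt"

    def graph(self) -> demes.Graph:
        if isinstance(self.model, str) and self.model in BUILTIN_MODELS:
            return builtin_model(self.model)
        return load_graph(self.model)


@dataclass
class SimulationResult:
    matrix: GenotypeMatrix
    populations: dict[str, list[str]]   # population name -> sample ids
    truth: pd.DataFrame                 # chrom, start, end, sample, donor
    config: SimulationConfig


def _pulse_donors(graph: demes.Graph, tgt_pop: str):
    return [(pulse.sources[0], pulse.time) for pulse in graph.pulses
            if pulse.dest == tgt_pop]


def _extract_truth(ts, graph, tgt_pop: str, sample_names, chrom="1"):
    """Donor-ancestry tracts per diploid target individual.

    A haplotype segment is introgressed from donor D iff its lineage sits in D
    at the pulse time, i.e. there is a migration record into D at that time
    covering the segment with the haplotype below the migrating node.
    """
    pop_names = {p.id: p.metadata.get("name", str(p.id))
                 for p in ts.populations()}
    name_to_id = {v: k for k, v in pop_names.items()}
    donors = _pulse_donors(graph, tgt_pop)
    donor_ids = {name_to_id[d]: (d, t) for d, t in donors}

    node_owner = {}   # sample node -> (individual sample name)
    for k, ind in enumerate(ts.individuals()):
        pop = pop_names[ts.node(ind.nodes[0]).population]
        if pop == tgt_pop:
            for n in ind.nodes:
                node_owner[n] = sample_names[k]

    migs = [m for m in ts.migrations()
            if m.dest in donor_ids
            and np.isclose(m.time, donor_ids[m.dest][1])]
    spans = defaultdict(list)  # (sample, donor) -> [(start, end)]
    for tree in ts.trees():
        left, right = tree.interval
        for m in migs:
            if m.right <= left or m.left >= right:
                continue
            lo, hi = int(max(left, m.left)), int(min(right, m.right))
            donor = donor_ids[m.dest][0]
            if m.node in node_owner:
                spans[(node_owner[m.node], donor)].append((lo, hi))
            else:
                for leaf in tree.leaves(m.node):
                    if leaf in node_owner:
                        spans[(node_owner[leaf], donor)].append((lo, hi))
    rows = []
    for (sample, donor), ivs in spans.items():
        for a, b in merge_intervals(ivs):
            rows.append((chrom, a, b, sample, donor))
    truth = pd.DataFrame(rows, columns=["chrom", "start", "end", "sample",
                                        "donor"])
    return truth.sort_values(["sample", "chrom", "start"],
                             ignore_index=True)


def simulate_with_truth(cfg: SimulationConfig) -> SimulationResult:
    """Simulate an introgression scenario and record the true tracts.

    The model must contain at least one pulse into the target population
    (use `starscan.null_model.simulate_null` for introgression-free data).
    Deterministic given ``cfg.seed``.
    """
    graph = cfg.graph()
    if not _pulse_donors(graph, cfg.tgt_pop):
        raise ValueError(
            f"model has no pulse into target {cfg.tgt_pop!r}; for null "
            "(no-introgression) data use simulate_null instead")
    ts = simulate_ts(graph, cfg.samples, cfg.seq_len, cfg.mu, cfg.recomb_rate,
                     cfg.seed, record_migrations=True)
    gm, by_pop = matrix_from_ts(ts)
    sample_names = gm.samples  # individual order matches ts.individuals()
    truth = _extract_truth(ts, graph, cfg.tgt_pop, sample_names)
    return SimulationResult(gm, by_pop, truth, cfg)


def assignment_for(result: SimulationResult,
                   ref_pop: str = "ref") -> PopulationAssignment:
    """Population assignment for a simulation (sampled donors become sources)."""
    donors = [d for d, _ in _pulse_donors(result.config.graph(),
                                          result.config.tgt_pop)]
    sources = {d: result.populations[d] for d in donors
               if d in result.populations}
    return PopulationAssignment(result.populations[ref_pop],
                                result.populations[result.config.tgt_pop],
                                sources)


def score_simulation(result: SimulationResult,
                     window_size: int = 50_000, step: int = 10_000,
                     params: ScoreFunctionParams = ScoreFunctionParams(),
                     ref_max_daf: float = 0.0, ref_pop: str = "ref"):
    """Standard preprocessing + S* scan of a simulated dataset.

    Returns ``(scores DataFrame, filtered GenotypeMatrix, assignment)``; the
    filtered matrix retains source columns for match-rate attribution.
    """
    assignment = assignment_for(result, ref_pop)
    scores, gm = score_matrix(result.matrix, assignment,
                              int(result.config.seq_len), window_size, step,
                              params, ref_max_daf)
    scores["recomb_rate"] = result.config.recomb_rate
    return scores, gm, assignment


def _by_sample(df: pd.DataFrame) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for t in df.itertuples():
        out[t.sample].append((int(t.start), int(t.end)))
    return out


def precision_recall(called: pd.DataFrame, truth: pd.DataFrame):
    """Base-pair precision and recall, pooled over individuals.

    precision = |called ∩ truth| / |called|, recall = |called ∩ truth| /
    |truth|, with lengths summed over individuals. No called bases →
    precision is undefined (NaN) and recall is 0.
    """
    called_by = _by_sample(called)
    truth_by = _by_sample(truth)
    tp = sum(intersect_length(called_by.get(s, []), truth_by.get(s, []))
             for s in set(called_by) | set(truth_by))
    n_called = sum(total_length(v) for v in called_by.values())
    n_truth = sum(total_length(v) for v in truth_by.values())
    precision = tp / n_called if n_called else float("nan")
    recall = tp / n_truth if n_truth else 0.0
    return precision, recall


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def baseline(truth: pd.DataFrame, genome_size: int, n_individuals: int) -> float:
    """Random-classifier precision: the true introgressed proportion."""
    n_truth = sum(total_length(v) for v in _by_sample(truth).values())
    return n_truth / (n_individuals * genome_size)


@dataclass
class PRPoint:
    cutoff: float
    precision: float
    recall: float
    f1: float


def pr_curve(scores: pd.DataFrame, model: ExpectedScoreModel,
             truth: pd.DataFrame, q_grid=(0.9, 0.95, 0.99), *,
             recomb=None, gap: int = 0) -> list[PRPoint]:
    """Sweep the quantile cutoff: flag, merge to tracts, score against truth."""
    points = []
    for q in q_grid:
        calls = call_outliers(scores, model, q, recomb=recomb)
        tracts = merge_windows_to_tracts(calls, gap=gap)
        p, r = precision_recall(tracts, truth)
        points.append(PRPoint(q, p, r,
                              f1(p, r) if not np.isnan(p) else float("nan")))
    return points


def truth_to_bed(truth: pd.DataFrame, path) -> None:
    """Write true tracts as BED: chrom, start, end, sample, donor."""
    truth.to_csv(path, sep="\t", header=False, index=False,
                 columns=["chrom", "start", "end", "sample", "donor"])


def tracts_to_bed(tracts: pd.DataFrame, path, name_col: str = "sample") -> None:
    tracts.to_csv(path, sep="\t", header=False, index=False,
                  columns=["chrom", "start", "end", name_col])


def make_fixture(kind: str, seed: int = 0):
    """Tiny hand-constructed datasets with known expected outputs.

    Kinds: ``filter_demo`` (one jointly fixed-derived site to remove),
    ``sstar_demo`` (three candidates at 100/105/9000 whose exhaustive-best
    chain scores 13900), ``matchrate_demo`` (four informative sites of which
    the source matches three: rate 0.75). Returns
    ``(GenotypeMatrix, PopulationAssignment, expected: dict)``.
    """
    if kind == "filter_demo":
        samples = ["ref_0", "ref_1", "tgt_0"]
        pos = [100, 200, 300]
        G = np.array([[2, 2, 2],    # jointly fixed derived -> removed
                      [2, 2, 1],    # fixed in ref only -> kept
                      [0, 1, 2]],   # segregating -> kept
                     dtype=np.int8)
        gm = GenotypeMatrix(["1"] * 3, pos, ["A"] * 3, ["T"] * 3, [True] * 3,
                            samples, G)
        a = PopulationAssignment(["ref_0", "ref_1"], ["tgt_0"])
        return gm, a, {"removed_pos": [100], "kept_pos": [200, 300]}
    if kind == "sstar_demo":
        samples = ["ref_0", "ref_1", "tgt_0"]
        pos = [100, 105, 9000]
        G = np.array([[0, 0, 2], [0, 0, 2], [0, 0, 2]], dtype=np.int8)
        gm = GenotypeMatrix(["1"] * 3, pos, ["A"] * 3, ["T"] * 3, [True] * 3,
                            samples, G)
        a = PopulationAssignment(["ref_0", "ref_1"], ["tgt_0"])
        return gm, a, {"sstar": 13900.0, "chain": (100, 9000)}
    if kind == "matchrate_demo":
        samples = ["ref_0", "tgt_0", "src_0"]
        pos = [100, 200, 300, 400]
        # tgt carries derived at all four (candidates); src matches 3 of 4
        G = np.array([[0, 1, 1], [0, 2, 2], [0, 1, 0], [0, 1, 1]],
                     dtype=np.int8)
        gm = GenotypeMatrix(["1"] * 4, pos, ["A"] * 4, ["T"] * 4, [True] * 4,
                            samples, G)
        a = PopulationAssignment(["ref_0"], ["tgt_0"], {"src": ["src_0"]})
        return gm, a, {"n_informative": 4, "n_matched": 3, "rate": 0.75}
    raise ValueError(f"unknown fixture kind {kind!r}")
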