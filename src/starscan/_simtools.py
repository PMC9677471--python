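"""Shared helpers for coalescent simulation and scoring of tree sequences."""

from __future__ import annotations

import numpy as np

import demes
import msprime

from .genotype_io import GenotypeMatrix, PopulationAssignment
from .preprocess import (assign_sites, drop_monomorphic, filter_fixed_derived,
                         make_windows)
from .sstar_core import ScoreFunctionParams, sstar_scan

__all__ = [
    "load_graph",
    "gene_flow_into",
    "simulate_ts",
    "matrix_from_ts",
    "score_matrix",
]


def load_graph(model) -> demes.Graph:
    """Accept a demes.Graph, a YAML string, or a path to a Demes YAML file."""
    if isinstance(model, demes.Graph):
        return model
    text = str(model)
    if "\n" in text:
        return demes.loads(text)
    return demes.load(text)


def gene_flow_into(graph: demes.Graph, deme_name: str) -> list[str]:
    """Names of demes with gene flow (pulse or migration) into ``deme_name``."""
    donors: list[str] = []
    for pulse in graph.pulses:
        if pulse.dest == deme_name:
            donors.extend(pulse.sources)
    for mig in graph.migrations:
        if getattr(mig, "dest", None) == deme_name:
            donors.append(mig.source)
    return donors


def simulate_ts(graph: demes.Graph, samples: dict[str, int], seq_len: float,
                mu: float, recomb_rate: float, seed: int,
                record_migrations: bool = False):
    """Simulate ancestry + mutations for diploid samples under a demes graph."""
    demography = msprime.Demography.from_demes(graph)
    rng = np.random.default_rng(seed)
    s1, s2 = (int(x) for x in rng.integers(1, 2**31 - 1, size=2))
    ts = msprime.sim_ancestry(
        samples, demography=demography, sequence_length=seq_len,
        recombination_rate=recomb_rate, record_migrations=record_migrations,
        random_seed=s1)
    return msprime.sim_mutations(ts, rate=mu, random_seed=s2)


def matrix_from_ts(ts, chrom: str = "1"):
    """Diploid derived-allele codes and per-population sample ids from a ts.

    Simulated mutations are polarized (ancestral state 0), so the derived code
    of an individual is the sum of its two haplotype alleles. Samples are named
    ``<population>_<k>`` with ``k`` counting individuals within a population.
    Returns ``(GenotypeMatrix, {population_name: [sample ids]})``.
    """
    pop_names = {p.id: p.metadata.get("name", str(p.id))
                 for p in ts.populations()}
    samples: list[str] = []
    node_pairs: list[tuple[int, int]] = []
    counters: dict[str, int] = {}
    for ind in ts.individuals():
        nodes = ind.nodes
        if len(nodes) != 2:
            raise ValueError("expected diploid individuals")
        pop = pop_names[ts.node(nodes[0]).population]
        k = counters.get(pop, 0)
        counters[pop] = k + 1
        samples.append(f"{pop}_{k}")
        node_pairs.append((nodes[0], nodes[1]))
    hap = ts.genotype_matrix()  # sites x haploid samples, derived = nonzero
    hap = (hap > 0).astype(np.int8)
    node_col = {n: i for i, n in enumerate(ts.samples())}
    G = np.empty((ts.num_sites, len(samples)), dtype=np.int8)
    for j, (a, b) in enumerate(node_pairs):
        G[:, j] = hap[:, node_col[a]] + hap[:, node_col[b]]
    pos = np.array([int(s.position) + 1 for s in ts.sites()], dtype=np.int64)
    gm = GenotypeMatrix([chrom] * ts.num_sites, pos, ["A"] * ts.num_sites,
                        ["T"] * ts.num_sites, [True] * ts.num_sites,
                        samples, G)
    by_pop: dict[str, list[str]] = {}
    for s in samples:
        by_pop.setdefault(s.rsplit("_", 1)[0], []).append(s)
    return gm, by_pop


def score_matrix(gm: GenotypeMatrix, assignment: PopulationAssignment,
                 seq_len: int, window_size: int, step: int,
                 params: ScoreFunctionParams, ref_max_daf: float = 0.0,
                 chrom: str = "1"):
    """Run the standard preprocessing + S* scan over one chromosome."""
    gm = filter_fixed_derived(gm, assignment)
    gm = drop_monomorphic(gm, assignment)
    windows = assign_sites(make_windows(int(seq_len), window_size, step,
                                        chrom=chrom), gm)
    return sstar_scan(gm, assignment, windows, params, ref_max_daf), gm
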