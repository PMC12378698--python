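"""Synthetic multiplexes, fluency lists and cohorts.

Everything downstream of edge-list ingestion is testable without the real
lexical resources: this module plants a mutually connected core across
every layer of a random multiplex (so the largest viable cluster is known
by construction), produces fluency lists as biased random walks on the
aggregate graph (a navigation process with a tunable preference for the
core), and builds cohorts whose trait scores depend linearly on the walk
features plus Gaussian noise — a planted model whose recovery the
prediction pipeline can be checked against.

Defaults emulate the study conditions the package targets: four layers, a
core of roughly a quarter of the lexicon, cohorts of 479 participants, and
list lengths of 10–40 responses (roughly what a 2-minute category-fluency
task yields).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .multiplex import (Layer, MultiplexNetwork, aggregate_graph,
                        build_multiplex, largest_viable_cluster)
from .walks import FEATURE_NAMES, FluencyList, feature_table

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "SyntheticCohort",
    "generate_multiplex",
    "generate_fluency_list",
    "generate_cohort",
    "DEFAULT_COHORT_SIZE",
]

#: Cohort size mirroring the scale of the study population the tool targets.
DEFAULT_COHORT_SIZE = 479


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a random multiplex with a planted viable core.

    ``p_core`` is the probability of each *extra* within-core edge per layer
    (on top of a random spanning tree that guarantees core connectivity);
    ``p_periphery`` applies independently per layer to every pair that is
    not fully inside the core.
    """

    n_nodes: int = 120
    n_layers: int = 4
    core_size: int = 30
    p_core: float = 0.12
    p_periphery: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_core <= 1 and 0 <= self.p_periphery <= 1):
            raise ConfigurationError("probabilities must be in [0, 1]")
        if self.core_size > self.n_nodes:
            raise ConfigurationError("core_size exceeds n_nodes")
        if self.n_layers < 2:
            raise ConfigurationError("need at least 2 layers")


@dataclass
class SyntheticCohort:
    """A simulated cohort: fluency lists, their true feature table, planted
    coefficients and the resulting noisy trait scores."""

    fluency_lists: list
    features: pd.DataFrame
    traits: pd.Series
    coefficients: Mapping[str, float]
    noise_sd: float
    lvc: frozenset = field(default_factory=frozenset)
    category: Optional[str] = None


def _node_labels(n: int) -> list:
    width = max(2, len(str(max(n - 1, 0))))
    return [f"w{i:0{width}d}" for i in range(n)]


def generate_multiplex(spec: SyntheticSpec) -> MultiplexNetwork:
    """Random multiplex whose designated core is viable by construction.

    In every layer the core nodes receive a random spanning tree (uniform
    attachment order) plus extra core edges at ``p_core``; all remaining
    pairs appear independently at ``p_periphery``.  The core is therefore
    connected in each layer, so the largest viable cluster contains it
    whenever no larger jointly-connected periphery structure arises (with
    the sparse default periphery this essentially never happens).
    """
    rng = np.random.default_rng(spec.seed)
    nodes = _node_labels(spec.n_nodes)
    core = nodes[:spec.core_size]
    if spec.core_size < 2 and spec.p_periphery == 0:
        logger.warning("core_size < 2 with p_periphery = 0: degenerate "
                       "viable cluster expected")
    periphery_pairs = [(nodes[i], nodes[j])
                       for i in range(spec.n_nodes)
                       for j in range(i + 1, spec.n_nodes)
                       if not (i < spec.core_size and j < spec.core_size)]
    core_pairs = [(core[i], core[j])
                  for i in range(spec.core_size)
                  for j in range(i + 1, spec.core_size)]
    layers = []
    for k in range(spec.n_layers):
        edges = set()
        if spec.core_size >= 2:
            order = list(rng.permutation(spec.core_size))
            for pos in range(1, spec.core_size):
                anchor = order[int(rng.integers(0, pos))]
                u, v = core[order[pos]], core[anchor]
                edges.add((min(u, v), max(u, v)))
        if core_pairs:
            mask = rng.random(len(core_pairs)) < spec.p_core
            edges.update(p for p, m in zip(core_pairs, mask) if m)
        if periphery_pairs and spec.p_periphery > 0:
            mask = rng.random(len(periphery_pairs)) < spec.p_periphery
            edges.update(p for p, m in zip(periphery_pairs, mask) if m)
        layers.append(Layer(f"layer{k + 1}", sorted(edges), nodes))
    return build_multiplex(layers)


def generate_fluency_list(mpx: MultiplexNetwork, lvc, length: int,
                          lvc_bias: float, seed: int,
                          participant_id: str = "p0",
                          graph=None) -> FluencyList:
    """Fluency list as a biased random walk on the aggregate graph.

    At each step the walk, standing at the current response, chooses
    uniformly among the LVC neighbors with probability ``lvc_bias`` (when
    any exist) and uniformly among all neighbors otherwise; the immediately
    preceding response is avoided when alternatives exist.  A stranded walk
    (isolated node) teleports to a uniformly random node with a warning.
    """
    lvc = frozenset(lvc)
    if lvc_bias > 0 and not lvc:
        raise ConfigurationError("lvc_bias > 0 requires a non-empty LVC")
    if graph is None:
        graph = aggregate_graph(mpx)
    rng = np.random.default_rng(seed)
    all_nodes = sorted(graph.nodes)
    if length > len(all_nodes):
        logger.warning("requested length %d exceeds %d distinct nodes; "
                       "revisits allowed", length, len(all_nodes))
    lvc_nodes = sorted(n for n in lvc if n in graph)
    if lvc_nodes and rng.random() < lvc_bias:
        current = lvc_nodes[int(rng.integers(len(lvc_nodes)))]
    else:
        current = all_nodes[int(rng.integers(len(all_nodes)))]
    responses = [current]
    previous = None
    while len(responses) < length:
        neighbors = sorted(graph[current])
        if previous in neighbors and len(neighbors) > 1:
            neighbors = [n for n in neighbors if n != previous]
        if not neighbors:
            logger.warning("walk stranded at %r; teleporting", current)
            previous, current = current, all_nodes[
                int(rng.integers(len(all_nodes)))]
            responses.append(current)
            continue
        in_core = [n for n in neighbors if n in lvc]
        if in_core and rng.random() < lvc_bias:
            nxt = in_core[int(rng.integers(len(in_core)))]
        else:
            nxt = neighbors[int(rng.integers(len(neighbors)))]
        previous, current = current, nxt
        responses.append(current)
    return FluencyList(participant_id=participant_id,
                       raw_responses=responses)


def generate_cohort(mpx: MultiplexNetwork,
                    n_participants: int = DEFAULT_COHORT_SIZE,
                    coefs: Optional[Mapping[str, float]] = None,
                    noise_sd: Optional[float] = 1.0,
                    seed: int = 0,
                    category: Optional[str] = None,
                    target_r2: Optional[float] = None,
                    length_range: tuple = (10, 40)) -> SyntheticCohort:
    """Cohort with trait scores planted on standardized walk features.

    Per participant, ``lvc_bias ~ Uniform(0, 1)`` and list length
    ``~ Uniform{length_range}``; features are computed through the real
    walk-features path.  The trait is ``Σ coef · z(feature) + N(0, sd)``
    (z-scores over the realized cohort, NaNs median-imputed first).  Passing
    ``target_r2`` derives the noise sd from the realized planted-signal sd
    so the cohort's population R² equals the requested value — with
    correlated features a fixed sd cannot pin R² directly.
    """
    if coefs is None:
        coefs = {"fraction_responses_in_lvc": 1.0}
    unknown = [f for f in coefs if f not in FEATURE_NAMES]
    if unknown:
        raise ConfigurationError(f"unknown feature names in coefs: {unknown}")
    rng = np.random.default_rng(seed)
    lvc = largest_viable_cluster(mpx).members
    graph = aggregate_graph(mpx)
    if category is None:
        category = min(lvc) if lvc else min(graph.nodes)
    lo, hi = length_range
    lists = []
    for i in range(n_participants):
        bias = float(rng.random())
        length = int(rng.integers(lo, hi + 1))
        child_seed = int(rng.integers(2 ** 31))
        lists.append(generate_fluency_list(
            mpx, lvc, length, bias, child_seed,
            participant_id=f"p{i:04d}", graph=graph))
    features = feature_table(lists, graph, core=lvc, category=category)
    filled = features.fillna(features.median()).fillna(0.0)
    signal = np.zeros(n_participants)
    for name, coef in coefs.items():
        col = filled[name].to_numpy(float)
        sd = col.std()
        if sd == 0:
            logger.warning("planted feature %r is constant; it contributes "
                           "no signal", name)
            continue
        signal += coef * (col - col.mean()) / sd
    if target_r2 is not None:
        if not 0 < target_r2 < 1:
            raise ConfigurationError("target_r2 must be in (0, 1)")
        sig_sd = signal.std()
        noise_sd = float(sig_sd * math.sqrt((1 - target_r2) / target_r2))
    if noise_sd is None:
        noise_sd = 0.0
    traits = signal + rng.normal(0.0, noise_sd, n_participants)
    return SyntheticCohort(
        fluency_lists=lists,
        features=features,
        traits=pd.Series(traits, index=features.index, name="trait"),
        coefficients=dict(coefs),
        noise_sd=float(noise_sd),
        lvc=lvc,
        category=category,
    )
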