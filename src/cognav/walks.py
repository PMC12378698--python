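"""Collective walks and navigation measures from verbal fluency lists.

A fluency list is the ordered sequence of words a participant produced in a
timed category-fluency task.  Under the mental-navigation model, consecutive
responses are the *endpoints* of a memory search that traverses the mental
lexicon along shortest paths of the multiplex network.  The *collective
walk* is the concatenation of those shortest paths; its interaction with the
largest viable cluster (LVC) — how often the walk enters it, how long it
stays, how unpredictably it alternates — yields a 17-measure feature vector
per participant that downstream models use to predict trait scores.

Conventions (documented in docs/methods.md):
* the walk runs on the unweighted aggregate (union) graph;
* one deterministic shortest path per response pair (lexicographic BFS);
* path *coverage* counts nodes including both endpoints, while distance to
  the category identifier counts edges;
* in the flattened walk, shared endpoints of consecutive paths appear once.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd
from scipy import stats as _sstats

from .errors import ConfigurationError, DataError
from .multiplex import MultiplexNetwork, PathOracle, aggregate_graph, normalize_label

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "OOV",
    "FluencyList",
    "NormalizedResponses",
    "CollectiveWalk",
    "FeatureVector",
    "normalize_responses",
    "build_collective_walk",
    "shannon_entropy",
    "run_statistics",
    "compute_features",
    "feature_table",
]

#: Canonical feature order; the column header of every feature table.
FEATURE_NAMES = (
    "number_of_responses",
    "coverage_per_response",
    "fraction_responses_in_lvc",
    "fraction_lvc_accesses",
    "entropy_lvc_accesses",
    "entropy_lvc_coverage",
    "entropy_lvc_responses",
    "max_permanence_lvc",
    "median_permanence_lvc",
    "max_out",
    "median_out",
    "distance_from_category_per_response",
    "accesses_to_lvc_from_category",
    "start_in_lvc",
    "fraction_typos",
    "norm1",
    "norm2",
)

#: Marker for a response that could not be matched to any lexicon entry.
OOV = None


@dataclass(frozen=True)
class FluencyList:
    """One participant's ordered responses, exactly as produced.

    Whitespace-only entries are dropped at construction; everything else is
    preserved verbatim (normalization happens in
    :func:`normalize_responses`).
    """

    participant_id: str
    raw_responses: tuple

    def __init__(self, participant_id: str, raw_responses: Iterable[str]):
        responses = tuple(r for r in raw_responses if str(r).strip())
        if not responses:
            raise DataError(
                f"participant {participant_id!r}: empty fluency list")
        object.__setattr__(self, "participant_id", participant_id)
        object.__setattr__(self, "raw_responses", responses)


@dataclass(frozen=True)
class NormalizedResponses:
    """Responses matched against the lexicon.

    ``matched`` holds one ``(raw, node_or_OOV, typo_flag)`` triple per raw
    response; a typo flag marks a non-exact match (unique lexicon entry at
    edit distance 1).
    """

    matched: tuple
    n_typos: int
    n_oov: int

    @property
    def in_lexicon(self) -> tuple:
        """Matched node labels in response order (OOV entries dropped)."""
        return tuple(node for _, node, _ in self.matched if node is not OOV)


@dataclass(frozen=True)
class CollectiveWalk:
    """Shortest paths linking consecutive in-lexicon responses.

    ``flattened`` concatenates the paths, dropping each junction node shared
    by consecutive paths so endpoints are counted once.  ``skipped_pairs``
    counts consecutive pairs with no connecting path.  ``degenerate`` marks
    walks built from fewer than two usable responses; path-dependent
    measures then become missing values.
    """

    paths: tuple
    flattened: tuple
    skipped_pairs: int
    degenerate: bool = False


@dataclass(frozen=True)
class FeatureVector:
    """The 17 navigation measures for one participant (NaN = missing)."""

    number_of_responses: float
    coverage_per_response: float
    fraction_responses_in_lvc: float
    fraction_lvc_accesses: float
    entropy_lvc_accesses: float
    entropy_lvc_coverage: float
    entropy_lvc_responses: float
    max_permanence_lvc: float
    median_permanence_lvc: float
    max_out: float
    median_out: float
    distance_from_category_per_response: float
    accesses_to_lvc_from_category: float
    start_in_lvc: float
    fraction_typos: float
    norm1: float
    norm2: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def _within_edit1(a: str, b: str) -> bool:
    """Damerau edit distance exactly 1: one substitution, one adjacent
    transposition, or one insertion/deletion.  The transposition case is
    what typical typos ("dgo" for "dog") look like."""
    if a == b:
        return False
    la, lb = len(a), len(b)
    if la == lb:
        diffs = [i for i in range(la) if a[i] != b[i]]
        if len(diffs) == 1:
            return True
        if len(diffs) == 2:
            i, j = diffs
            return j == i + 1 and a[i] == b[j] and a[j] == b[i]
        return False
    if abs(la - lb) != 1:
        return False
    if la > lb:
        a, b = b, a  # a is the shorter
    for i in range(len(b)):
        if b[:i] + b[i + 1:] == a:
            return True
    return False


def _edit1_candidates(word: str, lexicon_by_len: dict) -> list:
    """Lexicon entries at Damerau edit distance exactly 1 from ``word``."""
    hits = []
    for length in (len(word) - 1, len(word), len(word) + 1):
        for cand in lexicon_by_len.get(length, ()):
            if _within_edit1(word, cand):
                hits.append(cand)
    return hits


def normalize_responses(fluency: FluencyList,
                        lexicon: Iterable[str]) -> NormalizedResponses:
    """Match raw responses to lexicon nodes, flagging typos and OOV.

    Each response is case-folded and trimmed; an exact lexicon match is
    clean; otherwise a *unique* lexicon entry at edit distance 1 is accepted
    as a typo-corrected match; anything else is out-of-vocabulary (counted,
    and excluded from walks).  Ambiguous distance-1 matches stay OOV rather
    than guessing.
    """
    lexicon = set(lexicon)
    if not lexicon:
        raise ConfigurationError("empty lexicon")
    by_len: dict = {}
    for entry in lexicon:
        by_len.setdefault(len(entry), []).append(entry)
    for bucket in by_len.values():
        bucket.sort()
    matched = []
    n_typos = n_oov = 0
    for raw in fluency.raw_responses:
        word = normalize_label(str(raw))
        if word in lexicon:
            matched.append((raw, word, False))
            continue
        candidates = _edit1_candidates(word, by_len)
        if len(candidates) == 1:
            matched.append((raw, candidates[0], True))
            n_typos += 1
        else:
            matched.append((raw, OOV, False))
            n_oov += 1
    return NormalizedResponses(matched=tuple(matched), n_typos=n_typos,
                               n_oov=n_oov)


def build_collective_walk(norm: NormalizedResponses, graph: nx.Graph,
                          paths: Optional[PathOracle] = None) -> CollectiveWalk:
    """Link consecutive in-lexicon responses by shortest paths on ``graph``.

    OOV responses are skipped over, pairing the nearest in-lexicon
    neighbors.  Pairs in different components contribute no path and
    increment ``skipped_pairs``.
    """
    if paths is None:
        paths = PathOracle(graph)
    usable = [node for node in norm.in_lexicon if node in graph]
    if len(usable) < 2:
        return CollectiveWalk(paths=(), flattened=tuple(usable[:1]),
                              skipped_pairs=0, degenerate=True)
    walk_paths = []
    skipped = 0
    flattened: list = []
    for a, b in zip(usable, usable[1:]):
        p = paths.path(a, b)
        if p is None:
            skipped += 1
            continue
        walk_paths.append(p)
        if flattened and flattened[-1] == p[0]:
            flattened.extend(p[1:])
        else:
            flattened.extend(p)
    return CollectiveWalk(paths=tuple(walk_paths), flattened=tuple(flattened),
                          skipped_pairs=skipped,
                          degenerate=not walk_paths)


def shannon_entropy(code: Sequence[int]) -> float:
    """Binary Shannon entropy (bits) of a 0/1 sequence.

    ``H = −p·log2 p − (1−p)·log2(1−p)`` with ``p`` the fraction of 1s;
    degenerate all-0/all-1 codings have zero entropy.  Empty input is a
    missing value (NaN).
    """
    code = list(code)
    if not code:
        return math.nan
    p = sum(code) / len(code)
    return float(_sstats.entropy([p, 1.0 - p], base=2))


def run_statistics(membership: Sequence[int]):
    """Maximal-run statistics of a 0/1 sequence.

    Returns ``(max 1-run, median 1-run, max 0-run, median 0-run)``; a symbol
    with no runs gets 0 for both of its statistics.
    """
    membership = list(membership)
    if not membership:
        raise ConfigurationError("run_statistics needs a non-empty sequence")
    runs = {0: [], 1: []}
    for symbol, group in groupby(membership):
        runs[symbol].append(sum(1 for _ in group))
    out = []
    for symbol in (1, 0):
        if runs[symbol]:
            out.append(max(runs[symbol]))
            out.append(statistics.median(runs[symbol]))
        else:
            out.extend((0, 0))
    return tuple(out)


def _mean(values: Sequence[float]) -> float:
    values = list(values)
    return sum(values) / len(values) if values else math.nan


def compute_features(fluency: FluencyList, norm: NormalizedResponses,
                     walk: CollectiveWalk, lvc: frozenset, category,
                     graph: nx.Graph,
                     paths: Optional[PathOracle] = None) -> FeatureVector:
    """Compute the 17 navigation measures for one participant.

    ``lvc`` is the node set of the largest viable cluster (or, in
    single-layer null models, a layer's largest connected component);
    ``category`` is the category identifier node (e.g. "animal" or "hot").
    Degenerate walks leave the path-dependent measures as NaN; measures that
    need only the responses are still computed.
    """
    if paths is None:
        paths = PathOracle(graph)
    lvc = frozenset(lvc)
    responses = [node for node in norm.in_lexicon if node in graph]
    n_responses = len(responses)
    nan = math.nan

    # Response-based measures.
    if responses:
        resp_code = [1 if r in lvc else 0 for r in responses]
        fraction_responses_in_lvc = sum(resp_code) / n_responses
        entropy_lvc_responses = shannon_entropy(resp_code)
        start_in_lvc = float(resp_code[0])
    else:
        fraction_responses_in_lvc = entropy_lvc_responses = start_in_lvc = nan
    fraction_typos = norm.n_typos / len(fluency.raw_responses)

    # Walk-based measures.
    if walk.degenerate or not walk.flattened or not walk.paths:
        coverage = fraction_lvc_accesses = nan
        entropy_accesses = entropy_coverage = nan
        max_perm = med_perm = max_out_run = med_out_run = nan
        norm1 = norm2 = nan
    else:
        coverage = _mean([len(p) for p in walk.paths])
        walk_code = [1 if node in lvc else 0 for node in walk.flattened]
        fraction_lvc_accesses = sum(walk_code) / len(walk_code)
        entropy_coverage = shannon_entropy(walk_code)
        # Entry coding: 1 iff the node is inside the LVC and its predecessor
        # in the flattened walk is outside; the walk's first node counts as
        # entering from outside.
        entries = [1 if (walk_code[i] == 1
                         and (i == 0 or walk_code[i - 1] == 0)) else 0
                   for i in range(len(walk_code))]
        entropy_accesses = shannon_entropy(entries)
        max_perm, med_perm, max_out_run, med_out_run = run_statistics(walk_code)
        one_runs = [sum(1 for _ in grp)
                    for sym, grp in groupby(walk_code) if sym == 1]
        norm1 = max_perm / n_responses
        norm2 = (_mean(one_runs) if one_runs else 0.0) / n_responses

    # Category-based measures.
    if category in graph and responses:
        distances = []
        lvc_on_path = []
        disconnected = 0
        for r in responses:
            p = paths.path(r, category)
            if p is None:
                disconnected += 1
                continue
            distances.append(len(p) - 1)
            lvc_on_path.append(sum(1 for node in p if node in lvc))
        if disconnected:
            logger.warning(
                "participant %s: %d responses disconnected from category %r",
                fluency.participant_id, disconnected, category)
        distance_per_response = (sum(distances) / n_responses
                                 if distances else nan)
        accesses_from_category = _mean(lvc_on_path)
    else:
        if category not in graph:
            logger.warning("category %r not in graph; category measures "
                           "missing", category)
        distance_per_response = accesses_from_category = nan

    return FeatureVector(
        number_of_responses=float(n_responses),
        coverage_per_response=coverage,
        fraction_responses_in_lvc=fraction_responses_in_lvc,
        fraction_lvc_accesses=fraction_lvc_accesses,
        entropy_lvc_accesses=entropy_accesses,
        entropy_lvc_coverage=entropy_coverage,
        entropy_lvc_responses=entropy_lvc_responses,
        max_permanence_lvc=float(max_perm),
        median_permanence_lvc=float(med_perm),
        max_out=float(max_out_run),
        median_out=float(med_out_run),
        distance_from_category_per_response=distance_per_response,
        accesses_to_lvc_from_category=accesses_from_category,
        start_in_lvc=start_in_lvc,
        fraction_typos=fraction_typos,
        norm1=norm1,
        norm2=norm2,
    )


def participant_features(fluency: FluencyList, graph: nx.Graph,
                         core: frozenset, category,
                         paths: Optional[PathOracle] = None) -> FeatureVector:
    """Normalize, walk and measure one participant on a given graph/core."""
    if paths is None:
        paths = PathOracle(graph)
    norm = normalize_responses(fluency, set(graph.nodes))
    walk = build_collective_walk(norm, graph, paths=paths)
    return compute_features(fluency, norm, walk, core, category, graph,
                            paths=paths)


def feature_table(cohort: Sequence[FluencyList], graph_or_mpx, core=None,
                  category=None) -> pd.DataFrame:
    """Participants × 17 feature table.

    ``graph_or_mpx`` is either a plain graph plus an explicit ``core`` node
    set, or a :class:`~cognav.multiplex.MultiplexNetwork`, in which case the
    aggregate graph and the largest viable cluster are derived here.  Rows
    follow cohort order; columns follow :data:`FEATURE_NAMES`; missing
    values are NaN.
    """
    if not cohort:
        raise ConfigurationError("feature_table needs at least 1 participant")
    if isinstance(graph_or_mpx, MultiplexNetwork):
        from .multiplex import largest_viable_cluster
        graph = aggregate_graph(graph_or_mpx)
        if core is None:
            core = largest_viable_cluster(graph_or_mpx).members
    else:
        graph = graph_or_mpx
        if core is None:
            raise ConfigurationError(
                "core node set required when passing a plain graph")
    ids = [fl.participant_id for fl in cohort]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataError(f"duplicate participant ids: {dupes}")
    paths = PathOracle(graph)
    rows = []
    for fl in cohort:
        fv = participant_features(fl, graph, frozenset(core), category,
                                  paths=paths)
        if math.isnan(fv.coverage_per_response):
            logger.info("participant %s: degenerate walk, path measures "
                        "missing", fl.participant_id)
        rows.append(fv.as_dict())
    table = pd.DataFrame(rows, index=pd.Index(ids, name="participant_id"),
                         columns=list(FEATURE_NAMES))
    return table
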