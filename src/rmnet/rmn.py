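"""The rule-based microbial network (RMN) algorithm.

The model assumes a taxon's relative abundance behaves according to the
abundances of a cooperator and a competitor: every ordered triplet
(target X, cooperator C, competitor K) of distinct taxa is tested against a
rule table over discretized abundance changes between sample pairs, and the
triplets that conform are assembled into a directed signed network.

Discretization: a change between a (before, after) sample pair is UP if it
exceeds +ε, DOWN below −ε, otherwise STEADY (ε is the steady-band
half-width, in abundance-fraction units).  The rule table makes a pair
*predictive* when the regulators move in opposite directions:

    C UP  and K DOWN  ⇒ predict X UP
    C DOWN and K UP   ⇒ predict X DOWN

A predictive pair supports the triplet when X moves as predicted and
contradicts it otherwise — including when X stays STEADY, since a predicted
change that fails to materialize is evidence against the hypothesis.
Non-predictive pairs are ignored.  The conformity score is
(support − contradiction) / informative; a triplet is accepted when it has
at least ``m_min`` informative pairs and score ≥ ``s_min``.  The defaults
(s_min = 1, i.e. zero contradictions, with m_min = 3) take "conform to the
model" literally.

Each accepted triplet contributes two directed edges, cooperator→target
(cooperative) and competitor→target (competitive); duplicate edges merge by
maximum score.  Because edges only ever enter in such pairs, any node with a
cooperative in-edge necessarily also has a competitive in-edge — no
cooperation is reported for a target without a competitor for that same
target.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterator, Mapping, Sequence

import numpy as np

from .matrix import AbundanceMatrix
from .network import COMPETITIVE, COOPERATIVE, InteractionNetwork

__all__ = [
    "Change",
    "RMNParams",
    "TripletResult",
    "classify_change",
    "sample_pairs",
    "filter_taxa",
    "evaluate_triplet",
    "evaluate_all_triplets",
    "infer_network",
    "annotate_site_category",
]


class Change(IntEnum):
    DOWN = -1
    STEADY = 0
    UP = 1


@dataclass
class RMNParams:
    """Tunable parameters of the RMN rule model.

    theta_min:
        Minimum relative abundance (fraction) for a taxon to enter the
        network or count as present in a region.  Default 0.001 (0.1%).
    epsilon:
        Steady-band half-width for change discretization (fraction).
    pair_mode:
        ``all_pairs`` compares every sample pair (spatial designs);
        ``consecutive`` compares successive samples (time series).
    m_min:
        Minimum informative pairs for a triplet to be considered.
    s_min:
        Minimum conformity score for acceptance; 1.0 means zero
        contradictions.
    """

    theta_min: float = 0.001
    epsilon: float = 0.001
    pair_mode: str = "all_pairs"
    m_min: int = 3
    s_min: float = 1.0

    def __post_init__(self) -> None:
        if self.theta_min < 0:
            raise ValueError("theta_min must be >= 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.pair_mode not in ("all_pairs", "consecutive"):
            raise ValueError("pair_mode must be 'all_pairs' or 'consecutive'")
        if self.m_min < 1:
            raise ValueError("m_min must be >= 1")
        if not -1.0 <= self.s_min <= 1.0:
            raise ValueError("s_min must lie in [-1, 1]")


@dataclass(frozen=True)
class TripletResult:
    """Outcome of testing one ordered (target, cooperator, competitor) hypothesis."""

    target: str
    cooperator: str
    competitor: str
    support: int
    contradiction: int
    score: float
    accepted: bool

    @property
    def informative(self) -> int:
        return self.support + self.contradiction


def classify_change(before: float, after: float, epsilon: float) -> Change:
    """Discretize an abundance change with a steady band of half-width ε."""
    delta = after - before
    if delta > epsilon:
        return Change.UP
    if delta < -epsilon:
        return Change.DOWN
    return Change.STEADY


def sample_pairs(samples: Sequence[str], pair_mode: str = "all_pairs") -> list[tuple[str, str]]:
    """Ordered (before, after) sample pairs under the given pairing mode."""
    n = len(samples)
    if pair_mode == "consecutive":
        return [(samples[i], samples[i + 1]) for i in range(n - 1)]
    if pair_mode == "all_pairs":
        return [(samples[i], samples[j]) for i in range(n) for j in range(i + 1, n)]
    raise ValueError("pair_mode must be 'all_pairs' or 'consecutive'")


def filter_taxa(matrix: AbundanceMatrix, theta_min: float) -> AbundanceMatrix:
    """Keep taxa whose maximum abundance over all samples reaches theta_min."""
    keep = matrix.max_abundance() >= theta_min
    return AbundanceMatrix(
        matrix.data.loc[keep], region_of=matrix.region_of, label=matrix.label
    )


def _pair_indices(n_samples: int, pair_mode: str) -> tuple[np.ndarray, np.ndarray]:
    if pair_mode == "consecutive":
        i = np.arange(n_samples - 1)
        return i, i + 1
    i, j = np.triu_indices(n_samples, k=1)
    return i, j


def _change_matrix(values: np.ndarray, pair_mode: str, epsilon: float) -> np.ndarray:
    """Discretized change (−1/0/+1) per taxon per sample pair."""
    i, j = _pair_indices(values.shape[1], pair_mode)
    delta = values[:, j] - values[:, i]
    return np.where(delta > epsilon, 1, np.where(delta < -epsilon, -1, 0)).astype(np.int8)


def _score_triplet(changes: np.ndarray, t: int, c: int, k: int) -> tuple[int, int]:
    """Support/contradiction counts for one triplet from the change matrix."""
    pred = np.where(
        (changes[c] == 1) & (changes[k] == -1),
        1,
        np.where((changes[c] == -1) & (changes[k] == 1), -1, 0),
    )
    predictive = pred != 0
    support = int((predictive & (changes[t] == pred)).sum())
    contradiction = int(predictive.sum()) - support
    return support, contradiction


def _make_result(
    target: str, coop: str, comp: str, support: int, contradiction: int, params: RMNParams
) -> TripletResult:
    informative = support + contradiction
    score = (support - contradiction) / informative if informative else 0.0
    accepted = informative >= params.m_min and score >= params.s_min
    return TripletResult(target, coop, comp, support, contradiction, score, accepted)


def evaluate_triplet(
    matrix: AbundanceMatrix,
    target: str,
    cooperator: str,
    competitor: str,
    params: RMNParams | None = None,
) -> TripletResult:
    """Test one ordered triplet hypothesis against the rule model."""
    params = params or RMNParams()
    names = (target, cooperator, competitor)
    if len(set(names)) != 3:
        raise ValueError(f"triplet taxa must be distinct, got {names}")
    for name in names:
        if name not in matrix.data.index:
            raise KeyError(f"taxon {name!r} not in matrix")
    changes = _change_matrix(matrix.data.to_numpy(), params.pair_mode, params.epsilon)
    idx = {name: matrix.taxa.index(name) for name in names}
    support, contradiction = _score_triplet(
        changes, idx[target], idx[cooperator], idx[competitor]
    )
    return _make_result(target, cooperator, competitor, support, contradiction, params)


def evaluate_all_triplets(
    matrix: AbundanceMatrix, params: RMNParams | None = None
) -> Iterator[TripletResult]:
    """Evaluate every ordered triplet of distinct taxa (after no filtering).

    The change matrix is computed once and shared across the
    n·(n−1)·(n−2) hypotheses.
    """
    params = params or RMNParams()
    taxa = matrix.taxa
    changes = _change_matrix(matrix.data.to_numpy(), params.pair_mode, params.epsilon)
    for t, c, k in itertools.permutations(range(len(taxa)), 3):
        support, contradiction = _score_triplet(changes, t, c, k)
        yield _make_result(taxa[t], taxa[c], taxa[k], support, contradiction, params)


def infer_network(
    matrix: AbundanceMatrix,
    params: RMNParams | None = None,
    region_of: Mapping[str, str] | None = None,
    triplets_out: list[TripletResult] | None = None,
) -> InteractionNetwork:
    """Run the full RMN inference and assemble the interaction network.

    Taxa are pre-filtered at ``theta_min``; every ordered triplet of the
    remaining taxa is tested; each accepted triplet adds the edges
    cooperator→target (cooperative) and competitor→target (competitive),
    merged by maximum score.  When a sample→region mapping is given (or
    stored on the matrix), nodes are annotated with their site-presence
    category.  Fully deterministic.

    Pass a list as ``triplets_out`` to also collect every evaluated triplet.
    """
    params = params or RMNParams()
    region_of = region_of if region_of is not None else matrix.region_of
    filtered = filter_taxa(matrix, params.theta_min)
    if filtered.n_taxa < 3:
        raise ValueError(
            f"need at least 3 taxa above theta_min={params.theta_min}, "
            f"have {filtered.n_taxa}"
        )
    if filtered.n_samples < 2:
        raise ValueError("need at least 2 samples")

    net = InteractionNetwork()
    maxab = filtered.max_abundance()
    categories = (
        annotate_site_category(filtered, region_of, params.theta_min) if region_of else {}
    )
    for res in evaluate_all_triplets(filtered, params):
        if triplets_out is not None:
            triplets_out.append(res)
        if not res.accepted:
            continue
        for name in (res.target, res.cooperator, res.competitor):
            net.add_node(name, category=categories.get(name), max_abundance=maxab[name])
        net.add_interaction(res.cooperator, res.target, COOPERATIVE, res.score)
        net.add_interaction(res.competitor, res.target, COMPETITIVE, res.score)
    return net


def annotate_site_category(
    matrix: AbundanceMatrix,
    region_of: Mapping[str, str],
    theta_min: float = 0.001,
) -> dict[str, str]:
    """Classify each taxon's site presence across a two-region design.

    A taxon is present in a region when its maximum relative abundance over
    that region's samples reaches ``theta_min``.  Categories: ``both``,
    ``regionA_only``, ``regionB_only`` (regionA is the lexicographically
    smaller region label), or ``below_threshold``.
    """
    missing = [s for s in matrix.samples if s not in region_of]
    if missing:
        raise ValueError(f"samples without region labels: {missing}")
    regions = sorted({region_of[s] for s in matrix.samples})
    if len(regions) != 2:
        raise ValueError(f"exactly 2 regions required, got {regions}")
    region_a, region_b = regions
    out = {}
    for taxon in matrix.taxa:
        row = matrix.data.loc[taxon]
        present = {
            r: max((row[s] for s in matrix.samples if region_of[s] == r), default=0.0)
            >= theta_min
            for r in regions
        }
        if present[region_a] and present[region_b]:
            out[taxon] = "both"
        elif present[region_a]:
            out[taxon] = "regionA_only"
        elif present[region_b]:
            out[taxon] = "regionB_only"
        else:
            out[taxon] = "below_threshold"
    return out
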