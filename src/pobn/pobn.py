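"""The edge-pruning optimization loop.

One cycle: (1) Gibbs-sample M completions of the hidden regulators under the
*current* network, (2) compute the completion-averaged BD score of that
network and of every single-edge-removal variant against the same shared
completion set, (3) flag every edge whose removal strictly improves the
score as non-predictive.  All flagged edges are removed at once and the
cycle repeats, with fresh sampling on the reduced network, until the current
network ranks first among itself and all of its one-edge removals.

An edge whose removal leaves the score exactly unchanged is kept: a removal
must be strictly better than the network it came from to count as evidence
against the edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .gibbs import GibbsConfig, sample_completions
from .network import BipartiteNetwork
from .scoring import CompletionScoreTable, ScoreConfig

logger = logging.getLogger(__name__)


@dataclass
class EdgeVerdict:
    """Outcome of scoring one single-edge removal."""

    edge: tuple
    removal_score: float
    delta: float  # removal_score - initial_score; > 0 flags the edge
    non_predictive: bool
    rank: int  # position in the descending score list, initial net included


@dataclass
class CycleReport:
    """One sampling-scoring-ranking round."""

    cycle_index: int
    initial_score: float
    verdicts: list
    removed: list
    initial_rank: int
    seed: int

    @property
    def n_scored_networks(self) -> int:
        """Initial network plus one removal variant per edge."""
        return len(self.verdicts) + 1


@dataclass
class PruneResult:
    cycles: list
    final_network: BipartiteNetwork
    converged: bool = True

    @property
    def total_removed(self) -> int:
        return sum(len(c.removed) for c in self.cycles)

    @property
    def removed_edges(self) -> list:
        return [e for c in self.cycles for e in c.removed]

    def removed_frame(self) -> pd.DataFrame:
        """Tidy per-removed-edge table (cycle, regulator, target, scores)."""
        rows = []
        for c in self.cycles:
            by_edge = {v.edge: v for v in c.verdicts}
            for e in c.removed:
                v = by_edge[e]
                rows.append(
                    {
                        "cycle": c.cycle_index,
                        "regulator": e[0],
                        "target": e[1],
                        "initial_score": c.initial_score,
                        "removal_score": v.removal_score,
                        "delta": v.delta,
                    }
                )
        return pd.DataFrame(rows, columns=["cycle", "regulator", "target", "initial_score", "removal_score", "delta"])


def classify_edges(net: BipartiteNetwork, observed: pd.DataFrame, gcfg: GibbsConfig, cfg: ScoreConfig, cycle_index: int = 0) -> CycleReport:
    """Score every single-edge removal of ``net`` against one shared completion set.

    Samples ONE completion set under ``net`` (Gibbs sampling is done only for
    the initial network of the cycle), evaluates the averaged score of the
    network and of each removal, and ranks all of them by descending score.
    Ties rank the initial network first, then edges in lexicographic order.
    """
    if net.n_edges == 0:
        raise ValueError("network has no edges; nothing to classify (terminate the loop)")

    completions = sample_completions(net, observed, gcfg, cfg)
    table = CompletionScoreTable(net, observed, completions, cfg)
    initial_score = table.averaged()

    edges = sorted(net.edges)
    removal_scores = {e: table.removal_averaged(e) for e in edges}

    # rank descending; stable sort with the initial network first among equals
    entries = [(initial_score, 0, None)] + [(removal_scores[e], 1, e) for e in edges]
    entries.sort(key=lambda t: (-t[0], t[1], t[2] if t[2] is not None else ("",)))
    ranks = {e: pos + 1 for pos, (_, _, e) in enumerate(entries)}

    verdicts = []
    removed = []
    for e in edges:
        delta = removal_scores[e] - initial_score
        flag = delta > 0.0
        verdicts.append(EdgeVerdict(e, removal_scores[e], delta, flag, ranks[e]))
        logger.debug("cycle %d: edge %s->%s delta %+.4f rank %d%s",
                     cycle_index, e[0], e[1], delta, ranks[e], " FLAG" if flag else "")
        if flag:
            removed.append(e)

    report = CycleReport(cycle_index, initial_score, verdicts, removed, ranks[None], gcfg.seed)
    logger.info(
        "cycle %d: scored %d networks (seed %d), initial score %.4f rank %d, flagged %d/%d edges",
        cycle_index, report.n_scored_networks, gcfg.seed, initial_score, ranks[None], len(removed), len(edges),
    )
    return report


def pobn_optimize(net: BipartiteNetwork, observed: pd.DataFrame, gcfg: GibbsConfig, cfg: ScoreConfig, max_cycles: int = 50) -> PruneResult:
    """Iterate classify-and-remove cycles until the current network ranks first.

    Cycle ``c`` (0-based) samples with seed ``gcfg.seed + c`` so multi-cycle
    runs are reproducible while cycles stay decorrelated.  Stops when a cycle
    flags no edge (the network outranks all its removals), when no edges
    remain, or when ``max_cycles`` is exceeded (result flagged non-converged).
    """
    cycles = []
    current = net
    converged = False
    for c in range(max_cycles):
        if current.n_edges == 0:
            converged = True
            break
        cycle_cfg = gcfg.replace(seed=gcfg.seed + c)
        report = classify_edges(current, observed, cycle_cfg, cfg, cycle_index=c)
        cycles.append(report)
        if not report.removed:
            converged = True
            break
        for e in report.removed:
            current = current.remove_edge(e)
    if not converged:
        logger.warning("pobn_optimize: max_cycles=%d reached without convergence", max_cycles)
    return PruneResult(cycles=cycles, final_network=current, converged=converged)
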