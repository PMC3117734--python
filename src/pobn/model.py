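"""Model/Results front end over the pruning machinery.

`POBN` holds the data and hypothesis network plus all tuning parameters;
`fit()` runs the iterative classify-and-remove optimization and returns a
`POBNResults` carrying the per-cycle verdicts, the trimmed network, and a
`summary()` table, in the style of the classic statistical-modelling
packages.
"""

from __future__ import annotations

import json

import pandas as pd

from . import network as netmod
from .gibbs import GibbsConfig
from .network import BipartiteNetwork
from .pobn import PruneResult, pobn_optimize
from .preprocess import (
    discretize_tertiles,
    intersect_with_targets,
    load_expression,
    select_top_variable_genes,
    validate_discrete,
)
from .scoring import IMPORTANCE, ScoreConfig


class POBN:
    """Partially Observed Bipartite Network pruning model.

    Parameters
    ----------
    network : BipartiteNetwork
        Hypothesis regulator->gene network; regulators are treated as hidden.
    data : pandas.DataFrame
        Discrete (3-state) genes x samples matrix covering every target of
        ``network``.
    alpha : Dirichlet pseudocount of the BD score (default 1.0).
    averaging : completion averaging mode: ``importance`` (default,
        importance-weighted Bayes-factor estimate for edge removals),
        ``mean_of_logs`` or ``log_mean_exp``.
    m, burn_in, thin, n_chains : Gibbs sampler settings
        (defaults 250 / 100 / 2 / 5).
    max_cycles : safety cap on pruning cycles (default 50).

    Examples
    --------
    >>> model = POBN(net, discrete_data, m=250)
    >>> res = model.fit(seed=7)
    >>> print(res.summary())
    """

    def __init__(self, network: BipartiteNetwork, data: pd.DataFrame, *, alpha: float = 1.0,
                 averaging: str = IMPORTANCE, m: int = 250, burn_in: int = 100, thin: int = 2,
                 n_chains: int = 5, max_cycles: int = 50):
        validate_discrete(data)
        missing = network.targets - set(data.index)
        if missing:
            raise ValueError(f"data missing network targets: {sorted(missing)[:5]}")
        self.network = network
        self.data = data.loc[sorted(network.targets)] if network.targets else data.iloc[0:0]
        self.score_config = ScoreConfig(alpha=alpha, averaging=averaging)
        self.m = m
        self.burn_in = burn_in
        self.thin = thin
        self.n_chains = n_chains
        self.max_cycles = max_cycles

    @classmethod
    def from_files(cls, expression_path, network_path, *, top_k: int = 300, **kwargs) -> "POBN":
        """Build a model from an expression TSV and an edge-list TSV.

        Pipeline: load expression -> keep the ``top_k`` most variable genes
        (population SD) -> keep those that are network targets -> tertile
        discretization -> restrict the network to the retained targets.
        """
        expr = load_expression(expression_path)
        net = netmod.read_edge_list(network_path)
        genes = select_top_variable_genes(expr, top_k)
        genes = intersect_with_targets(genes, net)
        if not genes:
            raise ValueError("no selected high-variance gene appears as a network target")
        disc = discretize_tertiles(expr.loc[genes])
        return cls(net.restrict_targets(genes), disc, **kwargs)

    def _gibbs_config(self, seed: int) -> GibbsConfig:
        return GibbsConfig(m=self.m, burn_in=self.burn_in, thin=self.thin, n_chains=self.n_chains, seed=seed)

    def config_dict(self, seed: int = None) -> dict:
        out = {
            "alpha": self.score_config.alpha,
            "averaging": self.score_config.averaging,
            "m": self.m,
            "burn_in": self.burn_in,
            "thin": self.thin,
            "n_chains": self.n_chains,
            "max_cycles": self.max_cycles,
            "n_genes": len(self.network.targets),
            "n_regulators": len(self.network.regulators),
            "n_edges": self.network.n_edges,
            "n_samples": self.data.shape[1],
        }
        if seed is not None:
            out["base_seed"] = seed
        return out

    def fit(self, seed: int = 0) -> "POBNResults":
        """Run the pruning loop; deterministic given ``seed``."""
        prune = pobn_optimize(self.network, self.data, self._gibbs_config(seed), self.score_config, max_cycles=self.max_cycles)
        return POBNResults(self, prune, seed)


class POBNResults:
    """Fitted pruning result: per-cycle verdicts and the trimmed network."""

    def __init__(self, model: POBN, prune: PruneResult, seed: int):
        self.model = model
        self.prune = prune
        self.seed = seed
        self.final_network = prune.final_network
        self.converged = prune.converged
        self.cycles = prune.cycles
        self.n_cycles = len(prune.cycles)
        self.total_removed = prune.total_removed
        self.removed_edges = prune.removed_frame()

    def edge_table(self) -> pd.DataFrame:
        """All verdicts of all cycles (one row per scored removal)."""
        rows = []
        for c in self.cycles:
            for v in c.verdicts:
                rows.append(
                    {
                        "cycle": c.cycle_index,
                        "regulator": v.edge[0],
                        "target": v.edge[1],
                        "removal_score": v.removal_score,
                        "delta": v.delta,
                        "non_predictive": v.non_predictive,
                        "rank": v.rank,
                    }
                )
        return pd.DataFrame(rows, columns=["cycle", "regulator", "target", "removal_score", "delta", "non_predictive", "rank"])

    def summary(self) -> str:
        """Plain-text fit summary."""
        n_reg_active, n_targets = self.final_network.active_counts()
        lines = [
            "POBN pruning results",
            "=" * 64,
            f"edges in            {self.model.network.n_edges:>8}",
            f"edges removed       {self.total_removed:>8}",
            f"edges out           {self.final_network.n_edges:>8}",
            f"active regulators   {n_reg_active:>8}  (of {len(self.final_network.regulators)})",
            f"targets             {n_targets:>8}",
            f"cycles              {self.n_cycles:>8}",
            f"converged           {str(self.converged):>8}",
            f"base seed           {self.seed:>8}",
            f"completions M       {self.model.m:>8}   alpha {self.model.score_config.alpha:g}   averaging {self.model.score_config.averaging}",
            "-" * 64,
            f"{'cycle':>5} {'edges':>6} {'scored':>7} {'initial score':>16} {'rank':>5} {'removed':>8}",
        ]
        for c in self.cycles:
            lines.append(
                f"{c.cycle_index:>5} {len(c.verdicts):>6} {c.n_scored_networks:>7} {c.initial_score:>16.4f} {c.initial_rank:>5} {len(c.removed):>8}"
            )
        lines.append("-" * 64)
        return "\n".join(lines)

    def report_dict(self) -> dict:
        return {
            "config": self.model.config_dict(self.seed),
            "converged": self.converged,
            "total_removed": self.total_removed,
            "cycles": [
                {
                    "cycle": c.cycle_index,
                    "seed": c.seed,
                    "n_edges": len(c.verdicts),
                    "n_scored_networks": c.n_scored_networks,
                    "initial_score": c.initial_score,
                    "initial_rank": c.initial_rank,
                    "n_removed": len(c.removed),
                    "removed": [list(e) for e in c.removed],
                }
                for c in self.cycles
            ],
            "final_edges": sorted(list(e) for e in self.final_network.edges),
        }

    def save(self, out_dir) -> None:
        """Write removed-edges TSV, trimmed network TSV + dot, report JSON."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.removed_edges.to_csv(out / "removed_edges.tsv", sep="\t", index=False)
        netmod.write_edge_list(self.final_network, out / "trimmed_network.tsv")
        netmod.write_dot(self.final_network, out / "trimmed_network.dot")
        with open(out / "run_report.json", "w", encoding="utf-8") as fh:
            json.dump(self.report_dict(), fh, indent=1)
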