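"""Ground-truth generators and the spurious-edge injection study.

The validation design mirrors a small, fully known world: a bipartite
network of 4 hidden regulators and 9 observed response variables, every
response wired to 1-3 regulators for 11 edges total.  Conditional
probability tables give each node a strong 3-state signal, 5000 samples are
drawn ancestrally, the regulator rows are deleted, and known-spurious edges
are injected into the true network one at a time (25 possible positions) or
in pairs (300 positions).  A single classify-and-rank round per case then
asks whether the injected edges -- and only they -- are flagged as
non-predictive.

CPT scheme: root regulators draw their 3-state distribution from a
Dirichlet(1,1,1) resampled until every state has probability >= 0.1 (no
quasi-constant regulators).  Each edge is assigned an activator or
repressor role; a response's preferred state under a parent configuration
is the sign of the summed signed parent activities (low / medium / high),
i.e. monotone regulatory logic, the way transcriptional control is
conventionally simulated.  The preferred state carries probability
1 - epsilon, the remaining mass is split evenly; epsilon = 0.1 keeps the
parent-child signal strong but noisy.  Monotone tables both mirror real
activation/repression and make the hidden regulator states identifiable
from their targets, which the near-perfect recovery this study is built
around presupposes.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gibbs import GibbsConfig
from .network import BipartiteNetwork
from .pobn import classify_edges
from .preprocess import N_STATES
from .scoring import ScoreConfig

_SEED_CAP = 2**31 - 1


@dataclass
class GroundTruthModel:
    """A bipartite network plus full conditional probability tables.

    ``root_cpts`` maps each regulator to a length-3 distribution;
    ``gene_cpts`` maps each gene to a (3^P, 3) row-stochastic table indexed
    by the mixed-radix configuration of its sorted parents.
    """

    net: BipartiteNetwork
    root_cpts: dict = field(repr=False)
    gene_cpts: dict = field(repr=False)
    seed: int = 0
    edge_roles: dict = field(default_factory=dict, repr=False)  # +1 activator / -1 repressor

    def __post_init__(self):
        for name, dist in self.root_cpts.items():
            if abs(float(np.sum(dist)) - 1.0) > 1e-12:
                raise ValueError(f"root CPT of {name} does not sum to 1")
        for name, table in self.gene_cpts.items():
            if np.abs(np.sum(table, axis=1) - 1.0).max() > 1e-12:
                raise ValueError(f"CPT rows of {name} do not sum to 1")

    def parents(self, gene: str) -> tuple:
        return tuple(sorted(self.net.parents_of(gene)))

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "edges": sorted(self.net.edges),
            "root_cpts": {r: list(map(float, d)) for r, d in self.root_cpts.items()},
            "gene_cpts": {g: [list(map(float, row)) for row in t] for g, t in self.gene_cpts.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class CaseRecord:
    """Per-injection-case outcome of the validation study."""

    case_index: int
    injected: tuple  # edge set injected into the true network
    detected: bool  # every injected edge flagged non-predictive
    true_edges_flagged: tuple  # true edges wrongly flagged (should be empty)
    worst_weakness_rank: int  # best (lowest) weakness rank among undetected injected edges; 0 if detected


@dataclass
class ExperimentReport:
    """Aggregate of a single- or pair-injection experiment."""

    mode: str
    n_cases: int
    n_detected: int
    n_true_edge_false_positives: int
    near_miss: int  # undetected cases whose injected edge ranked 1st/2nd weakest
    cases: list = field(default_factory=list, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case": [c.case_index for c in self.cases],
                "injected": [";".join(f"{r}->{t}" for r, t in c.injected) for c in self.cases],
                "detected": [c.detected for c in self.cases],
                "true_edges_flagged": [";".join(f"{r}->{t}" for r, t in c.true_edges_flagged) for c in self.cases],
                "worst_weakness_rank": [c.worst_weakness_rank for c in self.cases],
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_cases": self.n_cases,
            "n_detected": self.n_detected,
            "n_true_edge_false_positives": self.n_true_edge_false_positives,
            "near_miss": self.near_miss,
        }


# ---------------------------------------------------------------------------
# generation


def _monotone_preferred_map(roles: np.ndarray) -> np.ndarray:
    """Preferred child state per parent configuration, mixed-radix order.

    ``roles`` holds +1 (activator) or -1 (repressor) per parent, in parent
    order.  The preferred state is the sign of the summed signed parent
    activities (states 0/1/2 centered to -1/0/+1): net positive drive ->
    high, net negative -> low, balanced -> medium.  The map is monotone in
    every parent and depends on every parent (changing one parent while the
    others balance always moves the preferred state).
    """
    n_parents = len(roles)
    q = N_STATES**n_parents
    pref = np.empty(q, dtype=np.int64)
    for j in range(q):
        digits = []
        jj = j
        for _ in range(n_parents):
            digits.append(jj % N_STATES)
            jj //= N_STATES
        digits.reverse()  # first parent most significant
        drive = int(np.sum(roles * (np.array(digits) - 1)))
        pref[j] = 0 if drive < 0 else (2 if drive > 0 else 1)
    return pref


def make_synthetic_network(n_reg: int = 4, n_resp: int = 9, n_edges: int = 11, max_parents: int = 3, seed: int = 0, epsilon: float = 0.1) -> GroundTruthModel:
    """Random ground-truth model with the default 4x9 / 11-edge topology.

    Every response gets one parent uniformly at random, then the remaining
    edge budget is spread uniformly over responses that still have fewer
    than ``max_parents`` parents.  CPTs follow the strong-signal scheme
    described in the module docstring.  Deterministic per seed.
    """
    if not (n_resp <= n_edges <= n_resp * min(max_parents, n_reg)):
        raise ValueError(f"n_edges={n_edges} infeasible for n_resp={n_resp}, max_parents={max_parents}, n_reg={n_reg}")
    if not (0.0 < epsilon < 2 / 3):
        raise ValueError("epsilon must be in (0, 2/3)")
    rng = np.random.default_rng(seed)
    regs = [f"R{i + 1}" for i in range(n_reg)]
    genes = [f"G{i + 1}" for i in range(n_resp)]

    # first parent per response; when feasible, make sure every regulator
    # actually regulates something (a childless "regulator" would be an
    # unconstrained hidden node, not part of the stated world)
    parent_sets = {g: set() for g in genes}
    gene_order = list(rng.permutation(genes))
    reg_order = list(rng.permutation(regs))
    for i, g in enumerate(gene_order):
        if n_resp >= n_reg and i < n_reg:
            parent_sets[g].add(reg_order[i])
        else:
            parent_sets[g].add(regs[rng.integers(n_reg)])
    budget = n_edges - n_resp
    cap = min(max_parents, n_reg)
    while budget > 0:
        open_genes = [g for g in genes if len(parent_sets[g]) < cap]
        g = open_genes[rng.integers(len(open_genes))]
        choices = [r for r in regs if r not in parent_sets[g]]
        parent_sets[g].add(choices[rng.integers(len(choices))])
        budget -= 1

    edges = frozenset((r, g) for g in genes for r in parent_sets[g])
    net = BipartiteNetwork(frozenset(regs), frozenset(genes), edges)

    root_cpts = {}
    for r in regs:
        dist = rng.dirichlet(np.ones(N_STATES))
        while dist.min() < 0.1:  # keep regulators away from quasi-constant
            dist = rng.dirichlet(np.ones(N_STATES))
        root_cpts[r] = dist
    gene_cpts = {}
    edge_roles = {}
    for g in genes:
        parents = sorted(parent_sets[g])
        roles = rng.choice([-1, 1], size=len(parents))
        for p, role in zip(parents, roles):
            edge_roles[(p, g)] = int(role)
        q = N_STATES ** len(parents)
        table = np.full((q, N_STATES), epsilon / (N_STATES - 1))
        preferred = _monotone_preferred_map(roles)
        table[np.arange(q), preferred] = 1.0 - epsilon
        gene_cpts[g] = table
    return GroundTruthModel(net=net, root_cpts=root_cpts, gene_cpts=gene_cpts, seed=int(seed), edge_roles=edge_roles)


def forward_sample(model: GroundTruthModel, n: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Ancestrally sample ``n`` complete observations (regulator + gene rows).

    Regulators draw from their root distributions; each gene draws from the
    CPT row selected by its sampled parent states.  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    regs = sorted(model.net.regulators)
    genes = sorted(model.net.targets)
    states = {}
    for r in regs:
        states[r] = rng.choice(N_STATES, size=n, p=model.root_cpts[r])
    for g in genes:
        parents = model.parents(g)
        j = np.zeros(n, dtype=np.int64)
        for p in parents:  # sorted order, first parent most significant
            j = j * N_STATES + states[p]
        table = np.asarray(model.gene_cpts[g])
        u = rng.random(n)
        cum = np.cumsum(table, axis=1)[j]  # (n, 3)
        states[g] = np.minimum((u[:, None] > cum).sum(axis=1), N_STATES - 1)
    samples = [f"s{i + 1}" for i in range(n)]
    rows = regs + genes
    data = np.stack([states[name] for name in rows]).astype(np.int8)
    return pd.DataFrame(data, index=rows, columns=samples)


def hide_regulators(completed: pd.DataFrame, model: GroundTruthModel) -> pd.DataFrame:
    """Drop the regulator rows, leaving the observed gene matrix."""
    regs = [r for r in completed.index if r in model.net.regulators]
    return completed.drop(index=regs)


def spurious_edge_cases(net: BipartiteNetwork, mode: str = "single") -> list:
    """Enumerate absent regulator->gene edges to inject.

    ``single``: every absent pair as a singleton set; ``pair``: every
    unordered pair of absent edges.  Lexicographic, deterministic order.
    """
    absent = sorted(
        (r, g) for r in sorted(net.regulators) for g in sorted(net.targets) if (r, g) not in net.edges
    )
    if mode == "single":
        return [(e,) for e in absent]
    if mode == "pair":
        return [tuple(pair) for pair in itertools.combinations(absent, 2)]
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# the injection experiment.  Injected edges change only the *hypothesis*
# network, never the data: samples always come from the true model.


def run_validation(
    model: GroundTruthModel,
    n_samples: int = 5000,
    mode: str = "single",
    gcfg: GibbsConfig = None,
    cfg: ScoreConfig = None,
    data_seed: int = None,
    cases: list = None,
) -> ExperimentReport:
    """Run the spurious-edge injection study on one ground-truth model.

    Data are forward-sampled once from the true model and the regulator rows
    hidden.  For every case the injected edge set is added to the true
    network and ONE classify-and-rank round is run on that augmented
    network; the case is *detected* if every injected edge is flagged
    non-predictive.  Any true edge flagged anywhere is a false positive.
    For undetected injected edges the weakness rank records where the edge
    sat in the removal-score ordering (1 = weakest edge in the network).

    ``cases`` restricts the run to an explicit subset of the enumerated case
    list (e.g. a random subsample of the 300 pairs for a quick check).
    Per-case Gibbs seeds are ``gcfg.seed + case_index`` over the full,
    deterministic enumeration, so a subsample scores identically to the same
    cases inside a full run.
    """
    gcfg = gcfg or GibbsConfig()
    cfg = cfg or ScoreConfig()
    if data_seed is None:
        data_seed = model.seed + 1
    completed = forward_sample(model, n=n_samples, seed=data_seed)
    observed = hide_regulators(completed, model)

    all_cases = spurious_edge_cases(model.net, mode=mode)
    index_of = {c: i for i, c in enumerate(all_cases)}
    selected = all_cases if cases is None else list(cases)

    true_edges = model.net.edges
    records = []
    n_detected = 0
    n_fp = 0
    near_miss = 0
    for case in selected:
        ci = index_of[tuple(case)]
        injected_net = model.net.add_edges(case)
        case_gcfg = gcfg.replace(seed=(gcfg.seed + ci) % _SEED_CAP)
        report = classify_edges(injected_net, observed, case_gcfg, cfg)
        flagged = set(report.removed)
        detected = all(e in flagged for e in case)
        fp = tuple(sorted(flagged & true_edges))
        # weakness rank: 1 = highest removal score among all edges
        by_weakness = sorted(report.verdicts, key=lambda v: (-v.removal_score, v.edge))
        weak_rank = {v.edge: i + 1 for i, v in enumerate(by_weakness)}
        undetected = [e for e in case if e not in flagged]
        worst = min((weak_rank[e] for e in undetected), default=0)
        records.append(CaseRecord(ci, tuple(case), detected, fp, worst))
        n_detected += detected
        n_fp += len(fp)
        if not detected and undetected and worst <= 2:
            near_miss += 1

    return ExperimentReport(
        mode=mode,
        n_cases=len(selected),
        n_detected=n_detected,
        n_true_edge_false_positives=n_fp,
        near_miss=near_miss,
        cases=records,
    )
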