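"""Collapsed Gibbs sampling of hidden regulator states.

Regulator activities are never measured, so every (regulator, sample) cell of
the data matrix is missing.  The sampler draws these cells from their full
conditionals with the Dirichlet parameters integrated out: the conditional of
one cell given everything else is the product of leave-one-out
Dirichlet-multinomial predictive terms of the regulator's own (root) family
and each of its children's families,

    P(state = v)  ~  (a + N~_v) / (ra + N~_.)
                   * prod_children (a + N~^c_{j(v), k_c}) / (ra + N~^c_{j(v), .})

where N~ are family counts with the cell's sample left out and j(v) is the
child's parent configuration when this regulator takes state v.

A *sweep* resamples every hidden cell once in fixed (sorted regulator, sample
index) order.  After ``burn_in`` sweeps the current configuration is saved,
then one more configuration every ``thin`` sweeps until ``m`` are stored.
The hot loop is a numba-compiled kernel over incremental count arrays; the
pure-Python :func:`full_conditional` is the reference implementation the
kernel is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .network import BipartiteNetwork
from .preprocess import N_STATES
from .scoring import ScoreConfig, _radix_weights, counts_from_arrays, sorted_parents

_SEED_CAP = 2**31 - 1


@dataclass
class GibbsConfig:
    """Sampler settings.

    m : number of saved configurations (default 250; the regime where
        larger pools stop changing edge verdicts while smaller ones get
        noticeably noisier).
    burn_in : full sweeps before the first save (per chain).
    thin : sweeps between consecutive saves.
    seed : RNG seed; runs are bit-reproducible given the seed.
    n_chains : number of independently initialized chains the M saved
        configurations are pooled from.  The hidden-state posterior is
        multimodal (state relabelings, and role-stealing modes when an
        extra parent can shadow a true one), and a single chain essentially
        never hops between modes; pooling a few independent chains makes
        the completion set cover the modes the scores depend on.
    random_scan : resample cells in a freshly permuted order each sweep
        instead of the fixed systematic order (off by default).
    """

    m: int = 250
    burn_in: int = 100
    thin: int = 2
    seed: int = 0
    n_chains: int = 5
    random_scan: bool = False

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    def replace(self, **kw) -> "GibbsConfig":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


@dataclass
class CompletionSet:
    """M saved assignments of 3-state values to every (regulator, sample) cell.

    ``states`` has shape (m, n_regulators, n_samples); provenance fields
    record the network and sampler settings the set was drawn under.
    """

    regulator_ids: tuple
    sample_ids: tuple
    states: np.ndarray = field(repr=False)
    network_hash: str = ""
    seed: int = 0
    burn_in: int = 0
    thin: int = 1

    @property
    def m(self) -> int:
        return self.states.shape[0]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format audit table (configuration, regulator, sample, state)."""
        m, r, n = self.states.shape
        cfg_i, reg_i, smp_i = np.meshgrid(np.arange(m), np.arange(r), np.arange(n), indexing="ij")
        return pd.DataFrame(
            {
                "configuration": cfg_i.ravel(),
                "regulator": np.array(self.regulator_ids)[reg_i.ravel()] if r else [],
                "sample": np.array(self.sample_ids)[smp_i.ravel()] if r else [],
                "state": self.states.ravel(),
            }
        )

    def write_tsv(self, path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference full conditional (pure Python)


def full_conditional(reg: str, sample: str, assignment: pd.DataFrame, net: BipartiteNetwork, cfg: ScoreConfig) -> np.ndarray:
    """Normalized conditional distribution of one hidden cell.

    ``assignment`` is a fully completed matrix (regulator and gene rows); the
    named cell's current value is ignored (leave-one-out counts).
    """
    alpha = cfg.alpha
    cols = list(assignment.columns)
    s_idx = cols.index(sample)
    mask = np.ones(len(cols), dtype=bool)
    mask[s_idx] = False

    reg_row = assignment.loc[reg].to_numpy(dtype=np.int64)
    root_counts = np.bincount(reg_row[mask], minlength=N_STATES)
    p = (alpha + root_counts) / (N_STATES * alpha + root_counts.sum())

    for child in sorted(net.children_of(reg)):
        parents = list(sorted_parents(net, child))
        w = _radix_weights(len(parents))
        w_reg = int(w[parents.index(reg)])
        child_row = assignment.loc[child].to_numpy(dtype=np.int64)
        pstates = assignment.loc[parents].to_numpy(dtype=np.int64)
        counts = counts_from_arrays(child_row[mask], pstates[:, mask])
        j_base = int(w @ pstates[:, s_idx]) - w_reg * int(reg_row[s_idx])
        k = int(child_row[s_idx])
        for v in range(N_STATES):
            j = j_base + w_reg * v
            p[v] *= (alpha + counts[j, k]) / (N_STATES * alpha + counts[j].sum())
    return p / p.sum()


# ---------------------------------------------------------------------------
# numba kernel


@njit(cache=True)
def _one_sweep(x, h, pptr, pidx, pw, cptr, cidx, cw, gene_off, counts, root_counts, alpha, random_scan):  # pragma: no cover - exercised via sample_completions
    n_reg, n = h.shape
    n_cells = n_reg * n
    if random_scan:
        order = np.random.permutation(n_cells)
    else:
        order = np.arange(n_cells)
    p = np.empty(3)
    for t in range(n_cells):
        r = order[t] // n
        s = order[t] % n
        v_old = h[r, s]
        root_counts[r, v_old] -= 1
        nroot = root_counts[r, 0] + root_counts[r, 1] + root_counts[r, 2]
        for v in range(3):
            p[v] = (alpha + root_counts[r, v]) / (3.0 * alpha + nroot)
        for ci in range(cptr[r], cptr[r + 1]):
            g = cidx[ci]
            w = cw[ci]
            j_cur = 0
            for pi in range(pptr[g], pptr[g + 1]):
                j_cur += pw[pi] * h[pidx[pi], s]
            k = x[g, s]
            off = gene_off[g]
            counts[off + j_cur * 3 + k] -= 1
            base = j_cur - w * v_old
            for v in range(3):
                j3 = off + (base + w * v) * 3
                njk = counts[j3 + k]
                nj = counts[j3] + counts[j3 + 1] + counts[j3 + 2]
                p[v] *= (alpha + njk) / (3.0 * alpha + nj)
            # rescale long products so hub regulators cannot underflow
            pmax = max(p[0], max(p[1], p[2]))
            if pmax < 1e-250:
                p[0] /= pmax
                p[1] /= pmax
                p[2] /= pmax
        u = np.random.random() * (p[0] + p[1] + p[2])
        if u < p[0]:
            v_new = 0
        elif u < p[0] + p[1]:
            v_new = 1
        else:
            v_new = 2
        h[r, s] = v_new
        root_counts[r, v_new] += 1
        for ci in range(cptr[r], cptr[r + 1]):
            g = cidx[ci]
            j_cur = 0
            for pi in range(pptr[g], pptr[g + 1]):
                j_cur += pw[pi] * h[pidx[pi], s]
            counts[gene_off[g] + j_cur * 3 + x[g, s]] += 1


@njit(cache=True)
def _run_chain(x, h, pptr, pidx, pw, cptr, cidx, cw, gene_off, counts, root_counts, alpha, burn_in, thin, n_save, seed, random_scan, out):  # pragma: no cover
    np.random.seed(seed)
    for _ in range(burn_in):
        _one_sweep(x, h, pptr, pidx, pw, cptr, cidx, cw, gene_off, counts, root_counts, alpha, random_scan)
    out[0] = h
    for m in range(1, n_save):
        for _ in range(thin):
            _one_sweep(x, h, pptr, pidx, pw, cptr, cidx, cw, gene_off, counts, root_counts, alpha, random_scan)
        out[m] = h


def _index_network(net: BipartiteNetwork, observed: pd.DataFrame):
    """Flatten the bipartite structure into the integer arrays the kernel uses."""
    regs = sorted(net.regulators)
    genes = sorted(net.targets)
    reg_idx = {r: i for i, r in enumerate(regs)}
    x = observed.loc[genes].to_numpy(dtype=np.int8)

    pptr = [0]
    pidx, pw = [], []
    qs = []
    reg_children = {r: [] for r in regs}  # (gene index, radix weight of reg)
    for gi, g in enumerate(genes):
        parents = list(sorted_parents(net, g))
        w = _radix_weights(len(parents))
        for pos, par in enumerate(parents):
            pidx.append(reg_idx[par])
            pw.append(int(w[pos]))
            reg_children[par].append((gi, int(w[pos])))
        pptr.append(len(pidx))
        qs.append(N_STATES ** len(parents))

    cptr = [0]
    cidx, cw = [], []
    for r in regs:
        for gi, wv in reg_children[r]:
            cidx.append(gi)
            cw.append(wv)
        cptr.append(len(cidx))

    gene_off = np.concatenate([[0], np.cumsum(np.asarray(qs) * N_STATES)]).astype(np.int64)
    return {
        "regs": regs,
        "genes": genes,
        "x": x,
        "pptr": np.asarray(pptr, dtype=np.int64),
        "pidx": np.asarray(pidx, dtype=np.int64),
        "pw": np.asarray(pw, dtype=np.int64),
        "cptr": np.asarray(cptr, dtype=np.int64),
        "cidx": np.asarray(cidx, dtype=np.int64),
        "cw": np.asarray(cw, dtype=np.int64),
        "gene_off": gene_off[:-1],
        "counts_size": int(gene_off[-1]),
        "qs": qs,
    }


def sample_completions(net: BipartiteNetwork, observed: pd.DataFrame, gcfg: GibbsConfig, cfg: ScoreConfig) -> CompletionSet:
    """Draw M completions of the hidden regulator rows under ``net``.

    Hidden cells are initialized uniformly at random from {0,1,2} with
    ``gcfg.seed``; the chain then runs ``burn_in`` sweeps, saves, and keeps
    saving every ``thin`` sweeps.  Bit-identical across reruns with the same
    configuration.
    """
    missing = net.targets - set(observed.index)
    if missing:
        raise ValueError(f"observed data missing target rows: {sorted(missing)[:5]}")
    sample_ids = tuple(observed.columns)
    regs = sorted(net.regulators)
    n = len(sample_ids)

    if not regs:
        states = np.zeros((gcfg.m, 0, n), dtype=np.int8)
        return CompletionSet((), sample_ids, states, net.content_hash(), gcfg.seed, gcfg.burn_in, gcfg.thin)

    idx = _index_network(net, observed)
    chains = min(gcfg.n_chains, gcfg.m)  # never more chains than saves
    per_chain = [gcfg.m // chains + (1 if c < gcfg.m % chains else 0) for c in range(chains)]
    blocks = []
    for chain, m_c in enumerate(per_chain):
        rng = np.random.default_rng([gcfg.seed, chain])
        h = rng.integers(0, N_STATES, size=(len(regs), n), dtype=np.int8)
        kernel_seed = int(rng.integers(1, _SEED_CAP))

        # initial count arrays consistent with h
        counts = np.zeros(idx["counts_size"], dtype=np.int64)
        for gi in range(len(idx["genes"])):
            sl = slice(idx["pptr"][gi], idx["pptr"][gi + 1])
            ps = h[idx["pidx"][sl]]
            c = counts_from_arrays(idx["x"][gi].astype(np.int64), ps.astype(np.int64))
            counts[idx["gene_off"][gi] : idx["gene_off"][gi] + c.size] = c.ravel()
        root_counts = np.stack(
            [np.bincount(h[ri], minlength=N_STATES) for ri in range(len(regs))]
        ).astype(np.int64)

        out = np.empty((m_c, len(regs), n), dtype=np.int8)
        _run_chain(
            idx["x"], h, idx["pptr"], idx["pidx"], idx["pw"], idx["cptr"], idx["cidx"], idx["cw"],
            idx["gene_off"], counts, root_counts, float(cfg.alpha),
            gcfg.burn_in, gcfg.thin, m_c, kernel_seed, gcfg.random_scan, out,
        )
        blocks.append(out)
    states = np.concatenate(blocks, axis=0)
    return CompletionSet(tuple(regs), sample_ids, states, net.content_hash(), gcfg.seed, gcfg.burn_in, gcfg.thin)


def completions_from_states(net: BipartiteNetwork, observed: pd.DataFrame, states: np.ndarray) -> CompletionSet:
    """Wrap explicit state arrays (m, n_reg, n_samples) as a CompletionSet.

    Convenience for tests and for scoring fully observed synthetic data
    (m = 1, states = the true hidden values).
    """
    regs = tuple(sorted(net.regulators))
    states = np.asarray(states, dtype=np.int8)
    if states.ndim != 3 or states.shape[1] != len(regs) or states.shape[2] != observed.shape[1]:
        raise ValueError("states must have shape (m, n_regulators, n_samples)")
    return CompletionSet(regs, tuple(observed.columns), states, net.content_hash())
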