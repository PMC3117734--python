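"""Expression-matrix loading, gene selection and tertile discretization.

Expression data live in a pandas DataFrame with gene identifiers as the index
and sample identifiers as columns (genes x samples, continuous values).  A
discretized matrix has the same layout with values in {0, 1, 2} for
low / medium / high.

Discretization is equal-frequency per gene: within each gene row the samples
are rank-ordered (stable, ties broken by sample position) and split into three
near-equal bins.  Per-gene binning is what makes genes on different absolute
expression scales comparable: the method looks at co-variation patterns, not
levels.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .network import BipartiteNetwork

STATE_LOW, STATE_MEDIUM, STATE_HIGH = 0, 1, 2
N_STATES = 3


def load_expression(path) -> pd.DataFrame:
    """Load a genes x samples expression TSV.

    The file must have a header row of sample ids, gene ids in the first
    column and a fully numeric body.  Duplicate gene or sample ids and
    non-numeric cells are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene id(s): {dups[:5]}")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample id(s)")
    try:
        out = df.astype(float)
    except ValueError:
        for gene in df.index:
            for sample in df.columns:
                try:
                    float(df.at[gene, sample])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric value {df.at[gene, sample]!r} "
                        f"at gene {gene!r}, sample {sample!r}"
                    ) from None
        raise
    if out.isna().any().any():
        raise ValueError(f"{path}: missing cells are not allowed")
    if out.shape[1] < 3:
        raise ValueError(f"{path}: need at least 3 samples, got {out.shape[1]}")
    return out


def write_expression(expr: pd.DataFrame, path) -> None:
    """Write a genes x samples matrix as TSV (first column ``gene``)."""
    expr.to_csv(path, sep="\t", index_label="gene")


def select_top_variable_genes(expr: pd.DataFrame, k: int) -> list:
    """The ``k`` gene ids with the largest per-gene standard deviation.

    Population SD (divisor n) across samples; ties broken by input order.
    If ``k`` is at least the number of genes, all genes are returned in
    SD order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise ValueError("empty expression matrix")
    sd = expr.to_numpy(dtype=float).std(axis=1, ddof=0)
    order = np.argsort(-sd, kind="stable")  # stable: ties keep input order
    return [expr.index[i] for i in order[: min(k, len(order))]]


def intersect_with_targets(genes, net: BipartiteNetwork) -> list:
    """Subset of ``genes`` that are targets of ``net``, input order kept."""
    targets = net.targets
    return [g for g in genes if g in targets]


def _tertile_cuts(n: int) -> tuple:
    return math.ceil(n / 3), math.ceil(2 * n / 3)


def discretize_tertiles(expr: pd.DataFrame) -> pd.DataFrame:
    """Equal-frequency three-state discretization, per gene across samples.

    For each gene the samples are sorted by value (stable; ties broken by
    sample position), the lowest ceil(n/3) become low (0), the next block up
    to ceil(2n/3) medium (1), and the rest high (2).  Bin sizes therefore
    differ pairwise by at most one.
    """
    n = expr.shape[1]
    if n < 3:
        raise ValueError(f"need at least 3 samples to form tertiles, got {n}")
    c1, c2 = _tertile_cuts(n)
    values = expr.to_numpy(dtype=float)
    states = np.empty_like(values, dtype=np.int8)
    for i in range(values.shape[0]):
        order = np.argsort(values[i], kind="stable")
        states[i, order[:c1]] = STATE_LOW
        states[i, order[c1:c2]] = STATE_MEDIUM
        states[i, order[c2:]] = STATE_HIGH
    return pd.DataFrame(states, index=expr.index, columns=expr.columns)


def load_discrete(path) -> pd.DataFrame:
    """Load a discretized genes x samples TSV (body in {0,1,2})."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    arr = df.to_numpy()
    if not np.isin(arr, (0, 1, 2)).all():
        raise ValueError(f"{path}: discrete matrix values must be in {{0,1,2}}")
    return df.astype(np.int8)


def write_discrete(disc: pd.DataFrame, path) -> None:
    disc.to_csv(path, sep="\t", index_label="gene")


def validate_discrete(disc: pd.DataFrame) -> None:
    """Raise if a matrix is not a valid 3-state discrete matrix."""
    if disc.index.has_duplicates or disc.columns.has_duplicates:
        raise ValueError("duplicate gene or sample ids")
    if not np.isin(disc.to_numpy(), (0, 1, 2)).all():
        raise ValueError("discrete states must be in {0,1,2}")
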