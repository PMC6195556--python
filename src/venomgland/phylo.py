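"""Blomberg's K phylogenetic-signal statistic with a tip-shuffle
permutation test.

K compares the variance of phylogenetically independent contrasts implied
by the data with its Brownian-motion expectation on the given tree:

    K = (MSE0 / MSE) / E[MSE0 / MSE]

where ``MSE0`` is the mean squared deviation of tip values from the
phylogenetically (GLS) estimated root state using the raw mean, ``MSE`` the
GLS mean squared error under the Brownian covariance ``V`` built from
branch lengths, and the expectation is ``(tr(V) - n / sum(V^-1)) / (n-1)``.
K = 1 matches the Brownian expectation; K > 1 means relatives resemble one
another more than Brownian motion predicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd


@dataclass
class KResult:
    transcript_id: str
    K: float
    p_perm: float
    n_perm: int


def load_tree(newick: str) -> dendropy.Tree:
    """Parse a Newick tree (branch lengths required for signal tests)."""
    return dendropy.Tree.get(data=newick, schema="newick")


def _patristic(tree: dendropy.Tree):
    """Pairwise tip-to-tip path lengths plus distance-to-file-root, computed
    by deterministic traversal."""
    leaves = {}
    for lf in tree.leaf_node_iter():
        if lf.taxon is None:
            raise ValueError("tree has an unlabeled leaf")
        leaves[lf.taxon.label] = lf
    names = sorted(leaves)
    depth: Dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depth[id(node)] = (depth[id(parent)] + edge) if parent is not None else 0.0
    anc: Dict[str, List] = {}
    for name in names:
        chain = []
        node = leaves[name]
        while node is not None:
            chain.append(node)
            node = node.parent_node
        anc[name] = chain
    n = len(names)
    D = np.zeros((n, n))
    droot = np.array([depth[id(leaves[nm])] for nm in names])
    for i, a in enumerate(names):
        seta = {id(x) for x in anc[a]}
        for j in range(i + 1, n):
            mrca = next(x for x in anc[names[j]] if id(x) in seta)
            D[i, j] = D[j, i] = droot[i] + droot[j] - 2.0 * depth[id(mrca)]
    return D, droot, names


def bm_covariance(
    tree: dendropy.Tree,
    taxa: Optional[Sequence[str]] = None,
    midpoint_root: bool = True,
):
    """Brownian-motion tip covariance from branch lengths: V[i, j] is the
    root-to-MRCA path length of tips i and j.

    With ``midpoint_root`` (the convention for trees inferred without an
    outgroup) the root is the midpoint of the longest tip-to-tip path,
    located in closed form from the patristic distances -- deterministic
    and independent of how the Newick happens to be rooted.  Otherwise the
    file root is used as-is.  Returns (V, tip names).
    """
    D, droot, names = _patristic(tree)
    if taxa is not None:
        missing = [t for t in taxa if t not in names]
        if missing:
            raise ValueError(f"taxa not in tree: {missing}")
        idx = [names.index(t) for t in taxa]
        D, droot = D[np.ix_(idx, idx)], droot[idx]
        names = list(taxa)
    if midpoint_root:
        # diameter endpoints (deterministic tie-break via sorted names)
        i, j = np.unravel_index(int(np.argmax(D)), D.shape)
        diam = D[i, j]
        # distance from the midpoint of path(i, j) to each tip x:
        # max(D[i, x], D[j, x]) - diam/2
        droot = np.maximum(D[i], D[j]) - diam / 2.0
    V = (droot[:, None] + droot[None, :] - D) / 2.0
    np.fill_diagonal(V, droot)
    return V, names


def blomberg_k_from_cov(V: np.ndarray, x: np.ndarray) -> float:
    """Evaluate K given a Brownian covariance matrix and trait vector."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if V.shape != (n, n):
        raise ValueError("trait length does not match covariance dimension")
    if np.allclose(x, x[0]):
        raise ValueError("K is undefined for a constant trait")
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular Brownian covariance matrix") from exc
    ones = np.ones(n)
    denom = ones @ Vinv @ ones
    a_hat = (ones @ Vinv @ x) / denom
    resid = x - a_hat
    mse = (resid @ Vinv @ resid) / (n - 1)
    # MSE0 deviates from the GLS (phylogenetically correct) mean -- the
    # original definition, which K = 1 under Brownian motion calibrates to
    mse0 = (resid @ resid) / (n - 1)
    expected = (np.trace(V) - n / denom) / (n - 1)
    return float((mse0 / mse) / expected)


def blomberg_k(tree: dendropy.Tree, trait: pd.Series) -> float:
    """K for one trait; ``trait`` is indexed by tip label."""
    V, names = bm_covariance(tree, taxa=sorted(trait.index))
    x = trait.reindex(names).to_numpy(dtype=float)
    return blomberg_k_from_cov(V, x)


def permutation_test(
    tree: dendropy.Tree,
    trait: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> KResult:
    """Tip-shuffle null for K: p = (1 + #{K_perm >= K_obs}) / (n_perm + 1)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    V, names = bm_covariance(tree, taxa=sorted(trait.index))
    x = trait.reindex(names).to_numpy(dtype=float)
    k_obs = blomberg_k_from_cov(V, x)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        k_p = blomberg_k_from_cov(V, rng.permutation(x))
        if k_p >= k_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return KResult(transcript_id=str(trait.name or ""), K=k_obs, p_perm=p,
                   n_perm=n_perm)


def simulate_bm(V: np.ndarray, n_traits: int, seed: int = 0) -> np.ndarray:
    """Simulate traits under Brownian motion on a tree: rows are replicate
    trait vectors drawn from N(0, V)."""
    L = np.linalg.cholesky(V)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_traits, V.shape[0]))
    return z @ L.T


def k_per_transcript(
    tree: dendropy.Tree,
    ln_expression: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """K and permutation p for every row of a (transcripts x individuals)
    ln-expression matrix.  Constant rows are skipped."""
    V, names = bm_covariance(tree, taxa=sorted(ln_expression.columns))
    rng = np.random.default_rng(seed)
    rows = []
    for tid in ln_expression.index:
        x = ln_expression.loc[tid].reindex(names).to_numpy(dtype=float)
        if np.allclose(x, x[0]):
            continue
        k_obs = blomberg_k_from_cov(V, x)
        hits = sum(
            blomberg_k_from_cov(V, rng.permutation(x)) >= k_obs
            for _ in range(n_perm)
        )
        rows.append(
            {
                "transcript_id": tid,
                "K": k_obs,
                "p_perm": (1 + hits) / (n_perm + 1),
                "n_perm": n_perm,
            }
        )
    return pd.DataFrame(rows)
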