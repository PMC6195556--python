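"""Read mapping with a mismatch cap, TPM estimation with EM resolution of
multi-mapping reads, compositional transforms, toxin-class aggregation, and
expression clustering.

TPM for transcript *i* is ``1e6 * (c_i/l_i) / sum_j (c_j/l_j)`` where
``c_i`` are (expected) read counts and ``l_i`` effective lengths (here: CDS
length; no fragment-length correction).  Multi-mapping reads are resolved
by a standard EM: the E-step reassigns each read across its candidate
transcripts proportionally to current abundance over length, the M-step
renormalizes abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from ._seq import revcomp
from .validate import CoverageProfile

MAX_MISMATCHES = 3
ZERO_REPLACEMENT_DELTA = 0.65


@dataclass
class ReadAlignments:
    """Alignments of one individual's merged reads to a transcript set.

    ``candidates[r]`` lists ``(transcript index, start, end, distance)`` for
    read index ``r``; multi-mapping reads keep all candidates with equal
    initial weight.
    """

    transcript_ids: List[str]
    candidates: List[List[Tuple[int, int, int, int]]]
    n_reads: int = 0

    def n_aligned(self) -> int:
        return sum(1 for c in self.candidates if c)


def map_reads(
    merged_reads: Sequence,
    transcripts: Sequence,
    max_mismatches: int = MAX_MISMATCHES,
    individual_id: str = "",
) -> Tuple[ReadAlignments, Dict[str, CoverageProfile]]:
    """Align each read to every transcript reachable within
    ``max_mismatches`` combined substitutions/gaps (either strand).

    Returns the alignment candidates plus per-transcript CDS coverage
    profiles (each candidate placement increments depth).
    """
    if not transcripts:
        raise ValueError("consensus transcript set is empty")
    recs = [(t.id, t.sequence, t.cds) for t in transcripts]
    tids = [r[0] for r in recs]
    depth = {tid: np.zeros(c[1] - c[0], dtype=float) for tid, _, c in recs}
    nreads = {tid: 0 for tid in tids}
    candidates: List[List[Tuple[int, int, int, int]]] = []
    for read in merged_reads:
        s = read.sequence
        cand: List[Tuple[int, int, int, int]] = []
        if s:
            rc = revcomp(s)
            for ti, (tid, tseq, (cs, ce)) in enumerate(recs):
                best = None
                for q in (s, rc):
                    res = edlib.align(q, tseq, mode="HW", task="locations",
                                      k=max_mismatches)
                    d = res["editDistance"]
                    if d >= 0 and (best is None or d < best[0]):
                        loc = res["locations"][0]
                        best = (d, loc[0], loc[1] + 1)
                if best is not None:
                    d, start, end = best
                    cand.append((ti, start, end, d))
                    lo = max(start, cs) - cs
                    hi = min(end, ce) - cs
                    if hi > lo:
                        depth[tid][lo:hi] += 1
                    nreads[tid] += 1
        candidates.append(cand)
    profiles = {
        tid: CoverageProfile(
            transcript_id=tid,
            individual_id=individual_id,
            depth=depth[tid],
            n_reads=nreads[tid],
        )
        for tid in tids
    }
    return ReadAlignments(transcript_ids=tids, candidates=candidates,
                          n_reads=len(candidates)), profiles


@dataclass
class ExpressionResult:
    """EM output for one individual: expected counts and TPM per transcript."""

    counts: pd.Series
    tpm: pd.Series
    log_likelihoods: List[float] = field(default_factory=list)


def estimate_tpm(
    alignments: ReadAlignments,
    effective_lengths: Mapping[str, float],
    em_iters: int = 100,
    tol: float = 1e-8,
) -> ExpressionResult:
    """EM over multi-mapping weights, then TPM normalization.

    Uniquely mapping reads pin their transcript; multi-mappers are
    fractionally reassigned each E-step proportional to ``theta_i / l_i``.
    The per-iteration log-likelihood is tracked and is non-decreasing.
    """
    tids = alignments.transcript_ids
    n_t = len(tids)
    lens = np.array([float(effective_lengths[t]) for t in tids])
    if (lens <= 0).any():
        raise ValueError("effective lengths must be positive")
    # collapse reads to their candidate-transcript sets
    groups: Dict[Tuple[int, ...], int] = {}
    for cand in alignments.candidates:
        if not cand:
            continue
        key = tuple(sorted({c[0] for c in cand}))
        groups[key] = groups.get(key, 0) + 1
    n_aligned = sum(groups.values())
    if n_aligned == 0:
        raise ValueError("no reads aligned for this individual")
    keys = list(groups)
    weights = np.array([groups[k] for k in keys], dtype=float)

    theta = np.full(n_t, 1.0 / n_t)
    ll_hist: List[float] = []
    for _ in range(em_iters):
        rate = theta / lens
        counts = np.zeros(n_t)
        ll = 0.0
        for key, w in zip(keys, weights):
            idx = np.array(key)
            r = rate[idx]
            tot = r.sum()
            if tot <= 0:
                r = np.full(len(idx), 1.0 / len(idx))
                tot = 1.0
            counts[idx] += w * r / tot
            ll += w * np.log(tot)
        ll_hist.append(ll)
        new_theta = counts / n_aligned
        if np.abs(new_theta - theta).max() < tol:
            theta = new_theta
            break
        theta = new_theta

    rate = theta / lens
    counts = np.zeros(n_t)
    for key, w in zip(keys, weights):
        idx = np.array(key)
        r = rate[idx]
        tot = r.sum()
        if tot > 0:
            counts[idx] += w * r / tot
    denom = (counts / lens).sum()
    tpm = 1e6 * (counts / lens) / denom if denom > 0 else np.zeros(n_t)
    return ExpressionResult(
        counts=pd.Series(counts, index=tids),
        tpm=pd.Series(tpm, index=tids),
        log_likelihoods=ll_hist,
    )


def replace_zeros(matrix: pd.DataFrame,
                  delta_frac: float = ZERO_REPLACEMENT_DELTA) -> pd.DataFrame:
    """Multiplicative zero replacement, column-wise.

    Zeros become ``delta = delta_frac * min(nonzero in column)``; nonzero
    entries are scaled by ``1 - sum(deltas)/column_total`` so the column
    total is preserved.  Columns with no zeros pass through unchanged.
    """
    out = matrix.astype(float).copy()
    for col in out.columns:
        x = out[col].to_numpy(copy=True)
        if (x < 0).any():
            raise ValueError("negative entries are not compositional")
        zeros = x == 0
        if not zeros.any():
            continue
        if zeros.all():
            raise ValueError(f"column {col} is entirely zero")
        total = x.sum()
        delta = delta_frac * x[~zeros].min()
        x[~zeros] *= 1.0 - delta * zeros.sum() / total
        x[zeros] = delta
        out[col] = x
    return out


def clr(column) -> np.ndarray:
    """Centered log-ratio transform: ln(x_i) minus the mean of the logs."""
    x = np.asarray(column, dtype=float)
    if (x <= 0).any():
        raise ValueError("clr requires strictly positive input")
    lx = np.log(x)
    return lx - lx.mean()


def clr_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {col: clr(matrix[col]) for col in matrix.columns}, index=matrix.index
    )


def sum_by_class(
    expression: pd.DataFrame, families: Mapping[str, str]
) -> pd.DataFrame:
    """Sum expression rows by toxin class (gene family).

    Every row of ``expression`` must have a family label; per column, class
    totals conserve the transcript totals.
    """
    missing = [t for t in expression.index if t not in families or not families[t]]
    if missing:
        raise ValueError(f"transcripts without family annotation: {missing[:5]}")
    fam = pd.Series({t: families[t] for t in expression.index})
    out = expression.groupby(fam).sum()
    return out.sort_index()


@dataclass
class ClusteringResult:
    linkage_rows: Optional[np.ndarray]
    linkage_cols: np.ndarray
    row_order: List[str]
    col_order: List[str]


def expression_cluster(
    matrix_ln: pd.DataFrame,
    method: str = "average",
    metric: str = "euclidean",
) -> ClusteringResult:
    """Agglomerative clustering of a (transcripts x individuals) ln-expression
    matrix, rows and columns.  Input is sorted by label first so the result
    is invariant to input permutation."""
    if matrix_ln.shape[1] < 2:
        raise ValueError("clustering needs at least two individuals")
    if not np.isfinite(matrix_ln.to_numpy()).all():
        raise ValueError("clustering requires finite entries")
    m = matrix_ln.sort_index(axis=0).sort_index(axis=1)
    zc = hierarchy.linkage(pdist(m.to_numpy().T, metric=metric), method=method)
    col_order = [m.columns[i] for i in hierarchy.leaves_list(zc)]
    zr = None
    row_order = list(m.index)
    if m.shape[0] >= 2:
        zr = hierarchy.linkage(pdist(m.to_numpy(), metric=metric), method=method)
        row_order = [m.index[i] for i in hierarchy.leaves_list(zr)]
    return ClusteringResult(
        linkage_rows=zr, linkage_cols=zc, row_order=row_order, col_order=col_order
    )


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(Z)

    def rec(node):
        if node.is_leaf():
            return f"{labels[node.id]}:{0.0:.6g}"
        left = rec(node.left)
        right = rec(node.right)
        return f"({left},{right}):{node.dist:.6g}"

    return rec(tree) + ";"


def tpm_matrix(
    results: Mapping[str, ExpressionResult], transcript_ids: Sequence[str]
) -> pd.DataFrame:
    """Assemble per-individual EM results into a transcripts x individuals
    TPM matrix (column order = sorted individual ids)."""
    cols = {}
    for ind in sorted(results):
        cols[ind] = results[ind].tpm.reindex(transcript_ids).fillna(0.0)
    df = pd.DataFrame(cols, index=list(transcript_ids))
    sums = df.sum(axis=0)
    bad = sums[(sums - 1e6).abs() > 1.0]
    if len(bad):
        warnings.warn(f"TPM columns deviating from 1e6: {list(bad.index)}")
    return df


def counts_matrix(
    results: Mapping[str, ExpressionResult], transcript_ids: Sequence[str]
) -> pd.DataFrame:
    cols = {
        ind: results[ind].counts.reindex(transcript_ids).fillna(0.0)
        for ind in sorted(results)
    }
    return pd.DataFrame(cols, index=list(transcript_ids))
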