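"""Coverage-based screens: chimera detection, toxin presence/absence
calling, and shared-nontoxin-locus selection.

Two distinct absence rules coexist and are deliberately not interchangeable:

* the toxin reporting rule -- a transcript is absent from an individual
  when more than 10% of its coding sequence has depth below 5x (computed
  from mismatch-tolerant alignments);
* the shared-nontoxin rule used to pick phylogenetic loci -- a locus is
  kept only when every individual covers every site at least once (also
  from mismatch-tolerant alignments).

The chimera screen consumes zero-mismatch coverage of the assembling
individual's own reads: true transcripts are covered wall to wall, whereas
a chimeric fusion of two parents shows a coverage discontinuity at the
breakpoint (no real read spans it without mismatches).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp

VERDICT_KEEP = "keep"
VERDICT_REMOVE_ZERO = "remove-zero"
VERDICT_REMOVE_CHIMERIC = "remove-chimeric"
VERDICT_FLAG = "flag"

TOXIN_MIN_DEPTH = 5
TOXIN_MAX_LOW_FRAC = 0.10
CHIMERA_RATIO = 10.0
CHIMERA_WINDOW = 25
CHIMERA_MIN_SEG_FRAC = 0.10


@dataclass
class CoverageProfile:
    """Per-base depth over the coding sequence of one transcript in one
    individual."""

    transcript_id: str
    individual_id: str
    depth: np.ndarray
    n_reads: int = 0

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D vector")


def strict_align_coverage(
    merged_reads: Sequence,
    transcripts: Sequence,
    individual_id: str = "",
) -> Dict[str, CoverageProfile]:
    """Zero-mismatch coverage: each read is placed at every exact full-length
    occurrence (either strand) in each transcript, incrementing depth over
    the covered CDS bases.

    ``transcripts`` may be any objects with ``id``, ``sequence`` and ``cds``
    attributes.  Returns a profile per transcript (CDS coordinates).
    """
    profiles: Dict[str, CoverageProfile] = {}
    seqs = [(t.id, t.sequence, t.cds) for t in transcripts]
    depth = {tid: np.zeros(c[1] - c[0], dtype=float) for tid, _, c in seqs}
    nreads = {tid: 0 for tid, _, _ in seqs}
    for read in merged_reads:
        s = read.sequence
        if not s:
            continue
        rc = revcomp(s)
        for tid, tseq, (cs, ce) in seqs:
            placed = False
            for q in (s, rc):
                start = tseq.find(q)
                while start != -1:
                    placed = True
                    lo = max(start, cs) - cs
                    hi = min(start + len(q), ce) - cs
                    if hi > lo:
                        depth[tid][lo:hi] += 1
                    start = tseq.find(q, start + 1)
                if rc == s:
                    break
            if placed:
                nreads[tid] += 1
    for tid, _, _ in seqs:
        profiles[tid] = CoverageProfile(
            transcript_id=tid,
            individual_id=individual_id,
            depth=depth[tid],
            n_reads=nreads[tid],
        )
    return profiles


def _smooth(depth: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(depth) <= window:
        return depth.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(depth.astype(float), pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(depth)]
    return out


def chimera_screen(
    profile: CoverageProfile,
    max_ratio: float = CHIMERA_RATIO,
    window: int = CHIMERA_WINDOW,
    min_seg_frac: float = CHIMERA_MIN_SEG_FRAC,
) -> str:
    """Classify a transcript from its zero-mismatch coverage profile.

    * any zero-depth CDS base            -> ``remove-zero``
    * >``max_ratio``-fold depth range AND a two-segment changepoint whose
      segment means differ by >``max_ratio`` (segments each >=
      ``min_seg_frac`` of the CDS)      -> ``remove-chimeric``
    * >``max_ratio``-fold range without such a changepoint -> ``flag``
    * otherwise                          -> ``keep``
    """
    d = profile.depth
    if d.size == 0:
        raise ValueError(f"empty coverage profile for {profile.transcript_id}")
    if (d == 0).any():
        return VERDICT_REMOVE_ZERO
    if d.max() / d.min() <= max_ratio:
        return VERDICT_KEEP
    sm = _smooth(d, window)
    n = len(sm)
    lo = max(1, int(np.ceil(min_seg_frac * n)))
    hi = n - lo
    if hi > lo:
        csum = np.concatenate([[0.0], np.cumsum(sm)])
        splits = np.arange(lo, hi + 1)
        left_mean = csum[splits] / splits
        right_mean = (csum[n] - csum[splits]) / (n - splits)
        big = np.maximum(left_mean, right_mean)
        small = np.minimum(left_mean, right_mean)
        if (big > max_ratio * small).any():
            return VERDICT_REMOVE_CHIMERIC
    return VERDICT_FLAG


def call_absence_toxin(
    profile: CoverageProfile,
    min_depth: int = TOXIN_MIN_DEPTH,
    max_low_frac: float = TOXIN_MAX_LOW_FRAC,
) -> bool:
    """True (absent) iff strictly more than ``max_low_frac`` of CDS bases
    have depth below ``min_depth``.  Expects mismatch-tolerant coverage."""
    d = profile.depth
    if d.size == 0:
        raise ValueError(f"empty coverage profile for {profile.transcript_id}")
    return float((d < min_depth).mean()) > max_low_frac


def absence_matrix_toxin(
    profiles_by_individual: Mapping[str, Mapping[str, CoverageProfile]],
    transcript_ids: Sequence[str],
) -> pd.DataFrame:
    """Toxin absence matrix (True = absent) from per-individual coverage."""
    inds = sorted(profiles_by_individual)
    data = {
        ind: [
            call_absence_toxin(profiles_by_individual[ind][tid])
            for tid in transcript_ids
        ]
        for ind in inds
    }
    return pd.DataFrame(data, index=list(transcript_ids))


def select_shared_nontoxin_loci(
    profiles_by_individual: Mapping[str, Mapping[str, CoverageProfile]],
    locus_ids: Sequence[str],
) -> List[str]:
    """Loci covered at depth >= 1 at every site in every individual."""
    kept = []
    for tid in locus_ids:
        ok = True
        for ind in profiles_by_individual:
            try:
                prof = profiles_by_individual[ind][tid]
            except KeyError as exc:
                raise KeyError(
                    f"missing coverage profile for locus {tid} in individual {ind}"
                ) from exc
            if (prof.depth < 1).any():
                ok = False
                break
        if ok:
            kept.append(tid)
    return kept
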