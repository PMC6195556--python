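"""Greedy seed-extension de novo assembly of merged reads.

Seeds are drawn uniformly without replacement from the merged-read pool and
extended in both directions by exact overlaps of a fixed length: at each
step the contig's terminal overlap-mer is looked up in a read index, reads
whose overlapping portion matches the contig exactly become extension
candidates, and the contig grows by the longest extension on which all
candidates agree.  Extension halts when no read overlaps (``no-overlap``),
when candidate reads disagree on the next base (``ambiguous``), or when the
terminal overlap-mer repeats within the walk (``cycle-guard``).  Contigs
fully contained in another contig (either strand) are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from ._seq import revcomp
from .reads import MergedRead

DEFAULT_OVERLAP = 120
DEFAULT_N_SEEDS = 1000

STOP_NO_OVERLAP = "no-overlap"
STOP_AMBIGUOUS = "ambiguous"
STOP_CYCLE = "cycle-guard"


@dataclass
class Contig:
    id: str
    sequence: str
    seed_id: str
    n_reads_used: int
    left_stop: str
    right_stop: str

    def __len__(self):
        return len(self.sequence)


class OverlapIndex:
    """Exact-match lookup from any length-``overlap`` string to the reads
    containing it (both orientations) at a known offset."""

    def __init__(self, reads: Iterable[MergedRead], overlap: int = DEFAULT_OVERLAP):
        if overlap < 1:
            raise ValueError("overlap must be >= 1")
        self.overlap = overlap
        self.windows: Dict[str, List[Tuple[str, int, str]]] = {}
        n_short = 0
        for read in reads:
            s = read.sequence
            if len(s) < overlap:
                n_short += 1
                continue
            for oriented in (s, revcomp(s)):
                for p in range(len(oriented) - overlap + 1):
                    key = oriented[p : p + overlap]
                    self.windows.setdefault(key, []).append((read.id, p, oriented))
        if n_short:
            warnings.warn(
                f"{n_short} reads shorter than overlap={overlap} were excluded"
            )

    def prefix_matches(self, key: str) -> List[Tuple[str, int, str]]:
        """Reads whose oriented prefix of length ``overlap`` equals ``key``."""
        return [(rid, p, s) for rid, p, s in self.windows.get(key, []) if p == 0]

    def matches(self, key: str) -> List[Tuple[str, int, str]]:
        return self.windows.get(key, [])


def build_overlap_index(reads: Iterable[MergedRead],
                        overlap: int = DEFAULT_OVERLAP) -> OverlapIndex:
    return OverlapIndex(reads, overlap=overlap)


def _extend_right(
    contig: str,
    index: OverlapIndex,
    used_at: Dict[str, Tuple[int, int]],
    min_agreement: float,
) -> Tuple[str, str]:
    """Extend ``contig`` rightwards one base at a time.

    At each step the reads containing the contig's terminal overlap-mer
    (and whose bases left of it agree with the contig) vote on the next
    base.  Each read is usable at a single placement per contig:
    ``used_at`` maps read id to its (implied start, length) in contig
    coordinates, and a candidate whose implied placement contradicts an
    earlier one is ignored (this is what stops a read's reverse complement
    re-entering through a short repeated window).  With ``min_agreement``
    = 1.0 any disagreement halts extension (the conservative default);
    lower values extend along the plurality base as long as it carries at
    least that fraction of the votes.  Returns (contig, stop reason).
    """
    overlap = index.overlap
    seen_tails = set()
    while True:
        tail = contig[-overlap:]
        if tail in seen_tails:
            return contig, STOP_CYCLE
        seen_tails.add(tail)
        votes: Dict[str, List[Tuple[str, int, int]]] = {}
        for rid, p, s in index.matches(tail):
            start = len(contig) - overlap - p
            prev = used_at.get(rid)
            if prev is not None and prev[0] != start:
                continue
            # the read's bases left of the matched window must agree with
            # the contig (only over the part that lies within the contig)
            q = min(p, len(contig) - overlap)
            if q > 0 and s[p - q : p] != contig[len(contig) - overlap - q : len(contig) - overlap]:
                continue
            if p + overlap < len(s):
                votes.setdefault(s[p + overlap], []).append((rid, start, len(s)))
        if not votes:
            return contig, STOP_NO_OVERLAP
        total = sum(len(v) for v in votes.values())
        base, winners = max(votes.items(), key=lambda kv: (len(kv[1]), kv[0]))
        if len(winners) / total < min_agreement:
            return contig, STOP_AMBIGUOUS
        for rid, start, slen in winners:
            used_at[rid] = (start, slen)
        contig = contig + base


def extend_seed(
    seed: MergedRead, index: OverlapIndex, min_agreement: float = 1.0
) -> Contig:
    """Extend one seed read in both directions."""
    overlap = index.overlap
    if len(seed.sequence) < overlap:
        raise ValueError(
            f"seed {seed.id} shorter than overlap ({len(seed.sequence)} < {overlap})"
        )
    used_at: Dict[str, Tuple[int, int]] = {seed.id: (0, len(seed.sequence))}
    contig, right_stop = _extend_right(seed.sequence, index, used_at, min_agreement)
    # flip coordinates for the left phase so placements stay consistent
    L = len(contig)
    flipped_used = {rid: (L - (st + sl), sl) for rid, (st, sl) in used_at.items()}
    flipped, left_stop = _extend_right(
        revcomp(contig), index, flipped_used, min_agreement
    )
    contig = revcomp(flipped)
    return Contig(
        id=f"contig-{seed.id}",
        sequence=contig,
        seed_id=seed.id,
        n_reads_used=len(flipped_used),
        left_stop=left_stop,
        right_stop=right_stop,
    )


def _contained(seq: str, others: Sequence[str]) -> bool:
    rc = revcomp(seq)
    return any(seq in o or rc in o for o in others)


def assemble(
    reads: Sequence[MergedRead],
    n_seeds: int = DEFAULT_N_SEEDS,
    overlap: int = DEFAULT_OVERLAP,
    rng_seed: int = 0,
    min_agreement: float = 1.0,
) -> List[Contig]:
    """Assemble contigs from ``n_seeds`` uniformly sampled seed reads.

    Reads are sorted by id before sampling so the output is invariant to
    input order for a fixed ``rng_seed``.  Seeds shorter than ``overlap``
    are skipped.  Contigs contained in a longer contig (either strand) are
    dropped.  ``min_agreement`` is the per-base vote fraction required to
    extend (1.0 = halt on any disagreement; lower values assemble through
    sparse sequencing errors and rely on the downstream coverage screens
    to catch mis-joins).
    """
    if not reads:
        raise ValueError("no reads to assemble")
    ordered = sorted(reads, key=lambda r: r.id)
    index = build_overlap_index(ordered, overlap=overlap)
    rng = np.random.default_rng(rng_seed)
    n = min(n_seeds, len(ordered))
    picks = rng.choice(len(ordered), size=n, replace=False)
    contigs: List[Contig] = []
    for j in picks:
        seed = ordered[int(j)]
        if len(seed.sequence) < overlap:
            continue
        contigs.append(extend_seed(seed, index, min_agreement=min_agreement))
    # containment dedupe, longest first; ties broken lexicographically
    contigs.sort(key=lambda c: (-len(c.sequence), c.sequence, c.id))
    kept: List[Contig] = []
    kept_seqs: List[str] = []
    for c in contigs:
        if _contained(c.sequence, kept_seqs):
            continue
        kept.append(c)
        kept_seqs.append(c.sequence)
    return kept


def find_exact_placements(contig: str, reads: Sequence[MergedRead]):
    """All zero-mismatch placements of reads on ``contig`` (both strands),
    as (start, end, read id) intervals."""
    placements = []
    for read in reads:
        for s in (read.sequence, revcomp(read.sequence)):
            start = contig.find(s)
            while start != -1:
                placements.append((start, start + len(s), read.id))
                start = contig.find(s, start + 1)
            if s == read.sequence and s == revcomp(s):
                break
    return placements


def chain_validate(contig: str, reads: Sequence[MergedRead],
                   overlap: int) -> bool:
    """Check that ``contig`` is spelled by a chain of exactly matching reads
    whose consecutive placements overlap by at least ``overlap`` bases.

    This is the independent re-validation of assembly output: greedy
    interval chaining over zero-mismatch read placements.
    """
    placements = sorted(set(find_exact_placements(contig, reads)))
    if not placements:
        return False
    starts = [p for p in placements if p[0] == 0]
    if not starts:
        return False
    end = max(p[1] for p in starts)
    if end >= len(contig):
        return True
    while True:
        # next read must start early enough to overlap the chain by `overlap`
        candidates = [p for p in placements if p[0] <= end - overlap and p[1] > end]
        if not candidates:
            return False
        end = max(p[1] for p in candidates)
        if end >= len(contig):
            return True
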