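"""Raw-read processing: cross-sample contamination filtering, quality
trimming, and overlap merging of read pairs.

Libraries on a shared sequencing lane can bleed into each other when reads
are mis-assigned during demultiplexing.  The filter implemented here works
from k-mer census tables of each sample's raw reads: a k-mer is treated as
contaminant-indicative for a focal sample when it is strongly and
asymmetrically enriched in another sample on the same lane, and a read is
discarded when at least a fixed fraction of its k-mer windows are
indicative.  Filtering precedes quality trimming, which precedes pair
merging, mirroring the order in which these steps are normally applied to
venom-gland libraries.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from ._seq import revcomp

DEFAULT_K = 57
DEFAULT_FRACTION = 0.25
DEFAULT_ENRICHMENT = 10.0
DEFAULT_MIN_OTHER = 2
DEFAULT_PHRED_MIN = 5


@dataclass
class SequencingRead:
    """A single read with per-base phred qualities and provenance labels."""

    id: str
    sequence: str
    quality: tuple
    sample_id: str = ""
    lane_id: str = ""
    mate: int = 1

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )

    def __len__(self):
        return len(self.sequence)


@dataclass
class MergedRead:
    """A fragment reconstructed by merging an overlapping read pair."""

    id: str
    sequence: str
    quality: tuple
    sample_id: str = ""

    def __len__(self):
        return len(self.sequence)


@dataclass
class KmerProfile:
    """Canonical k-mer counts over one sample's raw reads."""

    sample_id: str
    k: int = DEFAULT_K
    counts: Counter = field(default_factory=Counter)


def canonical(kmer: str) -> str:
    """Strand-collapsed representative: lexicographic min of k-mer and its
    reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _windows(seq: str, k: int):
    """Yield canonical k-mers over all windows of ``seq``; windows containing
    N are skipped."""
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        yield canonical(w)


def count_kmers(reads: Iterable[SequencingRead], k: int = DEFAULT_K,
                sample_id: str | None = None) -> KmerProfile:
    """Census of canonical k-mers across a sample's reads.

    Reads shorter than ``k`` contribute nothing (a warning is emitted once).
    """
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be a positive odd integer")
    counts: Counter = Counter()
    warned = False
    sid = sample_id
    for read in reads:
        if sid is None:
            sid = read.sample_id
        if len(read.sequence) < k:
            if not warned:
                warnings.warn(f"reads shorter than k={k} contribute no k-mers")
                warned = True
            continue
        counts.update(_windows(read.sequence, k))
    return KmerProfile(sample_id=sid or "", k=k, counts=counts)


def find_contaminant_reads(
    focal_reads: Sequence[SequencingRead],
    focal_profile: KmerProfile,
    other_profiles: Sequence[KmerProfile],
    fraction: float = DEFAULT_FRACTION,
    enrichment: float = DEFAULT_ENRICHMENT,
    min_other_count: int = DEFAULT_MIN_OTHER,
) -> set:
    """Identify reads in the focal sample that look demultiplex-misassigned.

    A k-mer is contaminant-indicative iff for some other same-lane sample its
    count there is >= ``min_other_count`` and >= ``enrichment`` * (focal
    count + 1).  A read is flagged iff the fraction of its valid k-mer
    windows that are indicative is >= ``fraction``.

    Returns the set of read ids to drop.
    """
    if not other_profiles:
        raise ValueError("at least one other same-lane profile is required")
    k = focal_profile.k
    for p in other_profiles:
        if p.k != k:
            raise ValueError(f"profile k mismatch: {p.k} != {k}")
    focal_counts = focal_profile.counts
    others = [p.counts for p in other_profiles]
    # cache the indicative verdict per k-mer: reads share most windows
    verdict: dict = {}
    drop: set = set()
    for read in focal_reads:
        n_valid = 0
        n_ind = 0
        for km in _windows(read.sequence, k):
            n_valid += 1
            v = verdict.get(km)
            if v is None:
                fc = focal_counts.get(km, 0)
                bar = enrichment * (fc + 1)
                v = any(
                    oc >= min_other_count and oc >= bar
                    for oc in (o.get(km, 0) for o in others)
                )
                verdict[km] = v
            if v:
                n_ind += 1
        if n_valid and n_ind / n_valid >= fraction:
            drop.add(read.id)
    return drop


def _mate_id(read_id: str) -> str | None:
    if read_id.endswith("/1"):
        return read_id[:-2] + "/2"
    if read_id.endswith("/2"):
        return read_id[:-2] + "/1"
    return None


def decontaminate_lane(
    reads_by_sample: Mapping[str, Sequence[SequencingRead]],
    k: int = DEFAULT_K,
    fraction: float = DEFAULT_FRACTION,
    enrichment: float = DEFAULT_ENRICHMENT,
    min_other_count: int = DEFAULT_MIN_OTHER,
    drop_pairs: bool = True,
):
    """Run the pairwise contamination filter across all samples of one lane.

    Profiles are computed from the raw reads of every sample, then each
    sample is screened against all others (symmetric, all pairwise
    comparisons).  Because demultiplex mis-assignment acts on whole
    clusters, both mates of a fragment land in the wrong sample together;
    with ``drop_pairs`` (the default) flagging either mate of a
    ``.../1``-``.../2`` pair removes both.  Returns
    ``(kept_by_sample, dropped_ids_by_sample)``.
    """
    if len(reads_by_sample) < 2:
        raise ValueError("contamination filtering needs >=2 samples per lane")
    profiles = {
        s: count_kmers(rs, k=k, sample_id=s) for s, rs in reads_by_sample.items()
    }
    kept = {}
    dropped = {}
    for s, rs in reads_by_sample.items():
        others = [p for t, p in profiles.items() if t != s]
        drop = find_contaminant_reads(
            rs, profiles[s], others,
            fraction=fraction, enrichment=enrichment,
            min_other_count=min_other_count,
        )
        if drop_pairs:
            present = {r.id for r in rs}
            mates = {m for m in (_mate_id(d) for d in drop) if m in present}
            drop = drop | mates
        kept[s] = [r for r in rs if r.id not in drop]
        dropped[s] = drop
    return kept, dropped


def quality_trim(read: SequencingRead, phred_min: int = DEFAULT_PHRED_MIN):
    """3' quality trim: cut at the first base whose phred score falls below
    ``phred_min``; everything 5' of the cut is kept.

    Returns ``(trimmed_read, discarded)`` where ``discarded`` is True when
    nothing survives.
    """
    cut = len(read.quality)
    for i, q in enumerate(read.quality):
        if q < phred_min:
            cut = i
            break
    if cut == 0:
        return replace(read, sequence="", quality=()), True
    if cut == len(read.quality):
        return read, False
    return replace(read, sequence=read.sequence[:cut], quality=read.quality[:cut]), False


def merge_pairs(
    r1: SequencingRead,
    r2: SequencingRead,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
):
    """Merge a read pair by its best ungapped 3' overlap.

    ``r2`` is reverse complemented; every overlap length ``o`` (suffix of r1
    against prefix of rc(r2)) with ``o >= min_overlap`` and mismatch
    fraction <= ``max_mismatch_frac`` is a candidate.  The candidate with
    the most matching bases wins (ties to the longer overlap).  Disagreeing
    overlap bases take the higher-quality call.  Returns a
    :class:`MergedRead`, or None when no qualifying overlap exists.
    """
    s1, q1 = r1.sequence, r1.quality
    s2 = revcomp(r2.sequence)
    q2 = r2.quality[::-1]
    best = None  # (matches, o)
    max_o = min(len(s1), len(s2))
    for o in range(min_overlap, max_o + 1):
        a = s1[len(s1) - o :]
        b = s2[:o]
        mism = sum(x != y for x, y in zip(a, b))
        if mism / o <= max_mismatch_frac:
            cand = (o - mism, o)
            if best is None or cand > best:
                best = cand
    if best is None:
        return None
    o = best[1]
    left = s1[: len(s1) - o]
    lq = q1[: len(s1) - o]
    ov_seq = []
    ov_q = []
    for i in range(o):
        a, qa = s1[len(s1) - o + i], q1[len(s1) - o + i]
        b, qb = s2[i], q2[i]
        if a == b:
            ov_seq.append(a)
            ov_q.append(max(qa, qb))
        elif qa >= qb:
            ov_seq.append(a)
            ov_q.append(qa)
        else:
            ov_seq.append(b)
            ov_q.append(qb)
    right = s2[o:]
    rq = q2[o:]
    seq = left + "".join(ov_seq) + right
    qual = tuple(lq) + tuple(ov_q) + tuple(rq)
    base_id = r1.id[:-2] if r1.id.endswith(("/1", "/2")) else r1.id
    return MergedRead(id=base_id, sequence=seq, quality=qual, sample_id=r1.sample_id)
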