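"""Annotation against a curated reference set, greedy identity clustering,
and species-consensus transcriptome construction.

Identity between two sequences follows the convention of greedy redundancy
clusterers: the number of matching columns over the length of the shorter
sequence, with the shorter sequence aligned against the best-matching
region of the longer (both strands considered).  Edit distance is computed
with edlib, so "matching columns" is approximated as shorter-length minus
edit distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import edlib

from ._seq import revcomp

AUTO_ANNOTATION_THRESHOLD = 0.80
CONSENSUS_CLUSTER_THRESHOLD = 0.98


@dataclass
class Transcript:
    """An annotated coding sequence with per-individual provenance."""

    id: str
    sequence: str
    cds: Tuple[int, int] = (0, 0)
    annotation: str = "unannotated"  # toxin family, "nontoxin", or "unannotated"
    family: str = ""
    reference_id: Optional[str] = None
    identity: float = 0.0
    signal_peptide: Optional[Tuple[int, int]] = None
    source_individuals: Set[str] = field(default_factory=set)

    @property
    def is_toxin(self) -> bool:
        return self.annotation not in ("nontoxin", "unannotated")

    def cds_sequence(self) -> str:
        return self.sequence[self.cds[0] : self.cds[1]]

    def __len__(self):
        return len(self.sequence)


@dataclass
class ReferenceRecord:
    id: str
    sequence: str
    family: str  # toxin family, or "nontoxin"
    cds: Tuple[int, int] = (0, 0)
    signal_peptide: Optional[Tuple[int, int]] = None


@dataclass
class Cluster:
    representative_id: str
    member_ids: List[str]


@dataclass
class ConsensusTranscriptome:
    transcripts: List[Transcript]
    clustering_threshold: float = CONSENSUS_CLUSTER_THRESHOLD
    clusters: List[Cluster] = field(default_factory=list)

    def __iter__(self):
        return iter(self.transcripts)

    def __len__(self):
        return len(self.transcripts)

    def get(self, tid: str) -> Transcript:
        for t in self.transcripts:
            if t.id == tid:
                return t
        raise KeyError(tid)


def sequence_identity(a: str, b: str) -> float:
    """Fraction of the shorter sequence matching its best hit in the longer
    one, maximized over strands.  Returns 0 for empty input."""
    if not a or not b:
        return 0.0
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    best = len(query) + 1
    for q in (query, revcomp(query)):
        res = edlib.align(q, target, mode="HW", task="distance")
        d = res["editDistance"]
        if d >= 0:
            best = min(best, d)
    return max(0.0, 1.0 - best / len(query))


def greedy_identity_cluster(
    records: Sequence[Tuple[str, str]], threshold: float
) -> List[Cluster]:
    """Greedy incremental clustering by identity to cluster representatives.

    Records (id, sequence) are visited by decreasing length (ties broken by
    sequence then id, so clustering is deterministic); each joins the first
    existing cluster whose representative it matches at >= ``threshold``,
    else founds a new cluster.  Because of the visiting order the founder is
    always the longest member, and remains the representative.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r[1]), r[1], r[0]))
    clusters: List[Cluster] = []
    reps: List[str] = []
    for rid, seq in ordered:
        placed = False
        for cl, rep_seq in zip(clusters, reps):
            if sequence_identity(seq, rep_seq) >= threshold:
                cl.member_ids.append(rid)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative_id=rid, member_ids=[rid]))
            reps.append(seq)
    return clusters


def _locate_cds(contig: str, ref: ReferenceRecord) -> Tuple[int, int]:
    """Map the reference CDS onto the contig by aligning the reference CDS
    subsequence; trimmed to a codon multiple."""
    cds_seq = ref.sequence[ref.cds[0] : ref.cds[1]]
    if not cds_seq:
        return (0, len(contig) // 3 * 3)
    best = None  # (distance, start, end)
    for q in (cds_seq, revcomp(cds_seq)):
        res = edlib.align(q, contig, mode="HW", task="locations")
        d = res["editDistance"]
        if d >= 0 and (best is None or d < best[0]):
            s, e = res["locations"][0]
            best = (d, s, e + 1)
    if best is None:
        return (0, len(contig) // 3 * 3)
    start, end = best[1], best[2]
    end = start + (end - start) // 3 * 3
    return (start, end)


def annotate_by_reference(
    contigs: Sequence[Tuple[str, str]],
    reference: Sequence[ReferenceRecord],
    auto_threshold: float = AUTO_ANNOTATION_THRESHOLD,
    individual_id: Optional[str] = None,
) -> Tuple[List[Transcript], List[Transcript]]:
    """Annotate contigs by best identity match to a curated reference.

    A contig at identity >= ``auto_threshold`` to its best toxin reference
    inherits that record's family, CDS placement, and signal peptide; best
    matches in the nontoxin reference yield the ``nontoxin`` annotation.
    Everything below threshold lands in the manual-review queue (returned
    second), annotated ``unannotated`` with its longest-ORF CDS.

    Returns ``(annotated, review_queue)``; the review queue is a subset of
    the annotated list.
    """
    if reference and not all(r.family for r in reference):
        raise ValueError("reference records must carry family labels")
    out: List[Transcript] = []
    review: List[Transcript] = []
    sources = {individual_id} if individual_id else set()
    for cid, seq in contigs:
        best_ref, best_ident = None, -1.0
        for ref in reference:
            ident = sequence_identity(seq, ref.sequence)
            if ident > best_ident:
                best_ref, best_ident = ref, ident
        t = Transcript(id=cid, sequence=seq, source_individuals=set(sources))
        if best_ref is not None and best_ident >= auto_threshold:
            t.annotation = best_ref.family
            t.family = best_ref.family if best_ref.family != "nontoxin" else ""
            t.reference_id = best_ref.id
            t.identity = best_ident
            t.cds = _locate_cds(seq, best_ref)
            t.signal_peptide = best_ref.signal_peptide
        else:
            t.identity = max(best_ident, 0.0)
            t.cds = longest_orf(seq)
            review.append(t)
        out.append(t)
    return out, review


def longest_orf(seq: str, min_codons: int = 90) -> Tuple[int, int]:
    """Longest open reading frame (ATG..stop) on either strand, reported in
    forward coordinates; falls back to the frame-0 prefix when nothing
    reaches ``min_codons``."""
    stops = {"TAA", "TAG", "TGA"}
    best: Tuple[int, Tuple[int, int]] = (0, (0, len(seq) // 3 * 3))
    for strand, s in ((1, seq), (-1, revcomp(seq))):
        n = len(s)
        for frame in range(3):
            start = None
            i = frame
            while i + 3 <= n:
                codon = s[i : i + 3]
                if start is None and codon == "ATG":
                    start = i
                elif start is not None and codon in stops:
                    length = i + 3 - start
                    if length >= min_codons * 3 and length > best[0]:
                        if strand == 1:
                            best = (length, (start, i + 3))
                        else:
                            best = (length, (n - (i + 3), n - start))
                    start = None
                i += 3
    return best[1]


def build_consensus(
    per_individual_sets: Mapping[str, Sequence[Transcript]],
    threshold: float = CONSENSUS_CLUSTER_THRESHOLD,
) -> ConsensusTranscriptome:
    """Pool per-individual transcript sets and cluster them into a species
    consensus transcriptome.

    The representative of each cluster is retained; its
    ``source_individuals`` becomes the union over all members.  Duplicate
    ids across individuals are disambiguated by suffixing.
    """
    if not per_individual_sets:
        raise ValueError("at least one individual set is required")
    pooled: Dict[str, Transcript] = {}
    for ind in sorted(per_individual_sets):
        for t in per_individual_sets[ind]:
            tid = t.id
            k = 2
            while tid in pooled:
                tid = f"{t.id}.{k}"
                k += 1
            srcs = set(t.source_individuals) or {ind}
            pooled[tid] = Transcript(
                id=tid,
                sequence=t.sequence,
                cds=t.cds,
                annotation=t.annotation,
                family=t.family,
                reference_id=t.reference_id,
                identity=t.identity,
                signal_peptide=t.signal_peptide,
                source_individuals=srcs,
            )
    clusters = greedy_identity_cluster(
        [(tid, t.sequence) for tid, t in pooled.items()], threshold
    )
    consensus: List[Transcript] = []
    for cl in clusters:
        rep = pooled[cl.representative_id]
        for mid in cl.member_ids:
            rep.source_individuals |= pooled[mid].source_individuals
        consensus.append(rep)
    return ConsensusTranscriptome(
        transcripts=consensus, clustering_threshold=threshold, clusters=clusters
    )
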