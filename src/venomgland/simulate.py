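"""Synthetic venom-gland study generator.

This module produces every input the analysis pipeline consumes, with the
statistical structure the downstream methods assume, so that each stage can
be exercised and scored against a known ground truth:

* a reference transcript set with toxin-family structure (paralogous
  families derived from family ancestors) and in-frame coding sequences;
* per-individual transcript haplotypes, so that samples on a shared lane
  have individual-specific k-mer content (the signal the contamination
  filter exploits in real data);
* heavy-tailed (lognormal) expression profiles with planted per-lineage
  fold changes and planted per-individual transcript absences;
* paired-end reads with a configurable fragment-length distribution,
  substitution errors and a two-state quality model;
* injected cross-sample contaminant reads with full bookkeeping;
* planted chimeric transcripts (5' half of one parent fused to the 3' half
  of another) whose reads come only from the parents, leaving the
  diagnostic mid-transcript coverage discontinuity;
* normalized spectral-count tables with three spiked internal standards per
  replicate.

All randomness flows from ``SimulationConfig.seed`` through independent
named streams, so a fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._seq import revcomp
from .metadata import (
    DEFAULT_FAMILY_SIZES,
    sidewinder_factor_table,
    validate_factor_table,
)
from .reads import MergedRead, SequencingRead

_BASES = np.array(list("ACGT"))
_STOP = {"TAA", "TAG", "TGA"}

#: Spiked internal standards: (protein id, known amount in fmol per injection).
DEFAULT_STANDARDS = (
    ("P00811", 25.0),
    ("P31658", 250.0),
    ("P31697", 2500.0),
)


@dataclass
class DEEffect:
    """A planted expression effect: individuals with ``level`` of ``factor``
    express ``transcript_id`` at ``2**log2fc`` times the base abundance."""

    transcript_id: str
    factor: str
    level: str
    log2fc: float


@dataclass
class SimulationConfig:
    seed: int = 0
    n_individuals: int = 8
    n_toxins: int = 62
    n_nontoxins: int = 20
    family_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_SIZES)
    )
    read_length: int = 150
    fragment_mean: float = 400.0
    fragment_sd: float = 100.0
    depth_per_transcript: float = 30.0  # expected fragments per kb per individual
    error_rate: float = 0.002
    low_qual_rate: float = 0.002  # per-base chance of a quality-2 call
    contamination_rate: float = 0.0
    absence_rate: float = 0.12
    chimera_count: int = 0
    individual_divergence: float = 0.004  # per-site SNP rate of each haplotype
    family_divergence: float = 0.25  # per-site divergence of member from ancestor
    expression_sigma: float = 1.2  # lognormal sd of base abundance
    individual_expression_sigma: float = 0.3  # biological noise between individuals
    toxin_abundance_multiplier: float = 8.0
    toxin_length_range: Tuple[int, int] = (450, 1200)
    nontoxin_length_range: Tuple[int, int] = (600, 1500)
    utr_length: int = 30
    factor_table: Optional[pd.DataFrame] = None
    de_effects: List[DEEffect] = field(default_factory=list)
    lane_of: Optional[Mapping[str, str]] = None  # individual -> lane label

    def validate(self) -> "SimulationConfig":
        for name in ("error_rate", "contamination_rate", "absence_rate",
                     "low_qual_rate", "individual_divergence", "family_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_toxins + self.n_nontoxins < 1:
            raise ValueError("at least one transcript must be requested")
        if self.n_toxins < 0 or self.n_nontoxins < 0:
            raise ValueError("transcript counts must be nonnegative")
        if self.read_length >= self.fragment_mean:
            raise ValueError("read_length must be smaller than fragment_mean")
        return self

    def individuals(self) -> List[str]:
        return list(self.resolved_factor_table().index)

    def resolved_factor_table(self) -> pd.DataFrame:
        if self.factor_table is not None:
            table = self.factor_table
        else:
            table = sidewinder_factor_table().iloc[: self.n_individuals]
        if len(table) != self.n_individuals:
            raise ValueError(
                f"factor table has {len(table)} rows but n_individuals="
                f"{self.n_individuals}"
            )
        return validate_factor_table(table)

    def resolved_lanes(self) -> Dict[str, str]:
        inds = self.individuals()
        if self.lane_of is not None:
            return {i: self.lane_of[i] for i in inds}
        return {i: "L1" for i in inds}


@dataclass
class ReferenceTranscript:
    id: str
    sequence: str
    cds: Tuple[int, int]  # 0-based half-open
    family: str  # toxin family, or "nontoxin"

    @property
    def is_toxin(self) -> bool:
        return self.family != "nontoxin"

    def __len__(self):
        return len(self.sequence)


@dataclass
class PlantedChimera:
    id: str
    individual_id: str
    sequence: str
    cds: Tuple[int, int]
    parent_5p: str
    parent_3p: str
    breakpoint: int


@dataclass
class GroundTruth:
    """Everything the recovery oracles in the test-suite are allowed to see."""

    transcripts: List[ReferenceTranscript]
    haplotypes: Dict[str, Dict[str, str]]  # individual -> transcript id -> seq
    base_abundance: pd.Series  # molar scale, per transcript
    true_expression: pd.DataFrame  # TPM scale, transcripts x individuals
    planted_absences: pd.DataFrame  # bool, transcripts x individuals
    planted_chimeras: List[PlantedChimera] = field(default_factory=list)
    contaminant_read_ids: Dict[str, set] = field(default_factory=dict)
    true_protein_concentrations: Optional[pd.DataFrame] = None
    true_slopes: Optional[pd.DataFrame] = None
    fragment_counts: Optional[pd.DataFrame] = None

    def transcript(self, tid: str) -> ReferenceTranscript:
        for t in self.transcripts:
            if t.id == tid:
                return t
        raise KeyError(tid)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """An in-frame CDS: ATG, ``n_codons`` non-stop codons, one stop."""
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(_BASES, 3))
        if c not in _STOP:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    if hits.size == 0:
        return seq
    base_idx = {b: i for i, b in enumerate(b"ACGT")}
    for p in hits:
        cur = arr[p][0]
        choices = [b for b in b"ACGT" if b != cur]
        arr[p] = bytes([choices[rng.integers(3)]])
    return arr.tobytes().decode()


def _family_plan(config: SimulationConfig) -> List[str]:
    """Family label per toxin transcript.  If the configured family sizes sum
    to ``n_toxins`` they are used verbatim; otherwise labels are recycled."""
    sizes = dict(config.family_sizes)
    labels = []
    if sum(sizes.values()) == config.n_toxins:
        for fam, n in sizes.items():
            labels.extend([fam] * n)
    else:
        fams = list(sizes) or ["TOX"]
        for i in range(config.n_toxins):
            labels.append(fams[i % len(fams)])
    return labels


def generate_reference(config: SimulationConfig) -> GroundTruth:
    """Build the reference transcript set and the full ground-truth skeleton
    (haplotypes, expression, absences, chimeras)."""
    config.validate()
    table = config.resolved_factor_table()
    inds = list(table.index)

    rng = _rng(config.seed, 1)
    transcripts: List[ReferenceTranscript] = []

    # toxins: per-family ancestors, members mutated away from the ancestor
    fam_labels = _family_plan(config)
    ancestors: Dict[str, str] = {}
    fam_counter: Dict[str, int] = {}
    for fam in fam_labels:
        if fam not in ancestors:
            lo, hi = config.toxin_length_range
            n_codons = int(rng.integers(lo // 3, max(hi // 3, lo // 3 + 1)))
            ancestors[fam] = _random_cds(rng, n_codons)
        fam_counter[fam] = fam_counter.get(fam, 0) + 1
        member = _mutate(rng, ancestors[fam], config.family_divergence)
        member = "ATG" + member[3:-3] + member[-3:]
        if member[-3:] not in _STOP:  # start/stop codons are conserved
            member = member[:-3] + "TAA"
        utr5 = "".join(rng.choice(_BASES, config.utr_length))
        utr3 = "".join(rng.choice(_BASES, config.utr_length))
        seq = utr5 + member + utr3
        cds = (config.utr_length, config.utr_length + len(member))
        transcripts.append(
            ReferenceTranscript(
                id=f"{fam}-{fam_counter[fam]}", sequence=seq, cds=cds, family=fam
            )
        )

    for i in range(config.n_nontoxins):
        lo, hi = config.nontoxin_length_range
        n_codons = int(rng.integers(lo // 3, max(hi // 3, lo // 3 + 1)))
        body = _random_cds(rng, n_codons)
        utr5 = "".join(rng.choice(_BASES, config.utr_length))
        utr3 = "".join(rng.choice(_BASES, config.utr_length))
        seq = utr5 + body + utr3
        cds = (config.utr_length, config.utr_length + len(body))
        transcripts.append(
            ReferenceTranscript(
                id=f"NTX-{i + 1}", sequence=seq, cds=cds, family="nontoxin"
            )
        )

    tids = [t.id for t in transcripts]

    # per-individual haplotypes
    hap_rng = _rng(config.seed, 2)
    haplotypes = {
        ind: {
            t.id: _mutate(hap_rng, t.sequence, config.individual_divergence)
            for t in transcripts
        }
        for ind in inds
    }

    # base abundance: heavy-tailed, toxins boosted
    expr_rng = _rng(config.seed, 3)
    base = pd.Series(
        np.exp(expr_rng.normal(0.0, config.expression_sigma, len(transcripts))),
        index=tids,
    )
    for t in transcripts:
        if t.is_toxin:
            base[t.id] *= config.toxin_abundance_multiplier

    # planted absences (never removing a transcript from every individual)
    abs_rng = _rng(config.seed, 4)
    absent = pd.DataFrame(
        abs_rng.random((len(tids), len(inds))) < config.absence_rate,
        index=tids,
        columns=inds,
    )
    for tid in tids:
        if absent.loc[tid].all():
            keep = inds[int(abs_rng.integers(len(inds)))]
            absent.loc[tid, keep] = False

    # per-individual expression with planted effects and biological noise
    mult = pd.DataFrame(1.0, index=tids, columns=inds)
    for eff in config.de_effects:
        hit = table.index[table[eff.factor].astype(str) == str(eff.level)]
        mult.loc[eff.transcript_id, hit] *= 2.0 ** eff.log2fc
    noise = np.exp(
        expr_rng.normal(
            0.0, config.individual_expression_sigma, (len(tids), len(inds))
        )
    )
    abund = mult.mul(base, axis=0) * noise
    abund[absent] = 0.0
    tpm = abund.div(abund.sum(axis=0), axis=1) * 1e6

    # planted chimeras: per individual, 5' half of one toxin + 3' half of another
    chim_rng = _rng(config.seed, 5)
    chimeras: List[PlantedChimera] = []
    toxin_ids = [t.id for t in transcripts if t.is_toxin]
    for k in range(config.chimera_count):
        for ind in inds:
            a, b = chim_rng.choice(len(toxin_ids), 2, replace=False)
            ta, tb = toxin_ids[int(a)], toxin_ids[int(b)]
            sa = haplotypes[ind][ta]
            sb = haplotypes[ind][tb]
            bp = len(sa) // 2
            seq = sa[:bp] + sb[len(sb) // 2 :]
            cds_len = (len(seq) - 2 * config.utr_length) // 3 * 3
            chimeras.append(
                PlantedChimera(
                    id=f"chimera-{k + 1}-{ind}",
                    individual_id=ind,
                    sequence=seq,
                    cds=(config.utr_length, config.utr_length + cds_len),
                    parent_5p=ta,
                    parent_3p=tb,
                    breakpoint=bp,
                )
            )

    return GroundTruth(
        transcripts=transcripts,
        haplotypes=haplotypes,
        base_abundance=base,
        true_expression=tpm,
        planted_absences=absent,
        planted_chimeras=chimeras,
    )


@dataclass
class SimulatedReads:
    """Per-individual reads plus the ideal (error-bearing but correctly
    merged) fragment sequences."""

    pairs: Dict[str, List[Tuple[SequencingRead, SequencingRead]]]
    fragments: Dict[str, List[MergedRead]]
    truth: GroundTruth


def _quality(rng: np.random.Generator, n: int, low_rate: float) -> tuple:
    q = np.full(n, 38, dtype=int)
    if low_rate > 0:
        q[rng.random(n) < low_rate] = 2
    return tuple(int(x) for x in q)


def simulate_reads(truth: GroundTruth, config: SimulationConfig) -> SimulatedReads:
    """Simulate paired-end reads for every individual.

    Fragment counts per transcript are Poisson with expectation proportional
    to molar abundance times length; the expectations sum exactly to the
    requested effort (``depth_per_transcript`` fragments per kb of reference
    per individual).  Fragments may overhang transcript ends (and are then
    clipped) so terminal bases are covered like interior ones.  Planted
    absences yield zero reads by construction.
    """
    config.validate()
    if not truth.transcripts:
        raise ValueError("reference is empty")
    rl = config.read_length
    if any(len(t) < rl for t in truth.transcripts):
        raise ValueError("every reference transcript must be >= read_length")
    inds = config.individuals()
    lanes = config.resolved_lanes()
    tids = [t.id for t in truth.transcripts]
    lengths = pd.Series({t.id: float(len(t)) for t in truth.transcripts})
    effort = config.depth_per_transcript * lengths.sum() / 1000.0

    pairs: Dict[str, List[Tuple[SequencingRead, SequencingRead]]] = {}
    fragments: Dict[str, List[MergedRead]] = {}
    frag_counts = pd.DataFrame(0, index=tids, columns=inds)

    for ii, ind in enumerate(inds):
        rng = _rng(config.seed, 100 + ii)
        abund = truth.true_expression[ind]
        w = abund * lengths
        total = w.sum()
        if total <= 0:
            raise ValueError(f"individual {ind} has no expressed transcripts")
        w = w / total
        pair_list: List[Tuple[SequencingRead, SequencingRead]] = []
        frag_list: List[MergedRead] = []
        n = 0
        for tid in tids:
            exp_frags = effort * w[tid]
            if exp_frags <= 0:
                continue
            n_frags = int(rng.poisson(exp_frags))
            frag_counts.loc[tid, ind] = n_frags
            seq = truth.haplotypes[ind][tid]
            L = len(seq)
            for _ in range(n_frags):
                flen = int(round(rng.normal(config.fragment_mean, config.fragment_sd)))
                flen = max(rl, min(flen, L))
                start = int(rng.integers(-(flen - rl), L - rl + 1))
                frag = seq[max(0, start) : min(L, start + flen)]
                frag = _mutate(rng, frag, config.error_rate)
                n += 1
                fid = f"{ind}.f{n}"
                r1 = SequencingRead(
                    id=f"{fid}/1",
                    sequence=frag[:rl],
                    quality=_quality(rng, rl, config.low_qual_rate),
                    sample_id=ind,
                    lane_id=lanes[ind],
                    mate=1,
                )
                rc = revcomp(frag)
                r2 = SequencingRead(
                    id=f"{fid}/2",
                    sequence=rc[:rl],
                    quality=_quality(rng, rl, config.low_qual_rate),
                    sample_id=ind,
                    lane_id=lanes[ind],
                    mate=2,
                )
                pair_list.append((r1, r2))
                frag_list.append(
                    MergedRead(
                        id=fid,
                        sequence=frag,
                        quality=_quality(rng, len(frag), config.low_qual_rate),
                        sample_id=ind,
                    )
                )
        pairs[ind] = pair_list
        fragments[ind] = frag_list

    truth.fragment_counts = frag_counts
    return SimulatedReads(pairs=pairs, fragments=fragments, truth=truth)


def inject_contamination(
    reads_by_sample: Mapping[str, Sequence[SequencingRead]],
    rate: float,
    seed: int,
    lane_of: Optional[Mapping[str, str]] = None,
    pair_aware: bool = False,
):
    """Inject cross-sample contaminant reads within each lane.

    For each sample A, ``Binomial(n_A, rate)`` reads are drawn uniformly
    from the other samples sharing A's lane and appended to A verbatim
    (ids, and hence provenance, preserved).  With ``pair_aware`` the unit
    of mis-assignment is the fragment: whole ``.../1``-``.../2`` pairs are
    injected together (what index mis-assignment actually does to
    paired-end data).  Returns
    ``(contaminated_reads_by_sample, contaminant_ids_by_sample)``.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    samples = list(reads_by_sample)
    if lane_of is None:
        lane_of = {s: "L1" for s in samples}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9]))
    out = {s: list(reads_by_sample[s]) for s in samples}
    contam_ids: Dict[str, set] = {s: set() for s in samples}
    if rate == 0.0:
        return out, contam_ids

    def _units(reads):
        if not pair_aware:
            return [[r] for r in reads]
        by_frag: Dict[str, list] = {}
        for r in reads:
            base = r.id[:-2] if r.id.endswith(("/1", "/2")) else r.id
            by_frag.setdefault(base, []).append(r)
        return list(by_frag.values())

    for s in samples:
        donors = [t for t in samples if t != s and lane_of[t] == lane_of[s]]
        if not donors:
            raise ValueError(f"sample {s} shares a lane with no other sample")
        donor_pool = [u for t in donors for u in _units(reads_by_sample[t])]
        n_native_units = len(_units(reads_by_sample[s]))
        n = int(rng.binomial(n_native_units, rate))
        take = rng.choice(len(donor_pool), size=min(n, len(donor_pool)), replace=False)
        for j in take:
            for r in donor_pool[int(j)]:
                out[s].append(r)
                contam_ids[s].add(r.id)
    return out, contam_ids


def simulate_protein_concentrations(
    truth: GroundTruth,
    seed: int,
    noise_sigma: float = 0.5,
    scale_fmol: float = 250.0,
) -> pd.DataFrame:
    """Per-individual venom protein amounts: transcript abundance times
    lognormal noise, scaled so the median quantifiable protein sits near
    ``scale_fmol``.  Rows are toxin transcripts only (the venom proteome)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))
    toxin_ids = [t.id for t in truth.transcripts if t.is_toxin]
    expr = truth.true_expression.loc[toxin_ids]
    noise = np.exp(rng.normal(0.0, noise_sigma, expr.shape))
    conc = expr * noise
    med = np.median(conc.values[conc.values > 0])
    conc = conc / med * scale_fmol
    truth.true_protein_concentrations = conc
    return conc


def simulate_spectral_counts(
    true_protein_concentrations: pd.DataFrame,
    standards: Sequence[Tuple[str, float]] = DEFAULT_STANDARDS,
    noise_cv: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
    true_slopes: Optional[pd.DataFrame] = None,
    detection_limit: float = 0.0,
):
    """Simulate normalized spectral counts from protein concentrations.

    Each replicate has its own conversion factor (fmol per count unit);
    expected count = concentration / slope.  Multiplicative lognormal noise
    with coefficient of variation ``noise_cv`` is mean-corrected so the
    expectation is exact.  Standards appear as rows in every replicate.
    Counts below ``detection_limit`` are zeroed (not detected).

    Returns ``(table, slopes)`` where ``table`` has a (individual,
    replicate) column MultiIndex and ``slopes`` the true per-replicate
    conversion factors.
    """
    if len(standards) != 3:
        raise ValueError("exactly three internal standards are expected")
    conc = true_protein_concentrations
    if (conc.values < 0).any():
        raise ValueError("protein concentrations must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 22]))
    inds = list(conc.columns)
    reps = [f"rep{j + 1}" for j in range(n_replicates)]
    if true_slopes is None:
        true_slopes = pd.DataFrame(
            np.exp(rng.normal(np.log(2.0), 0.25, (len(inds), n_replicates))),
            index=inds,
            columns=reps,
        )
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))

    std_ids = [sid for sid, _ in standards]
    std_amt = pd.Series({sid: amt for sid, amt in standards})
    rows = std_ids + list(conc.index)
    cols = pd.MultiIndex.from_product([inds, reps], names=["individual", "replicate"])
    table = pd.DataFrame(0.0, index=rows, columns=cols)
    for ind in inds:
        for rep in reps:
            slope = float(true_slopes.loc[ind, rep])
            expected = pd.concat([std_amt, conc[ind]]) / slope
            if sigma > 0:
                noise = np.exp(
                    rng.normal(-sigma**2 / 2.0, sigma, len(expected))
                )
            else:
                noise = 1.0
            obs = expected * noise
            obs[obs < detection_limit] = 0.0
            table[(ind, rep)] = obs.values
    return table, true_slopes


def lineage_tree(factor_table: pd.DataFrame, factor: str = "nontoxin_lineage",
                 within: float = 0.1, between: float = 1.0) -> str:
    """A simple ultrametric-ish Newick tree grouping individuals by lineage.

    Stands in for an externally inferred phylogeny: individuals of one
    lineage form a rake with short terminal branches, lineages hang off the
    root with longer stems.
    """
    groups: Dict[str, List[str]] = {}
    for ind, lev in factor_table[factor].items():
        groups.setdefault(str(lev), []).append(str(ind))
    parts = []
    for lev in sorted(groups):
        members = sorted(groups[lev])
        if len(members) == 1:
            parts.append(f"{members[0]}:{within + between}")
        else:
            inner = ",".join(f"{m}:{within}" for m in members)
            parts.append(f"({inner}):{between}")
    return "(" + ",".join(parts) + ");"
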