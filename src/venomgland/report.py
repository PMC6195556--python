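"""End-to-end orchestration and results bookkeeping.

:func:`run_pipeline` drives a complete synthetic study through every stage
in order -- decontaminate, trim, merge, assemble, annotate, chimera-screen,
consensus, map/quantify, absence calling, differential expression,
phylogenetic signal, proteomics -- and collects the headline bookkeeping a
study report prints: consensus composition, the toxin share of expression,
absence counts with their percentages, and the consensus-DE tallies.

Percent formatting mirrors how such results are printed: integer percents
for the absence share (half away from zero) and one decimal for the
differential-expression share (truncated, so 4 of 62 prints as 6.4).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import annotate as ann
from . import assembly as asm
from . import diffexpr as de
from . import phylo
from . import proteomics as prot
from . import quantify as qt
from . import reads as rp
from . import simulate as sim
from . import validate as val


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (what report text does, unlike banker's
    rounding)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def pct_int(numerator: float, denominator: float) -> int:
    """Integer percent, half away from zero (19/62 -> 31)."""
    if denominator == 0:
        return 0
    return int(round_half_away(100.0 * numerator / denominator, 0))


def pct1(numerator: float, denominator: float) -> float:
    """One-decimal percent, half away from zero (3/62 -> 4.8)."""
    if denominator == 0:
        return 0.0
    return round_half_away(100.0 * numerator / denominator, 1)


def pct1_trunc(numerator: float, denominator: float) -> float:
    """One-decimal percent, truncated toward zero (4/62 -> 6.4)."""
    if denominator == 0:
        return 0.0
    return math.floor(1000.0 * numerator / denominator) / 10.0


def summarize_absence(absence: pd.DataFrame) -> Dict:
    """Absence bookkeeping: transcripts absent in >=1 individual and the
    per-individual missing range, as counts and printed percents."""
    if absence.empty:
        raise ValueError("absence matrix is empty")
    n_transcripts = absence.shape[0]
    absent_any = int(absence.any(axis=1).sum())
    per_ind = absence.sum(axis=0)
    return {
        "n_transcripts": int(n_transcripts),
        "n_absent_any_individual": absent_any,
        "pct_absent_any_individual": pct_int(absent_any, n_transcripts),
        "per_individual_missing": {k: int(v) for k, v in per_ind.items()},
        "min_missing": int(per_ind.min()),
        "max_missing": int(per_ind.max()),
        "mean_missing": float(per_ind.mean()),
        "pct_missing_min": pct1(per_ind.min(), n_transcripts),
        "pct_missing_max": pct1(per_ind.max(), n_transcripts),
    }


def summarize_de(results: pd.DataFrame) -> Dict:
    """Differential-expression bookkeeping over the full contrast set."""
    s = de.consensus_summary(results)
    s["pct_significant_transcripts"] = pct1_trunc(
        s["n_significant_transcripts"], s["n_transcripts"]
    )
    return s


@dataclass
class PipelineSummary:
    n_consensus_toxins: int
    n_consensus_nontoxins: int
    toxin_expression_share_pct: float
    class_expression_shares_pct: Dict[str, float]
    absence: Dict
    de_transcript: Dict
    de_class: Dict
    proteome: Dict
    seed: int = 0

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True, default=float)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s


@dataclass
class PipelineResult:
    truth: sim.GroundTruth
    consensus: ann.ConsensusTranscriptome
    tpm: pd.DataFrame
    counts: pd.DataFrame
    absence: pd.DataFrame
    shared_nontoxin_loci: List[str]
    chimera_verdicts: Dict[str, Dict[str, str]]
    de_results: pd.DataFrame
    de_class_results: pd.DataFrame
    k_results: pd.DataFrame
    protein_quant: pd.DataFrame
    correlations: Dict[str, Dict[str, float]]
    summary: PipelineSummary
    dropped_contaminants: Dict[str, set] = field(default_factory=dict)


def _trim_and_merge(pairs, phred_min=rp.DEFAULT_PHRED_MIN, kept_ids=None):
    """Quality-trim both mates and merge surviving pairs."""
    merged = []
    for r1, r2 in pairs:
        if kept_ids is not None and (r1.id not in kept_ids or r2.id not in kept_ids):
            continue
        t1, d1 = rp.quality_trim(r1, phred_min)
        t2, d2 = rp.quality_trim(r2, phred_min)
        if d1 or d2 or len(t1) < 30 or len(t2) < 30:
            continue
        m = rp.merge_pairs(t1, t2)
        if m is not None:
            merged.append(m)
    return merged


def run_pipeline(
    config: sim.SimulationConfig,
    outdir: Optional[str] = None,
    overlap: int = 120,
    n_seeds: int = asm.DEFAULT_N_SEEDS,
    min_agreement: float = 0.75,
    alpha: float = de.ALPHA,
    k_permutations: int = 199,
    proteome_noise_cv: float = 0.1,
    proteome_detection_limit: float = 0.05,
    tree_newick: Optional[str] = None,
    run_decontamination: Optional[bool] = None,
) -> PipelineResult:
    """Execute the full synthetic study; see the module docstring for the
    stage order.  All stage seeds derive from ``config.seed``."""
    truth = sim.generate_reference(config)
    simulated = sim.simulate_reads(truth, config)
    table = config.resolved_factor_table()
    inds = list(table.index)
    lanes = config.resolved_lanes()

    # ---- contamination injection + filtering on raw reads ----------------
    raw = {
        ind: [r for pair in simulated.pairs[ind] for r in pair] for ind in inds
    }
    if config.contamination_rate > 0:
        raw, contam_ids = sim.inject_contamination(
            raw, config.contamination_rate, seed=config.seed, lane_of=lanes
        )
        truth.contaminant_read_ids = contam_ids
    dropped: Dict[str, set] = {ind: set() for ind in inds}
    decontam = run_decontamination
    if decontam is None:
        decontam = config.contamination_rate > 0
    kept_ids = {ind: None for ind in inds}
    if decontam:
        by_lane: Dict[str, List[str]] = {}
        for ind in inds:
            by_lane.setdefault(lanes[ind], []).append(ind)
        for lane_members in by_lane.values():
            if len(lane_members) < 2:
                continue
            kept, drop = rp.decontaminate_lane(
                {m: raw[m] for m in lane_members}
            )
            for m in lane_members:
                dropped[m] = drop[m]
                kept_ids[m] = {r.id for r in kept[m]}

    # ---- trim + merge ----------------------------------------------------
    merged = {
        ind: _trim_and_merge(simulated.pairs[ind], kept_ids=kept_ids[ind])
        for ind in inds
    }

    # ---- per-individual assembly + annotation ----------------------------
    reference = [
        ann.ReferenceRecord(id=t.id, sequence=t.sequence, family=t.family, cds=t.cds)
        for t in truth.transcripts
    ]
    per_ind_sets: Dict[str, List[ann.Transcript]] = {}
    chimera_verdicts: Dict[str, Dict[str, str]] = {}
    for ind in inds:
        contigs = asm.assemble(
            merged[ind], n_seeds=n_seeds, overlap=overlap, rng_seed=config.seed,
            min_agreement=min_agreement,
        )
        annotated, _review = ann.annotate_by_reference(
            [(c.id, c.sequence) for c in contigs], reference, individual_id=ind
        )
        candidates = [t for t in annotated if t.annotation != "unannotated"]
        # plant this individual's chimeras among the assembly candidates
        for ch in truth.planted_chimeras:
            if ch.individual_id == ind:
                candidates.append(
                    ann.Transcript(
                        id=ch.id, sequence=ch.sequence, cds=ch.cds,
                        annotation=truth.transcript(ch.parent_5p).family or "chimera",
                        family=truth.transcript(ch.parent_5p).family,
                        source_individuals={ind},
                    )
                )
        profiles = val.strict_align_coverage(merged[ind], candidates, ind)
        verdicts = {}
        screened = []
        for t in candidates:
            prof = profiles[t.id]
            if prof.depth.size == 0 or prof.n_reads == 0:
                verdicts[t.id] = val.VERDICT_REMOVE_ZERO
                continue
            v = val.chimera_screen(prof)
            verdicts[t.id] = v
            if v in (val.VERDICT_KEEP, val.VERDICT_FLAG):
                screened.append(t)
        chimera_verdicts[ind] = verdicts
        # redundancy clustering within the individual
        clusters = ann.greedy_identity_cluster(
            [(t.id, t.sequence) for t in screened],
            ann.CONSENSUS_CLUSTER_THRESHOLD,
        )
        reps = {c.representative_id for c in clusters}
        per_ind_sets[ind] = [t for t in screened if t.id in reps]

    consensus = ann.build_consensus(per_ind_sets)
    # biological ids: adopt the annotation reference id where available
    used_ids = set()
    for t in consensus.transcripts:
        base = t.reference_id or t.id
        tid, k = base, 2
        while tid in used_ids:
            tid = f"{base}.{k}"
            k += 1
        used_ids.add(tid)
        t.id = tid

    # ---- mapping, quantification, absence --------------------------------
    results: Dict[str, qt.ExpressionResult] = {}
    cov3: Dict[str, Dict[str, val.CoverageProfile]] = {}
    lengths = {t.id: max(t.cds[1] - t.cds[0], 1) for t in consensus.transcripts}
    for ind in inds:
        alignments, profiles = qt.map_reads(
            merged[ind], consensus.transcripts, individual_id=ind
        )
        cov3[ind] = profiles
        results[ind] = qt.estimate_tpm(alignments, lengths)
    tids = [t.id for t in consensus.transcripts]
    tpm = qt.tpm_matrix(results, tids)
    counts = qt.counts_matrix(results, tids)

    toxin_ids = [t.id for t in consensus.transcripts if t.is_toxin]
    nontoxin_ids = [t.id for t in consensus.transcripts if t.annotation == "nontoxin"]
    absence = val.absence_matrix_toxin(cov3, toxin_ids)
    shared = val.select_shared_nontoxin_loci(cov3, nontoxin_ids)

    # ---- differential expression -----------------------------------------
    contrasts = de.enumerate_contrasts(table)
    tox_counts = counts.loc[toxin_ids].round()
    de_results = de.run_de(tox_counts, table, contrasts, alpha=alpha)
    families = {
        t.id: (t.family or t.annotation) for t in consensus.transcripts if t.is_toxin
    }
    class_counts = qt.sum_by_class(tox_counts, families)
    de_class = de.run_de(class_counts, table, contrasts, alpha=alpha)

    # ---- phylogenetic signal ---------------------------------------------
    newick = tree_newick or sim.lineage_tree(table)
    tree = phylo.load_tree(newick)
    ln_tpm = np.log(qt.replace_zeros(tpm.loc[toxin_ids]))
    k_results = phylo.k_per_transcript(
        tree, ln_tpm, n_perm=k_permutations, seed=config.seed
    )

    # ---- proteomics -------------------------------------------------------
    conc = sim.simulate_protein_concentrations(truth, seed=config.seed)
    spectral, slopes_true = sim.simulate_spectral_counts(
        conc,
        noise_cv=proteome_noise_cv,
        seed=config.seed,
        detection_limit=proteome_detection_limit,
    )
    truth.true_slopes = slopes_true
    standards = prot.StandardSet()
    slopes = prot.fit_all_conversion_factors(spectral, standards)
    ref_families = {t.id: t.family for t in truth.transcripts}
    quants = prot.quantify(spectral, slopes, standards, families=ref_families)
    quant_df = prot.quant_frame(quants)

    # transcript-protein correlation per individual, over quantifiable,
    # non-excluded proteins whose transcript was measured
    ref_of = {t.id: t.reference_id for t in consensus.transcripts}
    measured = (
        tpm.rename(index={k: v for k, v in ref_of.items() if v})
        .groupby(level=0)
        .sum()
    )  # allelic duplicates of one locus collapse onto its reference id
    correlations: Dict[str, Dict[str, float]] = {}
    for ind in inds:
        q = quant_df[
            (quant_df.individual_id == ind)
            & quant_df.quantifiable
            & quant_df.excluded_reason.isna()
        ].set_index("protein_id")["concentration"]
        shared_ids = [
            p for p in q.index if p in measured.index and measured.loc[p, ind] > 0
        ]
        if len(shared_ids) < 3:
            continue
        ct = qt.clr(measured.loc[shared_ids, ind])
        cp = qt.clr(q.loc[shared_ids])
        rho, r, r2 = prot.correlate_abundances(
            pd.Series(ct, index=shared_ids), pd.Series(cp, index=shared_ids)
        )
        correlations[ind] = {"spearman_rho": rho, "pearson_r": r, "r_squared": r2}

    # ---- summary ----------------------------------------------------------
    toxin_share = 100.0 * tpm.loc[toxin_ids].sum().sum() / tpm.sum().sum()
    class_tpm = qt.sum_by_class(tpm.loc[toxin_ids], families)
    class_share = (
        100.0 * class_tpm.sum(axis=1) / tpm.loc[toxin_ids].sum().sum()
    )
    n_detected = quant_df[quant_df.detected].protein_id.nunique()
    conserved = (
        quant_df[quant_df.quantifiable].groupby("protein_id").individual_id.nunique()
    )
    n_conserved = int((conserved == len(inds)).sum())
    summary = PipelineSummary(
        n_consensus_toxins=len(toxin_ids),
        n_consensus_nontoxins=len(nontoxin_ids),
        toxin_expression_share_pct=round_half_away(toxin_share, 1),
        class_expression_shares_pct={
            k: round_half_away(v, 1) for k, v in class_share.items()
        },
        absence=summarize_absence(absence),
        de_transcript=summarize_de(de_results),
        de_class=summarize_de(de_class),
        proteome={"n_verified": int(n_detected), "n_conserved": n_conserved},
        seed=config.seed,
    )

    result = PipelineResult(
        truth=truth,
        consensus=consensus,
        tpm=tpm,
        counts=counts,
        absence=absence,
        shared_nontoxin_loci=shared,
        chimera_verdicts=chimera_verdicts,
        de_results=de_results,
        de_class_results=de_class,
        k_results=k_results,
        protein_quant=quant_df,
        correlations=correlations,
        summary=summary,
        dropped_contaminants=dropped,
    )
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    from . import io as vio

    outdir.mkdir(parents=True, exist_ok=True)
    vio.write_fasta(
        outdir / "consensus.fasta",
        [
            (t.id, f"family={t.family or t.annotation} cds={t.cds[0] + 1}-{t.cds[1]}",
             t.sequence)
            for t in result.consensus.transcripts
        ],
    )
    vio.write_tsv(outdir / "tpm.tsv", result.tpm)
    vio.write_tsv(outdir / "counts.tsv", result.counts)
    vio.write_tsv(outdir / "absence.tsv", result.absence)
    result.de_results.to_csv(outdir / "de_transcript.tsv", sep="\t", index=False)
    result.de_class_results.to_csv(outdir / "de_class.tsv", sep="\t", index=False)
    result.k_results.to_csv(outdir / "blomberg_k.tsv", sep="\t", index=False)
    result.protein_quant.to_csv(outdir / "protein_quant.tsv", sep="\t", index=False)
    result.summary.to_json(outdir / "summary.json")
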