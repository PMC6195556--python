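"""Internal-standard quantification of label-free venom proteomes.

Three spiked proteins of known amount (defaults: 25, 250 and 2500 fmol per
injection) anchor a per-replicate conversion factor: the slope of the
least-squares line through the origin of known amount on observed
normalized spectral count.  Venom-protein counts are converted to
concentrations with that slope and averaged over an individual's three
replicates.

Two flags are kept separate because they answer different questions:
``detected`` (seen in at least one replicate -- the protein is real) and
``quantifiable`` (seen in all three -- the concentration average is
meaningful).  Quantitative analyses use the stricter flag.  Families that
are systematically unreliable in this assay (by default the
bradykinin-potentiating peptides, which cleave extensively, and the
myotoxins) can be excluded by family label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_STANDARD_SET = (
    ("P00811", 25.0),
    ("P31658", 250.0),
    ("P31697", 2500.0),
)
DEFAULT_EXCLUDED_FAMILIES = ("BPP", "MYO")


@dataclass
class StandardSet:
    records: Tuple[Tuple[str, float], ...] = DEFAULT_STANDARD_SET

    def __post_init__(self):
        if len(self.records) != 3:
            raise ValueError("a standard set holds exactly three proteins")
        amounts = [a for _, a in self.records]
        if any(a <= 0 for a in amounts) or len(set(amounts)) != 3:
            raise ValueError("standard amounts must be positive and distinct")

    @property
    def ids(self) -> List[str]:
        return [pid for pid, _ in self.records]

    @property
    def amounts(self) -> pd.Series:
        return pd.Series({pid: a for pid, a in self.records})


@dataclass
class ProteinQuant:
    protein_id: str
    individual_id: str
    concentration: Optional[float]  # fmol scale, replicate-averaged
    detected: bool
    quantifiable: bool
    excluded_reason: Optional[str] = None


def fit_conversion_factor(
    standards: StandardSet, replicate_counts: Mapping[str, float]
) -> float:
    """Slope (fmol per count unit) of the through-origin least-squares fit
    of known amounts on observed counts: ``b = sum(c*s) / sum(s^2)``."""
    s = []
    c = []
    for pid, amount in standards.records:
        if pid not in replicate_counts or replicate_counts[pid] <= 0:
            raise ValueError(
                f"standard {pid} missing from replicate; replicate unusable"
            )
        s.append(float(replicate_counts[pid]))
        c.append(float(amount))
    s = np.asarray(s)
    c = np.asarray(c)
    return float((c * s).sum() / (s * s).sum())


def fit_all_conversion_factors(
    table: pd.DataFrame, standards: StandardSet = StandardSet()
) -> pd.Series:
    """One slope per (individual, replicate) column of a spectral-count
    table whose rows include the standard proteins."""
    slopes = {}
    for col in table.columns:
        slopes[col] = fit_conversion_factor(standards, table[col])
    return pd.Series(slopes)


def quantify(
    table: pd.DataFrame,
    slopes: pd.Series,
    standards: StandardSet = StandardSet(),
    families: Optional[Mapping[str, str]] = None,
    excluded_families: Sequence[str] = DEFAULT_EXCLUDED_FAMILIES,
) -> List[ProteinQuant]:
    """Convert counts to concentrations and apply detection/inclusion rules.

    ``table`` columns form a (individual, replicate) MultiIndex with three
    replicates per individual; rows are proteins (standards included, and
    reported separately from venom proteins).  A protein is ``detected``
    when any replicate count is positive, ``quantifiable`` when all three
    are; the replicate-averaged concentration is reported only for
    quantifiable proteins.  Proteins whose family is in
    ``excluded_families`` carry an ``excluded_reason`` and no concentration.
    """
    if not isinstance(table.columns, pd.MultiIndex):
        raise ValueError("table needs (individual, replicate) column MultiIndex")
    results: List[ProteinQuant] = []
    std_ids = set(standards.ids)
    for ind in table.columns.get_level_values(0).unique():
        sub = table[ind]
        if sub.shape[1] != 3:
            raise ValueError(f"individual {ind} does not have 3 replicates")
        rep_slopes = np.array([slopes[(ind, rep)] for rep in sub.columns])
        for pid in table.index:
            if pid in std_ids:
                continue
            counts = sub.loc[pid].to_numpy(dtype=float)
            detected = bool((counts > 0).any())
            quantifiable = bool((counts > 0).all())
            fam = families.get(pid, "") if families else ""
            excluded = fam in set(excluded_families)
            conc = None
            if quantifiable and not excluded:
                conc = float((counts * rep_slopes).mean())
            results.append(
                ProteinQuant(
                    protein_id=pid,
                    individual_id=str(ind),
                    concentration=conc,
                    detected=detected,
                    quantifiable=quantifiable,
                    excluded_reason=(f"excluded-family:{fam}" if excluded else None),
                )
            )
    return results


def quant_frame(results: Sequence[ProteinQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "individual_id": r.individual_id,
                "concentration": r.concentration,
                "detected": r.detected,
                "quantifiable": r.quantifiable,
                "excluded_reason": r.excluded_reason,
            }
            for r in results
        ]
    )


def correlate_abundances(
    clr_transcript: pd.Series, clr_protein: pd.Series
) -> Tuple[float, float, float]:
    """Spearman rho, Pearson R and R^2 between paired clr abundances.

    Pairs over the shared index; requires at least three pairs and
    non-constant vectors.
    """
    shared = clr_transcript.index.intersection(clr_protein.index)
    if len(shared) < 3:
        raise ValueError("need at least three paired proteins")
    x = clr_transcript.reindex(shared).to_numpy(dtype=float)
    y = clr_protein.reindex(shared).to_numpy(dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("correlation undefined for constant vectors")
    rho = float(stats.spearmanr(x, y).statistic)
    r = float(stats.pearsonr(x, y).statistic)
    return rho, r, r * r
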