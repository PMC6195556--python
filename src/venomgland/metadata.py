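"""Individual metadata structures for the sidewinder study design.

The study design crosses eight individuals with five factors: sex, body
size (snout-to-vent length, a proxy for life stage), subspecies, a
mitochondrial lineage assignment, and a nuclear ("nontoxin") lineage
assignment.  :func:`sidewinder_factor_table` returns that published design
as a DataFrame; the synthetic-data generator reuses it (or a subset) so
simulated studies carry the same factor structure.
"""

from __future__ import annotations

import pandas as pd

FACTOR_COLUMNS = ("sex", "svl_cm", "subspecies", "mtdna_lineage", "nontoxin_lineage")

#: Default toxin-family composition of the consensus venom-gland
#: transcriptome: 62 toxin transcripts in 19 families.
DEFAULT_FAMILY_SIZES = {
    "SVMP": 16,
    "SVSP": 15,
    "CTL": 11,
    "PLA2": 1,
    "BPP": 1,
    "LAAO": 1,
    "VEGF": 2,
    "MYO": 2,
    "NGF": 1,
    "CRISP": 1,
    "3FTx": 2,
    "Vespryn": 1,
    "NUC": 1,
    "PDE": 1,
    "HYAL": 1,
    "KUN": 1,
    "Waprin": 1,
    "Ficolin": 2,
    "FusedToxin": 1,
}

_SIDEWINDER_ROWS = [
    # individual_id, sex, svl_cm, subspecies, mtdna_lineage, nontoxin_lineage
    ("CLP2065", "M", 47.8, "cerastes", "N Mojave", "N Mojave"),
    ("CLP2068", "M", 39.1, "cerastes", "S Mojave", "N Mojave"),
    ("CLP2109", "F", 40.8, "cerastes", "S Mojave", "S Mojave"),
    ("CLP2071", "F", 37.7, "laterorepens", "S Mojave", "S Mojave"),
    ("CLP2057", "M", 30.9, "laterorepens", "Colorado", "Colorado"),
    ("CLP2105", "M", 48.4, "cercobombus", "Sonora", "Sonora"),
    ("CLP2137", "M", 45.0, "cercobombus", "Sonora", "Sonora"),
    ("KW1744", "M", 43.5, "cercobombus", "Sonora", "Sonora"),
]


def sidewinder_factor_table() -> pd.DataFrame:
    """Metadata for the eight sidewinder individuals (indexed by field id)."""
    df = pd.DataFrame(
        _SIDEWINDER_ROWS,
        columns=("individual_id",) + FACTOR_COLUMNS,
    ).set_index("individual_id")
    return df


def validate_factor_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the invariants of a factor table (columns present, SVL > 0)."""
    missing = [c for c in FACTOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"factor table missing columns: {missing}")
    if (table["svl_cm"] <= 0).any():
        raise ValueError("svl_cm must be strictly positive")
    bad_sex = set(table["sex"]) - {"M", "F"}
    if bad_sex:
        raise ValueError(f"unknown sex levels: {bad_sex}")
    return table
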