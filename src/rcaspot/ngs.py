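"""Multi-region variant-allele-frequency filtering and heterogeneity profiles.

Sequencing a panel over several microdissected areas of one tumor yields a
per-area variant allele frequency (VAF) for each mutation. Raw VAFs confound
genetic heterogeneity with tumor-cell content, so each kept variant's
per-area VAFs are divided by their across-area mean ("mean set to 1"):
a clonal mutation then sits flat at 1 in every area regardless of purity,
while wide deviations from 1 indicate genuine sub-clonal structure.

Heterogeneity is reported as a continuous score (max |normalized − 1|) with
a configurable flag, never a hard verdict: apparent NGS heterogeneity can be
a technical artifact of amplicon sequencing, so a flag is a *candidate* that
requires orthogonal confirmation (e.g. pyro-sequencing or in situ detection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: normal-tissue VAF at or below this is treated as "absent in normal"
#: (somatic); above it the call is considered germline/contaminated.
GERMLINE_THRESHOLD = 0.02

#: per-area VAF must exceed this in at least one area for a call to be kept.
MIN_AREA_VAF = 0.05

CONSEQUENCE_CLASSES = ("missense", "synonymous", "intronic", "frameshift", "stop")


@dataclass
class VariantRecord:
    """One mutation call across tumor areas and matched normal tissue."""

    gene: str
    coding_change: str
    consequence: str
    area_frequencies: list[float]
    normal_frequency: float
    kept: bool | None = None
    normalized: list[float] | None = field(default=None)

    def __post_init__(self) -> None:
        for f in [*self.area_frequencies, self.normal_frequency]:
            if not 0.0 <= f <= 1.0:
                raise ValueError(
                    f"{self.gene} {self.coding_change}: frequency {f} not in [0,1]"
                )


def filter_variants(
    records: list[VariantRecord],
    min_area_vaf: float = MIN_AREA_VAF,
    germline_threshold: float = GERMLINE_THRESHOLD,
) -> list[VariantRecord]:
    """Set the ``kept`` flag on each record (records returned in order).

    A call is kept iff its VAF exceeds ``min_area_vaf`` in at least one area
    (strict >) AND it is somatic, i.e. effectively absent in the matched
    normal tissue (normal VAF <= ``germline_threshold``, a sequencing noise
    floor).
    """
    for rec in records:
        rec.kept = (
            max(rec.area_frequencies) > min_area_vaf
            and rec.normal_frequency <= germline_threshold
        )
    return records


def normalize_profile(frequencies: list[float] | np.ndarray) -> np.ndarray:
    """Divide per-area frequencies by their mean; the output mean is 1.

    Removes the common scale (tumor-cell content, amplification efficiency)
    so profiles of different mutations are comparable.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size < 2:
        raise ValueError("need >= 2 areas to normalize")
    mean = freqs.mean()
    if mean <= 0:
        raise ValueError("cannot normalize a profile with mean 0")
    return freqs / mean


def heterogeneity_score(
    normalized: list[float] | np.ndarray, flag_threshold: float = 0.5
) -> tuple[float, bool]:
    """Max absolute deviation of the normalized profile from 1, plus a flag.

    The flag marks a *candidate* heterogeneous mutation (score above the
    threshold); it is advisory and requires orthogonal confirmation.
    """
    arr = np.asarray(normalized, dtype=float)
    score = float(np.max(np.abs(arr - 1.0)))
    return score, score > flag_threshold


def analyze_table(
    df: pd.DataFrame,
    area_columns: list[str] | None = None,
    normal_column: str = "normal",
    min_area_vaf: float = MIN_AREA_VAF,
    germline_threshold: float = GERMLINE_THRESHOLD,
    flag_threshold: float = 0.5,
) -> pd.DataFrame:
    """Filter + normalize + score a variant table.

    Expects one row per variant with columns ``gene``, ``coding_change``,
    ``consequence``, per-area VAF columns (default: every column named
    ``area*``) and a matched-normal VAF column. Adds ``kept``, per-area
    ``norm_*`` columns, ``het_score`` and ``het_candidate`` (normalized
    values and scores only for kept rows with positive mean VAF).
    """
    if area_columns is None:
        area_columns = [c for c in df.columns if c.startswith("area")]
    if len(area_columns) < 2:
        raise ValueError("need >= 2 per-area frequency columns")
    out = df.copy()
    freqs = out[area_columns].to_numpy(dtype=float)
    out["kept"] = (freqs.max(axis=1) > min_area_vaf) & (
        out[normal_column].to_numpy(dtype=float) <= germline_threshold
    )
    norm_cols = [f"norm_{c}" for c in area_columns]
    out[norm_cols] = np.nan
    out["het_score"] = np.nan
    out["het_candidate"] = False
    for i in out.index[out["kept"]]:
        row = freqs[out.index.get_loc(i)]
        if row.mean() <= 0:
            continue
        prof = normalize_profile(row)
        out.loc[i, norm_cols] = prof
        score, flagged = heterogeneity_score(prof, flag_threshold)
        out.loc[i, "het_score"] = score
        out.loc[i, "het_candidate"] = flagged
    return out


def read_variant_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def records_from_frame(
    df: pd.DataFrame,
    area_columns: list[str] | None = None,
    normal_column: str = "normal",
) -> list[VariantRecord]:
    if area_columns is None:
        area_columns = [c for c in df.columns if c.startswith("area")]
    return [
        VariantRecord(
            gene=str(row["gene"]),
            coding_change=str(row.get("coding_change", "")),
            consequence=str(row.get("consequence", "")),
            area_frequencies=[float(row[c]) for c in area_columns],
            normal_frequency=float(row[normal_column]),
        )
        for _, row in df.iterrows()
    ]
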