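"""Per-area spot counting and mutant-allele-frequency statistics.

Mutant allele frequency in situ is mutant spots / (mutant + wild-type spots)
within a tumor area, reported both pooled over all counted fields of view
(a count ratio, e.g. "13.4% (45/334 signals)") and as the mean of the ten
per-field percentages ("Mean 14.8%") — the two generally differ. Fields of
view are restricted to >80% tumor content so the surrounding stroma does not
dilute the denominator, and each area's per-field percentages are compared
to non-neoplastic control tissue with an unpaired two-sided t test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .detection import Spot

logger = logging.getLogger(__name__)


@dataclass
class RegionLayout:
    """Tumor areas as a label mask plus tumor-content and control annotation.

    ``labels`` holds one region id per pixel (0 = unassigned tissue).
    ``tumor_content`` is a per-pixel fraction map; a dict of per-region
    scalars is broadcast onto the mask. ``control_region`` names the
    non-neoplastic region the areas are tested against.
    """

    labels: np.ndarray
    tumor_content: np.ndarray | dict
    control_region: int
    region_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        present = [int(v) for v in np.unique(self.labels) if v != 0]
        if not self.region_ids:
            self.region_ids = present
        if isinstance(self.tumor_content, dict):
            content = np.zeros(self.labels.shape, dtype=np.float64)
            for rid, frac in self.tumor_content.items():
                content[self.labels == rid] = float(frac)
            self.tumor_content = content
        else:
            self.tumor_content = np.asarray(self.tumor_content, dtype=np.float64)
        if self.tumor_content.shape != self.labels.shape:
            raise ValueError("tumor content map shape mismatch")
        if self.control_region not in self.region_ids:
            raise ValueError(
                f"control region {self.control_region} absent from layout"
            )


@dataclass
class FieldOfView:
    """One microscope field: a fixed-size box inside a region."""

    region: int
    row0: int
    col0: int
    height: int
    width: int
    mean_tumor_content: float
    field_id: int = -1
    counts: dict = field(default_factory=dict)

    def contains(self, y: int, x: int) -> bool:
        # half-open membership: lower/left edge in, upper/right edge out
        return (
            self.row0 <= y < self.row0 + self.height
            and self.col0 <= x < self.col0 + self.width
        )

    @property
    def mutant_pct(self) -> float:
        m = self.counts.get("mutant", 0)
        w = self.counts.get("wildtype", 0)
        return mutant_percentage(m, m + w)


@dataclass
class QuantResult:
    """Per-region quantification summary."""

    region: int
    wildtype: int
    mutant: int
    field_percentages: list[float]
    n_fields: int
    n_empty_fields: int = 0
    t_statistic: float | None = None
    p_value: float | None = None
    stars: str | None = None
    is_control: bool = False

    @property
    def total(self) -> int:
        return self.wildtype + self.mutant

    @property
    def pooled_pct(self) -> float:
        return mutant_percentage(self.mutant, self.total)

    @property
    def mean_field_pct(self) -> float:
        if not self.field_percentages:
            return math.nan
        return float(np.mean(self.field_percentages))


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables),
    avoiding binary-float artifacts via decimal arithmetic."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def mutant_percentage(
    mutant: int, total: int, decimals: int | None = None
) -> float:
    """100·mutant/total; NaN when total is 0 (no informative signals).

    ``decimals`` applies half-up rounding at the printed precision; the
    default returns the exact ratio.
    """
    if mutant < 0 or total < 0:
        raise ValueError("counts must be non-negative")
    if mutant > total:
        raise ValueError(f"mutant count {mutant} exceeds total {total}")
    if total == 0:
        return math.nan
    pct = 100.0 * mutant / total
    if decimals is None:
        return pct
    return round_half_up(pct, decimals)


def star_label(p: float) -> str:
    """Significance stars: * p<0.05, *** p<0.001, **** p<0.0001.

    The two-star level is deliberately absent from this legend.
    """
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


def compare_to_control(
    sample: list[float] | np.ndarray,
    control: list[float] | np.ndarray,
    equal_var: bool = True,
) -> tuple[float, float, str]:
    """Unpaired two-sided t test of area field-percentages vs control.

    Equal-variance (pooled) Student t by default; Welch via
    ``equal_var=False``. Returns (t, p, star label).
    """
    sample = np.asarray(sample, dtype=float)
    control = np.asarray(control, dtype=float)
    if sample.size < 2 or control.size < 2:
        raise ValueError("t test needs >= 2 values per group")
    if np.ptp(sample) == 0 and np.ptp(control) == 0:
        # degenerate zero-variance case scipy reports as NaN
        if sample[0] == control[0]:
            return 0.0, 1.0, ""
        return math.inf, 0.0, star_label(0.0)
    res = stats.ttest_ind(sample, control, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    return t, p, star_label(p)


def select_fields(
    layout: RegionLayout,
    region_id: int,
    field_size: tuple[int, int] = (512, 512),
    n: int = 10,
    min_tumor_content: float = 0.8,
    seed: int | np.random.Generator = 0,
) -> list[FieldOfView]:
    """Choose ``n`` non-overlapping fields of view inside a region.

    Candidate placements tile the region's bounding box at a stride of one
    field, which makes non-overlap structural and "not enough eligible
    placements" decidable; a field is eligible when it lies wholly inside the
    region mask and its mean tumor content exceeds ``min_tumor_content``.
    ``n`` eligible tiles are drawn uniformly at random under the seed.
    """
    h, w = field_size
    mask = layout.labels == region_id
    if not mask.any():
        raise ValueError(f"region {region_id} not present in layout")
    rows, cols = np.nonzero(mask)
    rmin, rmax = rows.min(), rows.max()
    cmin, cmax = cols.min(), cols.max()
    candidates: list[FieldOfView] = []
    for r0 in range(rmin, rmax - h + 2, h):
        for c0 in range(cmin, cmax - w + 2, w):
            sub = mask[r0 : r0 + h, c0 : c0 + w]
            if sub.shape != (h, w) or not sub.all():
                continue
            content = float(layout.tumor_content[r0 : r0 + h, c0 : c0 + w].mean())
            if content > min_tumor_content:
                candidates.append(
                    FieldOfView(
                        region=region_id, row0=int(r0), col0=int(c0),
                        height=h, width=w, mean_tumor_content=content,
                    )
                )
    if len(candidates) < n:
        raise ValueError(
            f"region {region_id}: only {len(candidates)} eligible field "
            f"placements (size {h}x{w}, tumor content > {min_tumor_content}), "
            f"{n} requested"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen_idx = rng.choice(len(candidates), size=n, replace=False)
    chosen = [candidates[i] for i in sorted(int(i) for i in chosen_idx)]
    for i, f in enumerate(chosen):
        f.field_id = i
    return chosen


def count_in_fields(
    spots: list[Spot], fields: list[FieldOfView]
) -> list[FieldOfView]:
    """Tally per-class spot counts in each field (half-open membership).

    All four classes are tallied for audit; only wild-type and mutant enter
    the mutant-percentage numerator/denominator. Spot ``field`` ids are set
    on spots falling inside a field.
    """
    for f in fields:
        f.counts = {"wildtype": 0, "mutant": 0, "control": 0, "unspecific": 0}
    for s in spots:
        for f in fields:
            if f.contains(s.y, s.x):
                cls = s.allele if s.allele in f.counts else None
                if cls is not None:
                    f.counts[cls] += 1
                s.field = f.field_id
                break
    return fields


def quantify_regions(
    spots: list[Spot],
    layout: RegionLayout,
    field_size: tuple[int, int] = (512, 512),
    n_fields: int = 10,
    min_tumor_content: float = 0.8,
    seed: int = 0,
) -> list[QuantResult]:
    """Full per-region quantification: fields → counts → percentages → t test.

    One QuantResult per region in layout order (control included). Fields
    with zero informative (wild-type + mutant) signals are dropped from the
    per-field mean with a logged count. Each tumor area's field percentages
    are tested against the control region's.
    """
    results: list[QuantResult] = []
    control_pcts: list[float] | None = None
    per_region_fields: dict[int, list[FieldOfView]] = {}
    for idx, rid in enumerate(layout.region_ids):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(idx,)))
        fields = select_fields(
            layout, rid, field_size=field_size, n=n_fields,
            min_tumor_content=min_tumor_content, seed=rng,
        )
        count_in_fields(spots, fields)
        per_region_fields[rid] = fields
        wt = sum(f.counts["wildtype"] for f in fields)
        mu = sum(f.counts["mutant"] for f in fields)
        pcts = [f.mutant_pct for f in fields]
        kept = [p for p in pcts if not math.isnan(p)]
        n_empty = len(pcts) - len(kept)
        if n_empty:
            logger.info(
                "region %s: %d field(s) with no informative signals dropped "
                "from the per-field mean", rid, n_empty,
            )
        res = QuantResult(
            region=rid, wildtype=int(wt), mutant=int(mu),
            field_percentages=kept, n_fields=len(fields),
            n_empty_fields=n_empty, is_control=(rid == layout.control_region),
        )
        results.append(res)
        if res.is_control:
            control_pcts = kept
    if control_pcts is None or len(control_pcts) < 2:
        raise ValueError("control region yielded < 2 informative fields")
    for res in results:
        if not res.is_control and len(res.field_percentages) >= 2:
            t, p, stars = compare_to_control(res.field_percentages, control_pcts)
            res.t_statistic, res.p_value, res.stars = t, p, stars
    return results


def results_to_frame(results: list[QuantResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "region": r.region,
                "wildtype": r.wildtype,
                "mutant": r.mutant,
                "total": r.total,
                "pooled_pct": r.pooled_pct,
                "mean_field_pct": r.mean_field_pct,
                "n_fields": r.n_fields,
                "n_empty_fields": r.n_empty_fields,
                "t": r.t_statistic,
                "p": r.p_value,
                "stars": r.stars if r.stars is not None else "",
                "is_control": r.is_control,
            }
            for r in results
        ]
    )
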