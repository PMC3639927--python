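"""CNV-region detection on dye-swap probe data.

Two callers plus a concordance filter:

* ``call_rule_based`` — maximal runs of consecutive probes whose direct label
  exceeds the log2 threshold in absolute value and (when required) whose
  dye-swap label exceeds it with the opposite sign, with the direction
  constant across the run; runs must contain at least
  ``min_consecutive_probes`` probes and span at least ``min_span`` bp.
* ``call_window`` — sliding windows over the dye-swap-combined signal
  ``s = (direct - swap) / 2`` (clipped at +/-2 per probe); qualifying windows
  are merged into maximal regions; the same span filter applies.
* ``consensus`` — regions from one caller kept only when a same-direction
  region from the other caller reciprocally overlaps them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CNVRegion, GAIN, LOSS, ValidationError, overlap_bp
from .io_formats import ProbeTable

logger = logging.getLogger(__name__)

#: Per-probe cap on the combined dye-swap signal used by the window caller.
SIGNAL_CLIP = 2.0


@dataclass(frozen=True)
class DetectionParams:
    log2_threshold: float = 0.25
    min_consecutive_probes: int = 3
    min_span: int = 30_000
    require_dye_swap: bool = True
    window_size: int = 5
    concordance_overlap: float = 0.5

    def __post_init__(self):
        if self.log2_threshold <= 0:
            raise ValidationError("log2_threshold must be > 0")
        if self.min_consecutive_probes < 1:
            raise ValidationError("min_consecutive_probes must be >= 1")
        if self.min_span < 0:
            raise ValidationError("min_span must be >= 0")
        if self.window_size < 1:
            raise ValidationError("window_size must be >= 1")
        if not (0 < self.concordance_overlap <= 1):
            raise ValidationError("concordance_overlap must be in (0, 1]")


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def combined_signal(direct, swap) -> float:
    """Dye-swap-combined signal for one probe, using whichever labels exist."""
    d_miss, s_miss = _is_missing(direct), _is_missing(swap)
    if d_miss and s_miss:
        return 0.0
    if s_miss:
        return float(direct)
    if d_miss:
        return -float(swap)
    return (float(direct) - float(swap)) / 2.0


def _probe_direction(direct, swap, params: DetectionParams):
    """Direction of a qualifying probe under the rule criteria, else None."""
    if _is_missing(direct) or abs(direct) < params.log2_threshold:
        return None
    if params.require_dye_swap:
        if _is_missing(swap) or abs(swap) < params.log2_threshold:
            return None
        if direct * swap >= 0:  # dye swap must flip the sign
            return None
    return LOSS if direct < 0 else GAIN


def _emit(chrom, rows, direction, caller, comparison_id, params) -> CNVRegion | None:
    if len(rows) < params.min_consecutive_probes:
        return None
    start = int(rows[0].start)
    end = int(rows[-1].end)
    if end - start < params.min_span:
        return None
    mean_log2 = float(np.mean([combined_signal(r.log2_direct, r.log2_swap) for r in rows]))
    return CNVRegion(
        chrom=chrom,
        start=start,
        end=end,
        direction=direction,
        n_probes=len(rows),
        mean_log2=mean_log2,
        caller=caller,
        comparison_id=comparison_id,
    )


def call_rule_based(probes: ProbeTable, params: DetectionParams | None = None) -> list[CNVRegion]:
    """Call regions as maximal runs of threshold-qualifying consecutive probes."""
    params = params or DetectionParams()
    regions: list[CNVRegion] = []
    for chrom, sub in probes.probes.groupby("chrom", sort=False):
        run: list = []
        run_dir = None
        for row in sub.itertuples(index=False):
            d = _probe_direction(row.log2_direct, row.log2_swap, params)
            if d is None or d != run_dir:
                if run:
                    region = _emit(chrom, run, run_dir, "rule", probes.comparison_id, params)
                    if region:
                        regions.append(region)
                run, run_dir = ([row], d) if d is not None else ([], None)
            else:
                run.append(row)
        if run:
            region = _emit(chrom, run, run_dir, "rule", probes.comparison_id, params)
            if region:
                regions.append(region)
    return regions


def call_window(probes: ProbeTable, params: DetectionParams | None = None) -> list[CNVRegion]:
    """Sliding-window caller on the combined dye-swap signal.

    Windows of ``window_size`` probes with |mean signal| >= threshold are
    merged into maximal covered stretches; within a stretch each probe takes
    the direction of the net qualifying-window signal covering it, so output
    regions never overlap.  Stretch boundaries are then trimmed to the
    outermost probes whose own |signal| clears the threshold (windowed means
    otherwise smear the boundary by up to window_size - 1 probes).  Only the
    span filter applies afterwards.
    """
    params = params or DetectionParams()
    if params.window_size < 3:
        raise ValidationError("window_size must be >= 3 for the window caller")
    regions: list[CNVRegion] = []
    for chrom, sub in probes.probes.groupby("chrom", sort=False):
        n = len(sub)
        w = params.window_size
        if n < w:
            continue
        s = np.array(
            [combined_signal(r.log2_direct, r.log2_swap) for r in sub.itertuples(index=False)]
        )
        s = np.clip(s, -SIGNAL_CLIP, SIGNAL_CLIP)
        means = np.convolve(s, np.ones(w) / w, mode="valid")  # means[j] over [j, j+w)
        qualifying = np.abs(means) >= params.log2_threshold
        net = np.zeros(n)  # summed qualifying-window means covering each probe
        for j in np.nonzero(qualifying)[0]:
            net[j : j + w] += means[j]
        covered = net != 0.0
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        i = 0
        while i < n:
            if not covered[i]:
                i += 1
                continue
            direction = LOSS if net[i] < 0 else GAIN
            j = i
            while j + 1 < n and covered[j + 1] and (net[j + 1] < 0) == (net[i] < 0):
                j += 1
            next_i = j + 1
            # trim boundary smear: keep the stretch between the outermost
            # probes that individually clear the threshold in this direction
            sign = -1.0 if direction == LOSS else 1.0
            lo, hi = i, j
            while lo <= hi and not (sign * s[lo] >= params.log2_threshold):
                lo += 1
            while hi >= lo and not (sign * s[hi] >= params.log2_threshold):
                hi -= 1
            if lo > hi:
                i = next_i
                continue
            i, j = lo, hi
            start, end = int(starts[i]), int(ends[j])
            mean_log2 = float(np.mean(s[i : j + 1]))
            direction_ok = (mean_log2 <= 0) if direction == LOSS else (mean_log2 >= 0)
            if end - start >= params.min_span and direction_ok:
                regions.append(
                    CNVRegion(
                        chrom=chrom,
                        start=start,
                        end=end,
                        direction=direction,
                        n_probes=j - i + 1,
                        mean_log2=mean_log2,
                        caller="window",
                        comparison_id=probes.comparison_id,
                    )
                )
            i = next_i
    return regions


def reciprocal_overlap(a: CNVRegion, b: CNVRegion) -> float:
    """Smaller of the two mutual overlap fractions (0 for different chroms)."""
    if a.chrom != b.chrom:
        return 0.0
    ov = overlap_bp(a.start, a.end, b.start, b.end)
    return min(ov / a.span, ov / b.span)


def consensus(
    regions_a: list[CNVRegion],
    regions_b: list[CNVRegion],
    concordance_overlap: float = 0.5,
) -> list[CNVRegion]:
    """Regions from ``regions_a`` confirmed by a same-direction region in ``regions_b``.

    A region is kept when some region of the other list with the same
    direction has reciprocal overlap >= ``concordance_overlap``; the kept
    region's interval is taken from list a and relabelled ``consensus``.
    """
    kept = []
    for ra in regions_a:
        for rb in regions_b:
            if ra.direction == rb.direction and reciprocal_overlap(ra, rb) >= concordance_overlap:
                kept.append(
                    CNVRegion(
                        chrom=ra.chrom,
                        start=ra.start,
                        end=ra.end,
                        direction=ra.direction,
                        n_probes=ra.n_probes,
                        mean_log2=ra.mean_log2,
                        caller="consensus",
                        comparison_id=ra.comparison_id,
                    )
                )
                break
    return kept


def annotate_overlaps(
    regions: list[CNVRegion], features: pd.DataFrame
) -> list[list[tuple[str, float]]]:
    """Per-region overlapping feature names with overlap fraction of the region.

    Any (>= 1 bp) intersection counts as an overlap; adjacent half-open
    intervals that merely share a boundary coordinate do not overlap.
    """
    feature_chroms = set(features["chrom"]) if len(features) else set()
    result = []
    for region in regions:
        if region.chrom not in feature_chroms:
            logger.warning(
                "region chromosome %s absent from feature intervals", region.chrom
            )
            result.append([])
            continue
        hits = []
        sub = features[features["chrom"] == region.chrom]
        for f in sub.itertuples(index=False):
            ov = overlap_bp(region.start, region.end, int(f.start), int(f.end))
            if ov >= 1:
                hits.append((f.name, ov / region.span))
        result.append(hits)
    return result


def regions_stats_table(regions: list[CNVRegion]) -> pd.DataFrame:
    """Per-region statistics as a DataFrame (for TSV output next to the BED)."""
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "span": r.span,
            "direction": r.direction,
            "n_probes": r.n_probes,
            "mean_log2": round(r.mean_log2, 4),
            "caller": r.caller,
            "comparison_id": r.comparison_id,
        }
        for r in regions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "span",
            "direction",
            "n_probes",
            "mean_log2",
            "caller",
            "comparison_id",
        ],
    )
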