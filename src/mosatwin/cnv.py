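"""Windowed depth-ratio CNV calling and the twin-differential filter cascade.

Depth over fixed windows (100 bp by default) is normalised per sample to unit
median, then expressed as a ratio against the average of a background panel.
Windows beyond the loss/gain ratio thresholds (0.62 / 1.38) are merged into
regions that must span a minimum number of windows (20) with a minimum
fraction of supporting windows (80%).

The differential cascade then keeps regions reciprocally overlapping by >= 90%
between the two samples of the affected twin, drops any candidate touched by a
CNV in either sample of the healthy twin, and removes loss candidates lying in
poorly mappable sequence. A loss call can finally be probed for loss of
heterozygosity: a real deletion depletes heterozygous genotypes in the carrier.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .errors import AuditError, ValidationError
from .io_formats import Interval


@dataclasses.dataclass
class CnvParams:
    """Region-filter and cascade parameters."""

    min_windows: int = 20
    min_support: float = 0.80
    loss_ratio: float = 0.62
    gain_ratio: float = 1.38
    reciprocal_frac: float = 0.90
    min_uniqueness: float = 0.5
    background_center: str = "mean"  # "median" behind this flag
    direction_sensitive_exclusion: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.reciprocal_frac <= 1:
            raise ValidationError("reciprocal_frac must lie in (0, 1]")
        if not 0 < self.min_support <= 1:
            raise ValidationError("min_support must lie in (0, 1]")
        if not 0 < self.loss_ratio < 1 < self.gain_ratio:
            raise ValidationError("need loss_ratio < 1 < gain_ratio")


@dataclasses.dataclass
class DepthMatrix:
    """Per-window, per-sample depth (summed base coverage per window)."""

    windows: list[Interval]
    samples: list[str]
    depth: np.ndarray  # (n_windows, n_samples)
    window_size: int | None = None
    background_samples: list[str] | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (len(self.windows), len(self.samples)):
            raise ValidationError("depth matrix shape does not match windows x samples")
        if self.depth.size and self.depth.min() < 0:
            raise ValidationError("depths must be non-negative")
        prev_end: dict[str, int] = {}
        for w in self.windows:
            if w.start < prev_end.get(w.contig, 0):
                raise ValidationError("windows must be sorted and non-overlapping")
            prev_end[w.contig] = w.end

    def column(self, sample: str) -> np.ndarray:
        return self.depth[:, self.samples.index(sample)]


@dataclasses.dataclass
class CnvRegion:
    """A called copy-number region (0-based half-open interval)."""

    interval: Interval
    direction: str  # loss | gain
    n_windows: int
    support_fraction: float
    mean_ratio: float
    sample: str

    def __post_init__(self) -> None:
        if self.direction not in ("loss", "gain"):
            raise ValidationError(f"invalid direction {self.direction!r}")
        if self.direction == "loss" and not self.mean_ratio < 1:
            raise ValidationError("loss region requires mean_ratio < 1")
        if self.direction == "gain" and not self.mean_ratio > 1:
            raise ValidationError("gain region requires mean_ratio > 1")
        if not 0 <= self.support_fraction <= 1:
            raise ValidationError("support_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# normalisation and region calling
# ---------------------------------------------------------------------------

def normalize_depth(
    matrix: DepthMatrix,
    test_samples: Sequence[str] | None = None,
    background_samples: Sequence[str] | None = None,
    center: str = "mean",
) -> dict[str, np.ndarray]:
    """Per-window depth ratios of each test sample against the background panel.

    Every sample is first scaled to unit median (removing library-size
    effects); the ratio at window w is the scaled test depth over the mean
    (or median, per ``center``) scaled background depth. Windows with zero
    background depth are masked as NaN.
    """
    background = list(
        background_samples
        if background_samples is not None
        else (matrix.background_samples or [])
    )
    if len(background) < 2:
        raise ValidationError("need at least 2 background samples")
    tests = list(
        test_samples
        if test_samples is not None
        else [s for s in matrix.samples if s not in background]
    )

    def scaled(sample: str) -> np.ndarray:
        col = matrix.column(sample)
        med = np.median(col)
        if med <= 0:
            raise ValidationError(f"sample {sample!r} has non-positive median depth")
        return col / med

    bg = np.stack([scaled(s) for s in background], axis=1)
    if not bg.any():
        raise ValidationError("background panel is all-zero")
    center_fn = np.median if center == "median" else np.mean
    bg_center = center_fn(bg, axis=1)
    zero = bg_center <= 0
    if zero.mean() > 0.05:
        raise ValidationError(
            f"{zero.mean():.0%} of windows have zero background depth (max 5%)"
        )
    ratios: dict[str, np.ndarray] = {}
    for s in tests:
        r = scaled(s) / np.where(zero, np.nan, bg_center)
        ratios[s] = r
    return ratios


def call_cnv_regions(
    ratios: np.ndarray,
    windows: Sequence[Interval],
    sample: str,
    params: CnvParams | None = None,
) -> list[CnvRegion]:
    """Merge thresholded windows into loss/gain regions and apply the filters.

    A window is called loss when its ratio is below ``loss_ratio`` and gain
    when above ``gain_ratio``. Maximal same-direction runs are extended across
    uncalled gaps as long as the merged support stays at least ``min_support``
    (an opposite-direction call breaks the run). Regions are kept when they
    span >= ``min_windows`` windows with support >= ``min_support`` and a mean
    ratio beyond their direction's threshold.
    """
    p = params or CnvParams()
    ratios = np.asarray(ratios, dtype=float)
    if len(ratios) != len(windows):
        raise ValidationError("ratios and windows length mismatch")
    state = np.zeros(len(ratios), dtype=int)  # -1 loss, +1 gain
    with np.errstate(invalid="ignore"):
        state[ratios < p.loss_ratio] = -1
        state[ratios > p.gain_ratio] = 1
    state[np.isnan(ratios)] = 0

    # maximal runs of identical called state
    runs: list[tuple[int, int, int]] = []  # (first, last, direction)
    i = 0
    n = len(state)
    while i < n:
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and state[j + 1] == state[i]:
            j += 1
        runs.append((i, j, int(state[i])))
        i = j + 1

    # greedy left-to-right merge of same-direction runs across uncalled gaps
    merged: list[tuple[int, int, int, int]] = []  # (first, last, direction, n_called)
    for first, last, direction in runs:
        n_called = last - first + 1
        if merged:
            mf, ml, md, mc = merged[-1]
            gap_states = state[ml + 1 : first]
            gap_clean = not np.any(gap_states != 0)
            if md == direction and gap_clean:
                span = last - mf + 1
                if (mc + n_called) / span >= p.min_support:
                    merged[-1] = (mf, last, md, mc + n_called)
                    continue
        merged.append((first, last, direction, n_called))

    out: list[CnvRegion] = []
    for first, last, direction, n_called in merged:
        span = last - first + 1
        support = n_called / span
        mean_ratio = float(np.nanmean(ratios[first : last + 1]))
        if span < p.min_windows or support < p.min_support:
            continue
        if direction == -1 and not mean_ratio < p.loss_ratio:
            continue
        if direction == 1 and not mean_ratio > p.gain_ratio:
            continue
        if windows[first].contig != windows[last].contig:
            continue  # regions never bridge contigs
        out.append(
            CnvRegion(
                interval=Interval(windows[first].contig, windows[first].start,
                                  windows[last].end),
                direction="loss" if direction == -1 else "gain",
                n_windows=span, support_fraction=support,
                mean_ratio=mean_ratio, sample=sample,
            )
        )
    return out


# ---------------------------------------------------------------------------
# differential cascade
# ---------------------------------------------------------------------------

def reciprocal_overlap(
    a: Interval, b: Interval, frac: float
) -> tuple[bool, float, float]:
    """Whether two intervals each cover >= ``frac`` of themselves mutually."""
    if not 0 < frac <= 1:
        raise ValidationError("frac must lie in (0, 1]")
    ov = a.overlap_length(b)
    fa, fb = ov / len(a), ov / len(b)
    return (fa >= frac and fb >= frac), fa, fb


def _mean_uniqueness(region: Interval, track: Sequence[Interval]) -> float:
    covered = 0
    weighted = 0.0
    any_contig = False
    for iv in track:
        if iv.contig != region.contig:
            continue
        any_contig = True
        ov = region.overlap_length(iv)
        if ov:
            covered += ov
            weighted += ov * (iv.score if iv.score is not None else 0.0)
    if not any_contig:
        raise AuditError(f"no mappability data for contig {region.contig!r}")
    if covered == 0:
        return 0.0
    return weighted / covered


@dataclasses.dataclass
class CascadeResult:
    candidates: list[CnvRegion]
    audit: dict


def differential_cnv_filter(
    affected_regions: tuple[Sequence[CnvRegion], Sequence[CnvRegion]],
    healthy_regions: tuple[Sequence[CnvRegion], Sequence[CnvRegion]],
    mappability: Sequence[Interval],
    params: CnvParams | None = None,
) -> CascadeResult:
    """Three-stage twin-differential CNV filter with a per-stage audit.

    Stage 1 pairs regions from the affected twin's two samples that pass the
    reciprocal-overlap test in the same direction, merging each pair as its
    intersection (conservative bounds). Stage 2 drops candidates with any
    (>= 1 bp) overlap with a healthy-twin region. Stage 3 drops loss
    candidates whose mean mappability uniqueness falls below the threshold.
    """
    p = params or CnvParams()
    stage1: list[CnvRegion] = []
    for ra in affected_regions[0]:
        for rb in affected_regions[1]:
            if ra.direction != rb.direction:
                continue
            ok, _, _ = reciprocal_overlap(ra.interval, rb.interval, p.reciprocal_frac)
            if not ok:
                continue
            inter = Interval(
                ra.interval.contig,
                max(ra.interval.start, rb.interval.start),
                min(ra.interval.end, rb.interval.end),
            )
            window = len(ra.interval) // max(ra.n_windows, 1)
            stage1.append(
                CnvRegion(
                    interval=inter, direction=ra.direction,
                    n_windows=max(1, len(inter) // max(window, 1)),
                    support_fraction=min(ra.support_fraction, rb.support_fraction),
                    mean_ratio=(ra.mean_ratio + rb.mean_ratio) / 2.0,
                    sample=f"{ra.sample}&{rb.sample}",
                )
            )

    healthy_all = list(healthy_regions[0]) + list(healthy_regions[1])
    stage2 = []
    for cand in stage1:
        hit = any(
            cand.interval.overlap_length(h.interval) > 0
            and (not p.direction_sensitive_exclusion or h.direction == cand.direction)
            for h in healthy_all
        )
        if not hit:
            stage2.append(cand)

    stage3 = []
    for cand in stage2:
        if cand.direction == "loss":
            if _mean_uniqueness(cand.interval, mappability) < p.min_uniqueness:
                continue
        stage3.append(cand)

    audit = {
        "affected_input": (len(affected_regions[0]), len(affected_regions[1])),
        "healthy_input": (len(healthy_regions[0]), len(healthy_regions[1])),
        "stage1_reciprocal": len(stage1),
        "stage2_healthy_exclusion": len(stage2),
        "stage3_mappability": len(stage3),
    }
    return CascadeResult(candidates=stage3, audit=audit)


# ---------------------------------------------------------------------------
# LOH support
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LohResult:
    het_fraction_carrier: float | None
    het_fraction_other: float | None
    n_informative: int
    verdict: str  # supported | unsupported | insufficient


def loh_support(
    region: Interval,
    carrier_calls: Mapping[tuple[str, int], object],
    other_calls: Mapping[tuple[str, int], object],
    min_snvs: int = 5,
) -> LohResult:
    """Check whether genotypes support a loss of heterozygosity in a region.

    Counts heterozygous calls among sites inside the region genotyped in both
    samples. The verdict is "supported" when the putative deletion carrier's
    het fraction is below half the other sample's with at least ``min_snvs``
    informative sites, "insufficient" when too few sites exist, otherwise
    "unsupported".
    """
    def inside(site: tuple[str, int]) -> bool:
        contig, pos = site
        return contig == region.contig and region.start <= pos - 1 < region.end

    common = [
        s for s in carrier_calls
        if inside(s) and s in other_calls
        and carrier_calls[s] is not None and other_calls[s] is not None
    ]
    n = len(common)
    if n < min_snvs:
        return LohResult(None, None, n, "insufficient")

    def het_frac(calls) -> float:
        het = sum(1 for s in common if calls[s].genotype[0] != calls[s].genotype[1])
        return het / n

    fc, fo = het_frac(carrier_calls), het_frac(other_calls)
    verdict = "supported" if fc < 0.5 * fo else "unsupported"
    return LohResult(fc, fo, n, verdict)
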