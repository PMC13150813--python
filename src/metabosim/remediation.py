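"""Automatic remediation of simulated spectra against experimental grids.

Simulations that fall below the 0.9 similarity threshold are adjusted, in
order: (1) solvent suppression — ROIs overlapping the water (4.6–4.9 ppm)
or reference (−0.1–0.1 ppm) regions are trimmed or dropped; (2) global
chemical-shift alignment — a single ppm offset absorbs referencing
differences between standards (e.g. TSP vs DSS), seeded by matching the
lowest-ppm simulated multiplet to the nearest experimental maximum;
(3) a global line-width scale — source databases often carry a 1 Hz
placeholder width where experimental lines are nearer 3 Hz.  Each step is
kept only if it does not lower the score, so the recorded score never
decreases.  What was done, and the scores before and after, live in a
:class:`RemediationRecord`; spectra that cannot be brought above threshold
are classed as needing manual work, and exact-1.0 matches are flagged
unverified (a perfect score against noiseless "experimental" data is a
sign the reference was cleaned, not measured).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import (
    AlignmentError,
    EmptyReportError,
    OptimizationError,
    ValidationError,
)
from .lineshape import PeakList, SpectrumGrid, render
from .similarity import (
    DEFAULT_SNR_MIN,
    DEFAULT_THRESHOLD,
    RegionOfInterest,
    merge_rois,
    overall_score,
    regions_of_interest,
)

__all__ = [
    "RemediationStep",
    "RemediationRecord",
    "align_offset",
    "fit_width_scale",
    "suppress_solvent",
    "auto_remediate",
    "summarize_records",
    "DEFAULT_SOLVENT_INTERVALS",
    "DEFAULT_MAX_OFFSET_PPM",
    "DEFAULT_WIDTH_BOUNDS",
]

#: water region and reference-compound region excluded from scoring (ppm)
DEFAULT_SOLVENT_INTERVALS = ((4.9, 4.6), (0.1, -0.1))
#: covers typical TSP/DSS referencing offsets
DEFAULT_MAX_OFFSET_PPM = 0.05
DEFAULT_WIDTH_BOUNDS = (0.2, 20.0)

STATUSES = ("verified", "remediated", "needs_manual", "unverified")
CATEGORIES = (
    "peak_position",
    "peak_height",
    "multiplet_pattern",
    "j_coupling",
    "width",
    "alignment",
    "solvent",
    "unverifiable",
)


@dataclass
class RemediationStep:
    """One applied adjustment and the score it achieved."""

    name: str  # solvent | alignment | width
    fitted: dict
    score_after_step: float


@dataclass
class RemediationRecord:
    """Outcome of one automatic remediation run."""

    steps: list[RemediationStep]
    score_before: float
    score_after: float
    status: str
    category: Optional[str] = None
    adjusted_peaks: Optional[PeakList] = None  # not serialized

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValidationError(f"status must be one of {STATUSES}")
        if self.category is not None and self.category not in CATEGORIES:
            raise ValidationError(f"category must be one of {CATEGORIES}")
        if self.status == "remediated" and self.score_after < self.score_before:
            raise ValidationError(
                "a remediated record cannot lower the score"
            )
        if self.status == "verified" and self.steps:
            raise ValidationError("a verified record has no steps")

    def to_log(self) -> str:
        """Delimited text log, one step per row."""
        lines = [
            f"status\t{self.status}",
            f"category\t{self.category if self.category else '.'}",
            f"score_before\t{self.score_before!r}",
            f"score_after\t{self.score_after!r}",
            "step\tname\tfitted\tscore_after_step",
        ]
        for i, st in enumerate(self.steps, 1):
            fitted = ";".join(f"{k}={v!r}" for k, v in st.fitted.items())
            lines.append(
                f"step\t{st.name}\t{fitted or '.'}\t{st.score_after_step!r}"
            )
        return "\n".join(lines) + "\n"


def summarize_records(records: Sequence[RemediationRecord]) -> pd.DataFrame:
    """Counts per (status, category) — the remediation bookkeeping table."""
    rows = [
        {"status": r.status, "category": r.category or "none"}
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["status", "category"])
    return (
        df.groupby(["status", "category"])
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["status", "category"])
        .reset_index(drop=True)
    )


def _score_grids(
    sim: SpectrumGrid,
    exp: SpectrumGrid,
    rois: Sequence[RegionOfInterest],
    snr_min: float,
) -> float:
    return overall_score(sim, exp, rois, snr_min=snr_min).overall


def _shift_grid(sim: SpectrumGrid, offset_ppm: float) -> np.ndarray:
    """Intensities of ``sim`` displaced by +offset_ppm, on the same axis."""
    # axis is decreasing; np.interp needs increasing x
    x = sim.ppm_axis[::-1]
    y = sim.intensities[::-1]
    shifted = np.interp(sim.ppm_axis - offset_ppm, x, y, left=0.0, right=0.0)
    return shifted


def align_offset(
    sim: SpectrumGrid,
    exp: SpectrumGrid,
    max_offset_ppm: float = DEFAULT_MAX_OFFSET_PPM,
    rois: Optional[Sequence[RegionOfInterest]] = None,
    snr_min: float = 0.0,
) -> float:
    """Global ppm shift of the simulation maximizing the ROI-mean score.

    Grid search at axis resolution over ±max_offset_ppm (seeded by
    aligning the lowermost simulated multiplet to the nearest experimental
    maximum), followed by parabolic refinement around the best step.  A
    fit pinned at the search bound is returned with a warning.
    """
    if max_offset_ppm <= 0:
        raise ValidationError("max_offset_ppm must be positive")
    if not sim.same_axis(exp):
        raise ValidationError("grids must share the axis")
    if float(np.ptp(exp.intensities)) == 0.0:
        raise AlignmentError("experimental grid is flat; alignment undefined")
    if rois is None:
        rois = [
            RegionOfInterest(
                float(exp.ppm_axis[0]), float(exp.ppm_axis[-1]), "full"
            )
        ]

    step = sim.step_ppm
    n_steps = max(1, int(np.floor(max_offset_ppm / step)))
    candidates = list(np.arange(-n_steps, n_steps + 1) * step)

    # lowermost-multiplet seed: nearest experimental max to the lowest-ppm
    # simulated feature
    low_roi = min(rois, key=lambda r: r.ppm_low)
    idx = sim.slice_indices(low_roi.ppm_high, low_roi.ppm_low)
    if idx.size:
        sim_pos = float(sim.ppm_axis[idx[np.argmax(sim.intensities[idx])]])
        window = exp.slice_indices(
            sim_pos + max_offset_ppm, sim_pos - max_offset_ppm
        )
        if window.size:
            exp_pos = float(
                exp.ppm_axis[window[np.argmax(exp.intensities[window])]]
            )
            seed = exp_pos - sim_pos
            if abs(seed) <= max_offset_ppm:
                candidates.append(seed)

    def objective(delta: float) -> float:
        shifted = sim.with_intensities(_shift_grid(sim, delta))
        moved = [r.shifted(delta) for r in rois]
        try:
            return _score_grids(shifted, exp, moved, snr_min)
        except EmptyReportError:
            return -1.0

    scores = np.array([objective(d) for d in candidates])
    best = int(np.argmax(scores))
    d0 = candidates[best]

    # parabolic refinement on (d0 - step, d0, d0 + step)
    triple = [d0 - step, d0, d0 + step]
    s = [objective(d) for d in triple]
    denom = s[0] - 2 * s[1] + s[2]
    if denom < 0:  # genuine interior maximum
        refined = d0 + 0.5 * step * (s[0] - s[2]) / denom
        if abs(refined - d0) <= step and objective(refined) >= s[1]:
            d0 = refined
    if abs(d0) > max_offset_ppm:
        d0 = float(np.clip(d0, -max_offset_ppm, max_offset_ppm))
    if abs(abs(d0) - max_offset_ppm) < 0.5 * step:
        warnings.warn(
            "fitted offset lies at the search bound; the true displacement "
            "may exceed max_offset_ppm",
            stacklevel=2,
        )
    return float(d0)


def fit_width_scale(
    peaklist: PeakList,
    exp: SpectrumGrid,
    bounds: tuple[float, float] = DEFAULT_WIDTH_BOUNDS,
    rois: Optional[Sequence[RegionOfInterest]] = None,
    snr_min: float = 0.0,
) -> float:
    """Multiplicative factor on every peak width maximizing the ROI score.

    One-dimensional bounded maximization on the log of the factor,
    re-rendering the peak list on the experimental axis per candidate.
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValidationError("width-scale bounds must satisfy 0 < lo < hi")
    if rois is None:
        rois = regions_of_interest(peaklist, exp.spectrometer_mhz)
    first = float(exp.ppm_axis[0])
    last = float(exp.ppm_axis[-1])

    def objective(log_f: float) -> float:
        f = float(np.exp(log_f))
        sim = render(
            peaklist.scaled_widths(f),
            exp.spectrometer_mhz,
            first,
            last,
            exp.n_points,
        )
        try:
            score = _score_grids(sim, exp, rois, snr_min)
        except EmptyReportError:
            return 1.0
        if not np.isfinite(score):
            raise OptimizationError(
                f"non-finite similarity score at width factor {f!r}"
            )
        return -score

    res = minimize_scalar(
        objective,
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    if not np.isfinite(res.fun):
        raise OptimizationError("width-scale optimization failed to converge")
    return float(np.exp(res.x))


def suppress_solvent(
    rois: Sequence[RegionOfInterest],
    exp: SpectrumGrid,
    solvent_intervals: Sequence[tuple[float, float]] = DEFAULT_SOLVENT_INTERVALS,
) -> list[RegionOfInterest]:
    """Trim ROIs to their part outside the solvent/reference intervals.

    An ROI fully inside a solvent interval is dropped; one straddling an
    interval is replaced by the set difference (possibly two pieces).
    """
    out: list[RegionOfInterest] = []
    for roi in rois:
        pieces = [(roi.ppm_high, roi.ppm_low)]
        for s_hi, s_lo in solvent_intervals:
            if s_hi < s_lo:
                s_hi, s_lo = s_lo, s_hi
            nxt: list[tuple[float, float]] = []
            for hi, lo in pieces:
                if s_lo >= hi or s_hi <= lo:  # disjoint
                    nxt.append((hi, lo))
                    continue
                if hi > s_hi:
                    nxt.append((hi, s_hi))
                if s_lo > lo:
                    nxt.append((s_lo, lo))
            pieces = nxt
        for hi, lo in pieces:
            if hi > lo:
                out.append(RegionOfInterest(hi, lo, roi.origin))
    if not out:
        raise EmptyReportError(
            "every ROI lies inside a solvent/reference interval"
        )
    return merge_rois(out)


def auto_remediate(
    entry_sim: PeakList,
    exp: SpectrumGrid,
    threshold: float = DEFAULT_THRESHOLD,
    snr_min: float = DEFAULT_SNR_MIN,
    solvent_intervals: Sequence[tuple[float, float]] = DEFAULT_SOLVENT_INTERVALS,
    max_offset_ppm: float = DEFAULT_MAX_OFFSET_PPM,
    width_bounds: tuple[float, float] = DEFAULT_WIDTH_BOUNDS,
    margin_factor: float = 10.0,
) -> RemediationRecord:
    """Adjust a simulation until it reaches the similarity threshold.

    Applies solvent suppression, offset alignment and a global width-scale
    fit in that order, re-scoring after each and keeping only steps that do
    not lower the score; stops early once the threshold is reached.  The
    adjusted peak list is attached to the returned record.
    """
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must lie in (0, 1]")
    if len(entry_sim) == 0:
        raise ValidationError("cannot remediate an empty peak list")
    mhz = exp.spectrometer_mhz
    first, last = float(exp.ppm_axis[0]), float(exp.ppm_axis[-1])

    def rois_for(peaks: PeakList, solvent: bool) -> list[RegionOfInterest]:
        rois = regions_of_interest(peaks, mhz, margin_factor=margin_factor)
        if solvent:
            rois = suppress_solvent(rois, exp, solvent_intervals)
        return rois

    def score_for(peaks: PeakList, solvent: bool) -> float:
        sim = render(peaks, mhz, first, last, exp.n_points)
        rois = rois_for(peaks, solvent)
        try:
            return overall_score(sim, exp, rois, snr_min=snr_min).overall
        except EmptyReportError:
            # no experimental signal above the SNR floor anywhere the
            # simulation predicts peaks: score without exclusion so the
            # record still carries a number (it will be low)
            try:
                return overall_score(sim, exp, rois, snr_min=0.0).overall
            except EmptyReportError:
                return -1.0

    peaks = entry_sim
    use_solvent = False
    score_before = score_for(peaks, use_solvent)
    if score_before == 1.0:
        return RemediationRecord(
            steps=[],
            score_before=score_before,
            score_after=score_before,
            status="unverified",
            category="unverifiable",
            adjusted_peaks=peaks,
        )
    if score_before >= threshold:
        return RemediationRecord(
            steps=[],
            score_before=score_before,
            score_after=score_before,
            status="verified",
            adjusted_peaks=peaks,
        )

    steps: list[RemediationStep] = []
    current = score_before

    # 1. solvent suppression
    try:
        base_rois = rois_for(peaks, False)
        trimmed = suppress_solvent(base_rois, exp, solvent_intervals)
        if trimmed != base_rois:
            candidate = score_for(peaks, True)
            if candidate >= current:
                use_solvent = True
                current = candidate
                steps.append(
                    RemediationStep(
                        name="solvent",
                        fitted={
                            "suppressed_intervals": list(solvent_intervals)
                        },
                        score_after_step=current,
                    )
                )
    except EmptyReportError:
        pass

    # 2. offset alignment
    if current < threshold:
        sim = render(peaks, mhz, first, last, exp.n_points)
        try:
            offset = align_offset(
                sim,
                exp,
                max_offset_ppm,
                rois=rois_for(peaks, use_solvent),
                snr_min=snr_min,
            )
        except AlignmentError:
            offset = 0.0
        if offset != 0.0:
            moved = peaks.shifted(offset)
            candidate = score_for(moved, use_solvent)
            if candidate >= current:
                peaks = moved
                current = candidate
                steps.append(
                    RemediationStep(
                        name="alignment",
                        fitted={"ppm_offset": offset},
                        score_after_step=current,
                    )
                )

    # 3. global width scale
    if current < threshold:
        factor = fit_width_scale(
            peaks,
            exp,
            bounds=width_bounds,
            rois=rois_for(peaks, use_solvent),
            snr_min=snr_min,
        )
        scaled = peaks.scaled_widths(factor)
        candidate = score_for(scaled, use_solvent)
        if candidate >= current:
            peaks = scaled
            current = candidate
            steps.append(
                RemediationStep(
                    name="width",
                    fitted={"width_scale": factor},
                    score_after_step=current,
                )
            )

    if current >= threshold:
        status = "remediated"
        category = _dominant_category(steps, score_before)
    else:
        status = "needs_manual"
        category = "unverifiable"
    return RemediationRecord(
        steps=steps,
        score_before=score_before,
        score_after=current,
        status=status,
        category=category,
        adjusted_peaks=peaks,
    )


def _dominant_category(
    steps: list[RemediationStep], score_before: float
) -> Optional[str]:
    """Label the record by the step that contributed the largest gain."""
    name_map = {"solvent": "solvent", "alignment": "alignment", "width": "width"}
    best, best_gain = None, 0.0
    prev = score_before
    for st in steps:
        gain = st.score_after_step - prev
        prev = st.score_after_step
        if gain >= best_gain:
            best, best_gain = name_map.get(st.name), gain
    return best
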