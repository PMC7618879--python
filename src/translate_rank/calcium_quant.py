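"""Single-cell cytosolic calcium trace quantification.

Background-corrected fluorescence traces F_C(t) (one per cell, typically one
frame per second) recorded while treatments are added sequentially -
glycine first (a co-agonist required for NMDA-receptor activation), then
the agonists of interest (glutamate, aspartate), and finally the calcium
ionophore ionomycin to elicit each cell's maximal response - are quantified
as follows:

1. one baseline window of ``width`` consecutive frames, shared by all cells
   in the sample, is chosen before the first agonist of interest where the
   signal is most stable (minimum summed within-window variance over an
   exhaustive window scan); F_C0 = per-cell median over the window;
2. traces are baseline-normalized, Delta(F/F0)_C(t) = F_C(t)/F_C0 - 1;
3. the amplitude of treatment T is the maximum of the normalized trace
   between T's addition and the next addition (the last window runs to the
   trace end);
4. trace and amplitudes are divided by the cell's own ionomycin amplitude,
   cancelling dye loading and gain; amplitudes above 1 or below 0 are kept
   (bona fide high/low responders);
5. cells without an ionomycin response, or whose signal does not return to
   baseline before the next addition, are excluded; and
6. the sample trace is the per-time-point mean +/- s.e.m. of the kept
   ionomycin-normalized traces (it need not reach 1 at the ionomycin peak,
   because cells peak at different times).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GLYCINE = "glycine"
IONOMYCIN = "ionomycin"

EXCL_NONE = "none"
EXCL_NO_IONO = "no_ionomycin_response"
EXCL_NO_RETURN = "no_return_to_baseline"


class ScheduleError(ValueError):
    """Invalid treatment schedule."""


@dataclass
class TraceSet:
    """Per-cell fluorescence vs time plus an ordered treatment schedule.

    ``traces`` is indexed by time (seconds) with one column per cell;
    ``schedule`` is an ordered list of (label, addition time) with strictly
    increasing times and ionomycin last.
    """

    traces: pd.DataFrame
    schedule: list[tuple[str, float]]

    def __post_init__(self) -> None:
        times = [t for _, t in self.schedule]
        if len(times) < 1:
            raise ScheduleError("schedule must contain at least one treatment")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ScheduleError("treatment times must be strictly increasing")
        if self.schedule[-1][0] != IONOMYCIN:
            raise ScheduleError("ionomycin must be the last treatment")

    @property
    def time(self) -> np.ndarray:
        return self.traces.index.to_numpy(dtype=float)

    @property
    def cells(self) -> list[str]:
        return list(self.traces.columns)

    def windows(self) -> dict[str, tuple[float, float]]:
        """Treatment label -> [start, end) time window; last runs to end."""
        out = {}
        times = [t for _, t in self.schedule]
        for i, (label, t0) in enumerate(self.schedule):
            t1 = times[i + 1] if i + 1 < len(times) else np.inf
            out[label] = (t0, t1)
        return out

    def first_scored_time(self) -> float:
        """Addition time of the first treatment of interest (the first
        non-glycine treatment when glycine leads the schedule)."""
        for label, t in self.schedule:
            if label != GLYCINE:
                return t
        raise ScheduleError("schedule has no treatment of interest")


def find_baseline_window(ts: TraceSet, width: int = 20) -> tuple[int, int]:
    """Select the common baseline window [start, end) in frame indices.

    Candidate windows of ``width`` consecutive frames must end before the
    addition of the first treatment of interest; the window minimizing the
    sum across cells of the within-window variance (highest shared signal
    stability) is chosen, earliest on ties.
    """
    time = ts.time
    limit = int(np.searchsorted(time, ts.first_scored_time(), side="left"))
    if limit < width:
        raise ValueError(
            f"only {limit} pre-treatment frames; need at least width={width}")
    data = ts.traces.to_numpy(dtype=float)
    best, best_score = 0, np.inf
    for start in range(0, limit - width + 1):
        seg = data[start:start + width]
        score = float(seg.var(axis=0, ddof=0).sum())
        if score < best_score - 1e-15:
            best, best_score = start, score
    return best, best + width


@dataclass
class CellQuant:
    """Quantification of one cell: baseline, amplitudes, normalized trace."""

    cell: str
    f0: float
    amplitudes: dict[str, float]           # Delta(F/F0) per treatment
    norm_amplitudes: dict[str, float]      # ionomycin-normalized
    norm_trace: np.ndarray                 # ionomycin-normalized trace
    dff_trace: np.ndarray                  # Delta(F/F0) trace
    exclusion: str = EXCL_NONE

    @property
    def ionomycin_amplitude(self) -> float:
        return self.amplitudes[IONOMYCIN]


def quantify_cell(trace: pd.Series, f0: float, ts: TraceSet) -> CellQuant:
    """Normalize one cell's trace and extract per-treatment amplitudes.

    Amplitudes outside [0, 1] after ionomycin normalization are retained.
    Cells with a non-positive ionomycin amplitude are flagged (their
    normalized quantities are NaN) and handled by :func:`apply_exclusions`.
    """
    if f0 <= 0:
        raise ValueError("baseline F0 must be positive")
    time = ts.time
    values = trace.to_numpy(dtype=float)
    dff = values / f0 - 1.0
    amplitudes = {}
    for label, (t0, t1) in ts.windows().items():
        mask = (time >= t0) & (time < t1)
        if not mask.any():
            raise ScheduleError(f"no frames in window of treatment {label!r}")
        amplitudes[label] = float(dff[mask].max())
    iono = amplitudes[IONOMYCIN]
    if iono > 0:
        norm_trace = dff / iono
        norm_amplitudes = {k: v / iono for k, v in amplitudes.items()}
        excl = EXCL_NONE
    else:
        norm_trace = np.full_like(dff, np.nan)
        norm_amplitudes = {k: np.nan for k in amplitudes}
        excl = EXCL_NO_IONO
    return CellQuant(cell=str(trace.name), f0=f0, amplitudes=amplitudes,
                     norm_amplitudes=norm_amplitudes, norm_trace=norm_trace,
                     dff_trace=dff, exclusion=excl)


def apply_exclusions(quants: list[CellQuant], ts: TraceSet,
                     iono_min: float = 0.1, return_frac: float = 0.2,
                     min_resp: float = 0.05
                     ) -> tuple[list[CellQuant], pd.DataFrame]:
    """Exclude non-responders and non-returners; report counts per reason.

    A cell is excluded when its ionomycin amplitude (Delta(F/F0) units) is
    below ``iono_min``, or when for any non-final treatment the normalized
    trace between that treatment's peak and the next addition never drops
    below ``return_frac`` times the treatment amplitude. The return check is
    only applied to genuine responses (ionomycin-normalized amplitude above
    ``min_resp``) so that noise on non-responding windows is not mistaken
    for a plateau.
    """
    time = ts.time
    windows = ts.windows()
    labels = [lab for lab, _ in ts.schedule]
    kept: list[CellQuant] = []
    for q in quants:
        if q.exclusion == EXCL_NO_IONO or q.ionomycin_amplitude < iono_min:
            q.exclusion = EXCL_NO_IONO
            continue
        excluded = False
        for i, label in enumerate(labels[:-1]):
            t0, t1 = windows[label]
            win = np.flatnonzero((time >= t0) & (time < t1))
            amp = q.norm_amplitudes[label]
            if amp <= min_resp:
                continue
            peak = win[int(np.argmax(q.norm_trace[win]))]
            tail = q.norm_trace[peak:win[-1] + 1]
            if float(tail.min()) > return_frac * amp:
                q.exclusion = EXCL_NO_RETURN
                excluded = True
                break
        if not excluded:
            q.exclusion = EXCL_NONE
            kept.append(q)
    counts = pd.Series([q.exclusion for q in quants]).value_counts()
    report = pd.DataFrame({
        "n_cells": counts,
        "fraction": counts / len(quants)}).rename_axis("reason")
    return kept, report


def sample_average(quants: list[CellQuant], ts: TraceSet) -> pd.DataFrame:
    """Mean +/- s.e.m. of the kept ionomycin-normalized traces per frame.

    Because normalization is per cell, the averaged trace does not in
    general reach 1 at the ionomycin peak (cells peak at different times).
    Requires at least two cells (s.e.m. is undefined otherwise).
    """
    if len(quants) < 2:
        raise ValueError("sample averaging requires at least 2 kept cells")
    mat = np.stack([q.norm_trace for q in quants])
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
    return pd.DataFrame({"mean": mean, "sem": sem}, index=ts.traces.index)


def quantify_sample(ts: TraceSet, width: int = 20, iono_min: float = 0.1,
                    return_frac: float = 0.2):
    """Full per-sample pipeline: baseline window, per-cell quantification,
    exclusions and the averaged trace.

    Returns ``(quants, kept, report, averaged)``.
    """
    start, end = find_baseline_window(ts, width=width)
    quants = []
    for cell in ts.cells:
        trace = ts.traces[cell]
        f0 = float(trace.iloc[start:end].median())
        quants.append(quantify_cell(trace, f0, ts))
    kept, report = apply_exclusions(quants, ts, iono_min=iono_min,
                                    return_frac=return_frac)
    averaged = sample_average(kept, ts) if len(kept) >= 2 else None
    return quants, kept, report, averaged
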