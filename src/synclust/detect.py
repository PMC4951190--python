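"""Classify spines as input-positive from ΔG/R calcium traces.

Each photostimulation trial yields 50 frames at 10 Hz per region of
interest (ROI): frame 1 with the laser shutter closed (electrical
offset), 5 baseline frames, 2 shuttered stimulus frames, and 42
response frames.  The calcium signal is the change in green
(calcium-indicator) fluorescence normalized to the red structural
channel, ΔG/R.  A spine is called input-positive when, in at least one
trial, its smoothed peak ΔG/R over the 2nd–4th post-stimulus points
exceeds the dendritic-base peak plus three times the larger of the
baseline and tail standard deviations — transmitter release is
stochastic, so a single clear success suffices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

TRACE_COLUMNS = ("cell_id", "segment_id", "spine_id", "trial", "roi", "frame", "green", "red")


@dataclass(frozen=True)
class FrameRoles:
    """Partition of the per-trial frame indices (0-based)."""

    offset: int = 0
    baseline: tuple[int, int] = (1, 6)    # half-open [start, stop)
    stimulus: tuple[int, int] = (6, 8)
    response: tuple[int, int] = (8, 50)

    @property
    def n_frames(self) -> int:
        return self.response[1]

    @property
    def baseline_idx(self) -> np.ndarray:
        return np.arange(*self.baseline)

    @property
    def response_idx(self) -> np.ndarray:
        return np.arange(*self.response)

    @property
    def open_idx(self) -> np.ndarray:
        """Open-shutter frames: baseline + response."""
        return np.concatenate([self.baseline_idx, self.response_idx])

    @property
    def n_baseline(self) -> int:
        return self.baseline[1] - self.baseline[0]


DEFAULT_ROLES = FrameRoles()


@dataclass
class TrialFeatures:
    """Per-trial summary of a smoothed ΔG/R trace."""

    peak: float          # max smoothed ΔG/R over post-stimulus points 2-4
    sd_baseline: float
    sd_tail: float       # SD over the last five points
    peak_index: float    # argmax of the smoothed response section
    responded: bool | None = None


def roi_intensity(
    green_pixels: np.ndarray,
    red_pixels: np.ndarray,
    brightest_fraction: float = 0.7,
    select: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame mean ROI intensities, optionally over the brightest red pixels.

    ``green_pixels``/``red_pixels`` have shape (frames, pixels).  With
    ``select`` (spine ROIs) the retained set is the brightest
    ``brightest_fraction`` of pixels by mean red intensity, fixed
    across frames; dendrite ROIs average all pixels (``select=False``).
    """
    green_pixels = np.asarray(green_pixels, dtype=float)
    red_pixels = np.asarray(red_pixels, dtype=float)
    if green_pixels.ndim != 2 or green_pixels.shape != red_pixels.shape:
        raise ValueError("pixel arrays must be (frames, pixels) and aligned")
    n_pix = green_pixels.shape[1]
    if n_pix == 0:
        raise ValueError("empty ROI")
    if not 0 < brightest_fraction <= 1:
        raise ValueError("brightest_fraction must lie in (0, 1]")
    if select:
        keep = max(1, ceil(brightest_fraction * n_pix))
        order = np.argsort(red_pixels.mean(axis=0))
        idx = order[-keep:]
    else:
        idx = np.arange(n_pix)
    return green_pixels[:, idx].mean(axis=1), red_pixels[:, idx].mean(axis=1)


def dgr_trace(G: np.ndarray, R: np.ndarray, roles: FrameRoles = DEFAULT_ROLES) -> np.ndarray:
    """ΔG/R trace from per-frame channel means.

    The electrical offset (shutter-closed frame) is subtracted from
    both channels, ΔG is the green deviation from the baseline mean,
    and the trace is ΔG divided by the mean red intensity over all
    open-shutter frames.  Stimulus frames are excluded, so the trace
    concatenates baseline and response sections.  A nonpositive mean R
    yields an all-NaN trace (undefined signal).
    """
    G = np.asarray(G, dtype=float)
    R = np.asarray(R, dtype=float)
    if G.shape != R.shape or G.size < roles.n_frames:
        raise ValueError(f"traces must be aligned with >= {roles.n_frames} frames")
    Gc = G - G[roles.offset]
    Rc = R - R[roles.offset]
    open_idx = roles.open_idx
    rbar = Rc[open_idx].mean()
    if rbar <= 0:
        warnings.warn("nonpositive mean red intensity; ΔG/R undefined")
        return np.full(open_idx.size, np.nan)
    dG = Gc - Gc[roles.baseline_idx].mean()
    return dG[open_idx] / rbar


def smooth3(x: np.ndarray) -> np.ndarray:
    """Centered 3-point moving average; edges average the points present."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    for i in range(x.size):
        out[i] = x[max(0, i - 1) : i + 2].mean()
    return out


def trial_features(
    trace: np.ndarray, n_baseline: int = DEFAULT_ROLES.n_baseline
) -> TrialFeatures:
    """Smooth a ΔG/R trace and extract peak and noise features.

    The peak is the maximum of the smoothed trace over the 2nd–4th
    post-stimulus points; SDs are taken over the smoothed baseline and
    the last five points.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < n_baseline + 9:
        raise ValueError("trace too short: need baseline plus >= 9 post-stimulus points")
    # baseline and response are separated in time by the shuttered stimulus
    # frames, so the moving average must not bleed across the gap
    base = smooth3(trace[:n_baseline])
    resp = smooth3(trace[n_baseline:])
    peak = float(np.max(resp[1:4]))
    return TrialFeatures(
        peak=peak,
        sd_baseline=float(np.std(base, ddof=1)),
        sd_tail=float(np.std(resp[-5:], ddof=1)),
        peak_index=float(np.argmax(resp)) if np.all(np.isfinite(resp)) else float("nan"),
    )


def classify_spine(
    spine_trials: Sequence[TrialFeatures],
    dendrite_trials: Sequence[TrialFeatures],
    sd_source: str = "spine",
    require_earlier_peak: bool = False,
) -> bool:
    """Input-positive call from paired spine/dendrite trial features.

    Positive iff some trial has ``spine.peak > dendrite.peak +
    3·max(SDs)`` (strict: exact equality is negative).  The SDs are the
    spine trace's baseline and tail SDs, which bound the measurement
    noise of the compared peak; ``sd_source='max'`` additionally folds
    in the dendrite SDs.  ``require_earlier_peak`` adds the optional
    secondary check that the spine's smoothed peak occurs strictly
    before the dendrite's.
    """
    if len(spine_trials) == 0 or len(spine_trials) != len(dendrite_trials):
        raise ValueError("need equal, nonzero numbers of paired trials")
    if sd_source not in ("spine", "max"):
        raise ValueError("sd_source must be 'spine' or 'max'")
    for sp, dd in zip(spine_trials, dendrite_trials):
        sds = [sp.sd_baseline, sp.sd_tail]
        if sd_source == "max":
            sds += [dd.sd_baseline, dd.sd_tail]
        hit = sp.peak > dd.peak + 3.0 * max(sds)
        if hit and require_earlier_peak:
            hit = sp.peak_index < dd.peak_index
        if hit:
            return True
    return False


# ---------------------------------------------------------------------------
# table-level driver
# ---------------------------------------------------------------------------

def load_traces(path: str | Path) -> pd.DataFrame:
    """Read a long-format trace CSV (one row per frame, ROI and trial)."""
    table = pd.read_csv(path)
    for col in TRACE_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"trace table {path} is missing column {col!r}")
    return table


def detect_inputs(
    traces: pd.DataFrame,
    roles: FrameRoles = DEFAULT_ROLES,
    sd_source: str = "spine",
    require_earlier_peak: bool = False,
) -> pd.DataFrame:
    """Classify every spine in a trace table; emit the spine-map schema.

    Expects for each (cell, segment, spine) paired ``spine`` and
    ``dendrite`` ROI traces per trial.  The output has columns
    ``cell_id, segment_id, position_um, positive`` (position carried
    through when a ``position_um`` column is present, else NaN), ready
    for :func:`synclust.spinemap.load_spine_maps` consumers.
    """
    rows = []
    for (cell, seg, spine), grp in traces.groupby(
        ["cell_id", "segment_id", "spine_id"], sort=True
    ):
        spine_feats, dend_feats = [], []
        for trial, tgrp in grp.groupby("trial", sort=True):
            feats = {}
            for roi, rgrp in tgrp.groupby("roi"):
                rgrp = rgrp.sort_values("frame")
                trace = dgr_trace(
                    rgrp["green"].to_numpy(), rgrp["red"].to_numpy(), roles
                )
                feats[roi] = trial_features(trace, roles.n_baseline)
            if "spine" not in feats or "dendrite" not in feats:
                raise ValueError(
                    f"spine {(cell, seg, spine)} trial {trial} lacks paired spine/dendrite ROIs"
                )
            spine_feats.append(feats["spine"])
            dend_feats.append(feats["dendrite"])
        positive = classify_spine(
            spine_feats, dend_feats, sd_source=sd_source,
            require_earlier_peak=require_earlier_peak,
        )
        pos_um = float(grp["position_um"].iloc[0]) if "position_um" in grp.columns else np.nan
        rows.append(
            {
                "cell_id": cell,
                "segment_id": seg,
                "spine_id": spine,
                "position_um": pos_um,
                "positive": int(positive),
            }
        )
    return pd.DataFrame(rows).sort_values(
        ["cell_id", "segment_id", "position_um", "spine_id"], ignore_index=True
    )
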