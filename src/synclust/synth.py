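"""Synthetic spine maps and calcium traces.

Generates data with the statistical structure the analyses assume:
spines as a homogeneous 1D point process (default 0.8 spines/µm) along
segments of realistic length, a background input-positive rate
(default 9.2%), optionally implanted clusters (default 7 inputs within
12.5 µm — the geometry of observed clusters), and per-trial ΔG/R
trace tables with stochastic transmitter release at 10 Hz frame
structure.  Everything is driven by a single seed: regenerating with
the same configuration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import DEFAULT_ROLES, FrameRoles
from .spinemap import SpineDataset, SpineSegment

#: decay time constant of the synthetic calcium transient (s)
TRANSIENT_TAU_S = 0.5
FRAME_INTERVAL_S = 0.1


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-data generator.

    Lengths in µm, rates as probabilities.  ``segment_length`` may be a
    fixed value or a ``(low, high)`` uniform range.  ``spacing`` is
    ``'poisson'`` (homogeneous point process) or ``'lattice'``
    (regular spacing ``1/spine_density``, for worked-example style
    toys).
    """

    n_segments: int = 40
    segment_length: float | tuple[float, float] = (40.0, 90.0)
    spine_density: float = 0.8
    background_positive_rate: float = 0.092
    clusters_per_segment: int = 0
    cluster_span: float = 12.5
    cluster_inputs: int = 7
    release_prob: float = 0.5
    spine_success_amplitude: float = 0.48
    dendrite_amplitude: float = 0.18
    noise_sd: float = 0.05
    trials: int = 3
    seed: int = 0
    spacing: str = "poisson"

    def __post_init__(self) -> None:
        if not 0 <= self.background_positive_rate <= 1:
            raise ValueError("background_positive_rate must lie in [0, 1]")
        if not 0 <= self.release_prob <= 1:
            raise ValueError("release_prob must lie in [0, 1]")
        if self.spine_density <= 0:
            raise ValueError("spine_density must be positive")
        if self.spacing not in ("poisson", "lattice"):
            raise ValueError("spacing must be 'poisson' or 'lattice'")


def _segment_length(cfg: GeneratorConfig, rng: np.random.Generator) -> float:
    if isinstance(cfg.segment_length, (tuple, list)):
        lo, hi = cfg.segment_length
        return float(rng.uniform(lo, hi))
    return float(cfg.segment_length)


def generate_segments(cfg: GeneratorConfig) -> SpineDataset:
    """Draw a dataset of marked segments under the configured conditions.

    Spine positions follow a homogeneous point process at
    ``spine_density`` (count Poisson, positions uniform; at least one
    spine); marks are background Bernoulli draws; clusters are
    implanted afterwards when ``clusters_per_segment > 0``.
    """
    rng = np.random.default_rng(cfg.seed)
    segments = []
    for s in range(cfg.n_segments):
        length = _segment_length(cfg, rng)
        if cfg.spacing == "lattice":
            pos = np.arange(0.0, length + 1e-9, 1.0 / cfg.spine_density)
        else:
            count = max(1, rng.poisson(cfg.spine_density * length))
            pos = np.sort(rng.uniform(0.0, length, count))
        marks = rng.random(pos.size) < cfg.background_positive_rate
        seg = SpineSegment(
            cell_id=f"cell{s // 2:03d}",
            segment_id=f"seg{s:03d}",
            positions=pos,
            marks=marks,
            branch_offset=float(rng.uniform(5.0, 60.0)),
        )
        if cfg.clusters_per_segment > 0:
            seg = implant_clusters(
                seg,
                cfg.clusters_per_segment,
                cfg.cluster_span,
                cfg.cluster_inputs,
                rng=rng,
            )
        segments.append(seg)
    return SpineDataset(segments, provenance=f"synclust.synth seed={cfg.seed}")


def implant_clusters(
    seg: SpineSegment,
    k: int,
    span: float,
    m: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_retries: int = 100,
) -> SpineSegment:
    """Mark ``m`` spines positive inside each of ``k`` disjoint windows.

    Windows of the given span are placed uniformly at random (resampled
    when they hold fewer than ``m`` spines or overlap a previous
    window, up to ``max_retries`` each); within a window, the ``m``
    spines nearest its center are marked.  Background positives are
    kept.  Returns a modified copy.
    """
    if k == 0:
        return seg
    if rng is None:
        rng = np.random.default_rng(seed)
    pos = seg.positions
    lo, hi = float(pos[0]), float(pos[-1])
    if hi - lo < span * k:
        raise ValueError("segment too short for the requested cluster windows")
    marks = seg.marks.copy()
    placed: list[tuple[float, float]] = []
    for _ in range(k):
        for attempt in range(max_retries):
            start = rng.uniform(lo, hi - span)
            window = (start, start + span)
            if any(window[0] < e and w < window[1] for w, e in placed):
                continue
            inside = np.flatnonzero((pos >= window[0]) & (pos <= window[1]))
            if inside.size < m:
                continue
            center = start + span / 2
            chosen = inside[np.argsort(np.abs(pos[inside] - center))[:m]]
            marks[chosen] = True
            placed.append(window)
            break
        else:
            raise RuntimeError(
                f"could not place a {span} µm window holding {m} spines "
                f"after {max_retries} attempts"
            )
    return seg.with_marks(marks)


# ---------------------------------------------------------------------------
# trace synthesis
# ---------------------------------------------------------------------------

def _transient(roles: FrameRoles, amplitude: float) -> np.ndarray:
    """Per-frame transient: instantaneous rise at the first response frame,
    exponential decay with a 0.5 s time constant."""
    sig = np.zeros(roles.n_frames)
    resp = roles.response_idx
    t = (resp - resp[0]) * FRAME_INTERVAL_S
    sig[resp] = amplitude * np.exp(-t / TRANSIENT_TAU_S)
    return sig


def generate_traces(
    ds: SpineDataset,
    cfg: GeneratorConfig,
    roles: FrameRoles = DEFAULT_ROLES,
) -> pd.DataFrame:
    """Synthesize a per-frame trace table for every spine in a dataset.

    For each positive spine and trial, a release success is drawn with
    ``release_prob``; successes add a calcium transient of
    ``spine_success_amplitude`` to the spine ROI.  The dendrite-base
    ROI carries a ``dendrite_amplitude`` transient on every trial
    (widespread stimulation), negative spines carry noise only.
    Gaussian noise of ``noise_sd`` is added to all open-shutter green
    frames; the red structural channel is constant up to small noise.
    Frame layout matches :class:`synclust.detect.FrameRoles`.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x7ACE)))
    g_off, r_off = 0.10, 0.05   # electrical offsets (shutter-closed level)
    g_base, r_level = 0.20, 1.00
    frames = np.arange(roles.n_frames)
    open_mask = np.zeros(roles.n_frames, dtype=bool)
    open_mask[roles.open_idx] = True
    rows = []
    for seg in ds.sorted_segments():
        for spine_idx in range(seg.n_spines):
            positive = bool(seg.marks[spine_idx])
            for trial in range(cfg.trials):
                success = positive and (rng.random() < cfg.release_prob)
                for roi, amp in (
                    ("spine", cfg.spine_success_amplitude if success else 0.0),
                    ("dendrite", cfg.dendrite_amplitude),
                ):
                    G = np.full(roles.n_frames, g_off)
                    R = np.full(roles.n_frames, r_off)
                    G[open_mask] += g_base + r_level * (
                        _transient(roles, amp)[open_mask]
                        + rng.normal(0.0, cfg.noise_sd, open_mask.sum())
                    )
                    R[open_mask] += r_level + rng.normal(0.0, 0.005, open_mask.sum())
                    rows.append(
                        pd.DataFrame(
                            {
                                "cell_id": seg.cell_id,
                                "segment_id": seg.segment_id,
                                "spine_id": spine_idx,
                                "position_um": seg.positions[spine_idx],
                                "trial": trial,
                                "roi": roi,
                                "frame": frames,
                                "green": G,
                                "red": R,
                            }
                        )
                    )
    if not rows:
        return pd.DataFrame(
            columns=list(TRACE_TABLE_COLUMNS)
        )
    return pd.concat(rows, ignore_index=True)


TRACE_TABLE_COLUMNS = (
    "cell_id",
    "segment_id",
    "spine_id",
    "position_um",
    "trial",
    "roi",
    "frame",
    "green",
    "red",
)
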