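"""Domain model and I/O for marked spine maps.

A *spine map* records, for each dendritic segment of a mapped cell, the
ordered path positions of all imaged spines (µm along the dendrite,
origin at the segment start) together with a binary mark saying whether
the spine was classified as receiving the specific input (e.g. an
intralaminar L5 input).  These maps are the substrate of every spatial
statistic in this package: the combinatorial cluster analysis
(:mod:`synclust.combclust`) and the nearest-neighbor reshuffling
analysis (:mod:`synclust.nnd`) both operate on :class:`SpineSegment`
objects grouped into a :class:`SpineDataset`.

The on-disk format is a plain CSV with columns ``cell_id``,
``segment_id``, ``position_um``, ``positive`` (0/1) and optionally
``soma_distance_um``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns a spine-map table must provide
REQUIRED_COLUMNS = ("cell_id", "segment_id", "position_um", "positive")

#: tolerance below which two path positions are considered duplicates (µm)
DUPLICATE_TOL_UM = 1e-9


class SpineMapFormatError(ValueError):
    """Raised when a spine-map file does not follow the expected schema."""


@dataclass
class SpineSegment:
    """Ordered spines with binary input marks on one dendritic path.

    Parameters
    ----------
    cell_id, segment_id
        Identifiers; the pair must be unique within a dataset.
    positions
        Nondecreasing path coordinates ``d_1..d_N`` in µm, origin at the
        segment start.  Ties are permitted (spines facing each other on
        the shaft) and are broken by input order.
    marks
        Booleans aligned to ``positions``; True = input-positive.
    branch_offset
        Path distance of the segment origin from the soma (µm), if known.
    soma_distances
        Optional explicit per-spine soma distances (µm).  When absent
        but ``branch_offset`` is set, ``branch_offset + position`` is
        used where soma distances are needed.
    """

    cell_id: str
    segment_id: str
    positions: np.ndarray
    marks: np.ndarray
    branch_offset: float | None = None
    soma_distances: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.marks = np.asarray(self.marks, dtype=bool)
        if self.positions.ndim != 1 or self.positions.size == 0:
            raise ValueError("a segment needs at least one spine")
        if self.positions.shape != self.marks.shape:
            raise ValueError("positions and marks must be aligned")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be nondecreasing (sort before constructing)")
        if self.soma_distances is not None:
            self.soma_distances = np.asarray(self.soma_distances, dtype=float)
            if self.soma_distances.shape != self.positions.shape:
                raise ValueError("soma_distances must be aligned to positions")

    # -- basic censuses ------------------------------------------------
    @property
    def key(self) -> tuple[str, str]:
        return (self.cell_id, self.segment_id)

    @property
    def n_spines(self) -> int:
        return int(self.positions.size)

    @property
    def n_positive(self) -> int:
        return int(self.marks.sum())

    @property
    def span(self) -> float:
        """Segment span ``d_N - d_1`` in µm."""
        return float(self.positions[-1] - self.positions[0])

    @property
    def positive_positions(self) -> np.ndarray:
        return self.positions[self.marks]

    def effective_soma_distances(self) -> np.ndarray | None:
        """Per-spine soma distances, explicit or derived from branch_offset."""
        if self.soma_distances is not None:
            return self.soma_distances
        if self.branch_offset is not None:
            return self.branch_offset + (self.positions - self.positions[0])
        return None

    def with_marks(self, marks: Sequence[bool]) -> "SpineSegment":
        """Copy of this segment with replaced marks."""
        return SpineSegment(
            self.cell_id,
            self.segment_id,
            self.positions.copy(),
            np.asarray(marks, dtype=bool),
            branch_offset=self.branch_offset,
            soma_distances=None if self.soma_distances is None else self.soma_distances.copy(),
        )


@dataclass
class SpineDataset:
    """Collection of :class:`SpineSegment` with unique (cell, segment) keys."""

    segments: list[SpineSegment] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [s.key for s in self.segments]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (cell_id, segment_id) pairs in dataset")

    def __iter__(self) -> Iterator[SpineSegment]:
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def get(self, cell_id: str, segment_id: str) -> SpineSegment:
        for seg in self.segments:
            if seg.key == (str(cell_id), str(segment_id)):
                return seg
        raise KeyError((cell_id, segment_id))

    @property
    def n_spines(self) -> int:
        return sum(s.n_spines for s in self.segments)

    @property
    def n_positive(self) -> int:
        return sum(s.n_positive for s in self.segments)

    def sorted_segments(self) -> list[SpineSegment]:
        return sorted(self.segments, key=lambda s: s.key)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_spine_maps(path: str | Path) -> SpineDataset:
    """Read a spine-map CSV into a :class:`SpineDataset`.

    Rows are grouped by ``(cell_id, segment_id)``; within a segment
    spines are sorted by position (stable, so ties keep file order).
    An unsorted file is accepted with a logged warning.  A missing
    required column raises :class:`SpineMapFormatError` naming it.
    An empty file yields an empty dataset.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return SpineDataset([], provenance=str(path))
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise SpineMapFormatError(f"spine map {path} is missing required column {col!r}")
    if table.empty:
        return SpineDataset([], provenance=str(path))

    segments = []
    for (cell, seg_id), grp in table.groupby(["cell_id", "segment_id"], sort=True):
        pos = grp["position_um"].to_numpy(dtype=float)
        if np.any(np.diff(pos) < 0):
            logger.warning(
                "segment (%s, %s) in %s has unsorted positions; auto-sorting", cell, seg_id, path
            )
            order = np.argsort(pos, kind="stable")
            grp = grp.iloc[order]
            pos = grp["position_um"].to_numpy(dtype=float)
        soma = None
        if "soma_distance_um" in grp.columns and grp["soma_distance_um"].notna().all():
            soma = grp["soma_distance_um"].to_numpy(dtype=float)
        segments.append(
            SpineSegment(
                str(cell),
                str(seg_id),
                pos,
                grp["positive"].to_numpy().astype(bool),
                soma_distances=soma,
            )
        )
    return SpineDataset(segments, provenance=str(path))


def write_spine_maps(ds: SpineDataset, path: str | Path) -> None:
    """Write a dataset back to the CSV schema (round-trips with load)."""
    rows = []
    for seg in ds.segments:
        soma = seg.effective_soma_distances() if seg.soma_distances is not None else None
        for i in range(seg.n_spines):
            row = {
                "cell_id": seg.cell_id,
                "segment_id": seg.segment_id,
                "position_um": seg.positions[i],
                "positive": int(seg.marks[i]),
            }
            if soma is not None:
                row["soma_distance_um"] = soma[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# validation & summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Finding:
    """One diagnostic from :func:`validate_segment` (report-only)."""

    code: str
    message: str
    index: int | None = None


def validate_segment(seg: SpineSegment) -> list[Finding]:
    """Report duplicate positions (within 1e-9 µm) and negative positions.

    Validation never raises; findings are informational so that e.g.
    spines facing each other on the shaft (genuine position ties) can be
    kept while still being visible to the analyst.
    """
    findings: list[Finding] = []
    pos = seg.positions
    dup = np.flatnonzero(np.diff(pos) <= DUPLICATE_TOL_UM)
    for i in dup:
        findings.append(
            Finding("duplicate_position", f"duplicate position {pos[i + 1]:g} µm", int(i + 1))
        )
    for i in np.flatnonzero(pos < 0):
        findings.append(
            Finding("negative_position", f"negative position {pos[i]:g} µm", int(i))
        )
    return findings


def validate_dataset(ds: SpineDataset) -> dict[tuple[str, str], list[Finding]]:
    """Per-segment findings for every segment with at least one finding."""
    out = {}
    for seg in ds.segments:
        findings = validate_segment(seg)
        if findings:
            out[seg.key] = findings
    return out


def summarize(ds: SpineDataset) -> dict:
    """Dataset totals: spine counts, positive fraction, length, density.

    ``density_per_um`` is total spines over the summed segment spans and
    is reported as None when the total span is zero.
    """
    if len(ds) == 0:
        raise ValueError("cannot summarize an empty dataset")
    n_spines = ds.n_spines
    n_positive = ds.n_positive
    total_length = float(sum(s.span for s in ds.segments))
    return {
        "n_spines": n_spines,
        "n_positive": n_positive,
        "fraction_positive": n_positive / n_spines,
        "total_length_um": total_length,
        "density_per_um": (n_spines / total_length) if total_length > 0 else None,
    }
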