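"""Digital immunohistochemistry quantification.

Slide scanners classify every pixel of a stained section into four intensity
classes: negative (0), weakly positive (1), positive (2) and strongly
positive (3).  This module turns the per-sample pixel counts of those classes
into the standard readouts used for marker scoring:

* the H-score, ``HSCORE = sum(i * Pi)`` with ``Pi`` the percentage of pixels
  in class ``i`` — a weighted staining score on ``[0, 300]``;
* the percentage of strongly positive pixels (used for macrophage markers
  such as CD68);
* a binary mutation call for mutation-specific antibodies (IDH1 R132H):
  any staining at all calls the sample mutant, none calls it wild-type.

Image segmentation and pixel classification are upstream of this module;
pre-binned counts are the interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "PixelBinCounts",
    "MarkerScore",
    "EmptyMeasurementError",
    "hscore",
    "percent_strong",
    "stain_presence_call",
    "score_table",
    "read_pixel_counts",
    "write_marker_scores",
]


class EmptyMeasurementError(ValueError):
    """Raised when a pixel-count vector contains no pixels at all."""


@dataclass(frozen=True)
class PixelBinCounts:
    """Pixel counts for the four staining-intensity classes of one measurement.

    Parameters
    ----------
    n0, n1, n2, n3
        Non-negative pixel counts for the negative, weak, positive and
        strong classes.  The total must be positive for any score.
    """

    n0: int
    n1: int
    n2: int
    n3: int

    def __post_init__(self) -> None:
        for name in ("n0", "n1", "n2", "n3"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"pixel count {name} must be >= 0, got {v}")

    @property
    def total(self) -> int:
        return self.n0 + self.n1 + self.n2 + self.n3

    def _require_pixels(self) -> None:
        if self.total <= 0:
            raise EmptyMeasurementError("no pixels in measurement")


@dataclass(frozen=True)
class MarkerScore:
    """A scored marker readout for one sample."""

    sample_id: str
    marker: str
    value: float
    kind: str  # "hscore" | "percent_strong"

    def __post_init__(self) -> None:
        if self.kind == "hscore" and not 0.0 <= self.value <= 300.0:
            raise ValueError(f"HSCORE {self.value} outside [0, 300]")
        if self.kind == "percent_strong" and not 0.0 <= self.value <= 100.0:
            raise ValueError(f"percent {self.value} outside [0, 100]")


def hscore(counts: PixelBinCounts) -> float:
    """Weighted staining score ``sum(i * Pi)`` on ``[0, 300]``.

    ``Pi`` is the percentage of pixels in intensity class ``i``; the score is
    invariant to uniform scaling of the counts.
    """
    counts._require_pixels()
    t = counts.total
    return 100.0 * (counts.n1 + 2 * counts.n2 + 3 * counts.n3) / t


def percent_strong(counts: PixelBinCounts) -> float:
    """Percentage of pixels in the strongest intensity class."""
    counts._require_pixels()
    return 100.0 * counts.n3 / counts.total


def stain_presence_call(counts: PixelBinCounts) -> str:
    """Binary call for mutation-specific staining.

    ``"wild_type"`` when no pixel shows staining of any intensity,
    ``"mutant"`` otherwise.
    """
    counts._require_pixels()
    return "wild_type" if counts.n1 + counts.n2 + counts.n3 == 0 else "mutant"


def score_table(rows: Iterable[tuple[str, str, PixelBinCounts]]) -> list[MarkerScore]:
    """Score a batch of measurements, emitting H-score and percent-strong per row."""
    out: list[MarkerScore] = []
    for sample_id, marker, counts in rows:
        out.append(MarkerScore(sample_id, marker, hscore(counts), "hscore"))
        out.append(MarkerScore(sample_id, marker, percent_strong(counts), "percent_strong"))
    return out


def read_pixel_counts(path) -> list[tuple[str, str, PixelBinCounts]]:
    """Read a pixel-count CSV with columns sample_id, marker, n0, n1, n2, n3."""
    df = pd.read_csv(path)
    required = {"sample_id", "marker", "n0", "n1", "n2", "n3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pixel-count CSV missing columns: {sorted(missing)}")
    return [
        (
            str(r.sample_id),
            str(r.marker),
            PixelBinCounts(int(r.n0), int(r.n1), int(r.n2), int(r.n3)),
        )
        for r in df.itertuples()
    ]


def write_marker_scores(scores: Iterable[MarkerScore], path) -> None:
    """Write scores as a CSV with columns sample_id, marker, kind, value."""
    pd.DataFrame(
        [
            {"sample_id": s.sample_id, "marker": s.marker, "kind": s.kind, "value": s.value}
            for s in scores
        ]
    ).to_csv(path, index=False)
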