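"""pH-dependent disorder prediction in charge-hydropathy space.

For a sequence and a pH, the predictor computes the mean pH-dependent
hydrophobicity ``<H_pH>`` (sliding-window averages assigned to the window
center, then averaged over all full windows) and the net charge per residue,
and combines them through the linear boundary

    Dis_pH = a * <H_pH> - |NCPR| - b        (default a=2.775, b=1.118)

Positive scores classify the sequence (or window) as folded, negative as
disordered; scores inside a +-margin band around the boundary (default 0.02)
are flagged as low-confidence. Scanning a pH grid profiles conditional
disorder: positions folded at every pH, disordered at every pH, or switching
class somewhere in the grid ("conditionally disordered").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .boundary import DEFAULT_BOUNDARY, BoundaryModel
from .charge import (
    FREE_TERMINI,
    PkaSet,
    TerminiSpec,
    WindowBoundsError,
    _clean_sequence,
    check_ph,
    default_pka_set,
    ncpr,
    window_ncpr,
)
from .scales import HydropathyScale, PhDependentScale, get_scale, normalize_scale

#: server-style default sliding window; internal benchmark analyses used 7
DEFAULT_WINDOW = 51

LABEL_FOLDED = "folded"
LABEL_DISORDERED = "disordered"
LABEL_MARGIN = "within-margin"


@dataclass(frozen=True)
class PhGrid:
    """An inclusive pH grid ``ph_min, ph_min + step, ... <= ph_max``."""

    ph_min: float
    ph_max: float
    step: float = 0.5

    def __post_init__(self) -> None:
        check_ph(self.ph_min)
        check_ph(self.ph_max)
        if self.ph_min > self.ph_max:
            raise ValueError("ph_min must not exceed ph_max")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @classmethod
    def single(cls, ph: float) -> "PhGrid":
        return cls(ph, ph, 1.0)

    def points(self) -> np.ndarray:
        n = int(np.floor((self.ph_max - self.ph_min) / self.step + 1e-9)) + 1
        pts = self.ph_min + self.step * np.arange(n)
        return np.round(pts, 10)


#: default scan grid when the caller gives none
DEFAULT_GRID = PhGrid(1.0, 13.0, 0.5)


def _resolve_scale(scale):
    if scale is None:
        return get_scale("ph_default")
    if isinstance(scale, str):
        return get_scale(scale)
    return scale


def _validate_window(window: int) -> int:
    if window < 1:
        raise ValueError("window must be a positive integer")
    if window % 2 == 0:
        warnings.warn(
            f"window must be odd (center assignment); using {window + 1}",
            stacklevel=3,
        )
        window += 1
    return window


def _per_residue_h(
    sequence: str, ph: float, scale, on_noncanonical: str = "error"
) -> np.ndarray:
    """Normalized hydropathy of every residue at ``ph`` as an array."""
    sequence, _ = _clean_sequence(sequence, on_noncanonical)
    if isinstance(scale, PhDependentScale):
        lut = {r: scale.value(r, ph) for r in set(sequence)}
    else:
        check_ph(ph)
        if not scale.normalized:
            scale = normalize_scale(scale)
        lut = {r: scale.values[r] for r in set(sequence)}
    return np.array([lut[r] for r in sequence], dtype=float)


def mean_hydrophobicity(
    sequence: str,
    ph: float,
    window: int = DEFAULT_WINDOW,
    scale: PhDependentScale | HydropathyScale | str | None = None,
    windowed: bool = True,
    on_noncanonical: str = "error",
) -> float:
    """Mean pH-dependent hydrophobicity ``<H_pH>`` of a sequence, in [0, 1].

    With ``windowed=True`` (default) the value is the mean over all
    full-window sliding averages; with ``windowed=False`` it is the plain
    per-residue mean. The two differ only by edge effects when the window is
    much shorter than the sequence. Sequences shorter than the window fall
    back to the plain mean with a warning.
    """
    scale = _resolve_scale(scale)
    window = _validate_window(window)
    h = _per_residue_h(sequence, ph, scale, on_noncanonical)
    if not windowed or window == len(h):
        return float(h.mean())
    if window > len(h):
        warnings.warn(
            f"sequence length {len(h)} < window {window}; "
            "falling back to the simple per-residue mean",
            stacklevel=2,
        )
        return float(h.mean())
    return float(sliding_window_view(h, window).mean(axis=1).mean())


def disph_score(
    mean_h: float, ncpr_abs: float, boundary: BoundaryModel = DEFAULT_BOUNDARY
) -> float:
    """The Dis_pH score ``a * mean_h - ncpr_abs - b``."""
    return float(boundary.a * mean_h - ncpr_abs - boundary.b)


def classify(disph: float, margin: float = 0.02) -> str:
    """Three-way classification of a Dis_pH score.

    Scores above ``+margin`` are folded, below ``-margin`` disordered, and
    anything in between is within-margin (low confidence; the sign is
    recoverable from the score itself). With ``margin=0`` every score gets a
    binary label, ties at exactly 0 counting as folded.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if disph > margin:
        return LABEL_FOLDED
    if disph < -margin:
        return LABEL_DISORDERED
    if margin == 0:
        return LABEL_FOLDED if disph >= 0 else LABEL_DISORDERED
    return LABEL_MARGIN


def binary_label(disph: float) -> str:
    """Two-way label used in confusion matrices and region calls."""
    return LABEL_FOLDED if disph >= 0 else LABEL_DISORDERED


@dataclass
class PhScanRow:
    """Global C-H coordinates and score of a sequence at one pH."""

    ph: float
    mean_h: float
    ncpr: float
    ncpr_abs: float
    disph: float
    label: str


def ch_coordinates(
    sequence: str,
    ph: float,
    window: int = DEFAULT_WINDOW,
    scale=None,
    pkas: PkaSet | None = None,
    termini: TerminiSpec = FREE_TERMINI,
    windowed: bool = True,
    on_noncanonical: str = "error",
    freeze_h_at: float | None = None,
) -> tuple[float, float]:
    """(mean_h, signed NCPR) of a sequence at ``ph``.

    ``freeze_h_at`` computes the hydrophobicity at a fixed pH (e.g. 7.0)
    while the charge still titrates -- the "pH-independent hydrophobicity"
    mode used as a negative control.
    """
    h_ph = ph if freeze_h_at is None else freeze_h_at
    mean_h = mean_hydrophobicity(
        sequence, h_ph, window, scale, windowed, on_noncanonical
    )
    q = ncpr(sequence, ph, pkas, termini, on_noncanonical=on_noncanonical)
    return mean_h, q


def scan_ph(
    sequence: str,
    grid: PhGrid = DEFAULT_GRID,
    window: int = DEFAULT_WINDOW,
    scale=None,
    pkas: PkaSet | None = None,
    termini: TerminiSpec = FREE_TERMINI,
    boundary: BoundaryModel = DEFAULT_BOUNDARY,
    windowed: bool = True,
    on_noncanonical: str = "error",
    freeze_h_at: float | None = None,
) -> list[PhScanRow]:
    """Global Dis_pH profile of a sequence over a pH grid."""
    rows = []
    for ph in grid.points():
        mean_h, q = ch_coordinates(
            sequence, float(ph), window, scale, pkas, termini,
            windowed, on_noncanonical, freeze_h_at,
        )
        score = disph_score(mean_h, abs(q), boundary)
        rows.append(
            PhScanRow(float(ph), mean_h, q, abs(q), score,
                      classify(score, boundary.margin))
        )
    return rows


@dataclass
class ResidueProfile:
    """Per-position Dis_pH scores at one pH (full windows only).

    ``start`` is the 1-based position of the first scored residue (the
    center of the first full window); positions without a complete window
    carry no score.
    """

    ph: float
    window: int
    start: int
    scores: np.ndarray

    @property
    def positions(self) -> np.ndarray:
        return self.start + np.arange(len(self.scores))


def residue_profile(
    sequence: str,
    ph: float,
    window: int = DEFAULT_WINDOW,
    scale=None,
    pkas: PkaSet | None = None,
    termini: TerminiSpec = FREE_TERMINI,
    boundary: BoundaryModel = DEFAULT_BOUNDARY,
    on_noncanonical: str = "error",
    freeze_h_at: float | None = None,
) -> ResidueProfile:
    """Sliding-window Dis_pH profile assigned to window centers.

    Each full window contributes one score computed from the window's mean
    hydrophobicity and the window's |NCPR| (terminal charges are included
    only in the first/last windows when the termini are free).
    """
    scale = _resolve_scale(scale)
    pkas = pkas or default_pka_set()
    window = _validate_window(window)
    sequence, _ = _clean_sequence(sequence, on_noncanonical)
    if window > len(sequence):
        raise WindowBoundsError(
            f"window {window} exceeds sequence length {len(sequence)}"
        )
    h_ph = ph if freeze_h_at is None else freeze_h_at
    h = _per_residue_h(sequence, h_ph, scale)
    win_h = sliding_window_view(h, window).mean(axis=1)
    n_win = len(win_h)
    win_q = np.empty(n_win)
    for i in range(n_win):
        win_q[i] = window_ncpr(sequence, ph, i, window, pkas, termini)
    scores = boundary.a * win_h - np.abs(win_q) - boundary.b
    return ResidueProfile(ph=ph, window=window,
                          start=(window - 1) // 2 + 1, scores=scores)


CLASS_ALWAYS_FOLDED = "always_folded"
CLASS_ALWAYS_DISORDERED = "always_disordered"
CLASS_CONDITIONAL = "conditionally_disordered"


@dataclass(frozen=True)
class Region:
    """A maximal run of equally classified positions, 1-based inclusive."""

    start: int
    end: int
    cls: str


def classify_regions(profiles: Sequence[ResidueProfile]) -> list[Region]:
    """Collapse per-pH residue profiles into pH-behaviour regions.

    A scored position is ``always_folded`` if its window score is on the
    folded side (>= 0) at every pH of the grid, ``always_disordered`` if on
    the disordered side at every pH, and ``conditionally_disordered``
    otherwise. Maximal runs are merged; the regions tile the scored
    positions exactly.
    """
    if not profiles:
        raise ValueError("at least one residue profile is required")
    starts = {p.start for p in profiles}
    lengths = {len(p.scores) for p in profiles}
    if len(starts) > 1 or len(lengths) > 1:
        raise ValueError("profiles must share window and sequence")
    start = profiles[0].start
    folded = np.stack([p.scores >= 0 for p in profiles])
    all_folded = folded.all(axis=0)
    none_folded = (~folded).all(axis=0)
    classes = np.where(
        all_folded, CLASS_ALWAYS_FOLDED,
        np.where(none_folded, CLASS_ALWAYS_DISORDERED, CLASS_CONDITIONAL),
    )
    regions: list[Region] = []
    run_start = 0
    for i in range(1, len(classes) + 1):
        if i == len(classes) or classes[i] != classes[run_start]:
            regions.append(
                Region(start + run_start, start + i - 1, str(classes[run_start]))
            )
            run_start = i
    return regions
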