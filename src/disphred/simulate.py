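"""Deterministic synthetic sequence and datapoint generators.

Three generators stand in for data the real analyses draw from databases
and the literature:

* :func:`gen_benchmark_sets` -- folded-like (hydrophobic, low-charge) vs
  disordered-like (E/K/S/P/Q-rich, high-charge) sequence sets whose
  charge-hydropathy clouds straddle the default boundary at pH 7, emulating
  curated folded/disordered benchmark databases (defaults: 150 folded,
  111 disordered).
* :func:`gen_ph_switchable` -- a single sequence engineered so its Dis_pH
  sign flips at a chosen pH: Glu-rich "acid folders" (fold as acidic side
  chains protonate at low pH) or Lys-rich "base folders" (fold as lysines
  deprotonate at high pH).
* :func:`gen_ch_points` -- labeled (mean_h, |NCPR|) points placed at known
  score offsets from a known boundary, for SVM parameter-recovery tests.

All generators are pure functions of their arguments and seed.
Composition profiles are data (``data/composition_profiles.json``), not code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .boundary import DEFAULT_BOUNDARY, BoundaryModel, LabeledPoint
from .charge import IONIZABLE_RESIDUES
from .io import SequenceRecord, write_fasta
from .predictor import DEFAULT_WINDOW, ch_coordinates, disph_score


class InfeasibleCompositionError(ValueError):
    """No composition in the search bracket yields the requested flip."""


def load_composition_profiles() -> dict:
    with resources.as_file(
        resources.files("disphred.data") / "composition_profiles.json"
    ) as p:
        return json.loads(Path(p).read_text())


@dataclass
class FixtureSpec:
    """Parameters of a synthetic benchmark-set draw (seed-deterministic)."""

    seed: int = 0
    n_folded: int = 150
    n_disordered: int = 111
    folded_length: tuple = (100, 300)
    disordered_length: tuple = (80, 250)
    out_dir: str | None = None


def _draw_sequence(rng: np.random.Generator, length: int, weights: dict) -> str:
    residues = sorted(weights)
    p = np.array([weights[r] for r in residues], dtype=float)
    p = p / p.sum()
    return "".join(rng.choice(residues, size=length, p=p))


def gen_benchmark_sets(
    spec: FixtureSpec | None = None, **kwargs
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Generate (folded-like, disordered-like) benchmark sequence sets.

    The two composition profiles are biased so that, at pH 7 under default
    settings, folded-like sequences score on the positive Dis_pH side and
    disordered-like sequences on the negative side. If ``spec.out_dir`` is
    set, ``folded.fasta`` and ``disordered.fasta`` are written there.
    """
    spec = spec or FixtureSpec(**kwargs)
    profiles = load_composition_profiles()
    rng = np.random.default_rng(spec.seed)
    folded, disordered = [], []
    for i in range(spec.n_folded):
        length = int(rng.integers(*spec.folded_length, endpoint=True))
        seq = _draw_sequence(rng, length, profiles["folded_like"]["weights"])
        folded.append(SequenceRecord(f"folded_{i:03d}", "synthetic folded-like",
                                     seq))
    for i in range(spec.n_disordered):
        length = int(rng.integers(*spec.disordered_length, endpoint=True))
        seq = _draw_sequence(rng, length, profiles["disordered_like"]["weights"])
        disordered.append(SequenceRecord(f"disordered_{i:03d}",
                                         "synthetic disordered-like", seq))
    if spec.out_dir:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(folded, out / "folded.fasta")
        write_fasta(disordered, out / "disordered.fasta")
    return folded, disordered


#: filler alphabet for switchable sequences: hydrophobic, non-titratable
_FILLER_RESIDUES = ("I", "L", "A")
_FILLER_WEIGHTS = (0.3, 0.3, 0.4)


def _switchable_seq(
    base: np.ndarray, perm: np.ndarray, titrating: str, fraction: float
) -> str:
    n_t = int(round(fraction * len(base)))
    arr = base.copy()
    arr[perm[:n_t]] = titrating
    return "".join(arr)


def _crossing_ph(
    seq: str, direction: str, window: int, boundary: BoundaryModel
) -> float:
    """pH at which Dis_pH changes sign; +-inf when it never does.

    Dis_pH is monotone in pH for single-titrating-residue compositions:
    decreasing for acid folders (E protonates at low pH), increasing for
    base folders (K deprotonates at high pH).
    """

    def dis(ph: float) -> float:
        mean_h, q = ch_coordinates(seq, ph, window)
        return disph_score(mean_h, abs(q), boundary)

    lo, hi = 0.0, 14.0
    d_lo, d_hi = dis(lo), dis(hi)
    if direction == "acid":  # folded (positive) at low pH
        if d_lo < 0:
            return -np.inf
        if d_hi > 0:
            return np.inf
    else:  # base folder: folded at high pH
        if d_hi < 0:
            return np.inf
        if d_lo > 0:
            return -np.inf
    return brentq(dis, lo, hi, xtol=1e-4)


def gen_ph_switchable(
    target_ph: float,
    direction: str = "acid",
    length: int = 80,
    seed: int = 0,
    window: int = DEFAULT_WINDOW,
    boundary: BoundaryModel = DEFAULT_BOUNDARY,
    titrating_residue: str | None = None,
    tol: float = 0.25,
) -> SequenceRecord:
    """Engineer a sequence whose Dis_pH sign flips near ``target_ph``.

    ``direction="acid"`` gives a Glu-rich sequence folded below the flip
    (acidic side chains protonate, raising hydrophobicity and shedding
    charge); ``direction="base"`` a Lys-rich sequence folded above it. The
    titrating-residue fraction is found by bisection against the package's
    own predictor; the flip pH of the returned sequence lies within
    ``tol`` (default 0.25) pH units of the target under the given settings.

    Raises :class:`InfeasibleCompositionError` when the target is out of
    range (must be in (2, 12)), the titrating residue cannot titrate, or no
    composition in the bracket achieves the flip.
    """
    if not (2.0 < target_ph < 12.0):
        raise InfeasibleCompositionError(
            f"target_ph must lie in (2, 12), got {target_ph}"
        )
    if direction not in ("acid", "base"):
        raise ValueError("direction must be 'acid' or 'base'")
    titrating = titrating_residue or ("E" if direction == "acid" else "K")
    if titrating not in IONIZABLE_RESIDUES:
        raise InfeasibleCompositionError(
            f"residue {titrating!r} has no titratable side chain; "
            "the Dis_pH score of such a sequence cannot depend on pH"
        )
    if window > length:
        raise ValueError(f"window {window} exceeds requested length {length}")
    rng = np.random.default_rng(seed)
    base = rng.choice(_FILLER_RESIDUES, size=length, p=_FILLER_WEIGHTS)
    perm = rng.permutation(length)

    def crossing(fraction: float) -> float:
        seq = _switchable_seq(base, perm, titrating, fraction)
        return _crossing_ph(seq, direction, window, boundary)

    # crossing pH is monotone in the titrating fraction: decreasing for
    # acid folders, increasing for base folders.
    f_lo, f_hi = 0.05, 0.95
    c_lo, c_hi = crossing(f_lo), crossing(f_hi)
    sign = -1.0 if direction == "acid" else 1.0
    g_lo, g_hi = sign * (c_lo - target_ph), sign * (c_hi - target_ph)
    if not (g_lo < 0 < g_hi or g_lo > 0 > g_hi):
        raise InfeasibleCompositionError(
            f"no {titrating}-fraction in [{f_lo}, {f_hi}] flips at pH "
            f"{target_ph} (crossings at fractions {f_lo}/{f_hi}: "
            f"{c_lo:.2f}/{c_hi:.2f})"
        )
    best_f, best_err = None, np.inf
    for _ in range(40):
        f_mid = 0.5 * (f_lo + f_hi)
        c_mid = crossing(f_mid)
        err = abs(c_mid - target_ph) if np.isfinite(c_mid) else np.inf
        if err < best_err:
            best_f, best_err = f_mid, err
        if err <= tol / 2:
            break
        g_mid = sign * (c_mid - target_ph) if np.isfinite(c_mid) else (
            sign * np.copysign(np.inf, c_mid - target_ph)
        )
        if (g_mid < 0) == (g_lo < 0):
            f_lo = f_mid
        else:
            f_hi = f_mid
    if best_err > tol:
        raise InfeasibleCompositionError(
            f"bisection could not place the flip within {tol} pH units of "
            f"{target_ph} (best: {best_err:.2f} away)"
        )
    seq = _switchable_seq(base, perm, titrating, best_f)
    return SequenceRecord(
        f"switch_{direction}_{target_ph:g}",
        f"synthetic {direction}-folder, flip target pH {target_ph:g}",
        seq,
    )


def gen_ch_points(
    a: float = DEFAULT_BOUNDARY.a,
    b: float = DEFAULT_BOUNDARY.b,
    margin: float = 0.05,
    n: int = 500,
    seed: int = 0,
    mislabel_fraction: float = 0.0,
    ph: float = 7.0,
) -> list[LabeledPoint]:
    """Labeled C-H points at known score offsets from a known boundary.

    Points alternate sides of the ``score = a*H - |NCPR| - b`` line, with
    score offsets drawn uniformly from (margin, margin + 0.35) so no point
    falls inside the +-margin band. ``mislabel_fraction`` flips that many
    labels to exercise the soft margin.
    """
    if n < 4:
        raise ValueError("need at least 4 points")
    if margin <= 0:
        raise ValueError("margin must be positive")
    rng = np.random.default_rng(seed)
    points = []
    for i in range(n):
        side = 1.0 if i % 2 == 0 else -1.0
        offset = side * rng.uniform(margin, margin + 0.35)
        h_lo = max(0.30, (b + offset) / a)  # keep ncpr_abs >= 0
        h = rng.uniform(h_lo, 0.80)
        ncpr_abs = a * h - b - offset
        label = "ordered" if side > 0 else "disordered"
        points.append(LabeledPoint(f"pt_{i:04d}", h, ncpr_abs, ph, label))
    if mislabel_fraction:
        k = int(round(mislabel_fraction * n))
        for idx in rng.choice(n, size=k, replace=False):
            p = points[idx]
            p.label = "ordered" if p.label == "disordered" else "disordered"
    return points
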