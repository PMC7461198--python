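"""Hydropathy scales: static tables, a two-state pH-dependent scale, and
residue-wise inter-scale correlation.

All scoring is done on min-max normalized values in [0, 1], with 1 assigned
to the most hydrophobic residue. Scales whose raw convention is "larger =
more hydrophilic" (e.g. Guy's transfer free energies) are flipped during
normalization; the orientation is recorded in the scale file header.

The pH-dependent scale models each ionizable residue as a two-state mixture:
the hydropathy at a given pH is the Henderson-Hasselbalch population-weighted
average of the neutral-species and charged-species values,

    H(r, pH) = f_neutral(r, pH) * H_neutral(r) + (1 - f_neutral(r, pH)) * H_charged(r),

normalized by global bounds taken over all residues and the full supported
pH range so that values at different pHs remain mutually comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

from .charge import (
    CANONICAL_RESIDUES,
    PkaSet,
    check_ph,
    default_pka_set,
    neutral_fraction,
)

#: names resolvable by :func:`get_scale`
PACKAGED_SCALES = (
    "kyte_doolittle",
    "guy",
    "idp_hydropathy",
    "ph_default",
    "ph_pro_corrected",
)


class DegenerateScaleError(ValueError):
    """All residues share one hydropathy value; normalization is undefined."""


class InsufficientDataError(ValueError):
    """Fewer than 3 residues left for a residue-wise regression."""


class UnknownResidueError(KeyError):
    """Residue is not one of the 20 canonical one-letter codes."""


def _check_coverage(values: Mapping[str, float], name: str) -> None:
    if set(values) != CANONICAL_RESIDUES:
        missing = CANONICAL_RESIDUES - set(values)
        extra = set(values) - CANONICAL_RESIDUES
        raise ValueError(
            f"scale {name!r} must cover exactly the 20 canonical residues "
            f"(missing {sorted(missing)}, extra {sorted(extra)})"
        )


@dataclass(frozen=True)
class HydropathyScale:
    """A named static per-residue hydropathy table.

    Parameters
    ----------
    name : str
        Identifier of the scale.
    values : mapping
        One-letter residue code -> raw hydropathy (dimensionless).
    normalized : bool
        True once the values have been min-max normalized to [0, 1].
    higher_is_hydrophobic : bool
        Orientation of the *raw* values. After normalization this is
        always True.
    """

    name: str
    values: Mapping[str, float]
    normalized: bool = False
    higher_is_hydrophobic: bool = True

    def __post_init__(self) -> None:
        _check_coverage(self.values, self.name)

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise UnknownResidueError(residue) from None


def normalize_scale(scale: HydropathyScale) -> HydropathyScale:
    """Min-max normalize a scale so the most hydrophobic residue maps to 1.

    Idempotent: a normalized scale is returned unchanged (as a copy).
    """
    vals = np.array([scale.values[r] for r in sorted(scale.values)], dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise DegenerateScaleError(f"scale {scale.name!r} is constant")
    if scale.higher_is_hydrophobic:
        norm = {r: (v - lo) / (hi - lo) for r, v in scale.values.items()}
    else:
        norm = {r: (hi - v) / (hi - lo) for r, v in scale.values.items()}
    return HydropathyScale(scale.name, norm, normalized=True)


@dataclass(frozen=True)
class PhDependentScale:
    """Two-state pH-dependent hydropathy scale.

    ``neutral_values`` holds the hydropathy of the uncharged species,
    ``charged_values`` that of the ionized species (equal to the neutral
    value for non-ionizable residues). Normalization bounds are global:
    the min/max over both species tables, which bound every mixture value
    attainable anywhere in the supported pH range.
    """

    name: str
    neutral_values: Mapping[str, float]
    charged_values: Mapping[str, float]
    pka_set: PkaSet = field(default_factory=default_pka_set)

    def __post_init__(self) -> None:
        _check_coverage(self.neutral_values, self.name)
        _check_coverage(self.charged_values, self.name)

    @property
    def normalization_bounds(self) -> tuple[float, float]:
        all_vals = [*self.neutral_values.values(), *self.charged_values.values()]
        return min(all_vals), max(all_vals)

    def raw_value(self, residue: str, ph: float) -> float:
        """Population-weighted raw hydropathy of ``residue`` at ``ph``."""
        check_ph(ph)
        if residue not in CANONICAL_RESIDUES:
            raise UnknownResidueError(residue)
        f = neutral_fraction(residue, ph, self.pka_set)
        return f * self.neutral_values[residue] + (1.0 - f) * self.charged_values[residue]

    def value(self, residue: str, ph: float) -> float:
        """Normalized hydropathy in [0, 1] of ``residue`` at ``ph``."""
        lo, hi = self.normalization_bounds
        if hi == lo:
            raise DegenerateScaleError(f"scale {self.name!r} is constant")
        return (self.raw_value(residue, ph) - lo) / (hi - lo)

    def at_ph(self, ph: float) -> HydropathyScale:
        """Freeze the scale at one pH as a normalized static scale."""
        vals = {r: self.value(r, ph) for r in sorted(CANONICAL_RESIDUES)}
        return HydropathyScale(f"{self.name}@pH{ph:g}", vals, normalized=True)

    def pro_corrected(self) -> "PhDependentScale":
        """Variant with Pro forced to the scale minimum (normalized 0)."""
        lo, _ = self.normalization_bounds
        neutral = dict(self.neutral_values)
        charged = dict(self.charged_values)
        neutral["P"] = charged["P"] = lo
        return PhDependentScale(
            f"{self.name}_pro_corrected", neutral, charged, self.pka_set
        )


def residue_hydropathy(
    residue: str, ph: float, scale: PhDependentScale
) -> float:
    """Normalized pH-dependent hydropathy of a single residue.

    Continuous and monotone in pH for each residue; constant for
    non-ionizable residues.
    """
    return scale.value(residue, ph)


@dataclass(frozen=True)
class ScaleCorrelation:
    """Residue-wise OLS correlation between two (normalized) scales."""

    scale_a: str
    scale_b: str
    excluded_residues: frozenset
    r_squared: float


def scale_correlation(
    a: HydropathyScale | PhDependentScale,
    b: HydropathyScale | PhDependentScale,
    exclude: frozenset[str] | set[str] = frozenset(),
    ph: float = 7.0,
) -> ScaleCorrelation:
    """Coefficient of determination of the residue-wise linear regression.

    pH-dependent scales are evaluated at ``ph`` (default 7.0) first; both
    scales are normalized before the fit. R^2 is symmetric in the two scales
    and invariant under affine transformation of either.
    """
    exclude = frozenset(exclude)
    if isinstance(a, PhDependentScale):
        a = a.at_ph(ph)
    if isinstance(b, PhDependentScale):
        b = b.at_ph(ph)
    if not a.normalized:
        a = normalize_scale(a)
    if not b.normalized:
        b = normalize_scale(b)
    residues = sorted(CANONICAL_RESIDUES - exclude)
    if len(residues) < 3:
        raise InsufficientDataError(
            f"only {len(residues)} residues left after excluding {sorted(exclude)}"
        )
    x = np.array([a.values[r] for r in residues])
    y = np.array([b.values[r] for r in residues])
    fit = stats.linregress(x, y)
    return ScaleCorrelation(a.name, b.name, exclude, fit.rvalue**2)


def load_scale(path: str | Path, name: str | None = None):
    """Load a scale from a TSV file.

    Expected columns: ``residue``, ``neutral`` and optionally ``charged``.
    A ``charged`` column makes the scale pH-dependent. Header comment lines
    may carry ``# higher_is_hydrophobic: true|false`` (default true).
    """
    path = Path(path)
    higher_is_hydrophobic = True
    neutral: dict[str, float] = {}
    charged: dict[str, float] = {}
    has_charged = False
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "higher_is_hydrophobic:" in line:
                higher_is_hydrophobic = line.split(":", 1)[1].strip().lower() == "true"
            continue
        fields = line.split("\t")
        if fields[0] == "residue":
            has_charged = len(fields) >= 3 and fields[2] == "charged"
            continue
        neutral[fields[0]] = float(fields[1])
        if has_charged and len(fields) >= 3:
            charged[fields[0]] = float(fields[2])
    name = name or path.stem
    if has_charged:
        return PhDependentScale(name, neutral, charged)
    return HydropathyScale(
        name, neutral, higher_is_hydrophobic=higher_is_hydrophobic
    )


_SCALE_FILES = {
    "kyte_doolittle": "kyte_doolittle.tsv",
    "guy": "guy.tsv",
    # synthetic stand-in; the original constants are not redistributable here
    "idp_hydropathy": "idp_hydropathy_synthetic.tsv",
    "ph_default": "ph_default.tsv",
}

_SCALE_CACHE: dict[str, HydropathyScale | PhDependentScale] = {}


def get_scale(name: str):
    """Return a packaged scale by name (see :data:`PACKAGED_SCALES`)."""
    if name in _SCALE_CACHE:
        return _SCALE_CACHE[name]
    if name == "ph_pro_corrected":
        scale = get_scale("ph_default").pro_corrected()
    elif name in _SCALE_FILES:
        with resources.as_file(
            resources.files("disphred.data") / _SCALE_FILES[name]
        ) as p:
            scale = load_scale(p, name=name)
    else:
        raise KeyError(
            f"unknown scale {name!r}; packaged scales: {PACKAGED_SCALES}"
        )
    _SCALE_CACHE[name] = scale
    return scale
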