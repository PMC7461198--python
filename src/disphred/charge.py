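"""Per-residue partial charges and net charge per residue (NCPR) versus pH.

Every ionizable group is treated as an independent two-state acid/base whose
fractional charge at a given pH follows the Henderson-Hasselbalch equation:

* bases (K, R, H, free N-terminus):  q = +1 / (1 + 10**(pH - pKa))
* acids (D, E, C, Y, free C-terminus): q = -1 / (1 + 10**(pKa - pH))

The NCPR of a sequence (or window) is the sum of partial charges divided by
its length. Capped termini (N-acetyl / C-amide) contribute no charge.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

PH_MIN = 0.0
PH_MAX = 14.0

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
ACIDIC_RESIDUES = frozenset("DECY")
BASIC_RESIDUES = frozenset("KRH")
IONIZABLE_RESIDUES = ACIDIC_RESIDUES | BASIC_RESIDUES
#: restriction used by the "basic_acidic" titration mode (no Cys/Tyr)
BASIC_ACIDIC_ONLY = frozenset("DEHKR")


class PhRangeError(ValueError):
    """pH outside the supported [0, 14] interval."""


class NonCanonicalResidueError(ValueError):
    """Sequence contains a residue outside the 20-letter canonical alphabet."""


class WindowBoundsError(IndexError):
    """Requested window does not lie fully inside the sequence."""


def check_ph(ph: float) -> float:
    if not (PH_MIN <= ph <= PH_MAX):
        raise PhRangeError(f"pH {ph!r} outside supported range [{PH_MIN}, {PH_MAX}]")
    return float(ph)


@dataclass(frozen=True)
class PkaSet:
    """pKa values for the seven ionizable side chains and the free termini."""

    name: str
    side_chain: Mapping[str, float]
    n_terminus: float
    c_terminus: float

    def __post_init__(self) -> None:
        missing = IONIZABLE_RESIDUES - set(self.side_chain)
        if missing:
            raise ValueError(f"pKa set {self.name!r} missing groups: {sorted(missing)}")
        for group, pka in [*self.side_chain.items(),
                           ("NTERM", self.n_terminus), ("CTERM", self.c_terminus)]:
            if not (PH_MIN < pka < PH_MAX):
                raise ValueError(f"pKa for {group} out of (0, 14): {pka}")

    def pka(self, group: str) -> float:
        if group == "NTERM":
            return self.n_terminus
        if group == "CTERM":
            return self.c_terminus
        return self.side_chain[group]


def load_pka_set(path: str | Path, name: str | None = None) -> PkaSet:
    """Read a pKa set from a TSV file with columns ``group`` and ``pka``."""
    path = Path(path)
    values: dict[str, float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("group"):
            continue
        group, pka = line.split("\t")
        values[group] = float(pka)
    side = {g: v for g, v in values.items() if g not in ("NTERM", "CTERM")}
    return PkaSet(name or path.stem, side, values["NTERM"], values["CTERM"])


_DEFAULT_PKA: PkaSet | None = None


def default_pka_set() -> PkaSet:
    """The packaged default pKa set (standard textbook values)."""
    global _DEFAULT_PKA
    if _DEFAULT_PKA is None:
        with resources.as_file(
            resources.files("disphred.data") / "pka_default.tsv"
        ) as p:
            _DEFAULT_PKA = load_pka_set(p, name="default")
    return _DEFAULT_PKA


@dataclass(frozen=True)
class TerminiSpec:
    """Chemical state of the chain ends; capped ends carry no charge."""

    n_term: str = "free"  # "free" | "acetylated"
    c_term: str = "free"  # "free" | "amidated"

    def __post_init__(self) -> None:
        if self.n_term not in ("free", "acetylated"):
            raise ValueError(f"n_term must be free|acetylated, got {self.n_term!r}")
        if self.c_term not in ("free", "amidated"):
            raise ValueError(f"c_term must be free|amidated, got {self.c_term!r}")


FREE_TERMINI = TerminiSpec("free", "free")
CAPPED_TERMINI = TerminiSpec("acetylated", "amidated")


def neutral_fraction(residue: str, ph: float, pkas: PkaSet | None = None) -> float:
    """Fraction of the *uncharged* species of an ionizable residue at ``ph``.

    Returns 1.0 for non-ionizable residues.
    """
    pkas = pkas or default_pka_set()
    check_ph(ph)
    if residue not in IONIZABLE_RESIDUES:
        return 1.0
    pka = pkas.side_chain[residue]
    if residue in ACIDIC_RESIDUES:  # neutral when protonated (low pH)
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    return 1.0 / (1.0 + 10.0 ** (pka - ph))  # bases neutral at high pH


def partial_charge(group: str, ph: float, pkas: PkaSet | None = None) -> float:
    """Signed Henderson-Hasselbalch partial charge of a residue or terminus.

    ``group`` is a one-letter residue code or ``"NTERM"`` / ``"CTERM"``.
    Non-ionizable residues return 0.0 (not an error).
    """
    pkas = pkas or default_pka_set()
    check_ph(ph)
    if group == "NTERM":
        return 1.0 / (1.0 + 10.0 ** (ph - pkas.n_terminus))
    if group == "CTERM":
        return -1.0 / (1.0 + 10.0 ** (pkas.c_terminus - ph))
    if group in BASIC_RESIDUES:
        return 1.0 / (1.0 + 10.0 ** (ph - pkas.side_chain[group]))
    if group in ACIDIC_RESIDUES:
        return -1.0 / (1.0 + 10.0 ** (pkas.side_chain[group] - ph))
    return 0.0


def _clean_sequence(sequence: str, on_noncanonical: str) -> tuple[str, int]:
    """Validate/filter a sequence; returns (kept residues, skipped count)."""
    if not sequence:
        raise ValueError("empty sequence")
    bad = [r for r in sequence if r not in CANONICAL_RESIDUES]
    if bad:
        if on_noncanonical == "error":
            raise NonCanonicalResidueError(
                f"non-canonical residue(s) {sorted(set(bad))} in sequence"
            )
        if on_noncanonical != "skip":
            raise ValueError(f"on_noncanonical must be error|skip, got {on_noncanonical!r}")
        sequence = "".join(r for r in sequence if r in CANONICAL_RESIDUES)
        if not sequence:
            raise ValueError("no canonical residues left after skipping")
    return sequence, len(bad)


def _titratable(titratable: str) -> frozenset[str]:
    if titratable == "full":
        return IONIZABLE_RESIDUES
    if titratable == "basic_acidic":
        return BASIC_ACIDIC_ONLY
    raise ValueError(f"titratable must be full|basic_acidic, got {titratable!r}")


@dataclass
class ChargeProfile:
    """Per-position decomposition of a sequence's charge at one pH."""

    sequence: str
    ph: float
    per_position: np.ndarray  # signed side-chain partial charges, e units
    n_term_charge: float
    c_term_charge: float

    @property
    def total_charge(self) -> float:
        return float(self.per_position.sum() + self.n_term_charge + self.c_term_charge)

    @property
    def ncpr(self) -> float:
        return self.total_charge / len(self.per_position)


def charge_profile(
    sequence: str,
    ph: float,
    pkas: PkaSet | None = None,
    termini: TerminiSpec = FREE_TERMINI,
    titratable: str = "full",
    on_noncanonical: str = "error",
) -> ChargeProfile:
    pkas = pkas or default_pka_set()
    check_ph(ph)
    sequence, _ = _clean_sequence(sequence, on_noncanonical)
    groups = _titratable(titratable)
    per_res = {r: (partial_charge(r, ph, pkas) if r in groups else 0.0)
               for r in set(sequence)}
    charges = np.array([per_res[r] for r in sequence], dtype=float)
    n_q = partial_charge("NTERM", ph, pkas) if termini.n_term == "free" else 0.0
    c_q = partial_charge("CTERM", ph, pkas) if termini.c_term == "free" else 0.0
    return ChargeProfile(sequence, ph, charges, n_q, c_q)


def ncpr(
    sequence: str,
    ph: float,
    pkas: PkaSet | None = None,
    termini: TerminiSpec = FREE_TERMINI,
    titratable: str = "full",
    on_noncanonical: str = "error",
) -> float:
    """Net charge per residue: (sum of partial charges + termini) / length."""
    pkas = pkas or default_pka_set()
    check_ph(ph)
    sequence, _ = _clean_sequence(sequence, on_noncanonical)
    groups = _titratable(titratable)
    counts = Counter(sequence)
    total = math.fsum(
        n * partial_charge(r, ph, pkas) for r, n in counts.items() if r in groups
    )
    if termini.n_term == "free":
        total += partial_charge("NTERM", ph, pkas)
    if termini.c_term == "free":
        total += partial_charge("CTERM", ph, pkas)
    return total / len(sequence)


def window_ncpr(
    sequence: str,
    ph: float,
    window_start: int,
    window_len: int,
    pkas: PkaSet | None = None,
    termini: TerminiSpec = FREE_TERMINI,
    titratable: str = "full",
    on_noncanonical: str = "error",
) -> float:
    """NCPR of the window ``sequence[window_start : window_start + window_len]``.

    ``window_start`` is 0-based. Terminal charges are included only when the
    window touches a free terminus.
    """
    if window_len <= 0:
        raise WindowBoundsError("window_len must be positive")
    if window_start < 0 or window_start + window_len > len(sequence):
        raise WindowBoundsError(
            f"window [{window_start}, {window_start + window_len}) outside "
            f"sequence of length {len(sequence)}"
        )
    sub = sequence[window_start : window_start + window_len]
    touches_n = window_start == 0
    touches_c = window_start + window_len == len(sequence)
    sub_termini = TerminiSpec(
        termini.n_term if touches_n else "acetylated",
        termini.c_term if touches_c else "amidated",
    )
    return ncpr(sub, ph, pkas, sub_termini, titratable, on_noncanonical)
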