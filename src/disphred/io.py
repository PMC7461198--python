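"""Sequence and table I/O: FASTA records with terminal-cap notation,
JSON/TSV prediction reports, labeled C-H datasets, run configuration and
(optional, network-gated) UniProt retrieval."""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .boundary import BoundaryModel, LabeledPoint
from .charge import (
    FREE_TERMINI,
    PkaSet,
    TerminiSpec,
    default_pka_set,
    load_pka_set,
)
from .predictor import (
    DEFAULT_GRID,
    DEFAULT_WINDOW,
    PhGrid,
    classify_regions,
    mean_hydrophobicity,
    residue_profile,
    scan_ph,
)
from .charge import ncpr as _ncpr

logger = logging.getLogger("disphred")

_ACET_RE = re.compile(r"^ac-", re.IGNORECASE)
_AMID_RE = re.compile(r"-nh2$", re.IGNORECASE)


class FastaParseError(ValueError):
    pass


@dataclass
class SequenceRecord:
    """A parsed input sequence with its terminal chemistry."""

    id: str
    description: str
    residues: str
    termini: TerminiSpec = FREE_TERMINI
    flags: list = field(default_factory=list)


def parse_sequence(
    text: str, id: str = "seq", description: str = ""
) -> SequenceRecord:
    """Parse a raw one-letter sequence string.

    Handles ``Ac-`` / ``-NH2`` cap affixes, whitespace, a trailing ``*``
    stop, and lowercase letters (uppercased with a flag). Cap affixes found
    in the *id* are honored as well, to support FASTA records named after
    capped model peptides.
    """
    flags: list[str] = []
    seq = "".join(text.split())
    n_term, c_term = "free", "free"
    if _ACET_RE.search(seq):
        seq = _ACET_RE.sub("", seq)
        n_term = "acetylated"
    if _AMID_RE.search(seq):
        seq = _AMID_RE.sub("", seq)
        c_term = "amidated"
    if _ACET_RE.search(id):
        n_term = "acetylated"
    if _AMID_RE.search(id):
        c_term = "amidated"
    seq = seq.rstrip("*")
    if seq != seq.upper():
        flags.append("lowercase-uppercased")
        seq = seq.upper()
    if not seq:
        raise FastaParseError(f"record {id!r}: empty sequence after cap stripping")
    return SequenceRecord(id, description, seq, TerminiSpec(n_term, c_term), flags)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into :class:`SequenceRecord` objects."""
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: expected a '>' header, got {line[:30]!r}"
                )
            break
    else:
        raise FastaParseError(f"{path}: empty FASTA file")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(parse_sequence(str(rec.seq), id=rec.id,
                                      description=rec.description))
    if not records:
        raise FastaParseError(f"{path}: no records parsed")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} {rec.description}".rstrip() + "\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


@dataclass
class RunConfig:
    """Everything that determines a prediction run (reproducibility unit)."""

    grid: PhGrid = DEFAULT_GRID
    window: int = DEFAULT_WINDOW
    scale: str = "ph_default"
    pka: str | None = None  # None -> packaged default; else a TSV path
    termini: str = "auto"  # "auto" | "free" | "capped"
    margin: float = 0.02
    boundary_a: float = 2.775
    boundary_b: float = 1.118
    windowed_mean: bool = True
    freeze_h_at: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = {"ph_min": self.grid.ph_min, "ph_max": self.grid.ph_max,
                     "step": self.grid.step}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        g = d.pop("grid")
        return cls(grid=PhGrid(**g), **d)

    def boundary_model(self) -> BoundaryModel:
        return BoundaryModel(self.boundary_a, self.boundary_b, self.margin)

    def pka_set(self) -> PkaSet:
        return default_pka_set() if self.pka is None else load_pka_set(self.pka)


def _effective_termini(record: SequenceRecord, policy: str) -> TerminiSpec:
    if policy == "auto":
        return record.termini
    if policy == "free":
        return TerminiSpec("free", "free")
    if policy == "capped":
        return TerminiSpec("acetylated", "amidated")
    raise ValueError(f"termini policy must be auto|free|capped, got {policy!r}")


def run_prediction(record: SequenceRecord, config: RunConfig | None = None) -> dict:
    """Full prediction report for one sequence: pH scan, per-residue
    profiles at every grid pH, and region classification."""
    config = config or RunConfig()
    boundary = config.boundary_model()
    pkas = config.pka_set()
    termini = _effective_termini(record, config.termini)
    logger.info(
        "run: id=%s len=%d grid=[%g,%g,%g] window=%d scale=%s pka=%s",
        record.id, len(record.residues), config.grid.ph_min, config.grid.ph_max,
        config.grid.step, config.window, config.scale, config.pka or "default",
    )
    rows = scan_ph(
        record.residues, config.grid, config.window, config.scale, pkas,
        termini, boundary, windowed=config.windowed_mean,
        freeze_h_at=config.freeze_h_at,
    )
    profiles = {}
    region_profiles = []
    profile_start = None
    if config.window <= len(record.residues):
        for ph in config.grid.points():
            prof = residue_profile(
                record.residues, float(ph), config.window, config.scale,
                pkas, termini, boundary, freeze_h_at=config.freeze_h_at,
            )
            profiles[f"{ph:g}"] = [float(s) for s in prof.scores]
            region_profiles.append(prof)
        profile_start = region_profiles[0].start
        regions = [
            {"start": r.start, "end": r.end, "class": r.cls}
            for r in classify_regions(region_profiles)
        ]
    else:
        regions = []
    return {
        "sequence_id": record.id,
        "sequence": record.residues,
        "window": config.window,
        "scale": config.scale,
        "termini": {"n_term": termini.n_term, "c_term": termini.c_term},
        "boundary": {"a": boundary.a, "b": boundary.b, "margin": boundary.margin},
        "scan": [
            {"ph": r.ph, "mean_h": r.mean_h, "ncpr": r.ncpr,
             "ncpr_abs": r.ncpr_abs, "disph": r.disph, "label": r.label}
            for r in rows
        ],
        "regions": regions,
        "profile_start": profile_start,
        "profiles": profiles,
        "config": config.to_dict(),
    }


def write_report(report: dict, out_dir: str | Path, formats=("json", "tsv")) -> list[Path]:
    """Serialize a report; JSON keeps full double precision (lossless
    round-trip), TSV rounds to 6 significant digits."""
    if not report.get("scan"):
        raise ValueError("refusing to write a report with an empty scan")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = re.sub(r"[^\w.-]", "_", report["sequence_id"])
    written = []
    if "json" in formats:
        p = out_dir / f"{stem}.json"
        with open(p, "w") as fh:
            json.dump(report, fh, indent=1)
        written.append(p)
    if "tsv" in formats:
        p = out_dir / f"{stem}_scan.tsv"
        with open(p, "w") as fh:
            fh.write("ph\tmean_h\tncpr\tdisph\tlabel\n")
            for row in report["scan"]:
                fh.write(
                    f"{row['ph']:.6g}\t{row['mean_h']:.6g}\t{row['ncpr']:.6g}"
                    f"\t{row['disph']:.6g}\t{row['label']}\n"
                )
        written.append(p)
        if report["profiles"]:
            p = out_dir / f"{stem}_residues.tsv"
            phs = list(report["profiles"])
            start = report["profile_start"]
            cols = "\t".join(f"disph_pH{ph}" for ph in phs)
            with open(p, "w") as fh:
                fh.write(f"position\tresidue\t{cols}\n")
                n = len(report["profiles"][phs[0]])
                for i in range(n):
                    pos = start + i
                    vals = "\t".join(
                        f"{report['profiles'][ph][i]:.6g}" for ph in phs
                    )
                    fh.write(f"{pos}\t{report['sequence'][pos - 1]}\t{vals}\n")
            written.append(p)
    return written


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def read_labeled_points(
    path: str | Path,
    window: int = 7,
    scale=None,
    pkas: PkaSet | None = None,
    termini: TerminiSpec = FREE_TERMINI,
    freeze_h_at: float | None = None,
) -> list[LabeledPoint]:
    """Load a labeled C-H dataset from CSV.

    Schema: ``id,sequence,ph,label[,h_override,ncpr_override]``. Rows with
    overrides use them verbatim (sequence may then be empty); otherwise
    mean_h and |NCPR| are computed from the sequence at the row's pH.
    ``freeze_h_at`` computes hydrophobicity at a fixed pH instead (the
    pH-independent control mode).
    """
    df = pd.read_csv(path)
    required = {"id", "sequence", "ph", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"labeled CSV needs columns {sorted(required)}")
    points = []
    for _, row in df.iterrows():
        h_over = row.get("h_override")
        n_over = row.get("ncpr_override")
        if pd.notna(h_over) and pd.notna(n_over):
            mean_h, ncpr_abs = float(h_over), float(n_over)
            seq = None if pd.isna(row["sequence"]) else str(row["sequence"])
        else:
            rec = parse_sequence(str(row["sequence"]), id=str(row["id"]))
            h_ph = row["ph"] if freeze_h_at is None else freeze_h_at
            mean_h = mean_hydrophobicity(rec.residues, float(h_ph), window, scale)
            q = _ncpr(rec.residues, float(row["ph"]), pkas, rec.termini)
            ncpr_abs = abs(q)
            seq = rec.residues
        points.append(
            LabeledPoint(str(row["id"]), mean_h, ncpr_abs, float(row["ph"]),
                         str(row["label"]), sequence=seq)
        )
    return points


_UNIPROT_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)
UNIPROT_URL = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"


def fetch_uniprot(
    accession: str,
    cache_dir: str | Path | None = None,
    timeout: float = 15.0,
) -> SequenceRecord:
    """Fetch a sequence by UniProt accession (network; cached to disk).

    The accession format is validated before any network call; cached
    entries are served offline.
    """
    if not _UNIPROT_RE.match(accession):
        raise ValueError(f"invalid UniProt accession: {accession!r}")
    cache_dir = Path(cache_dir) if cache_dir else Path.home() / ".cache" / "disphred"
    cache_dir.mkdir(parents=True, exist_ok=True)
    cached = cache_dir / f"{accession}.fasta"
    if not cached.exists():
        from urllib.request import urlopen

        with urlopen(UNIPROT_URL.format(acc=accession), timeout=timeout) as resp:
            data = resp.read().decode()
        if not data.startswith(">"):
            raise IOError(f"UniProt returned no FASTA for {accession}")
        cached.write_text(data)
    return read_fasta(cached)[0]
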