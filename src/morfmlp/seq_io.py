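"""Readers and writers for every external format the tool touches.

Formats: multi-record FASTA, PSI-BLAST ASCII PSSM (``-out_ascii_pssm``
dialect), amino-acid scale flat files, region-annotation TSV, prediction
TSV, and the JSON model archive.

Coordinates are 1-based inclusive in every file and 0-based half-open
internally; conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, FormatError

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter codes.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Row order of PSI-BLAST ASCII PSSM columns.
PSSM_ROW_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Substitutions for ambiguity codes; any residue not listed here and not in
#: ALPHABET collapses to 'X', which scores as the scale mean / zero profile.
AMBIGUITY_MAP = {"B": "D", "Z": "E", "U": "C", "O": "K"}

MODEL_FORMAT_VERSION = "morfmlp-model-v1"

_DEFAULT_SCALES_RESOURCE = "default_scales.txt"


def canonicalize_residues(residues: str, context: str = "") -> str:
    """Upper-case and substitute ambiguity codes (B→D, Z→E, U→C, O→K).

    Unknown letters become 'X'; the sequence length is always preserved so
    per-residue labels stay aligned. Substitutions are logged as warnings.
    """
    out = []
    for i, raw in enumerate(residues.upper()):
        if raw in ALPHABET:
            out.append(raw)
            continue
        sub = AMBIGUITY_MAP.get(raw, "X")
        logger.warning(
            "non-standard residue %r at position %d%s replaced by %r",
            raw, i + 1, f" in {context}" if context else "", sub,
        )
        out.append(sub)
    return "".join(out)


@dataclass
class SequenceRecord:
    """One protein chain: identifier, residues, optional per-residue labels."""

    id: str
    residues: str
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set(ALPHABET) - {"X"}
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains uncanonicalized letters {sorted(bad)}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (len(self.residues),):
                raise FormatError(
                    f"sequence {self.id!r}: {self.labels.size} labels for "
                    f"{len(self.residues)} residues"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ScaleTable:
    """A named amino-acid scale: one real value per standard residue.

    Lookup of a letter outside the 20-letter alphabet (e.g. 'X') returns the
    mean of the 20 values, so ambiguous residues contribute neutrally.
    """

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(ALPHABET) - set(self.values)
        if missing:
            raise FormatError(
                f"scale {self.name!r} is missing letters {sorted(missing)}"
            )
        extra = set(self.values) - set(ALPHABET)
        if extra:
            raise FormatError(f"scale {self.name!r} has unknown letters {sorted(extra)}")
        if not all(np.isfinite(list(self.values.values()))):
            raise FormatError(f"scale {self.name!r} contains non-finite values")
        self._mean = float(np.mean(list(self.values.values())))

    def value(self, letter: str) -> float:
        return self.values.get(letter, self._mean)

    def vector(self, residues: str) -> np.ndarray:
        return np.array([self.value(a) for a in residues], dtype=float)


@dataclass
class PSSMProfile:
    """20×L position-specific scores aligned to one SequenceRecord.

    Rows follow PSI-BLAST column order (:data:`PSSM_ROW_ORDER`).
    """

    sequence_id: str
    matrix: np.ndarray
    query: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 20:
            raise FormatError(
                f"PSSM for {self.sequence_id!r}: expected 20×L matrix, "
                f"got shape {self.matrix.shape}"
            )
        if self.matrix.shape[1] != len(self.query):
            raise AlignmentError(
                f"PSSM for {self.sequence_id!r}: {self.matrix.shape[1]} columns "
                f"vs query length {len(self.query)}"
            )
        if not np.isfinite(self.matrix).all():
            raise FormatError(f"PSSM for {self.sequence_id!r} has non-finite entries")


@dataclass
class RegionAnnotation:
    """One annotated interval, 1-based inclusive coordinates."""

    sequence_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"region {self.sequence_id}:{self.start}-{self.end}: "
                "require 1 <= start <= end"
            )


@dataclass
class PredictionTrack:
    """Per-residue fused scores in [0,1] with optional binary calls."""

    sequence_id: str
    scores: np.ndarray
    calls: np.ndarray | None = None
    residues: str | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise FormatError("scores must be one-dimensional")
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise FormatError(
                f"track {self.sequence_id!r}: scores outside [0, 1]"
            )
        if self.calls is not None:
            self.calls = np.asarray(self.calls, dtype=np.int8)
            if self.calls.shape != self.scores.shape:
                raise FormatError("calls/scores length mismatch")
        if self.residues is not None and len(self.residues) != self.scores.size:
            raise FormatError("residues/scores length mismatch")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file, canonicalizing residues.

    The record id is the first whitespace-delimited token of the header.
    Raises FormatError on an empty file or duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = canonicalize_residues(str(rec.seq), context=rec.id)
        records.append(SequenceRecord(id=rec.id, residues=residues))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM


def read_pssm(path: str | Path, record: SequenceRecord) -> PSSMProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file for *record*.

    Only the first 20 numeric columns per row (the log-odds block) are used.
    The residue column must match ``record.residues`` after canonicalization.
    """
    rows: list[list[float]] = []
    letters: list[str] = []
    order = PSSM_ROW_ORDER
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            # column header: 40 single-letter amino-acid tokens
            if len(tokens) >= 20 and all(len(t) == 1 and t.isalpha() for t in tokens[:20]):
                order = "".join(tokens[:20])
                continue
            if not tokens[0].lstrip("-").isdigit() or len(tokens) < 2:
                continue
            pos = int(tokens[0])
            if pos != len(rows) + 1:
                continue  # footer statistics lines can start with numbers
            if len(tokens) < 22:
                raise FormatError(
                    f"{path}: truncated PSSM row at position {pos}"
                )
            try:
                scores = [float(t) for t in tokens[2:22]]
            except ValueError as exc:
                raise FormatError(f"{path}: unparsable PSSM row at position {pos}") from exc
            letters.append(tokens[1])
            rows.append(scores)
    if not rows:
        raise FormatError(f"{path}: no PSSM rows found (truncated or wrong format?)")
    if len(rows) != len(record):
        raise AlignmentError(
            f"{path}: PSSM has {len(rows)} positions but sequence "
            f"{record.id!r} has {len(record)}; first mismatch at position "
            f"{min(len(rows), len(record)) + 1}"
        )
    query = canonicalize_residues("".join(letters), context=str(path))
    for i, (a, b) in enumerate(zip(query, record.residues)):
        if a != b:
            raise AlignmentError(
                f"{path}: residue mismatch with sequence {record.id!r} "
                f"at position {i + 1} ({a!r} vs {b!r})"
            )
    if len(order) != 20 or set(order) != set(PSSM_ROW_ORDER):
        raise FormatError(f"{path}: unrecognized PSSM column header {order!r}")
    mat = np.asarray(rows, dtype=float).T  # 20 x L, rows in file column order
    if order != PSSM_ROW_ORDER:
        perm = [order.index(a) for a in PSSM_ROW_ORDER]
        mat = mat[perm]
    return PSSMProfile(sequence_id=record.id, matrix=mat, query=record.residues)


def write_pssm(profile: PSSMProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect that read_pssm accepts.

    Percentage columns are written as zeros; information-content and weight
    columns as 0.00 (neither is consumed by this package).
    """
    mat = np.asarray(profile.matrix)
    header = " ".join(PSSM_ROW_ORDER)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write(f"            {header}  {header}\n")
        for j in range(mat.shape[1]):
            lod = " ".join(f"{int(round(v)):3d}" if float(v).is_integer() else f"{v:6.2f}"
                           for v in mat[:, j])
            pct = " ".join("0" for _ in range(20))
            fh.write(f"{j + 1:5d} {profile.query[j]}  {lod}  {pct}  0.00 0.00\n")
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1337     0.3175\n")


# ---------------------------------------------------------------------------
# Scale tables


def read_scales(path: str | Path) -> list[ScaleTable]:
    """Read a flat scale file: blocks of ``>name`` then 20 ``letter value`` lines."""
    scales: list[ScaleTable] = []
    name: str | None = None
    values: dict[str, float] = {}

    def flush() -> None:
        nonlocal name, values
        if name is not None:
            scales.append(ScaleTable(name=name, values=values))
        name, values = None, {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                continue
            parts = line.split()
            if name is None or len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: unexpected line {line!r}")
            letter = parts[0].upper()
            if letter in values:
                raise FormatError(
                    f"{path}:{lineno}: duplicate letter {letter!r} in scale {name!r}"
                )
            try:
                values[letter] = float(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad value {parts[1]!r}") from exc
    flush()
    if not scales:
        raise FormatError(f"{path}: no scales found")
    return scales


def default_scales() -> list[ScaleTable]:
    """The 15 scales shipped with the package (13 physicochemical + 2 propensity)."""
    ref = resources.files("morfmlp").joinpath("data", _DEFAULT_SCALES_RESOURCE)
    with resources.as_file(ref) as p:
        return read_scales(p)


# ---------------------------------------------------------------------------
# Regions and labels


def read_regions(path: str | Path) -> list[RegionAnnotation]:
    """Read a TSV of (sequence_id, start, end), 1-based inclusive."""
    regions: list[RegionAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "sequence_id":  # optional header row
                continue
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            regions.append(RegionAnnotation(parts[0], start, end))
    return regions


def write_regions(regions: Iterable[RegionAnnotation], path: str | Path,
                  header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for h in header_lines:
            fh.write(f"# {h}\n")
        fh.write("sequence_id\tstart\tend\n")
        for r in regions:
            fh.write(f"{r.sequence_id}\t{r.start}\t{r.end}\n")


def labels_from_regions(regions: Iterable[RegionAnnotation], length: int,
                        sequence_id: str = "") -> np.ndarray:
    """Binary label vector: 1 inside the union of the regions, 0 elsewhere."""
    labels = np.zeros(length, dtype=np.int8)
    for r in regions:
        if r.end > length:
            raise AlignmentError(
                f"region {r.sequence_id}:{r.start}-{r.end} exceeds sequence "
                f"length {length}" + (f" of {sequence_id!r}" if sequence_id else "")
            )
        labels[r.start - 1 : r.end] = 1
    return labels


def apply_regions(records: Sequence[SequenceRecord],
                  regions: Iterable[RegionAnnotation]) -> None:
    """Attach union-of-interval labels to each record, in place.

    Raises AlignmentError for a region whose sequence_id matches no record.
    """
    by_id = {rec.id: rec for rec in records}
    grouped: dict[str, list[RegionAnnotation]] = {}
    for r in regions:
        if r.sequence_id not in by_id:
            raise AlignmentError(f"region references unknown sequence {r.sequence_id!r}")
        grouped.setdefault(r.sequence_id, []).append(r)
    for rec in records:
        rec.labels = labels_from_regions(grouped.get(rec.id, []), len(rec), rec.id)


def regions_from_labels(labels: np.ndarray, sequence_id: str) -> list[RegionAnnotation]:
    """Maximal runs of 1s as 1-based inclusive intervals (inverse of the union)."""
    labels = np.asarray(labels).astype(bool)
    padded = np.concatenate([[False], labels, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1)
    return [RegionAnnotation(sequence_id, int(s), int(e)) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# Predictions


def write_predictions(tracks: Iterable[PredictionTrack], path: str | Path,
                      header_lines: Sequence[str] = ()) -> None:
    """TSV: sequence_id, position (1-based), residue, score (6 dp), call."""
    with open(path, "w") as fh:
        for h in header_lines:
            fh.write(f"# {h}\n")
        fh.write("sequence_id\tposition\tresidue\tscore\tcall\n")
        for t in tracks:
            residues = t.residues or "?" * t.scores.size
            for j, score in enumerate(t.scores):
                call = "" if t.calls is None else str(int(t.calls[j]))
                fh.write(f"{t.sequence_id}\t{j + 1}\t{residues[j]}\t{score:.6f}\t{call}\n")


def read_predictions(path: str | Path) -> list[PredictionTrack]:
    tracks: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("sequence_id"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            sid, pos, residue, score, call = parts
            if sid not in tracks:
                tracks[sid] = {"scores": [], "residues": [], "calls": []}
                order.append(sid)
            entry = tracks[sid]
            if int(pos) != len(entry["scores"]) + 1:
                raise FormatError(f"{path}:{lineno}: positions out of order for {sid!r}")
            entry["scores"].append(float(score))
            entry["residues"].append(residue)
            entry["calls"].append(None if call == "" else int(call))
    out = []
    for sid in order:
        e = tracks[sid]
        calls = None if any(c is None for c in e["calls"]) else np.array(e["calls"])
        out.append(PredictionTrack(sid, np.array(e["scores"]), calls,
                                   "".join(e["residues"])))
    return out


# ---------------------------------------------------------------------------
# Model archive


def save_model(model, path: str | Path) -> None:
    """Serialize an EnsembleModel to a deterministic JSON archive.

    Floats round-trip exactly (json uses repr); keys are sorted so
    save→load→save is byte-identical.
    """
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": model.config.to_dict(),
        "standardizer": {
            "mean": model.mean.tolist(),
            "std": model.std.tolist(),
        },
        "members": [m.to_dict() for m in model.members],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def load_model(path: str | Path):
    from .model import EnsembleModel, MLPConfig, MLPParams

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not a valid model archive ({exc})") from exc
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise FormatError(
            f"{path}: model format version {version!r}, "
            f"expected {MODEL_FORMAT_VERSION!r}"
        )
    config = MLPConfig.from_dict(payload["config"])
    members = [MLPParams.from_dict(d) for d in payload["members"]]
    return EnsembleModel(
        members=members,
        mean=np.asarray(payload["standardizer"]["mean"], dtype=float),
        std=np.asarray(payload["standardizer"]["std"], dtype=float),
        config=config,
    )
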