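"""Synthetic datasets with a planted, tunable MoRF signal.

Sequences are drawn over the 20-letter alphabet with 0-2 non-overlapping
planted intervals per sequence. Inside an interval the residue composition
is tilted toward letters with high values on a designated scale (strength
delta), and the synthetic PSSM gets a +shift on a designated row subset, so
the signal is visible to both feature branches while per-branch noise keeps
them non-redundant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, MorfMlpError
from .seq_io import (
    ALPHABET,
    PSSM_ROW_ORDER,
    PSSMProfile,
    RegionAnnotation,
    SequenceRecord,
    default_scales,
    write_fasta,
    write_pssm,
    write_regions,
)

#: PSSM rows receiving the planted shift inside MoRF intervals.
SHIFTED_PSSM_ROWS = tuple(range(5))

#: PSI-BLAST-like log-odds bounds for fixture PSSM entries.
PSSM_VALUE_RANGE = (-10, 12)


@dataclass(frozen=True)
class FixtureConfig:
    n_sequences: int = 50
    length_range: tuple[int, int] = (200, 400)
    morf_length_range: tuple[int, int] = (10, 70)
    max_regions_per_sequence: int = 2
    delta: float = 1.5
    pssm_noise: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ConfigurationError("n_sequences must be >= 1")
        if self.morf_length_range[0] > self.length_range[0]:
            raise ConfigurationError(
                "minimum MoRF length exceeds minimum sequence length"
            )
        if self.delta < 0:
            raise ConfigurationError("effect size delta must be >= 0")


@dataclass
class FixtureDataset:
    records: list[SequenceRecord]
    regions: list[RegionAnnotation]
    profiles: dict[str, PSSMProfile]


def _tilt_weights(delta: float) -> np.ndarray:
    """Per-letter sampling weights: exp(delta * standardized hydropathy)."""
    scale = default_scales()[0]
    z = scale.vector(ALPHABET)
    z = (z - z.mean()) / z.std()
    w = np.exp(delta * z)
    return w / w.sum()


def _place_regions(length: int, config: FixtureConfig,
                   rng: np.random.Generator) -> list[tuple[int, int]]:
    """0-based half-open non-overlapping intervals."""
    k = int(rng.integers(0, config.max_regions_per_sequence + 1))
    placed: list[tuple[int, int]] = []
    for _ in range(k):
        lo, hi = config.morf_length_range
        rlen = int(rng.integers(lo, min(hi, length) + 1))
        for _attempt in range(200):
            start = int(rng.integers(0, length - rlen + 1))
            if all(start >= e or start + rlen <= s for s, e in placed):
                placed.append((start, start + rlen))
                break
        else:
            raise MorfMlpError(
                f"could not place a {rlen}-residue interval in a "
                f"{length}-residue sequence"
            )
    return sorted(placed)


def make_dataset(config: FixtureConfig,
                 out_dir: str | Path | None = None) -> FixtureDataset:
    """Generate sequences, region annotations, and matched PSSM profiles.

    Fully reproducible from ``config.seed``; when *out_dir* is given, writes
    ``sequences.fasta``, ``regions.tsv``, and one ``pssm/<id>.pssm`` per
    sequence (byte-identical across runs with the same config).
    """
    rng = np.random.default_rng(config.seed)
    letters = np.array(list(ALPHABET))
    background = np.full(20, 1.0 / 20)
    morf_weights = _tilt_weights(config.delta)
    shift = int(round(2 * config.delta))
    lo_val, hi_val = PSSM_VALUE_RANGE

    records: list[SequenceRecord] = []
    regions: list[RegionAnnotation] = []
    profiles: dict[str, PSSMProfile] = {}
    for idx in range(config.n_sequences):
        sid = f"syn{idx + 1:04d}"
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        intervals = _place_regions(length, config, rng)
        residues = letters[rng.choice(20, size=length, p=background)]
        labels = np.zeros(length, dtype=np.int8)
        for s, e in intervals:
            residues[s:e] = letters[rng.choice(20, size=e - s, p=morf_weights)]
            labels[s:e] = 1
            regions.append(RegionAnnotation(sid, s + 1, e))
        seq = "".join(residues)
        record = SequenceRecord(id=sid, residues=seq, labels=labels)
        records.append(record)

        matrix = rng.normal(0.0, config.pssm_noise, size=(20, length))
        for s, e in intervals:
            matrix[list(SHIFTED_PSSM_ROWS), s:e] += shift
        matrix = np.clip(np.rint(matrix), lo_val, hi_val)
        profiles[sid] = PSSMProfile(sequence_id=sid, matrix=matrix, query=seq)

    dataset = FixtureDataset(records=records, regions=regions, profiles=profiles)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out_dir / "sequences.fasta")
        write_regions(regions, out_dir / "regions.tsv",
                      header_lines=[f"morf-mlp fixtures seed={config.seed} "
                                    f"delta={config.delta:g}"])
        pssm_dir = out_dir / "pssm"
        pssm_dir.mkdir(exist_ok=True)
        for sid, profile in profiles.items():
            write_pssm(profile, pssm_dir / f"{sid}.pssm")
    return dataset


# ---------------------------------------------------------------------------
# Worked examples with independently derived expected values.
#
# Every expected value below is computed by deliberately naive code (explicit
# loops, scalar arithmetic, exhaustive enumeration) that shares nothing with
# the library implementations it is used to check.


def _brute_force_pooling(v: list[float], length: int, n: int) -> list[float]:
    n0 = n // 2
    n_windows = length + 2 * n0 - n + 1
    out = []
    for j in range(1, length + 1):
        covering = [v[i - 1] for i in range(1, n_windows + 1)
                    if i <= j + n0 <= i + n - 1]
        out.append(sum(covering) / len(covering))
    return out


def _brute_force_forward(weights: dict, x: list[float]) -> float:
    def dot(w_row, a):
        return sum(wi * ai for wi, ai in zip(w_row, a))

    a = x
    for layer in ("1", "2"):
        z = [dot(row, a) + b for row, b in zip(weights[f"w{layer}"], weights[f"b{layer}"])]
        a = [max(0.0, zi) for zi in z]
    z3 = dot(weights["w3"][0], a) + weights["b3"][0]
    return 1.0 / (1.0 + math.exp(-z3))


def _brute_force_roc(scores: list[float], labels: list[int]) -> dict:
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg)
    auc = wins / (len(pos) * len(neg))
    points = []
    for t in sorted(set(scores), reverse=True):
        tp = sum(1 for s, y in zip(scores, labels) if y == 1 and s >= t)
        fp = sum(1 for s, y in zip(scores, labels) if y == 0 and s >= t)
        points.append((tp / len(pos), fp / len(neg)))
    fpr_at = {}
    for target in (0.2, 0.3, 0.4):
        feasible = [fpr for tpr, fpr in points if tpr >= target]
        fpr_at[target] = min(feasible) if feasible else 1.0
    return {"auc": auc, "points": points, "fpr_at_tpr": fpr_at}


def make_worked_example() -> dict:
    """Small fixed instances with brute-force-derived expected outputs."""
    pooling_v = [0.5, 1.5, 2.5, 3.5]  # L=3, N=2 has L+2*1-2+1 = 4 windows
    forward_weights = {
        "w1": [[1.0, -1.0], [0.5, 0.5]], "b1": [0.0, -0.25],
        "w2": [[1.0, 2.0], [-1.0, 1.0]], "b2": [0.1, 0.0],
        "w3": [[2.0, -3.0]], "b3": [-0.5],
    }
    forward_x = [0.8, -0.2]
    roc_scores = [0.9, 0.8, 0.7, 0.6, 0.4, 0.3]
    roc_labels = [1, 0, 1, 1, 0, 0]
    return {
        "pooling": {
            "length": 3,
            "n": 2,
            "v": pooling_v,
            "expected": _brute_force_pooling(pooling_v, 3, 2),
        },
        "forward": {
            "weights": forward_weights,
            "x": forward_x,
            "expected": _brute_force_forward(forward_weights, forward_x),
        },
        "roc": {
            "scores": roc_scores,
            "labels": roc_labels,
            "expected": _brute_force_roc(roc_scores, roc_labels),
        },
    }
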