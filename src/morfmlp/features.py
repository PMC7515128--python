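"""Per-residue feature extraction via multi-window pooling.

A sequence of length L is zero-padded by floor(N/2) on both ends for each
window size N. Every length-N window gets one value per property (scale
average, topological entropy, or PSSM row average), and each residue is then
assigned the mean of the values of the windows that cover it.

The three printed branches of the residue-pooling formula contain an index
inconsistency in the last branch; the single clamped-range form implemented
in :func:`pool_to_residues` reproduces the first two branches exactly and is
taken as the intended meaning of the third.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import AlignmentError, ConfigurationError
from .seq_io import PSSMProfile, PSSM_ROW_ORDER, ScaleTable, SequenceRecord

logger = logging.getLogger(__name__)

#: Sentinel letter used for pad positions in entropy windows. It is treated
#: as a 21st symbol distinct from every amino acid, so terminal windows are
#: not spuriously low-complexity.
PAD_LETTER = "-"

ENTROPY_PROPERTY_NAME = "entropy"

DEFAULT_WINDOW_SIZES = (10, 45, 90)


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window configuration shared by both feature branches."""

    sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES
    entropy_alphabet_size: int = 20
    pssm_sigmoid: bool = False  # optional 1/(1+e^-x) squashing of raw log-odds

    def __post_init__(self) -> None:
        object.__setattr__(self, "sizes", tuple(int(n) for n in self.sizes))
        if any(n < 2 for n in self.sizes):
            raise ConfigurationError("window sizes must be >= 2")
        if self.entropy_alphabet_size < 2:
            raise ConfigurationError("entropy alphabet size must be >= 2")

    @staticmethod
    def pad_width(n: int) -> int:
        return n // 2

    def padded_length(self, length: int, n: int) -> int:
        return length + 2 * self.pad_width(n)


@dataclass
class FeatureMatrix:
    """L×D per-residue features plus provenance."""

    sequence_id: str
    values: np.ndarray
    column_names: list[str]
    branch: str  # "properties" or "profile"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_names):
            raise ConfigurationError("feature matrix / column name mismatch")
        if not np.isfinite(self.values).all():
            raise ConfigurationError(
                f"non-finite features for sequence {self.sequence_id!r}"
            )


def pad(values: Sequence | np.ndarray, n: int, fill=0.0):
    """Append floor(n/2) copies of *fill* to both ends of a 1-D sequence.

    Works on numeric arrays (fill 0.0), residue strings (fill PAD_LETTER),
    or any list.
    """
    n0 = n // 2
    if isinstance(values, str):
        return str(fill) * n0 + values + str(fill) * n0
    arr = np.asarray(values)
    pad_block = np.full(n0, fill, dtype=arr.dtype)
    return np.concatenate([pad_block, arr, pad_block])


def window_means(padded: np.ndarray, n: int) -> np.ndarray:
    """Mean of every length-n window of a padded value array (L0-n+1 values)."""
    padded = np.asarray(padded, dtype=float)
    cumsum = np.concatenate([[0.0], np.cumsum(padded)])
    return (cumsum[n:] - cumsum[:-n]) / n


def window_scale_values(record: SequenceRecord, scale: ScaleTable, n: int) -> np.ndarray:
    """Per-window average scale value, pads contributing zero."""
    return window_means(pad(scale.vector(record.residues), n, 0.0), n)


def entropy_subword_params(n_window: int, alphabet_size: int) -> tuple[int, int]:
    """(n, m) for topological entropy on windows of length *n_window*.

    n is the largest integer >= 1 with A^n + n - 1 <= n_window, clamped to 1
    when no such integer exists (short windows); m = min(A^n + n - 1, n_window).
    """
    a = alphabet_size
    n = 1
    while a ** (n + 1) + n <= n_window:
        n += 1
    if a ** n + n - 1 > n_window:
        n = 1  # undefined regime; fall back to distinct-letter counting
    m = min(a ** n + n - 1, n_window)
    return n, m


def topological_entropy(word: str, alphabet_size: int = 20) -> float:
    """Normalized distinct-subword count of one window.

    Uses the first m = min(A^n+n-1, |word|) letters and counts distinct
    length-n subwords; the pad letter counts as its own symbol.
    """
    n, m = entropy_subword_params(len(word), alphabet_size)
    prefix = word[:m]
    distinct = {prefix[i : i + n] for i in range(len(prefix) - n + 1)}
    return math.log(len(distinct), alphabet_size) / n


def window_entropy_values(record: SequenceRecord, n: int,
                          alphabet_size: int = 20) -> np.ndarray:
    """Topological entropy of every length-n window over the padded letters."""
    padded = pad(record.residues, n, PAD_LETTER)
    n_windows = len(padded) - n + 1
    n_sub, m = entropy_subword_params(n, alphabet_size)
    log_a = math.log(alphabet_size)
    out = np.empty(n_windows)
    for i in range(n_windows):
        prefix = padded[i : i + m]
        distinct = {prefix[k : k + n_sub] for k in range(m - n_sub + 1)}
        out[i] = math.log(len(distinct)) / (log_a * n_sub)
    return out


def pool_to_residues(per_window: np.ndarray, length: int, n: int) -> np.ndarray:
    """Residue j's feature = mean of window values over windows covering it.

    Window i (1-based) covers padded positions i..i+n-1; residue j sits at
    padded position j+n0. The covering windows are i in
    [max(1, j+n0-n+1), min(j+n0, L0-n+1)], which collapses the printed
    three-branch formula into one clamped range (interior residues average
    exactly n windows).
    """
    per_window = np.asarray(per_window, dtype=float)
    n0 = n // 2
    n_windows = length + 2 * n0 - n + 1
    if per_window.size != n_windows:
        raise ConfigurationError(
            f"expected {n_windows} window values for L={length}, N={n}; "
            f"got {per_window.size}"
        )
    j = np.arange(1, length + 1)
    lo = np.maximum(1, j + n0 - n + 1)
    hi = np.minimum(j + n0, n_windows)
    cumsum = np.concatenate([[0.0], np.cumsum(per_window)])
    return (cumsum[hi] - cumsum[lo - 1]) / (hi - lo + 1)


def _warn_short(record: SequenceRecord, n: int) -> None:
    if n >= len(record):
        logger.warning(
            "window size %d >= sequence length %d for %r; clamped pooling "
            "still applies", n, len(record), record.id,
        )


def property_features(record: SequenceRecord, scales: Sequence[ScaleTable],
                      config: WindowConfig | None = None) -> FeatureMatrix:
    """Sequence-property branch: entropy + 15 scale averages per window size.

    Columns are ordered by window size block, entropy first then scales in
    the order given; D = 16 × len(sizes) (48 at defaults).
    """
    config = config or WindowConfig()
    if len(scales) != 15:
        raise ConfigurationError(
            f"property branch requires exactly 15 scales (plus the entropy "
            f"functional); got {len(scales)}"
        )
    columns: list[np.ndarray] = []
    names: list[str] = []
    length = len(record)
    for n in config.sizes:
        _warn_short(record, n)
        v = window_entropy_values(record, n, config.entropy_alphabet_size)
        columns.append(pool_to_residues(v, length, n))
        names.append(f"{ENTROPY_PROPERTY_NAME}@{n}")
        for scale in scales:
            v = window_scale_values(record, scale, n)
            columns.append(pool_to_residues(v, length, n))
            names.append(f"{scale.name}@{n}")
    return FeatureMatrix(record.id, np.column_stack(columns), names, "properties")


def profile_features(record: SequenceRecord, pssm: PSSMProfile,
                     config: WindowConfig | None = None) -> FeatureMatrix:
    """Evolutionary-information branch: 20 PSSM row averages per window size.

    Each of the 20 profile rows is zero-padded, averaged per window, and
    pooled to residues; D = 20 × len(sizes) (60 at defaults).
    """
    config = config or WindowConfig()
    if pssm.matrix.shape[1] != len(record) or pssm.query != record.residues:
        raise AlignmentError(
            f"PSSM for {pssm.sequence_id!r} is not aligned to sequence {record.id!r}"
        )
    matrix = pssm.matrix
    if config.pssm_sigmoid:
        matrix = 1.0 / (1.0 + np.exp(-matrix))
    columns: list[np.ndarray] = []
    names: list[str] = []
    length = len(record)
    for n in config.sizes:
        _warn_short(record, n)
        for row, letter in zip(matrix, PSSM_ROW_ORDER):
            v = window_means(pad(row, n, 0.0), n)
            columns.append(pool_to_residues(v, length, n))
            names.append(f"pssm_{letter}@{n}")
    return FeatureMatrix(record.id, np.column_stack(columns), names, "profile")
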