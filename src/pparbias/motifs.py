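"""PWM log-odds scanning of upstream sequence windows for receptor DNA motifs.

The target motif is the DR1 (direct repeat 1) element bound by the
PPARgamma:RXRalpha heterodimer.  A window of length equal to the matrix width
is scored as the sum over positions of the log-odds of the observed base
against a background model (uniform 0.25 per base by default, natural-log
odds); ``N`` bases contribute the background value 0.  Scans cover both
strands, coordinates are 0-based half-open, and per-sequence "presence" is
having at least one hit at or above the score threshold within the scanned
window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MotifMatrix",
    "MotifHit",
    "score_window",
    "scan_upstream",
    "compare_presence",
    "score_distribution",
    "random_match_probability",
    "DR1_CONSENSUS",
]

ALPHABET = "ACGT"
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}

#: PPARgamma:RXRalpha DR1 consensus (JASPAR-style)
DR1_CONSENSUS = "GGGTCAAAGGTCA"


@dataclass(frozen=True)
class MotifMatrix:
    """Position log-odds matrix over A, C, G, T columns (natural-log units)."""

    log_odds: np.ndarray  # (width, 4)
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        lo = np.asarray(self.log_odds, dtype=float)
        if lo.ndim != 2 or lo.shape[1] != 4 or lo.shape[0] < 1:
            raise ValueError("log_odds must have shape (width >= 1, 4)")
        object.__setattr__(self, "log_odds", lo)

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.log_odds, axis=1))

    @classmethod
    def from_probabilities(cls, probs, background=(0.25, 0.25, 0.25, 0.25),
                           pseudo: float = 0.0) -> "MotifMatrix":
        p = np.asarray(probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probabilities must have shape (width, 4)")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        p = p + pseudo
        p = p / p.sum(axis=1, keepdims=True)
        bg = np.asarray(background, dtype=float)
        if np.any(p == 0):
            raise ValueError("zero probability with zero pseudo-count; pass pseudo > 0")
        return cls(np.log(p / bg), tuple(bg))

    @classmethod
    def from_counts(cls, counts, background=(0.25, 0.25, 0.25, 0.25),
                    pseudo: float = 0.5) -> "MotifMatrix":
        c = np.asarray(counts, dtype=float)
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        p = (c + pseudo) / (c.sum(axis=1, keepdims=True) + 4.0 * pseudo)
        return cls.from_probabilities(p, background)

    @classmethod
    def from_consensus(cls, consensus: str, p_consensus: float = 0.94) -> "MotifMatrix":
        """Sharp synthetic matrix concentrated on a consensus string."""
        off = (1.0 - p_consensus) / 3.0
        probs = np.full((len(consensus), 4), off)
        for i, base in enumerate(consensus.upper()):
            probs[i, ALPHABET.index(base)] = p_consensus
        return cls.from_probabilities(probs)

    @property
    def probabilities(self) -> np.ndarray:
        return np.exp(self.log_odds) * np.asarray(self.background)

    def reverse_complement(self) -> "MotifMatrix":
        return MotifMatrix(self.log_odds[::-1, ::-1].copy(), self.background)

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int  # 0-based start on the forward strand
    strand: str  # "+" or "-"
    score: float


def _encode(seq: str) -> np.ndarray:
    table = np.full(128, 5, dtype=np.int8)  # 5 = invalid
    for i, base in enumerate(ALPHABET + "N"):
        table[ord(base)] = i
        table[ord(base.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def score_window(window: str, matrix: MotifMatrix) -> float:
    """Log-odds score of a single window (length must equal the matrix width)."""
    if len(window) != matrix.width:
        raise ValueError(f"window length {len(window)} != matrix width {matrix.width}")
    codes = _encode(window)
    if np.any(codes > 4):
        raise ValueError("window contains characters outside ACGTN")
    padded = np.hstack([matrix.log_odds, np.zeros((matrix.width, 1))])  # N scores 0
    return float(padded[np.arange(matrix.width), codes].sum())


def _scan_strand(codes: np.ndarray, matrix: MotifMatrix) -> np.ndarray:
    """Scores of every window on the forward reading of `codes`."""
    w = matrix.width
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0)
    padded = np.hstack([matrix.log_odds, np.zeros((w, 1))])
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return padded[np.arange(w), windows].sum(axis=1)


def scan_upstream(
    sequences: dict[str, str],
    matrix: MotifMatrix,
    threshold: float,
    window: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Scan sequences (both strands) for motif hits at or above `threshold`.

    Only the first ``window`` bases of each sequence are scanned when given
    (the upstream region of interest); shorter sequences are scanned fully.
    Returns ``(hits, presence)``: a BED-like DataFrame with columns
    ``sequence_id, start, end, strand, score`` (0-based half-open, forward
    coordinates for both strands) and a boolean presence flag per sequence.
    Overlapping hits are all reported.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    rows = []
    presence = {}
    w = matrix.width
    rc = matrix.reverse_complement()
    for seq_id, seq in sequences.items():
        region = seq if window is None else seq[:window]
        codes = _encode(region)
        if np.any(codes > 4):
            raise ValueError(f"sequence {seq_id!r} contains characters outside ACGTN")
        fwd = _scan_strand(codes, matrix)
        # a minus-strand hit at forward offset i is the reverse complement of
        # the window, equivalently the reverse-complemented matrix scanned forward
        rev = _scan_strand(codes, rc)
        found = False
        for strand, scores in (("+", fwd), ("-", rev)):
            idx = np.nonzero(scores >= threshold)[0]
            for i in idx:
                rows.append((seq_id, int(i), int(i) + w, strand, float(scores[i])))
                found = True
        presence[seq_id] = found
    hits = pd.DataFrame(rows, columns=["sequence_id", "start", "end", "strand", "score"])
    return hits, pd.Series(presence, dtype=bool, name="present")


def compare_presence(groups: dict[str, np.ndarray]) -> tuple[pd.DataFrame, float, float]:
    """Motif-presence frequencies per group with a 2 x k association test.

    Empty groups are dropped with a warning.  Two groups are compared with
    Fisher's exact test; more with a chi-square test of independence.
    Returns ``(frequency table, statistic, p_value)``.
    """
    import warnings

    clean = {}
    for name, flags in groups.items():
        flags = np.asarray(flags, dtype=bool)
        if flags.size == 0:
            warnings.warn(f"group {name!r} is empty; excluded", stacklevel=2)
            continue
        clean[name] = flags
    if len(clean) < 2:
        raise ValueError("need at least 2 nonempty groups")
    table = pd.DataFrame(
        {
            "n": [f.size for f in clean.values()],
            "n_present": [int(f.sum()) for f in clean.values()],
        },
        index=list(clean),
    )
    table["frequency"] = table["n_present"] / table["n"]
    contingency = np.array([[f.sum(), (~f).sum()] for f in clean.values()])
    if len(clean) == 2:
        stat, p = stats.fisher_exact(contingency)
    else:
        stat, p, _, _ = stats.chi2_contingency(contingency)
    return table, float(stat), float(p)


def score_distribution(matrix: MotifMatrix, decimals: int = 9) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of a single-window score under the background model.

    Dynamic programme over positions (scores rounded to ``decimals`` to merge
    numerically identical sums).  Practical for matrices whose per-position
    score sets are small (e.g. consensus-style matrices); returns
    ``(values, probabilities)`` sorted by value.
    """
    bg = np.asarray(matrix.background)
    dist = {0.0: 1.0}
    for row in matrix.log_odds:
        new: dict[float, float] = {}
        for value, prob in dist.items():
            for base in range(4):
                v = round(value + row[base], decimals)
                new[v] = new.get(v, 0.0) + prob * bg[base]
        if len(new) > 2_000_000:
            raise ValueError("score distribution too large; matrix has too many distinct values")
        dist = new
    values = np.array(sorted(dist))
    probs = np.array([dist[v] for v in values])
    return values, probs


def random_match_probability(matrix: MotifMatrix, threshold: float) -> float:
    """P(single background window scores >= threshold), exact."""
    values, probs = score_distribution(matrix)
    return float(probs[values >= round(threshold, 9) - 1e-9].sum())
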