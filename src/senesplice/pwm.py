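"""PWM scanning with exact score p-values.

A window of length k is scored by the log-odds sum
``sum_j log2(m[j, b_j] / bg[b_j])`` (with a small pseudocount on both the
matrix and the background).  Scores are discretised to a fixed grid and
the null distribution of the window score under the background model is
computed exactly by dynamic programming (position-wise convolution of the
per-position score distributions).  A window is a hit when the upper-tail
probability of its score is at or below the scan threshold.

The scan looks at the given strand only: event regions are extracted in
transcript orientation before scanning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PwmMotif

PSEUDOCOUNT = 1e-3
GRID = 1e-3  # score discretisation step, in log2-odds units

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


_ENCODE_LUT = np.full(256, -1, dtype=np.int64)
for _base, _idx in _BASE_INDEX.items():
    _ENCODE_LUT[ord(_base)] = _idx
    _ENCODE_LUT[ord(_base.lower())] = _idx


def encode_sequence(seq: str) -> np.ndarray:
    """Map a nucleotide string to indices 0..3; anything else (N) -> -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def integer_scores(motif: PwmMotif) -> np.ndarray:
    """k x 4 integer log-odds scores on the discretisation grid."""
    m = (motif.matrix + PSEUDOCOUNT) / (1.0 + 4 * PSEUDOCOUNT)
    bg = (motif.background + PSEUDOCOUNT) / (1.0 + 4 * PSEUDOCOUNT)
    lod = np.log2(m / bg[None, :])
    return np.rint(lod / GRID).astype(np.int64)


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact null distribution of the integer window score."""

    offset: int  # integer score represented by index 0
    tail: np.ndarray  # tail[i] = P(S >= offset + i) under the background

    def pvalue(self, score: int) -> float:
        """Upper-tail probability of an integer window score."""
        i = score - self.offset
        if i <= 0:
            return 1.0
        if i >= len(self.tail):
            return 0.0
        return float(self.tail[i])

    def score_threshold(self, p_thresh: float) -> int:
        """Smallest integer score whose p-value is <= ``p_thresh``.

        Returns one past the maximum attainable score when no score
        qualifies (then nothing can ever be a hit).
        """
        ok = np.nonzero(self.tail <= p_thresh)[0]
        if ok.size == 0:
            return self.offset + len(self.tail)
        return self.offset + int(ok[0])


def score_distribution(motif: PwmMotif) -> ScoreDistribution:
    """Exact DP over per-position score sums under the background model."""
    scores = integer_scores(motif)
    bg = (motif.background + PSEUDOCOUNT) / (1.0 + 4 * PSEUDOCOUNT)
    lo = int(scores.min(axis=1).sum())
    hi = int(scores.max(axis=1).sum())
    probs = np.zeros(hi - lo + 1)
    # running support starts at the sum of per-position minima
    cur_lo = 0
    probs[0] = 1.0
    cur_len = 1
    for j in range(scores.shape[0]):
        smin, smax = int(scores[j].min()), int(scores[j].max())
        new_len = cur_len + (smax - smin)
        new = np.zeros(new_len)
        for b in range(4):
            off = int(scores[j, b]) - smin
            new[off : off + cur_len] += bg[b] * probs[:cur_len]
        probs[:new_len] = new
        probs[new_len:] = 0.0
        cur_len = new_len
        cur_lo += smin
    assert cur_lo == lo and cur_len == hi - lo + 1
    tail = np.cumsum(probs[:cur_len][::-1])[::-1]
    return ScoreDistribution(offset=lo, tail=tail)


class MotifScanner:
    """Caches per-motif score matrices and hit thresholds."""

    def __init__(self, p_thresh: float = 0.05):
        self.p_thresh = p_thresh
        self._cache: dict[str, tuple[np.ndarray, int]] = {}

    def _prepare(self, motif: PwmMotif) -> tuple[np.ndarray, int]:
        key = motif.motif_id
        if key not in self._cache:
            dist = score_distribution(motif)
            self._cache[key] = (integer_scores(motif), dist.score_threshold(self.p_thresh))
        return self._cache[key]

    def hits(self, seq: str, motif: PwmMotif) -> np.ndarray:
        """0-based offsets of hit windows in ``seq``."""
        scores, thresh = self._prepare(motif)
        k = scores.shape[0]
        enc = encode_sequence(seq)
        n = len(enc) - k + 1
        if n <= 0:
            return np.array([], dtype=np.int64)
        windows = np.lib.stride_tricks.sliding_window_view(enc, k)
        valid = np.all(windows >= 0, axis=1)
        total = np.zeros(n, dtype=np.int64)
        safe = np.where(windows >= 0, windows, 0)
        total = scores[np.arange(k)[None, :], safe].sum(axis=1)
        return np.nonzero(valid & (total >= thresh))[0]

    def has_hit(self, seq: str, motif: PwmMotif) -> bool:
        return self.hits(seq, motif).size > 0


def scan_pwm(seq: str, motif: PwmMotif, p_thresh: float = 0.05) -> np.ndarray:
    """Hit offsets of ``motif`` in ``seq`` at score p-value <= ``p_thresh``."""
    return MotifScanner(p_thresh).hits(seq, motif)


def score_pvalue(motif: PwmMotif, score: int) -> float:
    """Exact p-value of an integer window score (DP route)."""
    return score_distribution(motif).pvalue(score)
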