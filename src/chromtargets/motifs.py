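"""PWM scanning and two-motif co-occurrence analysis over peaks.

Peaks are classified into four groups by the presence/absence of two
motifs (e.g. a telobox-like motif and a NAC-binding motif), and the
fraction of peaks carrying both is compared with the independence
expectation p̂_A * p̂_B via an exact binomial tail; a label-permutation
null is available as a cross-check because the plug-in binomial is
slightly anti-conservative at small peak counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome_io import Peak

_BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with background for log-odds scoring."""

    motif_id: str
    probs: np.ndarray  # 4 x L, rows A,C,G,T
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.001

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[0] != 4:
            raise ValueError("PWM matrix must be 4 x L (rows A,C,G,T)")
        if p.shape[1] < 4:
            raise ValueError("motif length must be >= 4")
        if ((p < 0) | (p > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "background", np.asarray(self.background, float))

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=0))

    def score_matrix(self) -> np.ndarray:
        """5 x L log2-odds lookup; row 4 (N) is -inf so N windows never hit."""
        pc = self.pseudocount
        m = np.log2((self.probs + pc) / (self.background[:, None] + pc))
        return np.vstack([m, np.full(self.length, -np.inf)])

    def max_score(self) -> float:
        return float(self.score_matrix()[:4].max(axis=0).sum())


def read_pwm(path: str | Path, motif_id: str | None = None) -> PWM:
    """Read a PWM: 4 tab-separated rows (A,C,G,T) of column probabilities."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([float(x) for x in line.split("\t")])
    if len(rows) != 4:
        raise ValueError(f"{path}: expected 4 rows (A,C,G,T), got {len(rows)}")
    return PWM(motif_id or Path(path).stem, np.array(rows))


def write_pwm(pwm: PWM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# motif {pwm.motif_id}; rows A,C,G,T; columns are positions\n")
        for row in pwm.probs:
            fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")


@dataclass(frozen=True)
class MotifHit:
    peak_id: str
    offset: int  # 0-based within the scanned sequence
    strand: str
    score: float


_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def scan_pwm(
    sequence: str,
    pwm: PWM,
    score_fraction_threshold: float = 0.8,
    peak_id: str = "",
) -> list[MotifHit]:
    """Log-odds scan of both strands of one sequence.

    A window is a hit when its score reaches ``score_fraction_threshold``
    times the maximum attainable score. Windows containing N never score.
    Minus-strand offsets refer to the forward sequence (0-based position of
    the leftmost base of the matched window).
    """
    if not 0 < score_fraction_threshold <= 1:
        raise ValueError("score_fraction_threshold must be in (0, 1]")
    L = pwm.length
    if len(sequence) < L:
        return []
    cutoff = score_fraction_threshold * pwm.max_score()
    mat = pwm.score_matrix()
    hits: list[MotifHit] = []
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        enc = _encode(seq)
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)
        scores = mat[windows, np.arange(L)].sum(axis=1)
        for off in np.flatnonzero(scores >= cutoff - 1e-9):
            fwd_off = int(off) if strand == "+" else len(sequence) - L - int(off)
            hits.append(MotifHit(peak_id, fwd_off, strand, float(scores[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_peaks(
    peaks: Sequence[Peak],
    sequences: Mapping[str, str],
    pwm: PWM,
    score_fraction_threshold: float = 0.8,
) -> list[MotifHit]:
    """Scan each peak's sequence slice; hit offsets are peak-relative."""
    hits: list[MotifHit] = []
    for p in peaks:
        seq = sequences[p.chrom][p.start:p.end]
        hits.extend(scan_pwm(seq, pwm, score_fraction_threshold, peak_id=p.peak_id))
    return hits


def classify_peaks(
    peaks: Sequence[Peak],
    hits_motif_a: Iterable[MotifHit],
    hits_motif_b: Iterable[MotifHit],
) -> dict[str, str]:
    """Four-way classification: both / a_only / b_only / neither."""
    known = {p.peak_id for p in peaks}
    has_a = {h.peak_id for h in hits_motif_a}
    has_b = {h.peak_id for h in hits_motif_b}
    stray = (has_a | has_b) - known
    if stray:
        raise ValueError(f"hits reference unknown peaks: {sorted(stray)[:5]}")
    out: dict[str, str] = {}
    for p in peaks:
        a, b = p.peak_id in has_a, p.peak_id in has_b
        out[p.peak_id] = "both" if a and b else "a_only" if a else "b_only" if b else "neither"
    return out


def cooccurrence_test(
    classes: Mapping[str, str],
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Test whether both-motif peaks exceed the independence expectation.

    Expected both-fraction is the product of the plug-in marginals. The
    headline p-value conditions on the observed margins: under
    independence, n_both ~ Hypergeometric(n, n_A, n_B), and p is its
    one-tailed enrichment tail (Fisher exact). The plug-in binomial tail
    P(X >= n_both; n, p̂_A·p̂_B) is reported alongside but is conservative,
    because it ignores that the expectation was estimated from the same
    peaks. With ``n_permutations`` > 0 a permutation p (shuffling motif-B
    labels across peaks) is reported as a third route.
    """
    n = len(classes)
    if n == 0:
        raise ValueError("no peaks")
    vals = list(classes.values())
    n_both = sum(v == "both" for v in vals)
    n_a = n_both + sum(v == "a_only" for v in vals)
    n_b = n_both + sum(v == "b_only" for v in vals)
    p_a, p_b = n_a / n, n_b / n
    expected = p_a * p_b
    observed = n_both / n
    ratio = observed / expected if expected > 0 else float("nan")
    p_hyp = float(sps.hypergeom.sf(n_both - 1, n, n_a, n_b))
    p_bin = float(sps.binom.sf(n_both - 1, n, expected)) if expected > 0 else 1.0
    out = {
        "n_peaks": n,
        "observed_both_fraction": observed,
        "expected_both_fraction": expected,
        "ratio": ratio,
        "p": p_hyp,
        "p_binomial": p_bin,
    }
    if n_permutations > 0:
        rng = rng or np.random.default_rng()
        a_flags = np.array([v in ("both", "a_only") for v in vals])
        b_flags = np.array([v in ("both", "b_only") for v in vals])
        exceed = 1  # add-one correction for a valid permutation p-value
        for _ in range(n_permutations):
            perm = rng.permutation(b_flags)
            if (a_flags & perm).sum() >= n_both:
                exceed += 1
        out["p_permutation"] = exceed / (n_permutations + 1)
    return out


def group_signal_summary(
    classes: Mapping[str, str],
    signal: pd.DataFrame,
) -> pd.DataFrame:
    """Mean enrichment per motif class per factor.

    ``signal`` is peak x factor. Classes absent from the data appear with
    count 0 and NaN means.
    """
    order = ["both", "a_only", "b_only", "neither"]
    rows = []
    for cls in order:
        ids = [p for p, c in classes.items() if c == cls and p in signal.index]
        row: dict[str, float] = {"class": cls, "n_peaks": len(ids)}
        for col in signal.columns:
            row[str(col)] = float(signal.loc[ids, col].mean()) if ids else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")
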