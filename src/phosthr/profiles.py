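"""Position conservation, class PWMs and the PWM-difference score.

Conservation of a window column is measured as the relative entropy (in
bits) of the observed residue distribution against a uniform background
p0 = 0.05:

    M(l) = sum_i f_i(l) * log2(f_i(l) / p0),   0 * log 0 := 0

M(l) = 0 exactly when the 20 residues are background-distributed at
position l, and grows with conservation.  Padding/unknown residues (X)
are excluded from both numerator and denominator.

Class-specific position weight matrices hold pseudocount-smoothed
log-ratio weights of the observed residue frequency over background:

    w(x, l) = log2( (n_xl + alpha * p0 * N_l) /
                    ((N_l + alpha * N_l * sum(p0)) * p0) )

with n_xl the count of residue x at position l, N_l the column total
(X excluded) and alpha an additive pseudocount (default 1; alpha = 0
reproduces the raw log-odds and is only allowed when explicitly
requested, since unobserved cells then go to -inf).

The per-window position score is the positive-minus-negative PWM lookup
of the observed residue, F(l) = w_pos(x_l, l) - w_neg(x_l, l), evaluated
at every flank offset (the invariant central threonine is excluded; X
scores 0).  Large positive F(l) marks contexts resembling phosphorylated
sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import ResidueWindow
from .errors import ParameterError
from .readwrite import AA20, AA_INDEX

DEFAULT_P0 = 0.05
DEFAULT_ALPHA = 1.0


def center_out_offsets(w: int) -> list[int]:
    """Signed offsets for ``w`` flanking residues, center excluded.

    Ordered center-outward (-1, +1, -2, +2, ...) so that widening the
    window appends outer offsets without moving inner ones.
    """
    if w % 2 != 0 or w < 2:
        raise ParameterError(f"window size w={w} must be a positive even count")
    out: list[int] = []
    for d in range(1, w // 2 + 1):
        out.extend((-d, d))
    return out


def _as_sequences(windows: Sequence[ResidueWindow] | Sequence[str]) -> list[str]:
    seqs = [w.residues if isinstance(w, ResidueWindow) else str(w) for w in windows]
    if not seqs:
        raise ParameterError("need at least one window")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ParameterError("all windows must have the same length")
    return seqs


def residue_index_matrix(windows: Sequence[ResidueWindow] | Sequence[str]) -> np.ndarray:
    """(n, L) matrix of residue indices into AA20; X/unknown -> -1."""
    seqs = _as_sequences(windows)
    out = np.full((len(seqs), len(seqs[0])), -1, dtype=np.int64)
    for i, s in enumerate(seqs):
        for j, ch in enumerate(s):
            out[i, j] = AA_INDEX.get(ch, -1)
    return out


def count_matrix(windows: Sequence[ResidueWindow] | Sequence[str]) -> np.ndarray:
    """(20, L) residue counts per column, X excluded."""
    R = residue_index_matrix(windows)
    L = R.shape[1]
    counts = np.zeros((20, L), dtype=float)
    for l in range(L):
        col = R[:, l]
        col = col[col >= 0]
        if col.size:
            counts[:, l] = np.bincount(col, minlength=20)
    return counts


@dataclass
class PositionProfile:
    """Per-position residue frequencies and conservation values."""

    freqs: np.ndarray  # (20, L); columns sum to 1 unless empty
    p0: float
    M: np.ndarray  # (L,); NaN on empty columns
    L: int
    empty: np.ndarray  # (L,) bool; True where a column saw only X


def position_conservation(
    windows: Sequence[ResidueWindow] | Sequence[str], p0: float = DEFAULT_P0
) -> PositionProfile:
    """Compute per-position frequencies f_i(l) and conservation M(l)."""
    counts = count_matrix(windows)
    totals = counts.sum(axis=0)
    empty = totals == 0
    freqs = np.zeros_like(counts)
    np.divide(counts, totals, where=~empty, out=freqs)

    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log2(freqs / p0), 0.0)
    M = terms.sum(axis=0)
    M[empty] = np.nan
    # clip the tiny negative float error a uniform column can produce
    M[~empty] = np.maximum(M[~empty], 0.0)
    return PositionProfile(freqs=freqs, p0=p0, M=M, L=counts.shape[1], empty=empty)


def pwm_from_counts(
    counts: np.ndarray,
    p0: float = DEFAULT_P0,
    alpha: float = DEFAULT_ALPHA,
    allow_infinite: bool = False,
) -> np.ndarray:
    """Smoothed log-ratio weights from a (20, L) count matrix."""
    if alpha < 0:
        raise ParameterError(f"pseudocount alpha={alpha} must be >= 0")
    N = counts.sum(axis=0)  # column totals, X excluded
    if np.any(N == 0):
        raise ParameterError("PWM column with no observed residues (all X)")
    sum_p0 = 20.0 * p0
    num = counts + alpha * p0 * N
    den = (N + alpha * N * sum_p0) * p0
    if alpha == 0 and np.any(counts == 0):
        if not allow_infinite:
            raise ParameterError(
                "alpha=0 with unobserved residue counts yields -inf weights; "
                "pass allow_infinite=True to accept them"
            )
        with np.errstate(divide="ignore"):
            return np.log2(num / den)
    return np.log2(num / den)


def build_pwm(
    windows: Sequence[ResidueWindow] | Sequence[str],
    p0: float = DEFAULT_P0,
    alpha: float = DEFAULT_ALPHA,
    allow_infinite: bool = False,
) -> np.ndarray:
    """Build a 20 x L position weight matrix from aligned windows."""
    return pwm_from_counts(count_matrix(windows), p0, alpha, allow_infinite)


@dataclass
class PWMPair:
    """Positive- and negative-class PWMs over the same offsets."""

    pos: np.ndarray  # (20, L)
    neg: np.ndarray  # (20, L)
    p0: float = DEFAULT_P0
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.pos.shape != self.neg.shape:
            raise ParameterError("positive and negative PWMs differ in shape")
        if self.pos.shape[0] != 20 or self.pos.shape[1] % 2 == 0:
            raise ParameterError("PWMs must be 20 x (2*flank + 1)")

    @property
    def flank(self) -> int:
        return self.pos.shape[1] // 2

    @property
    def diff(self) -> np.ndarray:
        return self.pos - self.neg

    @classmethod
    def from_windows(
        cls,
        pos_windows: Sequence[ResidueWindow] | Sequence[str],
        neg_windows: Sequence[ResidueWindow] | Sequence[str],
        p0: float = DEFAULT_P0,
        alpha: float = DEFAULT_ALPHA,
    ) -> "PWMPair":
        return cls(
            pos=build_pwm(pos_windows, p0, alpha),
            neg=build_pwm(neg_windows, p0, alpha),
            p0=p0,
            alpha=alpha,
        )


@dataclass
class ScoreVector:
    """Per-position PWM-difference scores for one query window."""

    F: np.ndarray  # (2*flank,) in center-out offset order
    offsets: list[int]
    flank: int


def score_peptide(
    window: ResidueWindow | str, pwm_pair: PWMPair, flank: int
) -> ScoreVector:
    """F(l) = pos_pwm[x_l, l] - neg_pwm[x_l, l] at each flank offset.

    Offsets run center-outward over -flank..+flank excluding 0; an X at
    offset l contributes F(l) = 0 (padding neutrality).
    """
    if flank < 1 or flank > pwm_pair.flank:
        raise ParameterError(
            f"flank {flank} outside the PWM width (max {pwm_pair.flank})"
        )
    residues = window.residues if isinstance(window, ResidueWindow) else str(window)
    w_flank = len(residues) // 2
    if flank > w_flank:
        raise ParameterError(f"flank {flank} exceeds the window's flank {w_flank}")
    offsets = center_out_offsets(2 * flank)
    D = pwm_pair.diff
    vals = np.zeros(len(offsets))
    for j, off in enumerate(offsets):
        x = AA_INDEX.get(residues[w_flank + off], -1)
        if x >= 0:
            vals[j] = D[x, pwm_pair.flank + off]
    return ScoreVector(F=vals, offsets=offsets, flank=flank)


def positional_stats(
    pos_windows: Sequence[ResidueWindow],
    neg_windows: Sequence[ResidueWindow],
    property_table=None,
    p0: float = DEFAULT_P0,
) -> pd.DataFrame:
    """Descriptive per-offset statistics for both classes.

    One row per signed offset; per class: H/E/C frequencies (over
    annotated residues), mean accessibility, mean raw value of each
    physicochemical property (X excluded), and the conservation M(l).
    """
    if not pos_windows or not neg_windows:
        raise ParameterError("both classes must be non-empty")
    if property_table is None:
        from .encoding import PropertyTable

        property_table = PropertyTable.load()

    flank = pos_windows[0].flank
    offsets = list(range(-flank, flank + 1))
    data: dict[str, np.ndarray] = {"offset": np.array(offsets)}

    for cls, windows in (("pos", pos_windows), ("neg", neg_windows)):
        R = residue_index_matrix(windows)
        ss = np.array([list(w.ss) for w in windows])
        acc = np.stack([w.acc for w in windows])
        M = position_conservation(windows, p0=p0).M
        known = ss != "X"
        n_known = known.sum(axis=0).astype(float)
        for state in "HEC":
            with np.errstate(invalid="ignore"):
                data[f"{cls}_{state}"] = np.where(
                    n_known > 0, (ss == state).sum(axis=0) / n_known, np.nan
                )
        data[f"{cls}_acc"] = acc.mean(axis=0)
        valid = R >= 0
        n_valid = valid.sum(axis=0).astype(float)
        for prop in property_table.properties:
            vals = property_table.raw_vector(prop)  # (20,)
            per = np.where(valid, vals[np.clip(R, 0, 19)], 0.0)
            with np.errstate(invalid="ignore"):
                data[f"{cls}_{prop}"] = np.where(
                    n_valid > 0, per.sum(axis=0) / n_valid, np.nan
                )
        data[f"{cls}_M"] = M
    return pd.DataFrame(data)
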