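"""Affine raw scores and Karlin-Altschul E-values.

The raw score of a fragment with ``I`` identities, length ``L`` columns,
``G_i`` opened gaps and ``G_e`` extension gaps is the affine model

    RS = I·M_r + (L − (G_i + G_e) − I)·M_p + G_i·P_i + G_e·P_e

with match score ``M_r``, mismatch penalty ``M_p`` and gap open/extension
penalties ``P_i``/``P_e``.  Raw scores are normalized to E-values with the
ungapped Karlin-Altschul statistics of the substitution part of the scheme:

    E = K · m · n · exp(−λ·RS)

where ``m`` is the read length and ``n`` the total reference length.  λ is
the unique positive root of Σᵢⱼ pᵢpⱼ·exp(λ·s(i,j)) = 1 and K comes from the
standard lattice renewal series (see :func:`estimate_K`).  Gap penalties
enter through RS only; the gapped statistics are approximated by the
ungapped ones for the substitution scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ScoreScheme",
    "raw_score",
    "solve_lambda",
    "estimate_K",
    "evalue",
    "rescore_all",
]

_UNIFORM = (0.25, 0.25, 0.25, 0.25)


class KarlinAltschulError(ValueError):
    """Raised when a scheme violates the Karlin-Altschul conditions."""


@dataclass
class ScoreScheme:
    """Scoring parameters plus the derived λ/K statistics.

    ``db_length`` is the total reference length n (sum of the taxonomy
    lengths); ``max_evalue`` is the mapping cut-off.  λ and K are computed
    lazily on first use and cached; pass them explicitly to pin values.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    background: tuple[float, float, float, float] = _UNIFORM
    db_length: int = 1
    max_evalue: float = 1e-3
    K: float | None = None
    lam: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise ValueError("background frequencies must be non-negative and sum to 1")
        if self.db_length < 1:
            raise ValueError("db_length must be >= 1")

    def calibrate(self) -> "ScoreScheme":
        """Solve λ and K for the substitution part of the scheme (idempotent)."""
        if self.lam is None:
            self.lam = solve_lambda(self.match, self.mismatch, self.background)
        if self.K is None:
            self.K = estimate_K(self.match, self.mismatch, self.background, self.lam)
        return self


def raw_score(
    identities: int,
    length: int,
    igaps: int,
    egaps: int,
    scheme: ScoreScheme,
) -> float:
    """Affine raw score RS of a fragment's summary statistics."""
    if min(identities, length, igaps, egaps) < 0:
        raise ValueError("alignment statistics must be non-negative")
    if identities + igaps + egaps > length:
        raise ValueError("identities + gap columns exceed alignment length")
    mismatches = length - (igaps + egaps) - identities
    return (
        identities * scheme.match
        + mismatches * scheme.mismatch
        + igaps * scheme.gap_open
        + egaps * scheme.gap_extend
    )


def _pair_probs(background) -> tuple[float, float]:
    """(P(identical pair), P(mismatching pair)) under the background."""
    q = float(sum(p * p for p in background))
    return q, 1.0 - q


def solve_lambda(match: float, mismatch: float, background=_UNIFORM) -> float:
    """Positive root λ of Σᵢⱼ pᵢpⱼ·exp(λ·s(i,j)) = 1.

    With a single match score on the diagonal and a single mismatch score off
    it, the identity collapses to q·e^{λ·match} + (1−q)·e^{λ·mismatch} = 1
    with q = Σpᵢ².  Requires a negative expected score and a positive
    maximum score (the Karlin-Altschul conditions).
    """
    q, r = _pair_probs(background)
    expected = q * match + r * mismatch
    if match <= 0:
        raise KarlinAltschulError("maximum score must be positive")
    if expected >= 0:
        raise KarlinAltschulError(
            f"expected per-column score must be negative, got {expected:.4g}"
        )

    def f(lam: float) -> float:
        return q * math.exp(lam * match) + r * math.exp(lam * mismatch) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - unreachable for valid schemes
            raise KarlinAltschulError("failed to bracket lambda")
    return float(brentq(f, 1e-12, hi, xtol=1e-14, rtol=1e-12))


def _lattice(match: float, mismatch: float) -> tuple[int, int, int]:
    """Integerize (match, mismatch) on a common grid; return (im, imm, scale).

    Scores are snapped to a 1/1000 grid so the renewal series can run on an
    integer lattice; exact integers pass through unchanged.
    """
    fm = Fraction(round(match * 1000), 1000)
    fmm = Fraction(round(mismatch * 1000), 1000)
    denom = np.lcm(fm.denominator, fmm.denominator)
    im = int(fm * denom)
    imm = int(fmm * denom)
    return im, imm, int(denom)


def estimate_K(match: float, mismatch: float, background=_UNIFORM, lam: float | None = None,
               terms: int = 120) -> float:
    """Karlin-Altschul K for an ungapped match/mismatch scheme.

    Uses the lattice renewal-series formula

        K = δ·λ·e^(−2σ) / (H·(1 − e^(−λδ)))

    where δ is the span of the integer score lattice, H = λ·E[S·e^(λS)] the
    relative entropy per column, and σ = Σ_{k≥1} (1/k)·[E(e^(λS_k); S_k<0)
    + P(S_k ≥ 0)] summed over the first ``terms`` partial sums S_k (the
    series converges geometrically; 120 terms leave the tail far below the
    returned precision for any scheme whose expected score is not marginal).
    """
    if lam is None:
        lam = solve_lambda(match, mismatch, background)
    q, r = _pair_probs(background)
    im, imm, scale = _lattice(match, mismatch)
    lam_i = lam / scale  # lambda on the integer lattice
    delta = math.gcd(abs(im), abs(imm))
    lo, hi = min(im, imm), max(im, imm)
    step = np.zeros(hi - lo + 1)
    step[im - lo] += q
    step[imm - lo] += r
    H = lam_i * (q * im * math.exp(lam_i * im) + r * imm * math.exp(lam_i * imm))
    sigma = 0.0
    dist = np.array([1.0])
    offset = 0
    for k in range(1, terms + 1):
        dist = np.convolve(dist, step)
        offset += lo
        vals = offset + np.arange(dist.size)
        neg = vals < 0
        term = float((dist[neg] * np.exp(lam_i * vals[neg])).sum() + dist[~neg].sum())
        sigma += term / k
    K = delta * lam_i * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam_i * delta)))
    return float(min(K, 1.0))


def evalue(rs: float, read_length: int, scheme: ScoreScheme) -> float:
    """E-value K·m·n·exp(−λ·RS) for a raw score; computed in log space."""
    if read_length < 1:
        raise ValueError("read length must be >= 1")
    if not math.isfinite(rs):
        raise ValueError("raw score must be finite")
    scheme.calibrate()
    log_e = math.log(scheme.K) + math.log(read_length) + math.log(scheme.db_length) - scheme.lam * rs
    if log_e < -700.0:
        return 0.0
    return math.exp(log_e)


def rescore_all(groups, scheme: ScoreScheme) -> None:
    """Recompute raw scores and similarity (100·I/L) for every fragment, in place.

    Fragments converted from gap-detail-free formats (``gap_detail_known``
    False) have all their gap columns charged as openings, the conservative
    choice when the true opening/extension split is unknown.
    """
    for grp in groups:
        for frags in grp.per_genome.values():
            for f in frags:
                igaps, egaps = f.igaps, f.egaps
                if not f.gap_detail_known:
                    igaps, egaps = igaps + egaps, 0
                f.score = raw_score(f.identities, f.length, igaps, egaps, scheme)
                f.similarity = 100.0 * f.identities / f.length
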