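"""Validation arithmetic: trend classification, predicted-vs-observed match
tabulation, and the exact binomial significance test.

Predicted and observed biomarker responses are compared by direction only
(up / down / no_change, with a configurable dead band).  Agreement across a
marker panel is summarized as a match rate k/n and an exact binomial p-value
under the null that each comparison matches at random with probability 0.5.
One-sided p is the upper tail P(X >= k); the two-sided convention is
2*min(tails) capped at 1.  The Experimental Trend Analysis quantity -- the
expected combined-culture magnitude as the arithmetic sum of the single-cell
magnitudes -- is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import pandas as pd

__all__ = [
    "TREND_LABELS",
    "classify_trend",
    "binomial_exact",
    "binomial_exact_rational",
    "TrendTable",
    "tabulate_matches",
    "ExpectedTrend",
    "expected_trend_sum",
]

TREND_LABELS = ("up", "down", "no_change")
TREND_ARROWS = {"up": "▲", "down": "▼", "no_change": "▬"}

#: default dead band (percent) inside which a response counts as no_change
DEFAULT_THETA = 5.0


def classify_trend(delta_percent: float, theta: float = DEFAULT_THETA) -> str:
    """Direction of a percent change: ``up`` iff delta > theta, ``down`` iff
    delta < -theta, else ``no_change`` (boundary |delta| == theta inclusive)."""
    if math.isnan(delta_percent):
        raise ValueError("delta_percent is NaN")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if delta_percent > theta:
        return "up"
    if delta_percent < -theta:
        return "down"
    return "no_change"


def binomial_exact_rational(k: int, n: int) -> Fraction:
    """Exact upper-tail P(X >= k) for X ~ Binomial(n, 1/2) as a Fraction."""
    _check_kn(k, n)
    num = sum(math.comb(n, j) for j in range(k, n + 1))
    return Fraction(num, 2**n)


def binomial_exact(k: int, n: int, p0: float = 0.5, sided: str = "one") -> float:
    """Exact binomial tail probability with integer binomial coefficients.

    one-sided: P(X >= k) = sum_{j=k}^{n} C(n,j) p0^j (1-p0)^(n-j)
    two-sided: 2*min(P(X >= k), P(X <= k)), capped at 1.
    """
    _check_kn(k, n)
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie in (0, 1)")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")

    def upper(kk: int) -> float:
        return float(sum(math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(kk, n + 1)))

    def lower(kk: int) -> float:
        return float(sum(math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(0, kk + 1)))

    if sided == "one":
        return upper(k)
    return min(1.0, 2.0 * min(upper(k), lower(k)))


def _check_kn(k: int, n: int) -> None:
    if not (isinstance(k, int) and isinstance(n, int)):
        raise ValueError("k and n must be integers")
    if n < 1 or not (0 <= k <= n):
        raise ValueError(f"require 0 <= k <= n with n >= 1, got k={k}, n={n}")


@dataclass
class TrendTable:
    """Per-marker predicted/observed trend comparison plus panel statistics."""

    rows: pd.DataFrame  # columns: marker, predicted, observed, match
    theta: float
    p0: float = 0.5

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def k(self) -> int:
        return int(self.rows["match"].sum())

    @property
    def match_percent(self) -> float:
        return 100.0 * self.k / self.n

    @property
    def p_one_sided(self) -> float:
        return binomial_exact(self.k, self.n, self.p0, "one")

    @property
    def p_two_sided(self) -> float:
        return binomial_exact(self.k, self.n, self.p0, "two")

    def p_rational(self) -> Fraction | None:
        """Exact one-sided p as a fraction when the null is 1/2."""
        if self.p0 == 0.5:
            return binomial_exact_rational(self.k, self.n)
        return None

    def summary(self) -> str:
        parts = [
            f"{self.k}/{self.n}",
            f"{self.match_percent:.0f}%",
            f"p_one={self.p_one_sided:.4g}",
            f"p_two={self.p_two_sided:.4g}",
        ]
        frac = self.p_rational()
        if frac is not None:
            parts.append(f"(exact {frac.numerator}/{frac.denominator})")
        parts.append(f"theta={self.theta:g}%")
        return ", ".join(parts)

    def to_frame(self) -> pd.DataFrame:
        df = self.rows.copy()
        df["match"] = df["match"].map({True: "MATCH", False: "MISMATCH"})
        return df


def _to_label(value, theta: float) -> str:
    if isinstance(value, str):
        if value not in TREND_LABELS:
            raise ValueError(f"unknown trend label {value!r}")
        return value
    return classify_trend(float(value), theta)


def tabulate_matches(
    predicted: Sequence,
    observed: Sequence,
    markers: Sequence[str] | None = None,
    theta: float = DEFAULT_THETA,
    p0: float = 0.5,
) -> TrendTable:
    """Tabulate per-marker trend matches (strict label equality; ``no_change``
    matches only ``no_change``).  Entries may be labels or percent changes
    (classified at ``theta``).  Lists must be aligned marker-for-marker."""
    if len(predicted) != len(observed):
        raise ValueError(
            f"predicted ({len(predicted)}) and observed ({len(observed)}) differ in length"
        )
    if len(predicted) == 0:
        raise ValueError("empty marker panel")
    if markers is None:
        markers = [f"marker_{i}" for i in range(len(predicted))]
    elif len(markers) != len(predicted):
        raise ValueError("marker list not aligned with trend lists")
    pred = [_to_label(v, theta) for v in predicted]
    obs = [_to_label(v, theta) for v in observed]
    rows = pd.DataFrame(
        {
            "marker": list(markers),
            "predicted": pred,
            "observed": obs,
            "match": [p == o for p, o in zip(pred, obs)],
        }
    )
    return TrendTable(rows=rows, theta=theta, p0=p0)


@dataclass(frozen=True)
class ExpectedTrend:
    """Expected combined-culture response: the arithmetic sum of single-cell
    percent-change magnitudes, classified at the dead band."""

    magnitudes: tuple[float, ...]
    expected_magnitude: float
    trend: str


def expected_trend_sum(
    magnitudes: Sequence[float], theta: float = DEFAULT_THETA
) -> ExpectedTrend:
    """Sum the per-cell single-culture percent changes exactly and classify."""
    if len(magnitudes) == 0:
        raise ValueError("need at least one per-cell magnitude")
    mags = tuple(float(m) for m in magnitudes)
    total = math.fsum(mags)
    return ExpectedTrend(magnitudes=mags, expected_magnitude=total, trend=classify_trend(total, theta))
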