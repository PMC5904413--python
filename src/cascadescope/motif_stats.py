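"""Spacer-anchored statistics over bound regions.

Instead of de novo motif discovery, bound regions are summarized as a match
matrix: one row per bound site, one boolean column per spacer position
(1..32) plus the site's PAM 3-mer.  Two exact hypothesis tests operate on
this matrix:

* a Fisher exact test asking whether matches at positions 7-9 are enriched
  among sites with a non-optimal PAM (extension matches compensating for a
  weak PAM), built position-pooled: each site contributes its three 7-9
  positions to a 2x2 [matched, mismatched] x [non-AAG, AAG] table;
* an exact binomial test for enrichment of a match at the flipped-out
  position 6 above the one-in-four chance rate.

Both tests are computed with exact integer arithmetic (hypergeometric /
binomial tail enumeration), not with asymptotic approximations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import pandas as pd

from .chip_quant import AnnotatedPeak
from .duplex_model import Spacer

logger = logging.getLogger(__name__)

POSITION_COLUMNS = [f"pos{i}" for i in range(1, 33)]

#: Sites matching at least this many non-flipped positions are treated as
#: the on-target site and excluded from motif statistics.
ON_TARGET_MIN_MATCHED = 27


@dataclass
class MatchMatrix:
    """Per-site match booleans (pos1..pos32) and PAM 3-mers.

    ``n_unassociated`` records peaks that had no associated site and hence
    contribute no row.
    """

    df: pd.DataFrame
    n_unassociated: int = 0
    n_on_target_excluded: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in POSITION_COLUMNS + ["pam"] if c not in self.df.columns]
        if missing:
            raise ValueError(f"match matrix missing columns: {missing[:3]}...")

    def __len__(self) -> int:
        return len(self.df)


def build_match_matrix(
    annotated: Sequence[AnnotatedPeak],
    spacer: Spacer,
    on_target_min_matched: int = ON_TARGET_MIN_MATCHED,
) -> MatchMatrix:
    """Match matrix over annotated peaks, excluding the on-target site.

    Peaks lacking an associated site are counted and logged; any site with
    >= ``on_target_min_matched`` matched non-flipped positions is dropped as
    on-target.
    """
    rows = []
    n_missing = 0
    n_on_target = 0
    for a in annotated:
        if a.hit is None:
            n_missing += 1
            continue
        profile = [s == p for s, p in zip(spacer.sequence, a.hit.site.protospacer)]
        if a.hit.matched_nonflipped >= on_target_min_matched:
            n_on_target += 1
            continue
        row = {f"pos{i + 1}": m for i, m in enumerate(profile)}
        row["pam"] = a.hit.site.pam
        row["enrichment"] = a.enrichment
        rows.append(row)
    if n_missing:
        logger.info("%d peaks had no associated site (recorded as missing rows)", n_missing)
    df = pd.DataFrame(rows, columns=POSITION_COLUMNS + ["pam", "enrichment"])
    return MatchMatrix(df=df, n_unassociated=n_missing, n_on_target_excluded=n_on_target)


def pam_tally(matrix: MatchMatrix) -> tuple[pd.Series, float]:
    """Exact counts per PAM 3-mer and the AAG fraction."""
    if len(matrix) == 0:
        raise ValueError("pam_tally requires a nonempty match matrix")
    counts = matrix.df["pam"].value_counts()
    return counts, float(counts.get("AAG", 0)) / len(matrix)


def hypergeom_weight(a: int, r1: int, c1: int, n: int) -> int:
    """Unnormalized hypergeometric weight of cell ``a`` in a 2x2 table.

    For fixed margins (row-1 total ``r1``, column-1 total ``c1``, grand total
    ``n``), P(A=a) = C(c1, a) C(n-c1, r1-a) / C(n, r1); the common
    denominator is dropped so weights are exact integers.
    """
    return math.comb(c1, a) * math.comb(n - c1, r1 - a)


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table by hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's.  Weights are exact
    integers, so ties are handled exactly (no floating-point slack needed).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be nonnegative")
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    w_obs = hypergeom_weight(a, r1, c1, n)
    num = sum(
        w for k in range(lo, hi + 1) if (w := hypergeom_weight(k, r1, c1, n)) <= w_obs
    )
    return float(Fraction(num, math.comb(n, r1)))


def binomial_tail_geq(k: int, n: int, p: float) -> float:
    """One-sided exact binomial tail P(X >= k | n, p) by direct summation.

    For ``p`` with a small exact rational form (e.g. 1/4, the one-in-four
    base-match null) the sum is computed in exact integer arithmetic and is
    correct to the last float bit for n up to at least 10^4.  Otherwise
    terms are computed in log space and accumulated with math.fsum
    (~1e-11 relative at n = 10^4).
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if k == 0:
        return 1.0
    if p == 0:
        return 0.0
    if p == 1:
        return 1.0

    frac = Fraction(p)
    if frac.denominator <= 4096:
        pn, d = frac.numerator, frac.denominator
        qn = d - pn
        # running term C(n,j) pn^j qn^(n-j); comb and powers updated exactly
        comb = math.comb(n, k)
        pw_p = pn**k
        pw_q = qn ** (n - k)
        total = 0
        for j in range(k, n + 1):
            total += comb * pw_p * pw_q
            comb = comb * (n - j) // (j + 1)
            pw_p *= pn
            if j < n:
                pw_q //= qn
        return float(Fraction(total, d**n))

    logp, logq = math.log(p), math.log1p(-p)
    terms = [
        math.exp(
            math.lgamma(n + 1)
            - math.lgamma(j + 1)
            - math.lgamma(n - j + 1)
            + j * logp
            + (n - j) * logq
        )
        for j in range(k, n + 1)
    ]
    return min(1.0, math.fsum(sorted(terms)))


@dataclass(frozen=True)
class ExtensionPamTest:
    """Result of the positions-7-9 vs PAM-class Fisher test."""

    mean_matches_non_aag: float
    mean_matches_aag: float
    n_non_aag: int
    n_aag: int
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float | None


def fisher_ext_vs_pam(matrix: MatchMatrix) -> ExtensionPamTest:
    """Are positions 7-9 more often matched when the PAM is not AAG?

    Pools the three positions per site into a position-level 2x2 table
    [matched, mismatched] x [non-AAG sites, AAG sites] (non-AAG row total =
    3 x n_non_aag, etc.), and computes the two-sided Fisher exact p.  With
    zero sites in either PAM class the p-value is undefined (None).
    """
    if len(matrix) == 0:
        raise ValueError("fisher_ext_vs_pam requires a nonempty match matrix")
    is_aag = matrix.df["pam"] == "AAG"
    ext = matrix.df[["pos7", "pos8", "pos9"]].sum(axis=1)
    n_aag = int(is_aag.sum())
    n_non = int((~is_aag).sum())
    m_non = int(ext[~is_aag].sum())
    m_aag = int(ext[is_aag].sum())
    table = ((m_non, 3 * n_non - m_non), (m_aag, 3 * n_aag - m_aag))
    if n_aag == 0 or n_non == 0:
        return ExtensionPamTest(
            mean_matches_non_aag=m_non / n_non if n_non else float("nan"),
            mean_matches_aag=m_aag / n_aag if n_aag else float("nan"),
            n_non_aag=n_non,
            n_aag=n_aag,
            table=table,
            p_value=None,
        )
    return ExtensionPamTest(
        mean_matches_non_aag=m_non / n_non,
        mean_matches_aag=m_aag / n_aag,
        n_non_aag=n_non,
        n_aag=n_aag,
        table=table,
        p_value=fisher_exact_two_sided(table),
    )


@dataclass(frozen=True)
class Position6Test:
    """Result of the position-6 match enrichment binomial test."""

    observed_fraction: float
    n: int
    k: int
    p0: float
    p_value: float


def binomial_position6(
    matrix: MatchMatrix, p0: float = 0.25, alternative: str = "greater"
) -> Position6Test:
    """Exact binomial test for match enrichment at flipped-out position 6.

    Under the null each site matches position 6 with probability ``p0``
    (one of four bases).  One-sided (greater) by default since the question
    is enrichment above chance; 'two-sided' doubles the smaller tail
    (capped at 1).
    """
    if len(matrix) == 0:
        raise ValueError("binomial_position6 requires a nonempty match matrix")
    n = len(matrix)
    k = int(matrix.df["pos6"].sum())
    if alternative == "greater":
        p = binomial_tail_geq(k, n, p0)
    elif alternative == "two-sided":
        upper = binomial_tail_geq(k, n, p0)
        lower = 1.0 - binomial_tail_geq(k + 1, n, p0) if k < n else 1.0
        p = min(1.0, 2 * min(upper, lower))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return Position6Test(observed_fraction=k / n, n=n, k=k, p0=p0, p_value=p)


def column_match_frequencies(matrix: MatchMatrix) -> pd.Series:
    """Per-position match frequency across all rows (motif frequency table)."""
    if len(matrix) == 0:
        raise ValueError("empty match matrix")
    return matrix.df[POSITION_COLUMNS].mean()
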