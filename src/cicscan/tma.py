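"""Tie-corrected Kendall rank correlation for paired ordinal IHC scores.

Tissue-microarray cores are scored 0-3 for each of two stains; with only
four levels over ~100 cores ties dominate, so the tie-corrected tau-b
variant is used:

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2))

with n0 = n(n-1)/2, n1 = sum_t t(t-1)/2 over tie groups of x and n2 the
same over y; C and D are the concordant and discordant pair counts.  The
default p-value is the two-sided normal approximation with the standard
tie-corrected variance of C - D; a seeded Monte-Carlo permutation p-value
is available as an alternative.  Scores are also dichotomised into the
conventional Low (0 or 1) / High (2 or 3) 2x2 table.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

VALID_SCORES = frozenset({0, 1, 2, 3})


@dataclass(frozen=True)
class ScorePair:
    sample_id: str
    score_x: int
    score_y: int

    def __post_init__(self) -> None:
        if self.score_x not in VALID_SCORES or self.score_y not in VALID_SCORES:
            raise ValueError(f"sample {self.sample_id}: scores must lie in 0..3")


@dataclass(frozen=True)
class CorrelationResult:
    tau_b: float
    n: int
    concordant: int
    discordant: int
    tied_x: int  # pairs tied in x only
    tied_y: int  # pairs tied in y only
    tied_xy: int  # pairs tied in both margins
    p_value: float
    p_method: str

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in (
            "tau_b", "n", "concordant", "discordant",
            "tied_x", "tied_y", "tied_xy", "p_value", "p_method",
        )}
        return json.dumps(d, indent=2, sort_keys=True)


class DegenerateInputError(ValueError):
    """All x or all y identical: tau is undefined."""


def _as_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, pd.DataFrame):
        x = pairs["cic_score"].to_numpy()
        y = pairs["yap_score"].to_numpy()
    elif pairs and isinstance(pairs[0], ScorePair):
        x = np.array([p.score_x for p in pairs])
        y = np.array([p.score_y for p in pairs])
    else:
        x, y = pairs
        x, y = np.asarray(x), np.asarray(y)
    if len(x) != len(y):
        raise ValueError("score vectors differ in length")
    return x.astype(float), y.astype(float)


def _pair_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int, int]:
    """Classify every unordered pair: concordant, discordant, tied in x
    only, tied in y only, tied in both."""
    dx = np.sign(np.subtract.outer(x, x))
    dy = np.sign(np.subtract.outer(y, y))
    iu = np.triu_indices(len(x), k=1)
    dx, dy = dx[iu], dy[iu]
    conc = int(np.sum(dx * dy > 0))
    disc = int(np.sum(dx * dy < 0))
    tx = int(np.sum((dx == 0) & (dy != 0)))
    ty = int(np.sum((dy == 0) & (dx != 0)))
    txy = int(np.sum((dx == 0) & (dy == 0)))
    return conc, disc, tx, ty, txy


def _tie_sums(v: np.ndarray) -> tuple[float, float, float]:
    """sum t(t-1)/2, sum t(t-1)(t-2), sum t(t-1)(2t+5) over tie groups."""
    ts = np.array(list(Counter(v.tolist()).values()), dtype=float)
    return (
        float(np.sum(ts * (ts - 1) / 2)),
        float(np.sum(ts * (ts - 1) * (ts - 2))),
        float(np.sum(ts * (ts - 1) * (2 * ts + 5))),
    )


def kendall_tau_b(
    pairs,
    p_method: str = "normal_approx",
    n_permutations: int = 100_000,
    seed: int = 0,
) -> CorrelationResult:
    """Kendall tau-b with explicit pair counts and a two-sided p-value.

    ``pairs`` may be a DataFrame with cic_score/yap_score columns, a list of
    ScorePair, or an (x, y) tuple of sequences.  ``p_method`` is
    "normal_approx" (tie-corrected variance) or "permutation" (Monte-Carlo,
    seeded, add-one corrected).
    """
    x, y = _as_arrays(pairs)
    n = len(x)
    if n < 2:
        raise ValueError("kendall_tau_b requires n >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("a margin is constant; tau is undefined")

    conc, disc, tx, ty, txy = _pair_counts(x, y)
    n0 = n * (n - 1) // 2
    n1, x3, xv = _tie_sums(x)
    n2, y3, yv = _tie_sums(y)
    tau_b = (conc - disc) / np.sqrt((n0 - n1) * (n0 - n2))

    if p_method == "normal_approx":
        # tie-corrected variance of C - D
        v0 = n * (n - 1) * (2 * n + 5)
        v1 = 2 * n1 * 2 * n2 / (2.0 * n * (n - 1))
        v2 = x3 * y3 / (9.0 * n * (n - 1) * (n - 2)) if n > 2 else 0.0
        var = (v0 - xv - yv) / 18.0 + v1 + v2
        if var <= 0:
            p = 1.0
        else:
            z = (conc - disc) / np.sqrt(var)
            p = float(2 * _scipy_stats.norm.sf(abs(z)))
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        dx = np.sign(np.subtract.outer(x, x))
        dy = np.sign(np.subtract.outer(y, y))
        observed = abs(conc - disc)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            num = float(np.einsum("ij,ij->", dx, dy[np.ix_(perm, perm)])) / 2.0
            if abs(num) >= observed - 1e-9:
                hits += 1
        p = (1 + hits) / (1 + n_permutations)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")

    return CorrelationResult(
        tau_b=float(tau_b), n=n, concordant=conc, discordant=disc,
        tied_x=tx, tied_y=ty, tied_xy=txy, p_value=float(min(p, 1.0)),
        p_method=p_method,
    )


def dichotomize(pairs) -> pd.DataFrame:
    """Cross-tabulate Low (score 0 or 1) vs High (score 2 or 3) for both
    margins; a 2x2 table whose margins sum to n."""
    x, y = _as_arrays(pairs)
    xh = x >= 2
    yh = y >= 2
    table = pd.DataFrame(
        [[int(np.sum(~xh & ~yh)), int(np.sum(~xh & yh))],
         [int(np.sum(xh & ~yh)), int(np.sum(xh & yh))]],
        index=pd.Index(["x_Low", "x_High"], name="x"),
        columns=pd.Index(["y_Low", "y_High"], name="y"),
    )
    return table


def fit_trend_line(pairs) -> tuple[float, float]:
    """Least-squares slope/intercept of y on x, for plotting only; carries
    no inferential claim."""
    x, y = _as_arrays(pairs)
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def load_scores(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "cic_score", "yap_score"):
        if col not in df.columns:
            raise ValueError(f"score table {path} missing column {col!r}")
    bad = ~df["cic_score"].isin(VALID_SCORES) | ~df["yap_score"].isin(VALID_SCORES)
    if bad.any():
        raise ValueError(f"score table {path}: {int(bad.sum())} row(s) outside 0..3")
    return df


def write_correlation(result: CorrelationResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(result.to_json() + "\n")


def write_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t")
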