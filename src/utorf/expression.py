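"""Expression summaries, ribosome-footprint framing, and prioritization.

Expression support is a strict max-TPM threshold; specificity uses the tau
index (0 = uniform across samples, 1 = single-sample). Translation framing is
tested with a one-sided binomial upper tail on the count of footprints whose
5' ends fall in the locus's own codon phase versus the other two phases
(null p = 1/3), pooled across replicates and read lengths. Candidate
prioritization averages per-factor midranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_TPM_SUPPORT = 0.2
DEFAULT_MIN_FOOTPRINTS = 2  # testable requires strictly more unique footprints


def tau(expression: Sequence[float]) -> float:
    """Tissue-specificity index tau = sum_i (1 - x_i / max) / (N - 1).

    Undefined (NaN) for an all-zero vector; 0 for uniform expression, 1 for
    single-sample expression. Invariant under positive scaling.
    """
    x = np.asarray(expression, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs a vector of at least two samples")
    if (x < 0).any():
        raise ValueError("negative expression")
    mx = x.max()
    if mx == 0:
        return float("nan")
    return float((1.0 - x / mx).sum() / (x.size - 1))


@dataclass(frozen=True)
class FrameCounts:
    """Footprint counts by codon phase relative to the locus start."""

    n0: int
    n1: int
    n2: int
    n_unique: int

    def __post_init__(self) -> None:
        if min(self.n0, self.n1, self.n2, self.n_unique) < 0:
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return self.n0 + self.n1 + self.n2


def framing_pvalue(
    counts: FrameCounts,
    min_unique: int = DEFAULT_MIN_FOOTPRINTS,
    two_sided: bool = False,
) -> Optional[float]:
    """One-sided upper binomial tail P(X >= n0 | n, p=1/3) for frame bias.

    Returns None (not testable) when the locus has ``min_unique`` or fewer
    unique footprints. ``two_sided`` doubles the smaller tail (capped at 1).
    """
    if counts.n_unique <= min_unique:
        return None
    n = counts.total
    if n == 0:
        return None
    upper = float(stats.binom.sf(counts.n0 - 1, n, 1.0 / 3.0))
    if not two_sided:
        return upper
    lower = float(stats.binom.cdf(counts.n0, n, 1.0 / 3.0))
    return min(1.0, 2.0 * min(upper, lower))


def max_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-locus maximum TPM and the sample achieving it (ties break to the
    first sample in column order)."""
    if matrix.shape[1] == 0:
        raise ValueError("matrix has no samples")
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative TPM")
    idx = values.argmax(axis=1)
    return pd.DataFrame(
        {
            "max_tpm": values[np.arange(len(matrix)), idx],
            "argmax_sample": matrix.columns.to_numpy()[idx],
        },
        index=matrix.index,
    )


def tpm_support(
    matrix: pd.DataFrame, threshold: float = DEFAULT_TPM_SUPPORT
) -> pd.Series:
    """Supported iff the maximum TPM across samples is strictly greater than
    the threshold."""
    return pd.Series(
        matrix.to_numpy(dtype=float).max(axis=1) > threshold,
        index=matrix.index,
        name="tpm_supported",
    )


def expression_contrast(
    matrix: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    pseudocount: float = 0.01,
) -> pd.Series:
    """Per-locus delta = log10(TPM_b + c) - log10(TPM_a + c); downstream rank
    tests are delegated to standard statistics routines."""
    for s in (sample_a, sample_b):
        if s not in matrix.columns:
            raise ValueError(f"sample {s!r} missing from matrix")
    a = matrix[sample_a].to_numpy(dtype=float)
    b = matrix[sample_b].to_numpy(dtype=float)
    return pd.Series(
        np.log10(b + pseudocount) - np.log10(a + pseudocount),
        index=matrix.index,
        name=f"delta_log10_{sample_b}_vs_{sample_a}",
    )


def priority_ranking(
    factors: pd.DataFrame, directions: Mapping[str, str]
) -> pd.DataFrame:
    """Rank-averaged prioritization.

    Each factor gets midranks with rank 1 = best according to its declared
    direction ("higher" or "lower" is better); the per-locus mean rank,
    ascending, is the priority order. Invariant under strictly monotone
    transforms of any factor.
    """
    if factors.shape[1] == 0:
        raise ValueError("no factors")
    missing = set(factors.columns) - set(directions)
    if missing:
        raise ValueError(f"no direction declared for {sorted(missing)}")
    ranks = pd.DataFrame(index=factors.index)
    for col in factors.columns:
        x = factors[col].to_numpy(dtype=float)
        if directions[col] == "higher":
            r = stats.rankdata(-x, method="average")
        elif directions[col] == "lower":
            r = stats.rankdata(x, method="average")
        else:
            raise ValueError(f"direction must be 'higher' or 'lower'")
        ranks[f"rank_{col}"] = r
    out = factors.copy()
    for col in ranks.columns:
        out[col] = ranks[col]
    out["mean_rank"] = ranks.mean(axis=1)
    return out.sort_values("mean_rank", kind="stable")
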