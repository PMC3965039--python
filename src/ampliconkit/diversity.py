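"""Alpha/beta diversity and rarefaction on OTU count vectors.

Shannon uses the natural log by default (H = -sum p_i ln p_i), Chao1 is
bias-corrected by default (S_obs + F1(F1-1)/(2(F2+1))), Jaccard and
Sørensen are incidence-based similarities, and rarefaction is the exact
hypergeometric expectation E[S_n] = sum_i [1 - C(N-N_i, n)/C(N, n)]
computed with log-gamma binomials for stability.
"""
from __future__ import annotations

import math
from typing import Sequence as _Seq

import numpy as np
from scipy.special import gammaln


class DiversityError(ValueError):
    pass


def _positive(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=np.float64)
    if c.size == 0 or c.sum() <= 0:
        raise DiversityError("counts must contain at least one positive entry")
    if (c < 0).any():
        raise DiversityError("negative counts")
    return c[c > 0]


def shannon(counts, base: float = math.e) -> float:
    """Shannon diversity H of one sample's counts (natural log default)."""
    c = _positive(counts)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum() / math.log(base))


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts."""
    c = _positive(counts)
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    if f2 == 0:
        raise DiversityError(
            "classic Chao1 undefined with no doubletons; use bias_corrected=True")
    return s_obs + f1 ** 2 / (2 * f2)


def _incidence(counts) -> set[int]:
    c = np.asarray(counts, dtype=np.float64)
    if (c > 0).sum() == 0:
        raise DiversityError("sample has no positive OTU")
    return set(np.nonzero(c > 0)[0].tolist())


def jaccard(sample_a, sample_b, similarity: bool = True) -> float:
    """Incidence-based Jaccard index |A∩B| / |A∪B| (or 1 - that)."""
    a, b = _incidence(sample_a), _incidence(sample_b)
    j = len(a & b) / len(a | b)
    return j if similarity else 1 - j


def sorensen(sample_a, sample_b, similarity: bool = True) -> float:
    """Incidence-based Sørensen index 2|A∩B| / (|A| + |B|)."""
    a, b = _incidence(sample_a), _incidence(sample_b)
    s = 2 * len(a & b) / (len(a) + len(b))
    return s if similarity else 1 - s


def _log_choose(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefaction(counts, sizes: _Seq[int]) -> list[float]:
    """Expected OTU richness in random subsamples of the given sizes."""
    c = _positive(counts)
    n_total = c.sum()
    out = []
    for n in sizes:
        if n > n_total:
            raise DiversityError(f"subsample size {n} exceeds total {int(n_total)}")
        log_denom = _log_choose(n_total, n)
        expect = 0.0
        for ni in c:
            if n_total - ni < n:
                expect += 1.0  # the OTU cannot be missed
            else:
                expect += 1.0 - math.exp(_log_choose(n_total - ni, n) - log_denom)
        out.append(expect)
    return out
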