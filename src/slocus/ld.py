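"""Permutation test of recombination from the decay of r^2 with distance.

Recombination lets linkage disequilibrium between pairs of polymorphic
sites decline with the physical distance separating them.  The test
statistic is the Pearson correlation between pairwise r^2 and distance; its
null distribution is obtained by permuting the assignment of polymorphic
columns to their positions, which leaves the multisets of r^2 values and of
distances unchanged and only re-pairs them.  The one-tailed p-value counts
permutations at least as negatively correlated as observed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numba import njit

_VALID = frozenset("ACGT")


@njit(cache=True)
def _perm_cross_sums(r2: np.ndarray, dmat: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """sum_{a<b} r2[sigma_a, sigma_b] * d[a, b] for each permutation row."""
    n_perm, S = perms.shape
    out = np.empty(n_perm, dtype=np.float64)
    for p in range(n_perm):
        sig = perms[p]
        acc = 0.0
        for a in range(S):
            ra = sig[a]
            for b in range(a + 1, S):
                acc += r2[ra, sig[b]] * dmat[a, b]
        out[p] = acc
    return out


class InsufficientSitesError(ValueError):
    """Raised when fewer than three usable polymorphic sites remain."""


@dataclass
class SiteMatrix:
    """Binary genotype matrix of biallelic polymorphic columns.

    ``matrix`` holds 0 for the majority (reference) allele and 1 for the
    alternate; ``positions`` are the 1-based column positions within the
    source alignment.  ``n_excluded`` counts columns dropped for carrying
    more than two states, gaps or ambiguity codes.
    """

    matrix: np.ndarray
    positions: np.ndarray
    n_excluded: int = 0

    @property
    def n_sites(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def n_sequences(self) -> int:
        return int(self.matrix.shape[0])


@dataclass
class LDTestResult:
    """Outcome of the r^2-distance permutation test."""

    observed_correlation: float
    p_value: float
    n_sites: int
    n_pairs: int
    n_permutations: int
    detected: bool
    alpha: float = 0.05
    exhaustive: bool = False

    def to_dict(self) -> dict:
        return {
            "observed_correlation": None
            if math.isnan(self.observed_correlation)
            else self.observed_correlation,
            "p_value": self.p_value,
            "n_sites": self.n_sites,
            "n_pairs": self.n_pairs,
            "n_permutations": self.n_permutations,
            "detected": self.detected,
            "alpha": self.alpha,
        }


def _char_matrix(sample) -> np.ndarray:
    """Coerce alignment-like input to an (n, L) uppercase character array."""
    if hasattr(sample, "alignment"):  # SequenceSample
        arr = np.asarray(sample.alignment)
    elif isinstance(sample, np.ndarray):
        arr = sample
    else:
        seqs = [str(s).upper() for s in sample]
        if len(seqs) < 2:
            raise ValueError("need at least 2 sequences")
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("ragged alignment: sequences have unequal lengths")
        arr = np.array([list(s) for s in seqs])
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need an (n>=2, L) alignment")
    return np.char.upper(arr.astype("U1"))


def segregating_sites(
    sample, exclude_singletons: bool = False
) -> SiteMatrix:
    """Extract biallelic polymorphic columns as a 0/1 site matrix.

    Columns containing gaps, ambiguity codes or more than two states are
    excluded entirely (their count is reported on the result).  0 encodes
    the majority allele (ties broken by the allele occurring first in the
    column).  ``exclude_singletons`` optionally applies a minor-allele-count
    > 1 filter; the default keeps singletons.
    """
    arr = _char_matrix(sample)
    n, L = arr.shape
    cols: list[np.ndarray] = []
    positions: list[int] = []
    n_excluded = 0
    for j in range(L):
        col = arr[:, j]
        states = set(col.tolist())
        if not states <= _VALID:
            n_excluded += 1
            continue
        if len(states) == 1:
            continue
        if len(states) > 2:
            n_excluded += 1
            continue
        first = col[0]
        counts = {s: int(np.sum(col == s)) for s in states}
        ordered = sorted(states, key=lambda s: (-counts[s], s != first))
        major = ordered[0]
        binary = (col != major).astype(np.int8)
        if exclude_singletons and min(counts.values()) == 1:
            continue
        cols.append(binary)
        positions.append(j + 1)
    if cols:
        matrix = np.column_stack(cols)
    else:
        matrix = np.empty((n, 0), dtype=np.int8)
    return SiteMatrix(matrix, np.asarray(positions, dtype=np.int64), n_excluded)


def _r2_matrix(matrix: np.ndarray) -> np.ndarray:
    """r^2 between all column pairs of a 0/1 matrix (zero diagonal)."""
    x = matrix.astype(np.float64)
    n = x.shape[0]
    p = x.mean(axis=0)
    p11 = (x.T @ x) / n
    d = p11 - np.outer(p, p)
    denom = np.outer(p * (1 - p), p * (1 - p))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, d * d / denom, 0.0)
    np.fill_diagonal(r2, 0.0)
    return np.clip(r2, 0.0, 1.0)


def pairwise_r2(sites: SiteMatrix) -> list[tuple[int, float]]:
    """(distance, r^2) for every unordered pair of polymorphic columns.

    r^2 = D^2 / (p_A q_A p_B q_B) with D the haplotype-frequency excess.
    """
    if sites.n_sites < 2:
        raise InsufficientSitesError("need at least 2 polymorphic columns")
    r2 = _r2_matrix(sites.matrix)
    iu = np.triu_indices(sites.n_sites, k=1)
    dist = np.abs(sites.positions[iu[0]] - sites.positions[iu[1]])
    return list(zip(dist.tolist(), r2[iu].tolist()))


def ld_distance_correlation(pairs: Iterable[tuple[float, float]]) -> float:
    """Pearson correlation of r^2 against distance; NaN when undefined."""
    arr = np.asarray(list(pairs), dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (distance, r2) pairs")
    d, r = arr[:, 0], arr[:, 1]
    if np.std(d) == 0.0 or np.std(r) == 0.0:
        return float("nan")
    return float(np.corrcoef(d, r)[0, 1])


def _pearson_cross_stats(dv: np.ndarray, r2v: np.ndarray):
    m = dv.size
    sd = dv.std()
    sr = r2v.std()
    if sd == 0.0 or sr == 0.0:
        return None
    return m, dv.mean(), r2v.mean(), sd, sr


def permutation_test(
    sites: SiteMatrix,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> LDTestResult:
    """Permutation test of the r^2-distance correlation.

    Columns are randomly re-assigned to the observed positions; because
    both marginal multisets are permutation-invariant only the cross-sum
    ``sum r^2_ij * d_ij`` varies, which the implementation exploits.  For
    few enough columns (S! <= n_perm) the permutation set is enumerated
    exhaustively and the p-value is exact.
    """
    if sites.n_sites < 3:
        raise InsufficientSitesError(
            f"permutation test degenerate with {sites.n_sites} column(s)"
        )
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    S = sites.n_sites
    r2 = _r2_matrix(sites.matrix)
    pos = sites.positions.astype(np.float64)
    dmat = np.abs(pos[:, None] - pos[None, :])
    iu = np.triu_indices(S, k=1)
    dv = dmat[iu]
    r2v = r2[iu]
    n_pairs = dv.size
    stats = _pearson_cross_stats(dv, r2v)
    if stats is None:
        return LDTestResult(
            observed_correlation=float("nan"),
            p_value=1.0,
            n_sites=S,
            n_pairs=n_pairs,
            n_permutations=0,
            detected=False,
            alpha=alpha,
        )
    m, mu_d, mu_r, sd_d, sd_r = stats
    scale = 1.0 / (m * sd_d * sd_r)
    offset = mu_d * mu_r / (sd_d * sd_r)
    obs = float(np.corrcoef(dv, r2v)[0, 1])
    exhaustive = math.factorial(S) <= n_perm
    if exhaustive:
        import itertools

        perms = np.array(list(itertools.permutations(range(S))), dtype=np.int64)
    else:
        perms = np.empty((n_perm, S), dtype=np.int64)
        for i in range(n_perm):
            perms[i] = rng.permutation(S)
    corrs = _perm_cross_sums(r2, dmat, perms) * scale - offset
    n_done = perms.shape[0]
    count = int(np.sum(corrs <= obs + 1e-12))
    if exhaustive:
        p = count / n_done  # identity permutation is in the enumeration
    else:
        p = (1.0 + count) / (n_done + 1.0)
    return LDTestResult(
        observed_correlation=obs,
        p_value=p,
        n_sites=S,
        n_pairs=n_pairs,
        n_permutations=n_done,
        detected=p <= alpha,
        alpha=alpha,
        exhaustive=exhaustive,
    )


def detect_recombination(
    alignment,
    alpha: float = 0.05,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    exclude_singletons: bool = False,
) -> LDTestResult:
    """Full pipeline: site matrix -> r^2 pairs -> permutation p-value.

    Degenerate inputs (fewer than 3 biallelic polymorphic sites) score
    "not detected" with p = 1 so they can contribute to grid detection
    proportions instead of erroring.
    """
    sites = segregating_sites(alignment, exclude_singletons=exclude_singletons)
    if sites.n_sites < 3:
        return LDTestResult(
            observed_correlation=float("nan"),
            p_value=1.0,
            n_sites=sites.n_sites,
            n_pairs=0,
            n_permutations=0,
            detected=False,
            alpha=alpha,
        )
    return permutation_test(sites, n_perm=n_perm, rng=rng, alpha=alpha)
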