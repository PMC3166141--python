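"""Nucleotide diversity and Nei-Gojobori synonymous/non-synonymous divergence.

Average pairwise nucleotide diversity (pi) is the mean, over all unordered
sequence pairs, of the proportion of differing sites among sites comparable
in both sequences (pairwise deletion of gap/ambiguous columns).  The
Nei-Gojobori pathway method partitions codon differences into synonymous
and non-synonymous classes by averaging over all orderings of the changed
positions, counts synonymous and non-synonymous *sites* from the fraction
of one-step changes per codon position that preserve the amino acid, and
applies the Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3) to the
per-site proportions.  A sliding-window profile of pi localises diversity
hotspots along an alignment, and a silent molecular clock converts silent
divergence into absolute time.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable

_VALID = frozenset("ACGT")
_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_STANDARD.stop_codons)


class SaturationError(ValueError):
    """Raised when every sequence pair is saturated (p >= 3/4)."""


def _codon_aa(codon: str) -> str | None:
    """Amino acid for a sense codon, None for a stop codon."""
    if codon in _STOPS:
        return None
    return _STANDARD.forward_table[codon]


@lru_cache(maxsize=None)
def _syn_site_count(codon: str) -> float:
    """Number of synonymous sites in a sense codon (0..3).

    Per position, the fraction of the three possible single-nucleotide
    changes that are synonymous; changes creating stop codons count as
    non-synonymous so that synonymous + non-synonymous sites sum to 3.
    """
    aa = _codon_aa(codon)
    total = 0.0
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _codon_aa(alt) == aa:
                syn += 1
        total += syn / 3.0
    return total


@lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences between two sense codons.

    Averages over all orderings of the differing positions; pathways that
    pass through a stop codon are excluded unless every pathway is blocked,
    in which case all pathways are used with stop steps counted as
    non-synonymous.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stop: bool) -> tuple[float, float] | None:
        cur = c1
        syn = nonsyn = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            aa_cur, aa_nxt = _codon_aa(cur), _codon_aa(nxt)
            if (aa_cur is None or aa_nxt is None) and not allow_stop:
                return None
            if aa_cur is not None and aa_cur == aa_nxt:
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        return syn, nonsyn

    orders = list(itertools.permutations(diff))
    results = [r for r in (walk(o, allow_stop=False) for o in orders) if r is not None]
    if not results:
        results = [walk(o, allow_stop=True) for o in orders]
    syn = sum(r[0] for r in results) / len(results)
    nonsyn = sum(r[1] for r in results) / len(results)
    return syn, nonsyn


def jukes_cantor(p: float) -> float:
    """JC69 distance from a proportion of differing sites (p < 3/4)."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        raise SaturationError(f"p = {p:.4f} >= 3/4 is saturated under JC69")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class PairDivergence:
    """Nei-Gojobori summary for one sequence pair."""

    Sd: float
    Nd: float
    S_sites: float
    N_sites: float
    pS: float
    pN: float
    dS: float  # NaN when saturated
    dN: float
    n_codons: int
    saturated_s: bool = False
    saturated_n: bool = False

    @property
    def saturated(self) -> bool:
        return self.saturated_s or self.saturated_n


@dataclass
class DiversityResult:
    """Averages of pairwise diversity statistics over an alignment."""

    pi: float
    pi_s: float
    pi_a: float
    mean_Sd: float
    mean_Nd: float
    mean_S_sites: float
    mean_N_sites: float
    mean_pS: float
    mean_pN: float
    n_pairs: int
    n_saturated: int = 0
    corrected: bool = True

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class WindowSeries:
    """Sliding-window diversity profile (1-based inclusive coordinates)."""

    windows: list[tuple[int, int, float, float]] = field(default_factory=list)

    def append(self, start: int, end: int, pi: float) -> None:
        self.windows.append((start, end, (start + end) / 2.0, pi))

    def argmax(self) -> tuple[int, int, float, float]:
        return max(self.windows, key=lambda w: w[3])

    def __iter__(self):
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)


def _clean_sequences(alignment) -> list[str]:
    if hasattr(alignment, "alignment"):
        seqs = ["".join(row) for row in np.asarray(alignment.alignment)]
    else:
        seqs = [str(getattr(s, "seq", s)).upper() for s in alignment]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("ragged alignment: sequences have unequal lengths")
    return [s.upper() for s in seqs]


def _pair_pi(a: np.ndarray, b: np.ndarray, valid: np.ndarray) -> float:
    ok = valid
    compared = int(ok.sum())
    if compared == 0:
        return float("nan")
    return float(np.sum((a != b) & ok)) / compared


def _encode(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.array([list(s) for s in seqs])
    valid = np.isin(arr, list(_VALID))
    return arr, valid


def pairwise_pi(alignment, window: tuple[int, int] | None = None) -> float:
    """Average pairwise proportion of differing sites (pairwise deletion).

    ``window`` optionally restricts the computation to a 0-based half-open
    column interval.  Pairs with no comparable sites are skipped.
    """
    seqs = _clean_sequences(alignment)
    arr, valid = _encode(seqs)
    if window is not None:
        arr = arr[:, window[0] : window[1]]
        valid = valid[:, window[0] : window[1]]
    n = arr.shape[0]
    vals = []
    for i, j in itertools.combinations(range(n), 2):
        pij = _pair_pi(arr[i], arr[j], valid[i] & valid[j])
        if not math.isnan(pij):
            vals.append(pij)
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def nei_gojobori_pair(
    seq1: str, seq2: str, frame: int = 0, correct: bool = True
) -> PairDivergence:
    """Nei-Gojobori (pathway) synonymous/non-synonymous divergence of a pair.

    Codons containing gaps, ambiguity codes or a stop in either sequence
    are skipped pairwise.  Site counts are averaged between the two
    sequences; the Jukes-Cantor correction is applied to pS and pN unless
    ``correct=False``, and proportions >= 3/4 flag the pair saturated
    (dS/dN become NaN).
    """
    s1, s2 = str(seq1).upper(), str(seq2).upper()
    if len(s1) != len(s2):
        raise ValueError("sequences must have equal length")
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    Sd = Nd = 0.0
    S1 = S2 = 0.0
    n_codons = 0
    for start in range(frame, len(s1) - 2, 3):
        c1, c2 = s1[start : start + 3], s2[start : start + 3]
        if not (set(c1) <= _VALID and set(c2) <= _VALID):
            continue
        if c1 in _STOPS or c2 in _STOPS:
            continue
        n_codons += 1
        S1 += _syn_site_count(c1)
        S2 += _syn_site_count(c2)
        syn, nonsyn = _pathway_counts(c1, c2)
        Sd += syn
        Nd += nonsyn
    if n_codons == 0:
        raise ValueError("no comparable codons between the two sequences")
    S_sites = (S1 + S2) / 2.0
    N_sites = 3.0 * n_codons - S_sites
    pS = Sd / S_sites if S_sites > 0 else 0.0
    pN = Nd / N_sites if N_sites > 0 else 0.0
    saturated_s = pS >= 0.75
    saturated_n = pN >= 0.75
    if correct:
        dS = float("nan") if saturated_s else jukes_cantor(pS)
        dN = float("nan") if saturated_n else jukes_cantor(pN)
    else:
        dS, dN = pS, pN
        saturated_s = saturated_n = False
    return PairDivergence(
        Sd=Sd,
        Nd=Nd,
        S_sites=S_sites,
        N_sites=N_sites,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        n_codons=n_codons,
        saturated_s=saturated_s,
        saturated_n=saturated_n,
    )


def average_pairwise_divergence(
    alignment, frame: int = 0, correct: bool = True
) -> DiversityResult:
    """Mean pairwise dS (Pi_s), dN (Pi_a) and total-site pi of an alignment.

    Saturated pairs are dropped from the dS/dN means with a logged count,
    never silently clipped; if every pair is saturated the computation
    fails explicitly.
    """
    seqs = _clean_sequences(alignment)
    pairs = [
        nei_gojobori_pair(a, b, frame=frame, correct=correct)
        for a, b in itertools.combinations(seqs, 2)
    ]
    usable = [p for p in pairs if not p.saturated]
    n_saturated = len(pairs) - len(usable)
    if not usable:
        raise SaturationError("all sequence pairs are saturated; no usable dS/dN")
    return DiversityResult(
        pi=pairwise_pi(seqs),
        pi_s=float(np.mean([p.dS for p in usable])),
        pi_a=float(np.mean([p.dN for p in usable])),
        mean_Sd=float(np.mean([p.Sd for p in pairs])),
        mean_Nd=float(np.mean([p.Nd for p in pairs])),
        mean_S_sites=float(np.mean([p.S_sites for p in pairs])),
        mean_N_sites=float(np.mean([p.N_sites for p in pairs])),
        mean_pS=float(np.mean([p.pS for p in pairs])),
        mean_pN=float(np.mean([p.pN for p in pairs])),
        n_pairs=len(pairs),
        n_saturated=n_saturated,
        corrected=correct,
    )


def sliding_window_pi(alignment, window: int = 50, step: int = 10) -> WindowSeries:
    """Average pairwise diversity in sliding windows along the alignment.

    Defaults (window 50, step 10) suit short, highly variable coding
    regions; both are freely configurable.  Reported coordinates are
    1-based inclusive.
    """
    seqs = _clean_sequences(alignment)
    L = len(seqs[0])
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > L:
        raise ValueError("window exceeds alignment length")
    if step < 1:
        raise ValueError("step must be >= 1")
    series = WindowSeries()
    for start in range(0, L - window + 1, step):
        pi = pairwise_pi(seqs, window=(start, start + window))
        series.append(start + 1, start + window, pi)
    return series


def divergence_time(
    ds: float, rate: float, pairwise_halving: bool = False
) -> float:
    """Divergence time in years from silent divergence and a silent clock.

    Computes ``ds / rate`` (substitutions per site over substitutions per
    site per year).  ``pairwise_halving`` divides by 2-rate instead, the
    convention for a pairwise divergence accumulating along two lineages.
    """
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    if ds < 0:
        raise ValueError("ds must be nonnegative")
    return ds / (2.0 * rate) if pairwise_halving else ds / rate
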