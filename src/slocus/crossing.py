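"""Genotype-phenotype concordance for gametophytic self-incompatibility.

Under single-locus GSI, haploid pollen is rejected when its S-allele matches
either allele of the pistil.  For crosses among full sibs this yields three
predictable phenotype classes from the parents' S-genotypes:

* ``incompatible``     - both genotypes identical (every pollen allele matches),
* ``semi_compatible``  - exactly one shared allele (half of pollen succeeds,
  which suffices for fruit set),
* ``compatible``       - no shared allele.

Plants from which only a single S-like product amplified cannot be scored
confidently and are classed ``ambiguous``.

This module provides the phenotype predictor, contingency statistics for
fruit-set concordance (Pearson chi-square without continuity correction and
Fisher's exact test), segregation goodness-of-fit, and diallel summaries,
including the exact probability that a diallel among *k* full sibs uncovers
no reciprocally incompatible pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

INCOMPATIBLE = "incompatible"
SEMI_COMPATIBLE = "semi_compatible"
COMPATIBLE = "compatible"
AMBIGUOUS = "ambiguous"

PHENOTYPE_CLASSES = (INCOMPATIBLE, SEMI_COMPATIBLE, COMPATIBLE, AMBIGUOUS)

FRUIT = "fruit"
NO_FRUIT = "no_fruit"
NOT_DONE = "not_done"


class InvalidGenotypeError(ValueError):
    """Raised for empty or malformed genotypes."""


class UndefinedTestError(ValueError):
    """Raised when a contingency test is undefined (zero marginal)."""


class ClassificationError(ValueError):
    """Raised when a record's predicted class is outside the requested pair."""


@dataclass(frozen=True)
class Haplotype:
    """One inherited S-haplotype unit.

    ``members`` lists the sequence products carried by the unit; products that
    co-segregate as if linked (e.g. the pair amplified together from one
    parent) are collapsed into a single unit before any prediction.
    """

    label: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.label:
            raise InvalidGenotypeError("haplotype label must be nonempty")
        if not self.members:
            object.__setattr__(self, "members", frozenset({self.label}))


class Genotype:
    """Set of 1-2 S-haplotype labels carried by a plant.

    Size 1 flags an ambiguously genotyped plant (only one product amplified);
    such plants predict class ``ambiguous`` in any cross.
    """

    __slots__ = ("haplotypes",)

    def __init__(self, haplotypes: Iterable[str]) -> None:
        labels = frozenset(str(h) for h in haplotypes)
        if not 1 <= len(labels) <= 2:
            raise InvalidGenotypeError(
                f"genotype must carry 1-2 haplotype units, got {sorted(labels)!r}"
            )
        self.haplotypes = labels

    @classmethod
    def parse(cls, text: str, sep: str = "+") -> "Genotype":
        """Parse a '+'-joined genotype field such as ``"S8a+S1c"``."""
        parts = [p.strip() for p in text.split(sep) if p.strip()]
        if not parts:
            raise InvalidGenotypeError(f"cannot parse genotype from {text!r}")
        return cls(parts)

    @property
    def is_ambiguous(self) -> bool:
        return len(self.haplotypes) == 1

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genotype) and self.haplotypes == other.haplotypes

    def __hash__(self) -> int:
        return hash(self.haplotypes)

    def __iter__(self):
        return iter(sorted(self.haplotypes))

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __repr__(self) -> str:
        return f"Genotype({'+'.join(sorted(self.haplotypes))})"

    def __str__(self) -> str:
        return "+".join(sorted(self.haplotypes))


@dataclass
class CrossRecord:
    """One pollination series between two full sibs."""

    family: str
    maternal: Genotype
    paternal: Genotype
    n_pollinations: int
    n_fruit: int
    predicted: str | None = None
    maternal_id: str = ""
    paternal_id: str = ""
    ambiguous_genotype: bool = False

    def __post_init__(self) -> None:
        if self.n_pollinations < 0 or self.n_fruit < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_fruit > self.n_pollinations:
            raise ValueError(
                f"n_fruit ({self.n_fruit}) exceeds n_pollinations ({self.n_pollinations})"
            )
        if self.predicted is None:
            self.predicted = predict_cross_phenotype(self.maternal, self.paternal)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts: rows = cross class, columns = (fruit, no fruit)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def predict_cross_phenotype(maternal: Genotype, paternal: Genotype) -> str:
    """Predict the GSI phenotype class of a cross from the two S-genotypes.

    Symmetric in its arguments for full (size-2) genotypes.  A size-1
    genotype yields ``ambiguous`` unless the sets still force a class: two
    identical size-1 genotypes must share their only known allele, so no
    pollen class is unambiguously non-matching and the prediction stays
    ``ambiguous``; a size-1 genotype disjoint from the partner is likewise
    ambiguous because the unamplified allele could match.
    """
    if not isinstance(maternal, Genotype) or not isinstance(paternal, Genotype):
        raise InvalidGenotypeError("both parents must be Genotype instances")
    m, p = maternal.haplotypes, paternal.haplotypes
    if maternal.is_ambiguous or paternal.is_ambiguous:
        return AMBIGUOUS
    if m == p:
        return INCOMPATIBLE
    shared = len(m & p)
    if shared == 1:
        return SEMI_COMPATIBLE
    return COMPATIBLE


def tabulate_fruit_set(
    records: Sequence[CrossRecord],
    classes: tuple[str, str] = (INCOMPATIBLE, SEMI_COMPATIBLE),
    on_ambiguous: str = "exclude",
) -> ContingencyTable2x2:
    """Collapse cross records into a 2x2 fruit-set contingency table.

    Row order follows ``classes``; column 1 sums fruits, column 2 sums
    failed pollinations.  Records whose recorded ``predicted`` class is
    ``ambiguous`` are dropped by default (``on_ambiguous="exclude"``) since
    they fit neither row; ``on_ambiguous="error"`` raises instead.  Any
    other class outside the requested pair always raises.
    """
    if on_ambiguous not in ("exclude", "error"):
        raise ValueError("on_ambiguous must be 'exclude' or 'error'")
    counts = {cls: [0, 0] for cls in classes}
    for rec in records:
        if rec.predicted == AMBIGUOUS and AMBIGUOUS not in classes:
            if on_ambiguous == "error":
                raise ClassificationError("record with ambiguous predicted class")
            continue
        if rec.predicted not in classes:
            raise ClassificationError(
                f"record predicted {rec.predicted!r} not in requested classes {classes}"
            )
        counts[rec.predicted][0] += rec.n_fruit
        counts[rec.predicted][1] += rec.n_pollinations - rec.n_fruit
    (a, b), (c, d) = counts[classes[0]], counts[classes[1]]
    return ContingencyTable2x2(a, b, c, d)


def _as_table(table: ContingencyTable2x2 | np.ndarray | Sequence) -> np.ndarray:
    if isinstance(table, ContingencyTable2x2):
        arr = table.as_array()
    else:
        arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("expected a 2x2 table of nonnegative counts")
    return arr


def pearson_chi_square(
    table: ContingencyTable2x2 | np.ndarray | Sequence,
) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Returns ``(statistic, df, p_value)`` with df = 1.  Raises
    :class:`UndefinedTestError` on any zero marginal.
    """
    arr = _as_table(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise UndefinedTestError("chi-square undefined: zero row or column sum")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), int(df), float(p)


def fisher_exact(
    table: ContingencyTable2x2 | np.ndarray | Sequence,
    sidedness: str = "two-sided",
) -> float:
    """Fisher's exact test p-value on a 2x2 table.

    Two-sided sums all tables of the hypergeometric support whose
    probability does not exceed the observed table's.
    """
    arr = _as_table(table)
    if arr.sum() == 0:
        raise UndefinedTestError("Fisher test undefined on an empty table")
    alternatives = {"two-sided": "two-sided", "less": "less", "greater": "greater"}
    if sidedness not in alternatives:
        raise ValueError(f"sidedness must be one of {sorted(alternatives)}")
    _, p = stats.fisher_exact(arr, alternative=alternatives[sidedness])
    return float(p)


def segregation_gof(
    observed: Sequence[int],
    expected_ratio: Sequence[float] | None = None,
) -> tuple[float, int, float]:
    """Goodness-of-fit of genotype-class counts to an expected ratio.

    Defaults to the 1:1:1:1 expectation for four offspring genotype classes
    produced by two heterozygous parents segregating independently.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("need counts for at least 2 classes")
    if obs.sum() <= 0:
        raise ValueError("total observed count must be positive")
    if expected_ratio is None:
        expected_ratio = np.ones_like(obs)
    weights = np.asarray(expected_ratio, dtype=float)
    if weights.shape != obs.shape:
        raise ValueError("observed and expected_ratio lengths differ")
    if (weights <= 0).any():
        raise ValueError("expected ratio weights must be positive")
    expected = weights / weights.sum() * obs.sum()
    stat, p = stats.chisquare(obs, f_exp=expected)
    return float(stat), int(obs.size - 1), float(p)


def diallel_incompatible_pairs(
    outcomes: Sequence[Sequence[str]],
) -> tuple[int, list[tuple[int, int]], list[tuple[int, int]]]:
    """Count reciprocally incompatible pairs in a k x k diallel outcome matrix.

    ``outcomes[i][j]`` is the result of pollinating plant *i* with pollen of
    plant *j*: one of ``"fruit"``, ``"no_fruit"``, ``"not_done"``.  A pair
    (i, j) counts when both directions were done and both set no fruit.
    Pairs with exactly one tested, fruitless direction are reported
    separately (third return value).
    """
    mat = [list(row) for row in outcomes]
    k = len(mat)
    if any(len(row) != k for row in mat):
        raise ValueError("diallel outcome matrix must be square")
    valid = {FRUIT, NO_FRUIT, NOT_DONE}
    for row in mat:
        for entry in row:
            if entry not in valid:
                raise ValueError(f"unknown outcome {entry!r}")
    reciprocal: list[tuple[int, int]] = []
    one_way: list[tuple[int, int]] = []
    for i in range(k):
        for j in range(i + 1, k):
            ij, ji = mat[i][j], mat[j][i]
            if ij == NO_FRUIT and ji == NO_FRUIT:
                reciprocal.append((i, j))
            elif (ij == NO_FRUIT and ji == NOT_DONE) or (ij == NOT_DONE and ji == NO_FRUIT):
                one_way.append((i, j))
    return len(reciprocal), reciprocal, one_way


def prob_no_incompatible_pair(
    k: int,
    model: str = "one_locus_gsi",
    n_classes: int | None = None,
    n_reps: int | None = None,
    rng: np.random.Generator | None = None,
) -> float | tuple[float, float]:
    """Probability that no two of *k* full sibs share a full incompatibility genotype.

    Offspring of a semi- or fully compatible cross between heterozygous
    parents fall into equally likely mating-type classes: 4 under one-locus
    GSI (``model="one_locus_gsi"``), 16 under a two-locus identity model
    (``model="two_locus_identity"``).  The exact probability that all *k*
    sibs differ is the birthday-problem product prod_{i<k} (m - i)/m, zero
    for k > m.  ``n_reps`` switches to Monte Carlo (returned with its
    binomial standard error), available for cross-checking any class count.
    """
    if k < 2:
        raise ValueError("need at least 2 sibs")
    models = {"one_locus_gsi": 4, "two_locus_identity": 16}
    if model in models:
        m = models[model]
    elif model == "custom":
        if not n_classes or n_classes < 1:
            raise ValueError("custom model requires n_classes >= 1")
        m = n_classes
    else:
        raise ValueError(f"unknown model {model!r}")
    if n_reps is None:
        if k > m:
            return 0.0
        prob = 1.0
        for i in range(k):
            prob *= (m - i) / m
        return prob
    rng = np.random.default_rng() if rng is None else rng
    draws = rng.integers(0, m, size=(n_reps, k))
    hits = np.array([len(set(row)) == k for row in draws])
    p_hat = float(hits.mean())
    se = math.sqrt(p_hat * (1.0 - p_hat) / n_reps)
    return p_hat, se
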