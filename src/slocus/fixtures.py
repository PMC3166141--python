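"""Synthetic GSI families, encoded crossing tables and planted alignments.

Everything the analysis pipeline consumes can be generated here without
external data: full-sib families segregating 1:1:1:1 at a heterozygous GSI
locus (with linked products transmitted as units and per-allele "weak SI"
leak rates), the two published full-sib fruit-set tables encoded cell by
cell as packaged data, and nucleotide alignments with a planted
high-diversity region for sliding-window analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from slocus.crossing import (
    AMBIGUOUS,
    COMPATIBLE,
    INCOMPATIBLE,
    SEMI_COMPATIBLE,
    CrossRecord,
    Genotype,
    predict_cross_phenotype,
)

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class FamilySpec:
    """A full-sib family design: two heterozygous parents, optional linkage."""

    maternal: Genotype
    paternal: Genotype
    linked_groups: Mapping[str, frozenset[str]] = field(default_factory=dict)
    n_offspring: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.maternal) != 2 or len(self.paternal) != 2:
            raise ValueError("family simulation requires two heterozygous parents")
        members = [frozenset(m) for m in self.linked_groups.values()]
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if a & b:
                    raise ValueError("linked groups must be disjoint")


@dataclass
class PhenotypeModel:
    """Probabilities of fruit set by predicted class, with weak-allele leaks.

    ``leak`` maps a haplotype label to the fruit probability of a
    matching-genotype cross whose genotype carries it (a "weak SI" allele);
    the largest applicable leak wins over ``baseline_incompatible``.
    """

    p_fruit_semi: float = 1.0
    p_fruit_compat: float = 1.0
    p_fruit_ambiguous: float | None = None
    baseline_incompatible: float = 0.0
    leak: Mapping[str, float] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        probs = [self.p_fruit_semi, self.p_fruit_compat, self.baseline_incompatible]
        probs += list(self.leak.values())
        if self.p_fruit_ambiguous is not None:
            probs.append(self.p_fruit_ambiguous)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")

    def fruit_probability(self, predicted: str, maternal: Genotype, paternal: Genotype) -> float:
        if predicted == INCOMPATIBLE:
            carried = maternal.haplotypes | paternal.haplotypes
            leaks = [p for h, p in self.leak.items() if h in carried]
            return max(leaks, default=self.baseline_incompatible)
        if predicted == SEMI_COMPATIBLE:
            return self.p_fruit_semi
        if predicted == COMPATIBLE:
            return self.p_fruit_compat
        if predicted == AMBIGUOUS:
            return (
                self.p_fruit_semi
                if self.p_fruit_ambiguous is None
                else self.p_fruit_ambiguous
            )
        raise ValueError(f"unknown phenotype class {predicted!r}")


def generate_family(
    spec: FamilySpec, rng: np.random.Generator | None = None
) -> list[Genotype]:
    """Draw offspring genotypes: one haplotype unit from each parent.

    Transmission is uniform and independent, so with distinct parental
    units the four offspring genotypes occur in an expected 1:1:1:1 ratio;
    linked groups are single units and therefore transmit together.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    mat = sorted(spec.maternal.haplotypes)
    pat = sorted(spec.paternal.haplotypes)
    offspring = []
    for _ in range(spec.n_offspring):
        m = mat[rng.integers(2)]
        p = pat[rng.integers(2)]
        offspring.append(Genotype({m, p}))
    return offspring


def simulate_cross_records(
    offspring: Sequence[Genotype],
    model: PhenotypeModel,
    design: Sequence[tuple[int, int, int]],
    rng: np.random.Generator | None = None,
    family: str = "sim",
) -> list[CrossRecord]:
    """Simulate fruit counts for a crossing design among offspring.

    ``design`` lists (maternal index, paternal index, n_pollinations)
    triples; fruit counts are binomial with the class-and-leak probability
    from ``model`` and the predicted class comes from the genotypes.
    """
    rng = np.random.default_rng(model.seed) if rng is None else rng
    records = []
    for mi, pi, n_poll in design:
        if not (0 <= mi < len(offspring) and 0 <= pi < len(offspring)):
            raise IndexError(f"design references invalid offspring index ({mi}, {pi})")
        if n_poll < 0:
            raise ValueError("n_pollinations must be nonnegative")
        mat, pat = offspring[mi], offspring[pi]
        predicted = predict_cross_phenotype(mat, pat)
        p_fruit = model.fruit_probability(predicted, mat, pat)
        n_fruit = int(rng.binomial(n_poll, p_fruit)) if n_poll else 0
        records.append(
            CrossRecord(
                family=family,
                maternal=mat,
                paternal=pat,
                n_pollinations=n_poll,
                n_fruit=n_fruit,
                predicted=predicted,
                maternal_id=str(mi),
                paternal_id=str(pi),
                ambiguous_genotype=mat.is_ambiguous or pat.is_ambiguous,
            )
        )
    return records


def _record(
    family: str,
    maternal: str,
    paternal: str,
    fruit: int,
    polls: int,
    predicted: str,
    ambiguous: bool = False,
) -> CrossRecord:
    return CrossRecord(
        family=family,
        maternal=Genotype.parse(maternal),
        paternal=Genotype.parse(paternal),
        n_pollinations=polls,
        n_fruit=fruit,
        predicted=predicted,
        ambiguous_genotype=ambiguous,
    )


def table1_fixture() -> list[CrossRecord]:
    """Published fruit-set table for the Argemone munita full-sib families.

    Family 8-1 parents were S8a S8b x S1c S1d; family 25-4 parents were
    S25a S25b x S4a S4d.  Row totals: predicted-incompatible 0/15 (8-1)
    and 20/77 (25-4); predicted semi-compatible 64/64.
    """
    inc, semi = INCOMPATIBLE, SEMI_COMPATIBLE
    return [
        _record("8-1", "S8a+S1c", "S8a+S1c", 0, 7, inc),
        _record("8-1", "S8b+S1d", "S8b+S1d", 0, 5, inc),
        _record("8-1", "S8b+S1c", "S8b+S1c", 0, 3, inc),
        _record("25-4", "S25a+S4a", "S25a+S4a", 0, 32, inc),
        _record("25-4", "S25b+S4a", "S25b+S4a", 8, 16, inc),
        _record("25-4", "S25a+S4d", "S25a+S4d", 0, 11, inc),
        _record("25-4", "S25b+S4d", "S25b+S4d", 12, 18, inc),
        _record("8-1", "S8a+S1c", "S8b+S1c", 7, 7, semi),
        _record("8-1", "S8a+S1d", "S8b+S1d", 7, 7, semi),
        _record("25-4", "S4a+S25a", "S4d+S25a", 20, 20, semi),
        _record("25-4", "S4a+S25a", "S4a+S25b", 12, 12, semi),
        _record("25-4", "S4a+S25b", "S4d+S25b", 18, 18, semi),
    ]


def table2_fixture() -> list[CrossRecord]:
    """Published fruit-set table for the Platystemon californicus families.

    Family 1-3 parents were S1a S1b x S3a,b S3c (S3a,b a linked pair);
    family 1-2 parents were S1a S1b x S2d,e S2? (alternative paternal
    product never amplified).  The 10/23 row crosses plants with only one
    recorded product (S1b*): it is tabulated predicted-incompatible as
    published but flagged as ambiguously genotyped, and the paternal
    unknown in family 1-2 is encoded as an explicit "S2?" haplotype.
    Row totals: incompatible 11/81 (1-3) and 5/48 (1-2); semi 56/60.
    """
    inc, semi = INCOMPATIBLE, SEMI_COMPATIBLE
    records = [
        _record("1-3", "S1a+S3ab", "S1a+S3ab", 0, 33, inc),
        _record("1-3", "S1b+S3ab", "S1b+S3ab", 0, 17, inc),
        _record("1-3", "S1a+S3c", "S1a+S3c", 1, 8, inc),
        CrossRecord(
            family="1-3",
            maternal=Genotype(["S1b"]),
            paternal=Genotype(["S1b"]),
            n_pollinations=23,
            n_fruit=10,
            predicted=inc,
            ambiguous_genotype=True,
        ),
        _record("1-2", "S1a+S2de", "S1a+S2de", 4, 18, inc),
        _record("1-2", "S1b+S2de", "S1b+S2de", 1, 13, inc),
        _record("1-2", "S1a+S1b", "S1a+S1b", 0, 17, inc),  # F2 cross
        _record("1-3", "S1a+S3ab", "S1a+S3c", 16, 17, semi),
        _record("1-3", "S1b+S3ab", "S1b+S3c", 18, 20, semi),
        _record("1-3", "S1a+S3ab", "S1b+S3ab", 7, 7, semi),
        _record("1-2", "S1b+S2de", "S1b+S2?", 5, 5, semi),
        _record("1-2", "S1a+S2de", "S1b+S2de", 10, 11, semi),
    ]
    return records


#: linked co-segregating product groups behind the collapsed haplotype units
LINKED_GROUPS = {
    "S3ab": frozenset({"S3a", "S3b"}),
    "S2de": frozenset({"S2d", "S2e"}),
}


def planted_diversity_alignment(
    n: int,
    L: int,
    hot_region: tuple[int, int],
    pi_in: float,
    pi_out: float,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Alignment with a planted high-diversity region (test surface).

    Each column is independently either monomorphic or biallelic with a
    minor-allele count chosen so the expected per-column heterozygosity
    matches the target (``pi_in`` inside the 1-based inclusive
    ``hot_region``, ``pi_out`` elsewhere).  Realised global pi concentrates
    within ~10% of the target for L >= 300, n >= 10.
    """
    rng = np.random.default_rng() if rng is None else rng
    if n < 2 or L < 1:
        raise ValueError("need n >= 2 sequences and L >= 1 sites")
    lo, hi = hot_region
    if not (1 <= lo <= hi <= L):
        raise ValueError("hot_region must lie within [1, L]")
    if not 0.0 <= pi_out <= pi_in:
        raise ValueError("require 0 <= pi_out <= pi_in")

    def h(k: int) -> float:  # heterozygosity of a biallelic column
        return 2.0 * k * (n - k) / (n * (n - 1))

    h_max = h(n // 2)
    if pi_in > h_max:
        raise ValueError(f"pi_in = {pi_in} unattainable with n = {n} (max {h_max:.3f})")

    def column(target: float) -> np.ndarray:
        base = rng.integers(4)
        col = np.full(n, base, dtype=np.int8)
        if target > 0:
            k = next(k for k in range(1, n // 2 + 1) if h(k) >= target)
            if rng.random() < target / h(k):
                alt = (base + rng.integers(1, 4)) % 4
                rows = rng.choice(n, size=k, replace=False)
                col[rows] = alt
        return col

    cols = [
        column(pi_in if lo <= j + 1 <= hi else pi_out) for j in range(L)
    ]
    arr = _BASES[np.column_stack(cols)]
    return ["".join(row) for row in arr]
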