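"""Structured coalescent for S-allele samples contaminated by a pseudogene.

The model treats the allelic genealogy of functional S-alleles under
long-term balancing selection as a neutral coalescent with effective size
inflated by a scaling factor ``f`` (time measured in units of ``4 N_e f``
generations, so a pair of S-lineages coalesces at rate 1).  A duplicated,
non-functional paralog ("pseudogene", class P) created ``t_d`` time units
ago is released from both balancing selection and recombination
suppression: its lineages coalesce at the faster rate ``f`` (relative
effective size ``1/f``, matching ``theta_p = theta_s / f``) and recombine
between adjacent sites at scaled rate ``rho_site = theta_s * (r/mu)`` per
interval, but only more recently than the duplication.  A severe bottleneck
of duration ``t_b`` immediately ancestral to ``t_d`` (pair-coalescence rate
``theta_s / theta_b``) collapses surviving pseudogene lineages to
(effectively) the single duplicated origin, after which they rejoin the
S-allele class.  A sample of ``n_sample`` sequences contains a proportion
``c`` of pseudogene contaminants.

Sequences evolve along the resulting marginal genealogies under
Jukes-Cantor, with branch lengths converted to expected substitutions per
site as ``time * theta_s / 2``.

The backward-in-time event loop is compiled with numba; it records one
merge per (site, coalescence) so marginal trees are reconstructed exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from numba import njit

from slocus import ld as _ld

_BASES = np.array(["A", "C", "G", "T"])

#: parameter values of the published factorial simulation design
PAPER_GRID = {
    "theta_s": (0.01, 0.1, 0.2, 0.3, 1.0, 2.0),
    "t_d": (0.01, 0.1, 1.0, 2.0, 3.0),
    "r_over_mu": (2.0, 20.0, 60.0, 100.0, 200.0, 2000.0),
    "c": (0.25, 0.5, 0.75),
}

#: reduced factorial design used for desk-scale reproduction of the
#: detection-ceiling claim
REDUCED_GRID = {
    "theta_s": (0.1, 1.0),
    "t_d": (0.1, 1.0),
    "r_over_mu": (20.0, 200.0),
    "c": (0.25, 0.75),
}


def default_theta_b(theta_s: float) -> float:
    """Published bottleneck-severity rule: theta_b = theta_s / 2,000,000."""
    return theta_s / 2_000_000.0


@dataclass(frozen=True)
class SimParams:
    """All simulation parameters.

    Times (``t_d``, ``t_b``) are in coalescent units of ``4 N_e f``
    generations; ``theta_s`` and ``theta_b`` are per-site; ``r_over_mu`` is
    the ratio of per-generation recombination to mutation rate, giving the
    per-adjacent-site scaled recombination rate ``theta_s * r_over_mu``.
    """

    theta_s: float = 0.1
    t_d: float = 1.0
    r_over_mu: float = 20.0
    c: float = 0.5
    f: float = 20.0
    t_b: float = 0.005
    theta_b: float | None = None
    n_sample: int = 24
    L: int = 327
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.theta_s <= 0:
            raise ValueError("theta_s must be positive")
        if self.f < 1:
            raise ValueError("f must be >= 1")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("c must lie in [0, 1]")
        if self.t_d <= 0:
            raise ValueError("t_d must be positive")
        if self.t_b < 0:
            raise ValueError("t_b must be nonnegative")
        if self.r_over_mu < 0:
            raise ValueError("r_over_mu must be nonnegative")
        if self.n_sample < 2:
            raise ValueError("need at least 2 sampled sequences")
        if self.L < 1:
            raise ValueError("L must be positive")
        if self.theta_b is not None and self.theta_b > self.theta_s:
            raise ValueError("theta_b must not exceed theta_s")

    @property
    def theta_p(self) -> float:
        """Per-site mutation parameter of the pseudogene (theta_s / f)."""
        return self.theta_s / self.f

    @property
    def theta_b_effective(self) -> float:
        return default_theta_b(self.theta_s) if self.theta_b is None else self.theta_b

    @property
    def rho_site(self) -> float:
        """Scaled recombination rate per adjacent-site interval."""
        return self.theta_s * self.r_over_mu

    @property
    def n_contaminant(self) -> int:
        n_p = int(round(self.c * self.n_sample))
        if not 0 <= n_p <= self.n_sample:
            raise ValueError("c * n_sample outside [0, n_sample]")
        return n_p


class MarginalTreeSet:
    """Marginal genealogies of all sites, in compact merge-record form.

    For each site the ``n_sample - 1`` coalescences are stored in time
    order as ``(parent, child1, child2)`` node-id triples; node times are
    in coalescent units.  Tips are node ids ``0 .. n_sample-1`` with time 0.
    """

    def __init__(
        self,
        n_sample: int,
        L: int,
        parent: np.ndarray,
        child1: np.ndarray,
        child2: np.ndarray,
        node_time: np.ndarray,
    ) -> None:
        self.n_sample = int(n_sample)
        self.L = int(L)
        self.parent = parent  # (L, n-1) int32
        self.child1 = child1
        self.child2 = child2
        self.node_time = node_time

    def segments(self) -> list[tuple[int, int]]:
        """Half-open site intervals sharing one genealogy."""
        if self.L == 1:
            return [(0, 1)]
        recs = np.stack([self.parent, self.child1, self.child2], axis=2)
        same = (recs[1:] == recs[:-1]).all(axis=(1, 2))
        bounds = [0] + list(np.nonzero(~same)[0] + 1) + [self.L]
        return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]

    @property
    def num_trees(self) -> int:
        return len(self.segments())

    def tmrca(self, site: int) -> float:
        return float(self.node_time[self.parent[site, -1]])

    def tree_length(self, site: int) -> float:
        """Total branch length of the site's marginal tree."""
        total = 0.0
        tp = self.node_time[self.parent[site]]
        for child in (self.child1[site], self.child2[site]):
            tc = np.where(child < self.n_sample, 0.0, self.node_time[child])
            total += float(np.sum(tp - tc))
        return total

    def to_newick(self, site: int, label: Callable[[int], str] = str) -> str:
        """Newick string (branch lengths in coalescent units) for one site."""
        children: dict[int, list[int]] = {}
        for k in range(self.n_sample - 1):
            p = int(self.parent[site, k])
            children[p] = [int(self.child1[site, k]), int(self.child2[site, k])]

        def t_of(v: int) -> float:
            return 0.0 if v < self.n_sample else float(self.node_time[v])

        def render(v: int) -> str:
            if v not in children:
                return label(v)
            parts = ",".join(
                f"{render(u)}:{t_of(v) - t_of(u):.8g}" for u in children[v]
            )
            return f"({parts})"

        root = int(self.parent[site, -1])
        return render(root) + ";"


@dataclass
class SequenceSample:
    """Simulated nucleotide alignment with per-sequence source labels."""

    alignment: np.ndarray  # (n, L) of single characters A/C/G/T
    source_labels: list[str]  # per-sequence "S" or "P"
    n_mutations: int = 0
    params: SimParams | None = None

    @property
    def sequences(self) -> list[str]:
        return ["".join(row) for row in self.alignment]

    @property
    def ids(self) -> list[str]:
        return [f"sim_{i}|{lab}" for i, lab in enumerate(self.source_labels)]


@njit(cache=True)
def _arg_kernel(n, L, n_p, f, t_d, t_b, bneck_rate, rho_int, seed):
    """Backward-in-time event loop.  Returns flat merge records.

    Classes: 0 = S (functional, pair rate 1, no recombination),
    1 = P (pseudogene, pair rate f, recombining while t < t_d).
    A site is dropped from the surviving lineage once its marginal MRCA is
    reached, so the loop ends when no ancestral material remains.
    """
    np.random.seed(seed)
    M = n * L + 2
    nrec_max = (n - 1) * L
    node = np.full((M, L), -1, dtype=np.int32)
    lmin = np.zeros(M, dtype=np.int32)
    lmax = np.zeros(M, dtype=np.int32)
    nsites = np.zeros(M, dtype=np.int64)
    pos = np.zeros(M, dtype=np.int64)
    act = np.zeros((2, M), dtype=np.int32)
    nact = np.zeros(2, dtype=np.int64)
    free = np.empty(M, dtype=np.int32)
    nfree = 0
    for r in range(M - 1, n - 1, -1):
        free[nfree] = r
        nfree += 1
    lps = np.full(L, n, dtype=np.int32)  # active lineages carrying each site
    # P-class carrier counts per site.  Once a site has a single P carrier,
    # P-internal recombination and coalescence can record nothing for it,
    # and when the bottleneck makes pairwise coalescence certain
    # (rate * t_b enormous) all P material provably ends in one lineage at
    # the duplication time.  Such sites are therefore parked in a frozen
    # "reservoir" lineage immediately -- an exact shortcut that strips
    # resolved sites out of the recombination/coalescence churn.
    lps_p = np.full(L, n_p, dtype=np.int32)
    collapse_ok = bneck_rate * t_b > 40.0
    rec_site = np.empty(nrec_max, dtype=np.int32)
    rec_parent = np.empty(nrec_max, dtype=np.int32)
    rec_c1 = np.empty(nrec_max, dtype=np.int32)
    rec_c2 = np.empty(nrec_max, dtype=np.int32)
    node_time = np.zeros(n + nrec_max, dtype=np.float64)
    n_nodes = n
    n_rec = 0
    span_p = 0
    resv = -1
    if collapse_ok and n_p >= 1:
        if n_p == 1:
            resv = 0  # the lone P tip is itself frozen until the class merge
        else:
            resv = free[nfree - 1]
            nfree -= 1
            lmin[resv] = L
            lmax[resv] = -1
            nsites[resv] = 0
    for i in range(n):
        for s in range(L):
            node[i, s] = i
        lmin[i] = 0
        lmax[i] = L - 1
        nsites[i] = L
        if i == resv:
            continue  # frozen: never joins an activity stack
        k = 1 if i < n_p else 0
        pos[i] = nact[k]
        act[k, nact[k]] = i
        nact[k] += 1
        if k == 1:
            span_p += L - 1
    t = 0.0
    epoch = 0
    t_merge = t_d + t_b
    while nact[0] + nact[1] > 0:
        n_s = nact[0]
        n_pp = nact[1]
        coal_s = 0.5 * n_s * (n_s - 1)
        if epoch == 0:
            coal_p = 0.5 * n_pp * (n_pp - 1) * f
            rec_rate = rho_int * span_p
            boundary = t_d
        elif epoch == 1:
            coal_p = 0.5 * n_pp * (n_pp - 1) * bneck_rate
            rec_rate = 0.0
            boundary = t_merge
        else:
            coal_p = 0.0
            rec_rate = 0.0
            boundary = 1.0e300
        total = coal_s + coal_p + rec_rate
        advance = False
        if total <= 0.0:
            advance = True
        else:
            dt = np.random.exponential(1.0 / total)
            if epoch < 2 and t + dt >= boundary:
                advance = True
            else:
                t += dt
        if advance:
            if epoch >= 2:  # defensive: cannot occur
                break
            t = boundary
            epoch += 1
            if epoch == 2:
                # duplication origin reached: pseudogene lineages rejoin S
                for idx in range(nact[1]):
                    r = act[1, idx]
                    pos[r] = nact[0]
                    act[0, nact[0]] = r
                    nact[0] += 1
                nact[1] = 0
                span_p = 0
                if resv >= 0 and nsites[resv] > 0:
                    pos[resv] = nact[0]
                    act[0, nact[0]] = resv
                    nact[0] += 1
                resv = -1
            continue
        u = np.random.random() * total
        if u < coal_s + coal_p:
            k = 0 if u < coal_s else 1
            m = nact[k]
            i = np.random.randint(0, m)
            j = np.random.randint(0, m - 1)
            if j >= i:
                j += 1
            A = act[k, i]
            B = act[k, j]
            # pop B
            pj = pos[B]
            last = act[k, nact[k] - 1]
            act[k, pj] = last
            pos[last] = pj
            nact[k] -= 1
            old_span = (lmax[A] - lmin[A]) + (lmax[B] - lmin[B])
            newnode = -1
            copied = 0
            dropped = 0
            for s in range(lmin[B], lmax[B] + 1):
                b = node[B, s]
                if b < 0:
                    continue
                node[B, s] = -1
                a = node[A, s]
                if a < 0:
                    node[A, s] = b
                    copied += 1
                else:
                    if newnode < 0:
                        newnode = n_nodes
                        n_nodes += 1
                        node_time[newnode] = t
                    rec_site[n_rec] = s
                    rec_parent[n_rec] = newnode
                    rec_c1[n_rec] = a
                    rec_c2[n_rec] = b
                    n_rec += 1
                    cc = lps[s] - 1
                    lps[s] = cc
                    park = False
                    if k == 1:
                        cp = lps_p[s] - 1
                        lps_p[s] = cp
                        park = cp == 1 and resv >= 0 and cc > 1
                    if cc == 1:
                        node[A, s] = -1  # marginal MRCA reached
                        dropped += 1
                    elif park:
                        node[resv, s] = newnode
                        node[A, s] = -1
                        dropped += 1
                        nsites[resv] += 1
                        if s < lmin[resv]:
                            lmin[resv] = s
                        if s > lmax[resv]:
                            lmax[resv] = s
                    else:
                        node[A, s] = newnode
            ns = nsites[A] + copied - dropped
            nsites[A] = ns
            nsites[B] = 0
            free[nfree] = B
            nfree += 1
            if k == 1:
                span_p -= old_span
            if ns > 0:
                lo = lmin[A] if lmin[A] < lmin[B] else lmin[B]
                hi = lmax[A] if lmax[A] > lmax[B] else lmax[B]
                while node[A, lo] < 0:
                    lo += 1
                while node[A, hi] < 0:
                    hi -= 1
                lmin[A] = lo
                lmax[A] = hi
                if k == 1:
                    span_p += hi - lo
            else:
                pa = pos[A]
                last = act[k, nact[k] - 1]
                act[k, pa] = last
                pos[last] = pa
                nact[k] -= 1
                free[nfree] = A
                nfree += 1
        else:
            # recombination on a P-class lineage, breakpoint within its span
            x = np.random.random() * span_p
            acc = 0.0
            R = act[1, nact[1] - 1]
            for idx in range(nact[1]):
                r = act[1, idx]
                acc += lmax[r] - lmin[r]
                if x < acc:
                    R = r
                    break
            bp = np.random.randint(lmin[R] + 1, lmax[R] + 1)
            C = free[nfree - 1]
            nfree -= 1
            cnt = 0
            hi_old = lmax[R]
            for s in range(bp, hi_old + 1):
                v = node[R, s]
                if v >= 0:
                    node[C, s] = v
                    node[R, s] = -1
                    cnt += 1
            old_span = hi_old - lmin[R]
            lo_c = bp
            while node[C, lo_c] < 0:
                lo_c += 1
            lmin[C] = lo_c
            lmax[C] = hi_old
            nsites[C] = cnt
            nsites[R] -= cnt
            hi_r = bp - 1
            while node[R, hi_r] < 0:
                hi_r -= 1
            lmax[R] = hi_r
            pos[C] = nact[1]
            act[1, nact[1]] = C
            nact[1] += 1
            span_p += (lmax[R] - lmin[R]) + (hi_old - lo_c) - old_span
    return rec_site, rec_parent, rec_c1, rec_c2, node_time, n_nodes, n_rec


def _resolve_rng(
    rng: np.random.Generator | None, params: SimParams
) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(params.seed)


def simulate_arg(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[MarginalTreeSet, list[str]]:
    """Simulate the ancestral process and return marginal trees plus labels.

    The first ``round(c * n_sample)`` samples are pseudogene contaminants
    (label ``"P"``); sample order is otherwise arbitrary because lineages
    are exchangeable within a class.
    """
    n, L = params.n_sample, params.L
    n_p = params.n_contaminant
    rng = _resolve_rng(rng, params)
    seed = int(rng.integers(1, 2**31 - 1))
    bneck_rate = params.theta_s / params.theta_b_effective
    rec_site, rec_parent, rec_c1, rec_c2, node_time, n_nodes, n_rec = _arg_kernel(
        n, L, n_p, params.f, params.t_d, params.t_b, bneck_rate, params.rho_site, seed
    )
    if n_rec != (n - 1) * L:  # pragma: no cover - internal consistency
        raise RuntimeError("ancestral process ended with unresolved sites")
    order = np.argsort(rec_site, kind="stable")
    shape = (L, n - 1)
    trees = MarginalTreeSet(
        n,
        L,
        rec_parent[order].reshape(shape),
        rec_c1[order].reshape(shape),
        rec_c2[order].reshape(shape),
        node_time[:n_nodes].copy(),
    )
    labels = ["P"] * n_p + ["S"] * (n - n_p)
    return trees, labels


def evolve_sequences(
    trees: MarginalTreeSet,
    params: SimParams,
    rng: np.random.Generator | None = None,
    source_labels: Sequence[str] | None = None,
) -> SequenceSample:
    """Evolve Jukes-Cantor sequences along each site's marginal genealogy.

    Mutations are Poisson with per-site rate ``theta_s / 2`` per unit
    branch time; each mutation replaces the current base of the affected
    subtree with one of the three alternatives, and root states are drawn
    from the uniform stationary distribution.
    """
    n, L = trees.n_sample, trees.L
    rng = _resolve_rng(rng, params)
    half_theta = params.theta_s / 2.0
    nt = trees.node_time
    t_parent = nt[trees.parent]  # (L, n-1)
    children = np.stack([trees.child1, trees.child2], axis=2)  # (L, n-1, 2)
    t_child = nt[children]  # tips 0..n-1 have time 0 in node_time
    lengths = t_parent[:, :, None] - t_child
    n_mut = rng.poisson(lengths * half_theta)
    aln = np.tile(rng.integers(0, 4, size=L, dtype=np.int8), (n, 1))
    total_mut = int(n_mut.sum())
    if total_mut:
        sites = np.unique(np.nonzero(n_mut)[0])
        for s in sites:
            masks: dict[int, np.ndarray] = {}

            def tip_mask(v: int) -> np.ndarray:
                got = masks.get(v)
                if got is None:
                    got = np.zeros(n, dtype=bool)
                    got[v] = True
                return got

            for k in range(n - 1):
                m = tip_mask(int(trees.child1[s, k])) | tip_mask(int(trees.child2[s, k]))
                masks[int(trees.parent[s, k])] = m
            events: list[tuple[float, int]] = []
            for k, w in zip(*np.nonzero(n_mut[s])):
                child = int(children[s, k, w])
                lo, hi = float(t_child[s, k, w]), float(t_parent[s, k])
                for tm in rng.uniform(lo, hi, size=int(n_mut[s, k, w])):
                    events.append((float(tm), child))
            events.sort(key=lambda e: -e[0])  # oldest first, root to tips
            for _, child in events:
                rows = np.nonzero(tip_mask(child))[0]
                cur = aln[rows[0], s]
                aln[rows, s] = (cur + rng.integers(1, 4)) % 4
    labels = (
        list(source_labels)
        if source_labels is not None
        else ["S"] * n
    )
    return SequenceSample(
        alignment=_BASES[aln],
        source_labels=labels,
        n_mutations=total_mut,
        params=params,
    )


def simulate_sample(
    params: SimParams, rng: np.random.Generator | None = None
) -> SequenceSample:
    """Simulate a contaminated sequence sample end to end.

    Deterministic given ``params.seed`` (or a supplied generator).
    """
    rng = _resolve_rng(rng, params)
    trees, labels = simulate_arg(params, rng)
    return evolve_sequences(trees, params, rng, source_labels=labels)


def run_grid(
    theta_s_values: Sequence[float] = REDUCED_GRID["theta_s"],
    t_d_values: Sequence[float] = REDUCED_GRID["t_d"],
    r_over_mu_values: Sequence[float] = REDUCED_GRID["r_over_mu"],
    c_values: Sequence[float] = REDUCED_GRID["c"],
    f: float = 20.0,
    t_b: float = 0.005,
    theta_b_rule: Callable[[float], float] = default_theta_b,
    n_sample: int = 24,
    L: int = 327,
    reps: int = 1000,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    progress: Callable[[str], None] | None = None,
) -> pd.DataFrame:
    """Detection proportion of the LD-distance permutation test over a grid.

    For every factorial combination, ``reps`` samples are simulated and the
    fraction with permutation p-value <= ``alpha`` is reported with its
    binomial standard error.  Each combination uses a subseed derived
    deterministically from ``seed``, so results are reproducible and
    independent of combination order.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    combos = list(
        itertools.product(theta_s_values, t_d_values, r_over_mu_values, c_values)
    )
    if not combos:
        raise ValueError("empty parameter grid")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(combos))
    rows = []
    for (theta_s, t_d, r_over_mu, c), child in zip(combos, children):
        rng = np.random.default_rng(child)
        params = SimParams(
            theta_s=theta_s,
            t_d=t_d,
            r_over_mu=r_over_mu,
            c=c,
            f=f,
            t_b=t_b,
            theta_b=theta_b_rule(theta_s),
            n_sample=n_sample,
            L=L,
        )
        detections = 0
        for _ in range(reps):
            sample = simulate_sample(params, rng)
            result = _ld.detect_recombination(
                sample, alpha=alpha, n_perm=n_perm, rng=rng
            )
            detections += int(result.detected)
        prop = detections / reps
        se = float(np.sqrt(prop * (1.0 - prop) / reps))
        rows.append(
            {
                "theta_s": theta_s,
                "t_d": t_d,
                "r_over_mu": r_over_mu,
                "c": c,
                "f": f,
                "t_b": t_b,
                "theta_b": params.theta_b_effective,
                "reps": reps,
                "detections": detections,
                "proportion": prop,
                "se": se,
            }
        )
        if progress is not None:
            progress(
                f"theta_s={theta_s} t_d={t_d} r/mu={r_over_mu} c={c}: "
                f"{detections}/{reps} detected ({prop:.3f} +/- {se:.3f})"
            )
    return pd.DataFrame(rows)
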