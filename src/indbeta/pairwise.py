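"""Pairwise (two-census) dissimilarity components and indices.

For a pair of census units j < k the classical incidence components are
a (shared species), b (species only in j) and c (species only in k), and the
abundance components A = sum_i min(x_ij, x_ik), B, C are their
individual-count analogues. When individuals are tracked, the same
min/complement construction applied to 0/1 occupancy vectors yields
P (persistent individuals), M (mortality: present at j, gone by k) and
R (recruitment: absent at j, present at k).

The indices are

    d_sor = (b+c)/(2a+b+c)        Sorensen dissimilarity
    d_bc  = (B+C)/(2A+B+C)        Bray-Curtis (percentage difference)
    d_mr  = (M+R)/(2P+M+R)        individual turnover rate
    v_s   = (B+C)/(M+R)           fraction of turnover shifting composition

Because conspecific replacement (E = E_loss = E_gain = A - P) inflates A
relative to P without changing composition, d_bc <= d_mr always, and
v_s = d_bc / d_mr exactly wherever both are defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._values import IndexValue, ratio
from .census import AbundanceMatrix, Census, to_abundance_matrix

__all__ = [
    "PairwiseComponents",
    "species_components",
    "abundance_components",
    "individual_components",
    "pairwise_components",
    "d_sor",
    "d_bc",
    "d_mr",
    "v_s",
    "all_pairs",
    "PairwiseTable",
    "PAIRWISE_INDICES",
]


@dataclass(frozen=True)
class PairwiseComponents:
    """All integer components for one ordered census pair (j before k).

    E_loss (= M - B) counts lost individuals replaced by conspecifics, and
    E_gain (= R - C) the replacing recruits; the two are always equal and
    equal A - P.
    """

    unit_j: object
    unit_k: object
    a: int
    b: int
    c: int
    A: int
    B: int
    C: int
    P: int
    M: int
    R: int

    @property
    def E_loss(self) -> int:
        return self.M - self.B

    @property
    def E_gain(self) -> int:
        return self.R - self.C

    @property
    def E(self) -> int:
        """Conspecific-replacement (compositional equilibrium) component."""
        return self.E_loss


def species_components(abund: AbundanceMatrix, j, k) -> tuple[int, int, int]:
    """Incidence components (a, b, c) for units j and k."""
    cj = abund.counts[:, abund.unit_index(j)] > 0
    ck = abund.counts[:, abund.unit_index(k)] > 0
    return int((cj & ck).sum()), int((cj & ~ck).sum()), int((~cj & ck).sum())


def abundance_components(abund: AbundanceMatrix, j, k) -> tuple[int, int, int]:
    """Abundance components (A, B, C) for units j and k."""
    xj = abund.counts[:, abund.unit_index(j)]
    xk = abund.counts[:, abund.unit_index(k)]
    m = np.minimum(xj, xk)
    return int(m.sum()), int((xj - m).sum()), int((xk - m).sum())


def individual_components(census: Census, j, k) -> tuple[int, int, int, int, int]:
    """Individual components (P, M, R, E_loss, E_gain) for units j and k.

    P, M and R are the occupancy-vector analogues of A, B and C;
    E_loss = M - B and E_gain = R - C count turnover of conspecifics.
    """
    comp = pairwise_components(census, j, k)
    return comp.P, comp.M, comp.R, comp.E_loss, comp.E_gain


def pairwise_components(census: Census, j, k) -> PairwiseComponents:
    """Compute every pairwise component for one census pair."""
    tj, tk = census.unit_index(j), census.unit_index(k)
    zj = census.occupancy[:, tj].astype(np.int64)
    zk = census.occupancy[:, tk].astype(np.int64)
    P = int((zj & zk).sum())
    M = int((zj & ~zk & 1).sum())
    R = int((~zj & 1 & zk).sum())
    abund = to_abundance_matrix(census)
    a, b, c = species_components(abund, j, k)
    A, B, C = abundance_components(abund, j, k)
    return PairwiseComponents(j, k, a, b, c, A, B, C, P, M, R)


def d_sor(a: int, b: int, c: int) -> IndexValue:
    """Sorensen dissimilarity (b+c)/(2a+b+c)."""
    return ratio(b + c, 2 * a + b + c, "no species in either unit")


def d_bc(A: int, B: int, C: int) -> IndexValue:
    """Bray-Curtis (percentage difference) dissimilarity (B+C)/(2A+B+C)."""
    return ratio(B + C, 2 * A + B + C, "both units empty")


def d_mr(P: int, M: int, R: int) -> IndexValue:
    """Individual-turnover dissimilarity (M+R)/(2P+M+R)."""
    return ratio(M + R, 2 * P + M + R, "both units empty")


def v_s(components: PairwiseComponents) -> IndexValue:
    """Compositional-shift fraction of individual turnover, (B+C)/(M+R).

    Equals d_bc / d_mr wherever both are defined; 0 means all turnover was
    conspecific replacement (dynamic equilibrium), 1 means every lost or
    gained individual shifted species composition.
    """
    return ratio(components.B + components.C,
                 components.M + components.R,
                 "no individual turnover")


def _index_from_components(which: str, comp: PairwiseComponents) -> IndexValue:
    if which == "sor":
        return d_sor(comp.a, comp.b, comp.c)
    if which == "bc":
        return d_bc(comp.A, comp.B, comp.C)
    if which == "mr":
        return d_mr(comp.P, comp.M, comp.R)
    if which == "vs":
        return v_s(comp)
    raise ValueError(f"unknown index {which!r}; expected one of {PAIRWISE_INDICES}")


PAIRWISE_INDICES = ("sor", "bc", "mr", "vs")


@dataclass(frozen=True)
class PairwiseTable:
    """All-pairs index values plus their mean over defined pairs."""

    index: str
    table: pd.DataFrame
    mean: float
    n_pairs: int
    n_undefined: int


def all_pairs(census: Census, which: str = "mr") -> PairwiseTable:
    """Evaluate one index for every census pair j < k (declared unit order).

    Returns the T(T-1)/2 pair values and their mean; undefined pairs are
    excluded from the mean and counted in ``n_undefined``.
    """
    rows = []
    values = []
    n_undef = 0
    for tj in range(census.n_units):
        for tk in range(tj + 1, census.n_units):
            comp = pairwise_components(census, census.units[tj], census.units[tk])
            val = _index_from_components(which, comp)
            rows.append({
                "unit_j": census.units[tj],
                "unit_k": census.units[tk],
                "index": which,
                "value": val.value,
                "defined": val.defined,
            })
            if val.defined:
                values.append(val.value)
            else:
                n_undef += 1
    table = pd.DataFrame(rows, columns=["unit_j", "unit_k", "index", "value", "defined"])
    mean = float(np.mean(values)) if values else float("nan")
    return PairwiseTable(which, table, mean, len(rows), n_undef)
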