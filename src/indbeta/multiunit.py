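"""Multiple-unit dissimilarity components and individual-based indices.

Averaging pairwise dissimilarities over all census pairs cannot see
components shared by three or more censuses; a long-lived individual that
spans every census contributes to every pair yet is a single organism. The
multiple-unit construction counts such shared components once, via the
inclusion-exclusion principle, on three scales:

* species incidence: a_mu, b_mu, c_mu
* species abundance:  A_mu, B_mu, C_mu
* tracked individuals: P_mu, M_mu, R_mu

Inclusion-exclusion over all unit subsets collapses to closed forms:

    a_mu = sum_j S_j - S_T          (S_j per-unit richness, S_T pooled)
    A_mu = T_AB - sum_i max_j x_ij  (T_AB grand total abundance)
    P_mu = sum_j I_j - I_T          (I_j per-unit count, I_T individuals)

while the complement components symmetrize the pairwise exclusives:
b_mu = sum_{j<k} min(p_jk, p_kj), c_mu the max-analogue, where p_jk counts
species present at j and absent at k (q_jk: same for individuals).

The indices keep the familiar form x/(2*shared + x):

    d_sor_mu = (b_mu+c_mu)/(2a_mu+b_mu+c_mu)
    d_bc_mu  = (B_mu+C_mu)/(2A_mu+B_mu+C_mu)
    d_mr_mu  = (M_mu+R_mu)/(2P_mu+M_mu+R_mu)
    v_s_mu   = d_bc_mu / d_mr_mu

:func:`brute_force_shared` evaluates the alternating-sign subset sum
directly (2^T terms) and is kept in the public API so any census can be
audited against the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from ._values import IndexValue, ratio
from .census import AbundanceMatrix, Census, to_abundance_matrix

__all__ = [
    "MultiUnitComponents",
    "incidence_components",
    "abundance_mu_components",
    "individual_mu_components",
    "multiunit_components",
    "d_sor_mu",
    "d_bc_mu",
    "d_mr_mu",
    "v_s_mu",
    "brute_force_shared",
]


@dataclass(frozen=True)
class MultiUnitComponents:
    """The nine multiple-unit components of one census, as exact integers.

    ``p`` and ``q`` are the full matrices of pairwise exclusives
    (p[j, k] = species present at unit j and absent at unit k; q the
    individual analogue) kept for auditing.
    """

    a_mu: int
    b_mu: int
    c_mu: int
    A_mu: int
    B_mu: int
    C_mu: int
    P_mu: int
    M_mu: int
    R_mu: int
    p: np.ndarray = field(repr=False, default=None)
    q: np.ndarray = field(repr=False, default=None)


def _min_max_over_pairs(excl: np.ndarray) -> tuple[int, int]:
    """Sum min and max of (excl[j,k], excl[k,j]) over unordered pairs j<k."""
    t = excl.shape[0]
    lo = hi = 0
    for j in range(t):
        for k in range(j + 1, t):
            x, y = int(excl[j, k]), int(excl[k, j])
            lo += min(x, y)
            hi += max(x, y)
    return lo, hi


def incidence_components(abund: AbundanceMatrix) -> tuple[int, int, int]:
    """Species-incidence components (a_mu, b_mu, c_mu)."""
    a_mu = int(abund.S_j.sum()) - abund.S_T
    p = _exclusive_matrix(abund.counts)
    b_mu, c_mu = _min_max_over_pairs(p)
    return a_mu, b_mu, c_mu


def abundance_mu_components(abund: AbundanceMatrix) -> tuple[int, int, int]:
    """Species-abundance components (A_mu, B_mu, C_mu)."""
    x = abund.counts
    A_mu = abund.T_AB - int(x.max(axis=1).sum()) if x.size else 0
    t = len(abund.units)
    B_mu = C_mu = 0
    for j in range(t):
        for k in range(j + 1, t):
            m = np.minimum(x[:, j], x[:, k])
            Bjk = int((x[:, j] - m).sum())
            Cjk = int((x[:, k] - m).sum())
            B_mu += min(Bjk, Cjk)
            C_mu += max(Bjk, Cjk)
    return A_mu, B_mu, C_mu


def _exclusive_matrix(mat: np.ndarray) -> np.ndarray:
    """excl[j, k] = number of rows positive in column j and zero in column k."""
    pres = (mat > 0).astype(np.int64)
    shared = pres.T @ pres
    per_unit = pres.sum(axis=0)
    return per_unit[:, None] - shared


def individual_mu_components(census: Census) -> tuple[int, int, int]:
    """Individual-scale components (P_mu, M_mu, R_mu) from occupancy."""
    return _individual_mu_from_occupancy(census.occupancy)


def _individual_mu_from_occupancy(occ: np.ndarray) -> tuple[int, int, int]:
    occ = occ.astype(np.int64, copy=False)
    I_j = occ.sum(axis=0)
    P_mu = int(I_j.sum()) - occ.shape[0]
    q = I_j[:, None] - occ.T @ occ
    M_mu, R_mu = _min_max_over_pairs(q)
    return P_mu, M_mu, R_mu


def multiunit_components(census: Census) -> MultiUnitComponents:
    """All nine multiple-unit components of a census."""
    abund = to_abundance_matrix(census)
    a_mu, b_mu, c_mu = incidence_components(abund)
    A_mu, B_mu, C_mu = abundance_mu_components(abund)
    P_mu, M_mu, R_mu = individual_mu_components(census)
    p = _exclusive_matrix(abund.counts)
    q = _exclusive_matrix(census.occupancy)
    return MultiUnitComponents(a_mu, b_mu, c_mu, A_mu, B_mu, C_mu,
                               P_mu, M_mu, R_mu, p=p, q=q)


def d_sor_mu(c: MultiUnitComponents) -> IndexValue:
    """Multiple-unit Sorensen dissimilarity."""
    return ratio(c.b_mu + c.c_mu, 2 * c.a_mu + c.b_mu + c.c_mu,
                 "no species in any unit pair")


def d_bc_mu(c: MultiUnitComponents) -> IndexValue:
    """Multiple-unit Bray-Curtis dissimilarity."""
    return ratio(c.B_mu + c.C_mu, 2 * c.A_mu + c.B_mu + c.C_mu,
                 "all units empty")


def d_mr_mu(c: MultiUnitComponents) -> IndexValue:
    """Multiple-unit individual-turnover dissimilarity."""
    return ratio(c.M_mu + c.R_mu, 2 * c.P_mu + c.M_mu + c.R_mu,
                 "all units empty")


def v_s_mu(c: MultiUnitComponents) -> IndexValue:
    """Multiple-unit compositional-shift fraction, d_bc_mu / d_mr_mu."""
    bc = d_bc_mu(c)
    mr = d_mr_mu(c)
    if not bc.defined or not mr.defined:
        return IndexValue(None, "all units empty")
    if mr.fraction == 0:
        return IndexValue(None, "no individual turnover")
    return IndexValue(bc.fraction / mr.fraction)


def brute_force_shared(matrix: np.ndarray, scale: str = "individual") -> int:
    """Shared multiple-unit component by direct inclusion-exclusion.

    Evaluates the alternating-sign sum over all unit subsets of size >= 2:
    pairwise minima, minus triple minima, plus quadruple minima, and so on.
    Returns a_mu for scale="species" (rows are species, entries coerced to
    presence/absence), A_mu for scale="abundance" (rows are species counts),
    or P_mu for scale="individual" (rows are 0/1 occupancy vectors).

    O(2^T) in the number of units; limited to T <= 10. Slow by design: it is
    the audit path against which the closed forms are checked.
    """
    mat = np.asarray(matrix, dtype=np.int64)
    if mat.ndim != 2:
        raise ValueError("matrix must be 2-D (rows x units)")
    if scale not in ("species", "abundance", "individual"):
        raise ValueError(f"unknown scale {scale!r}")
    if scale in ("species", "individual"):
        mat = (mat > 0).astype(np.int64)
    t = mat.shape[1]
    if t > 10:
        raise ValueError("brute-force enumeration limited to 10 units (2^T subsets)")
    total = 0
    for size in range(2, t + 1):
        sign = 1 if size % 2 == 0 else -1
        for subset in combinations(range(t), size):
            total += sign * int(mat[:, subset].min(axis=1).sum())
    return total
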