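"""Randomization null model for individual persistence (P_ses.all).

The question the null model answers: given exactly the observed demographic
flows — how many individuals died and how many were recruited in each
inter-census interval — is the observed pattern of individual *persistence*
(who the deaths fell on) distinguishable from ecological drift, i.e. from
deaths striking currently-alive individuals uniformly at random?

Each randomization replays the census: it starts from the observed number of
initially alive individuals, kills the observed number of deaths per interval
by uniform sampling without replacement among those currently alive, and adds
the observed number of recruits as brand-new individuals (recruits are mortal
at later intervals). Per-unit alive counts I_t are reproduced exactly in
every replicate, so the persistence component P_mu = sum_t I_t - I_T is
conserved; only the cross-interval sharing behind M_mu and R_mu — hence
d_mr_mu — varies.

The standardized effect size is

    P_ses.all = (observed d_mr_mu - null mean) / null sd.

Sign convention: with the literal definition above, an excess of long-lived
individuals gives observed d_mr_mu *below* the null mean, i.e. a negative
score. Published analyses using this statistic have read positive scores as
excess persistence, which corresponds to the reversed orientation
(mean - observed); both are exposed via ``sign_convention`` and the default
is the literal definition ("as_stated").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .census import Census
from .multiunit import _individual_mu_from_occupancy
from ._values import ratio

__all__ = ["IntervalFlows", "SESResult", "interval_flows", "randomize_once", "p_ses_all"]


@dataclass(frozen=True)
class IntervalFlows:
    """Demographic flows of a census: alive counts, deaths and recruits.

    I[t] individuals alive at unit t; D[t] deaths and R[t] recruits in the
    interval (t, t+1), for t = 0..T-2. Conservation: I[t+1] = I[t] - D[t] + R[t].
    """

    I: tuple
    D: tuple
    R: tuple

    def __post_init__(self) -> None:
        I = tuple(int(v) for v in self.I)
        D = tuple(int(v) for v in self.D)
        R = tuple(int(v) for v in self.R)
        object.__setattr__(self, "I", I)
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "R", R)
        if len(I) < 2 or len(D) != len(I) - 1 or len(R) != len(I) - 1:
            raise ValueError("need T alive counts and T-1 death/recruit counts")
        if min(I) < 0 or (D and min(D) < 0) or (R and min(R) < 0):
            raise ValueError("flow counts must be non-negative")
        for t, (d, r) in enumerate(zip(D, R)):
            if d > I[t]:
                raise ValueError(f"interval {t}: more deaths ({d}) than alive ({I[t]})")
            if I[t + 1] != I[t] - d + r:
                raise ValueError(f"interval {t}: I[t+1] != I[t] - D[t] + R[t]")

    @property
    def n_units(self) -> int:
        return len(self.I)

    @property
    def total_individuals(self) -> int:
        """Distinct individuals implied by the flows: I_0 + total recruits."""
        return self.I[0] + sum(self.R)


def interval_flows(census: Census) -> IntervalFlows:
    """Extract per-interval death and recruit counts from a census.

    Requires contiguous lifespans (gap policy "strict" or "fill"): with
    gapped occupancy a disappearance is not a death, and replaying the flows
    would not conserve the number of distinct individuals.
    """
    gapped = census.gapped_individuals()
    if gapped:
        raise ValueError(
            f"census has {len(gapped)} gapped individual(s) "
            "(e.g. {}); apply gap policy 'fill' before the null model".format(
                ", ".join(map(str, gapped[:5])))
        )
    occ = census.occupancy.astype(np.int64)
    I = occ.sum(axis=0)
    deaths = ((occ[:, :-1] == 1) & (occ[:, 1:] == 0)).sum(axis=0)
    recruits = ((occ[:, :-1] == 0) & (occ[:, 1:] == 1)).sum(axis=0)
    return IntervalFlows(tuple(I), tuple(deaths), tuple(recruits))


def _simulate_flows_lifespans(flows: IntervalFlows, rng: np.random.Generator
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Replay flows with uniformly random deaths; return (birth, death_after).

    birth[o] is the unit index at which individual o first appears;
    death_after[o] the last unit index at which it is alive.
    """
    T = flows.n_units
    n = flows.total_individuals
    birth = np.empty(n, dtype=np.int64)
    death = np.full(n, T - 1, dtype=np.int64)
    birth[: flows.I[0]] = 0
    alive = list(range(flows.I[0]))
    next_id = flows.I[0]
    for t in range(T - 1):
        d = flows.D[t]
        if d:
            doomed = rng.choice(len(alive), size=d, replace=False)
            for pos in sorted(doomed, reverse=True):
                o = alive.pop(int(pos))
                death[o] = t
        r = flows.R[t]
        if r:
            birth[next_id: next_id + r] = t + 1
            alive.extend(range(next_id, next_id + r))
            next_id += r
    return birth, death


def _occupancy_from_lifespans(birth: np.ndarray, death: np.ndarray, T: int) -> np.ndarray:
    units = np.arange(T)
    return ((units >= birth[:, None]) & (units <= death[:, None])).astype(np.int8)


def randomize_once(flows: IntervalFlows, rng: np.random.Generator,
                   units: tuple | None = None) -> Census:
    """One null-model replicate as a full Census.

    Individuals are anonymous (all share one placeholder species label;
    individual-scale indices do not use species identity). Per-unit alive
    counts match ``flows.I`` exactly.
    """
    birth, death = _simulate_flows_lifespans(flows, rng)
    occ = _occupancy_from_lifespans(birth, death, flows.n_units)
    if units is None:
        units = tuple(range(flows.n_units))
    ids = tuple(f"null{i}" for i in range(len(birth)))
    species = ("indet",) * len(birth)
    return Census(units, ids, species, occ)


def _d_mr_mu_from_occupancy(occ: np.ndarray) -> float:
    P_mu, M_mu, R_mu = _individual_mu_from_occupancy(occ)
    return float(ratio(M_mu + R_mu, 2 * P_mu + M_mu + R_mu, "empty").value)


@dataclass(frozen=True)
class SESResult:
    """Observed index, null distribution and standardized effect size."""

    observed: float
    null_mean: float
    null_sd: float
    ses: float | None
    ses_reason: str | None
    n_rand: int
    seed: int | None
    sign_convention: str
    replicates: np.ndarray = field(repr=False, default=None)

    def as_dict(self, keep_replicates: bool = False) -> dict:
        out = {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "ses": self.ses,
            "ses_reason": self.ses_reason,
            "n_rand": self.n_rand,
            "seed": self.seed,
            "sign_convention": self.sign_convention,
        }
        if keep_replicates:
            out["replicates"] = [float(v) for v in self.replicates]
        return out


def p_ses_all(
    census: Census,
    n_rand: int = 100,
    rng: np.random.Generator | int | None = None,
    sign_convention: str = "as_stated",
) -> SESResult:
    """Standardized effect size of individual persistence against drift.

    Parameters
    ----------
    census : Census
        Contiguous-lifespan census with at least 3 units (with 2 units the
        index is fully determined by the flows and the null sd is zero).
    n_rand : int
        Number of null replicates (100 is the conventional choice; increase
        for a more stable sd estimate).
    rng : numpy Generator or int seed
        Source of randomness; pass an integer for reproducibility.
    sign_convention : {"as_stated", "reversed"}
        "as_stated": (observed - null mean)/sd — negative when long-lived
        individuals are over-represented. "reversed": the negation, positive
        for excess persistence.
    """
    if sign_convention not in ("as_stated", "reversed"):
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    if census.n_units < 3:
        raise ValueError("the persistence null model needs at least 3 census units")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    flows = interval_flows(census)
    obs_P_mu, obs_M, obs_R = _individual_mu_from_occupancy(census.occupancy)
    observed = float(ratio(obs_M + obs_R, 2 * obs_P_mu + obs_M + obs_R, "empty").value)

    reps = np.empty(n_rand, dtype=float)
    for i in range(n_rand):
        birth, death = _simulate_flows_lifespans(flows, gen)
        occ = _occupancy_from_lifespans(birth, death, flows.n_units)
        P_mu, M_mu, R_mu = _individual_mu_from_occupancy(occ)
        # P_mu is fully determined by the flows; any mismatch is a bug.
        assert P_mu == obs_P_mu, "replicate persistence component diverged"
        reps[i] = float(ratio(M_mu + R_mu, 2 * P_mu + M_mu + R_mu, "empty").value)

    null_mean = float(reps.mean())
    null_sd = float(reps.std(ddof=1)) if n_rand > 1 else 0.0
    if null_sd > 0:
        ses = (observed - null_mean) / null_sd
        if sign_convention == "reversed":
            ses = -ses
        reason = None
    else:
        ses = None
        reason = "null distribution degenerate (sd = 0)"
    return SESResult(observed, null_mean, null_sd, ses, reason,
                     n_rand, seed, sign_convention, replicates=reps)
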