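"""Single-case comparison machinery.

A patient's deficit is quantified as a percentile rank of a per-subject
summary statistic within the patient's own control group.  Two patients
(or patient groups), each with their own control group, are then compared
with an ordinal bootstrap dissociation test: the observed difference in
mean ranks is referred to the distribution of rank differences obtained
from simulated control groups of the same sizes.  Because the statistic is
purely rank-based, the null distribution under exchangeability depends
only on the control-group sizes: a patient drawn from the same population
as its n controls is equally likely to occupy any of the n + 1 order
positions, giving the exact per-patient null rank pmf.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

_TOL = 1e-9


@dataclass(frozen=True)
class RankScore:
    """A patient's percentile rank within its control group."""

    patient_id: str
    control_group_id: str
    n_controls: int
    rank_pct: float
    direction: str = "higher_is_impaired"

    def __post_init__(self) -> None:
        if not 0.0 <= self.rank_pct <= 100.0:
            raise ValueError(f"rank_pct out of [0, 100]: {self.rank_pct}")


def percentile_rank(patient_value: float, control_values: Sequence[float],
                    direction: str = "higher_is_impaired",
                    patient_id: str = "patient",
                    control_group_id: str = "controls") -> RankScore:
    """Midrank percentile of a patient within its control group.

    ``rank_pct = 100 * (#controls strictly below + 0.5 * #ties) / n``.
    With ``direction="lower_is_impaired"`` the scale is flipped so that
    larger ranks always mean more impaired.
    """
    controls = np.asarray(control_values, dtype=float)
    if controls.size < 2:
        raise ValueError("need at least 2 finite control values")
    if not np.isfinite(controls).all() or not np.isfinite(patient_value):
        raise ValueError("non-finite score")
    # ties are exact: an absolute tolerance would break invariance under
    # monotone transforms for near-tied scores
    below = np.sum(controls < patient_value)
    ties = np.sum(controls == patient_value)
    pct = 100.0 * (below + 0.5 * ties) / controls.size
    if direction == "lower_is_impaired":
        pct = 100.0 - pct
    elif direction != "higher_is_impaired":
        raise ValueError(f"unknown direction {direction!r}")
    return RankScore(patient_id=patient_id, control_group_id=control_group_id,
                     n_controls=int(controls.size), rank_pct=float(pct),
                     direction=direction)


def null_rank_pmf(n_controls: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null pmf of a patient's percentile rank among n controls.

    Under exchangeability the patient occupies each of the ``n + 1`` order
    positions with equal probability, so the attainable ranks
    ``{0, 100/n, ..., 100}`` each carry probability ``1/(n + 1)``.
    """
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    values = 100.0 * np.arange(n_controls + 1) / n_controls
    probs = np.full(n_controls + 1, 1.0 / (n_controls + 1))
    return values, probs


def _sample_mean_ranks(control_sizes: Sequence[int], n_sim: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Vectorized draws of a pseudo-patient group's mean null rank."""
    total = np.zeros(n_sim)
    for n in control_sizes:
        slots = rng.integers(0, n + 1, size=n_sim)
        total += 100.0 * slots / n
    return total / len(control_sizes)


@dataclass
class RankDissociationResult:
    """Outcome of the ordinal bootstrap dissociation test."""

    ranks_a: tuple[float, ...]
    ranks_b: tuple[float, ...]
    control_sizes_a: tuple[int, ...]
    control_sizes_b: tuple[int, ...]
    observed_diff: float
    n_sim: int
    p: float
    sidedness: str
    seed: int
    null_mean: float = 0.0
    null_sd: float = 0.0
    null_quantiles: dict = field(default_factory=dict)

    def summary(self) -> str:
        return (
            f"Ordinal dissociation test ({self.sidedness}-sided, "
            f"n_sim={self.n_sim}, seed={self.seed})\n"
            f"  group A mean rank: {np.mean(self.ranks_a):.1f} "
            f"(n={len(self.ranks_a)}, controls {self.control_sizes_a})\n"
            f"  group B mean rank: {np.mean(self.ranks_b):.1f} "
            f"(n={len(self.ranks_b)}, controls {self.control_sizes_b})\n"
            f"  observed rank difference: {self.observed_diff:.2f}\n"
            f"  null difference: mean {self.null_mean:.2f}, "
            f"sd {self.null_sd:.2f}\n"
            f"  p = {self.p:.4f}")

    def plot_null(self, ax=None, bins: int = 40):
        """Histogram of the simulated null rank differences with the
        observed difference marked.  Returns the matplotlib axes."""
        import matplotlib.pyplot as plt
        rng = np.random.default_rng(self.seed)
        null = (_sample_mean_ranks(self.control_sizes_a, self.n_sim, rng)
                - _sample_mean_ranks(self.control_sizes_b, self.n_sim, rng))
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ax.hist(null, bins=bins, density=True, alpha=0.7)
        ax.axvline(self.observed_diff, color="crimson",
                   label=f"observed ({self.observed_diff:.1f}), "
                         f"p={self.p:.3f}")
        ax.set_xlabel("null mean-rank difference")
        ax.set_ylabel("density")
        ax.legend(fontsize=8)
        return ax

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in
             ("observed_diff", "n_sim", "p", "sidedness", "seed",
              "null_mean", "null_sd", "null_quantiles")}
        d["ranks_a"] = list(self.ranks_a)
        d["ranks_b"] = list(self.ranks_b)
        d["control_sizes_a"] = list(self.control_sizes_a)
        d["control_sizes_b"] = list(self.control_sizes_b)
        return json.dumps(d, indent=2)


def ordinal_dissociation_test(ranks_a: Sequence[float],
                              control_sizes_a: Sequence[int],
                              ranks_b: Sequence[float],
                              control_sizes_b: Sequence[int],
                              n_sim: int = 10_000,
                              sidedness: str = "one",
                              seed: int = 0) -> RankDissociationResult:
    """Ordinal bootstrap test of a dissociation between two patient groups.

    The observed statistic is ``mean(ranks_a) - mean(ranks_b)``.  Each null
    replicate draws every pseudo-patient's rank from the exchangeability
    pmf of its own control-group size and forms the same mean difference.
    The p value uses the add-one estimator ``(1 + #extreme)/(n_sim + 1)``;
    one-sided counts ``null >= observed``, two-sided ``|null| >=
    |observed|``.
    """
    ranks_a = tuple(float(r) for r in ranks_a)
    ranks_b = tuple(float(r) for r in ranks_b)
    sizes_a = tuple(int(n) for n in control_sizes_a)
    sizes_b = tuple(int(n) for n in control_sizes_b)
    if len(ranks_a) != len(sizes_a) or len(ranks_b) != len(sizes_b):
        raise ValueError("each rank needs a matching control-group size")
    if not ranks_a or not ranks_b:
        raise ValueError("both groups need at least one patient")
    if sidedness not in ("one", "two"):
        raise ValueError("sidedness must be 'one' or 'two'")
    if n_sim < 1000:
        warnings.warn(f"n_sim={n_sim} < 1000 gives an unstable p value",
                      stacklevel=2)

    observed = float(np.mean(ranks_a) - np.mean(ranks_b))
    rng = np.random.default_rng(seed)
    null = (_sample_mean_ranks(sizes_a, n_sim, rng)
            - _sample_mean_ranks(sizes_b, n_sim, rng))
    if sidedness == "one":
        extreme = np.sum(null >= observed - _TOL)
    else:
        extreme = np.sum(np.abs(null) >= abs(observed) - _TOL)
    p = (1.0 + extreme) / (n_sim + 1.0)
    qs = {f"q{int(q * 100):02d}": float(np.quantile(null, q))
          for q in (0.025, 0.05, 0.5, 0.95, 0.975)}
    return RankDissociationResult(
        ranks_a=ranks_a, ranks_b=ranks_b, control_sizes_a=sizes_a,
        control_sizes_b=sizes_b, observed_diff=observed, n_sim=n_sim,
        p=float(p), sidedness=sidedness, seed=seed,
        null_mean=float(null.mean()), null_sd=float(null.std(ddof=1)),
        null_quantiles=qs)


def exact_dissociation_p(ranks_a: Sequence[float],
                         control_sizes_a: Sequence[int],
                         ranks_b: Sequence[float],
                         control_sizes_b: Sequence[int],
                         sidedness: str = "one") -> float:
    """Exact-enumeration p value over the joint null rank pmf.

    Feasible only for small patient counts and control groups; enumerates
    the full product distribution of per-patient null ranks.  Used as the
    oracle for the Monte-Carlo test.
    """
    observed = float(np.mean(ranks_a) - np.mean(ranks_b))
    supports_a = [null_rank_pmf(n)[0] for n in control_sizes_a]
    supports_b = [null_rank_pmf(n)[0] for n in control_sizes_b]
    sizes = [len(s) for s in supports_a + supports_b]
    if np.prod(sizes) > 5e6:
        raise ValueError("enumeration too large; use the Monte-Carlo test")
    na, nb = len(supports_a), len(supports_b)
    p_extreme = 0.0
    total = 0.0
    for combo in itertools.product(*supports_a, *supports_b):
        diff = np.mean(combo[:na]) - np.mean(combo[na:])
        w = 1.0
        for s in sizes:
            w /= s
        total += w
        if sidedness == "one":
            hit = diff >= observed - _TOL
        else:
            hit = abs(diff) >= abs(observed) - _TOL
        if hit:
            p_extreme += w
    return p_extreme / total
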