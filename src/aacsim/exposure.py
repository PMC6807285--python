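"""Safe-predator-exposure (Task 2) analysis.

Key presses in the exposure task are analyzed through their latency with
respect to the most recent token onset (T2).  If presses were unrelated to
tokens, the T2 distribution would follow a token-independence null; a
token-triggered "simple response" instead concentrates T2 shortly after
onset.  The package provides two null constructions (simulation of
uniform pressing over the epoch timeline, and re-pairing of observed
presses with token streams of other epochs), KS tests against and between
distributions, and a two-component likelihood model

    p(t) = w * f_null(t) + (1 - w) * f_exGauss(t; mu, sigma, lam)

with both components renormalized over the observed T2 window.  Model
variants share all parameters between groups ("combined") or split one or
two of them; variants are compared via BIC converted to log Bayes factors
(LBF = 0.5 * (BIC_ref - BIC)), with |LBF| > 3 between the best and second
best model treated as decisive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize as opt
import scipy.special as sp
import scipy.stats as st

from .config import TaskConfig
from .events import EventLog
from .simulate import _task2_token_schedule

PARAM_NAMES = ("w", "mu", "sigma", "lam")

#: which parameters each model variant splits between groups
VARIANTS: dict[str, tuple[str, ...]] = {
    "combined": (),
    "split_lambda": ("lam",),
    "split_mu": ("mu",),
    "split_sigma": ("sigma",),
    "split_w": ("w",),
    "split_lambda_w": ("lam", "w"),
}


# ---------------------------------------------------------------------------
# exGauss density
# ---------------------------------------------------------------------------

def exgauss_pdf(t, mu: float, sigma: float, lam: float):
    """Exponentially-modified Gaussian density (per ms).

    Gaussian mean ``mu`` and SD ``sigma``, exponential rate ``lam``.  The
    ``sigma -> 0`` limit is the exponential density shifted to ``mu``.
    Evaluated in the scaled-complementary-error-function form
    ``(lam/2) * exp(-z^2/2) * erfcx((k - z)/sqrt(2))`` with
    ``z = (t - mu)/sigma`` and ``k = lam*sigma``, which stays finite for
    the extreme parameter values visited during optimization.
    """
    if sigma < 0 or lam <= 0:
        raise ValueError("require sigma >= 0 and lam > 0")
    t = np.asarray(t, dtype=float)
    if sigma < 1e-8:
        return np.where(t >= mu, lam * np.exp(-lam * np.maximum(t - mu, 0.0)), 0.0)
    z = (t - mu) / sigma
    k = lam * sigma
    u = (k - z) / np.sqrt(2.0)
    # far right tail (z >> k): erfcx overflows; erfc -> 2 there, leaving
    # the pure exponential tail lam * exp(k^2/2 - k*z)
    safe = u > -20.0
    tail_exponent = np.where(safe, -np.inf, 0.5 * k * k - k * z)
    return np.where(
        safe,
        0.5 * lam * np.exp(-0.5 * np.where(safe, z, 0.0) ** 2)
        * sp.erfcx(np.where(safe, u, 0.0)),
        lam * np.exp(np.minimum(tail_exponent, 700.0)))


def exgauss_cdf(t, mu: float, sigma: float, lam: float):
    """EMG cdf in the numerically stable erfcx form."""
    if sigma < 0 or lam <= 0:
        raise ValueError("require sigma >= 0 and lam > 0")
    t = np.asarray(t, dtype=float)
    if sigma < 1e-8:
        return np.where(t >= mu, 1.0 - np.exp(-lam * np.maximum(t - mu, 0.0)), 0.0)
    z = (t - mu) / sigma
    k = lam * sigma
    u = (k - z) / np.sqrt(2.0)
    safe = u > -20.0
    tail_exponent = np.where(safe, -np.inf, 0.5 * k * k - k * z)
    tail_term = np.where(
        safe,
        0.5 * np.exp(-0.5 * np.where(safe, z, 0.0) ** 2)
        * sp.erfcx(np.where(safe, u, 0.0)),
        np.exp(np.minimum(tail_exponent, 0.0)))
    return np.clip(sp.ndtr(z) - tail_term, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Exposure latencies
# ---------------------------------------------------------------------------

@dataclass
class ExposureLatencySet:
    """T2 latencies of one subject's exposure presses.

    ``latencies`` holds presses made after the first token of their epoch,
    timed from the most recent preceding token onset; presses before the
    first token are excluded from the set but counted.  ``epochs`` keeps
    (duration, token-onset) metadata for null construction.
    """

    subject_id: str
    latencies: np.ndarray
    n_pre_token: int
    n_total: int
    epochs: list[tuple[float, np.ndarray]] = field(default_factory=list)

    @property
    def fraction_included(self) -> float:
        return 0.0 if self.n_total == 0 else len(self.latencies) / self.n_total


def exposure_latencies(log: EventLog) -> ExposureLatencySet:
    """Extract T2 press latencies from one Task-2 block."""
    if log.task != "task2":
        raise ValueError("exposure latencies require a Task-2 log")
    lats: list[float] = []
    n_pre = 0
    n_total = 0
    epochs_meta: list[tuple[float, np.ndarray]] = []
    for events in log.epochs().values():
        t0 = events[0].t
        onsets = np.array(sorted(ev.t for ev in events if ev.kind == "token_on"))
        presses = sorted(ev.t for ev in events if ev.kind == "key_up")
        t_end = max((ev.t for ev in events if ev.kind == "epoch_end"),
                    default=t0)
        epochs_meta.append((t_end - t0, onsets - t0))
        for tp in presses:
            n_total += 1
            prior = onsets[onsets <= tp]
            if prior.size == 0:
                n_pre += 1
            else:
                lats.append(tp - prior[-1])
    return ExposureLatencySet(subject_id=log.subject_id,
                              latencies=np.asarray(lats, dtype=float),
                              n_pre_token=n_pre, n_total=n_total,
                              epochs=epochs_meta)


def merge_latency_sets(sets: Sequence[ExposureLatencySet],
                       subject_id: str = "merged") -> ExposureLatencySet:
    return ExposureLatencySet(
        subject_id=subject_id,
        latencies=np.concatenate([s.latencies for s in sets])
        if sets else np.empty(0),
        n_pre_token=sum(s.n_pre_token for s in sets),
        n_total=sum(s.n_total for s in sets),
        epochs=[e for s in sets for e in s.epochs])


# ---------------------------------------------------------------------------
# Null distributions
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Empirical token-independence null over T2."""

    method: str
    samples: np.ndarray       # sorted T2 samples
    n_sim: int
    seed: int
    grid: np.ndarray = field(default=None)      # bin edges
    pdf_vals: np.ndarray = field(default=None)  # density per bin

    def __post_init__(self) -> None:
        self.samples = np.sort(np.asarray(self.samples, dtype=float))
        if self.samples.size < 10_000:
            warnings.warn(
                f"only {self.samples.size} null T2 samples; tail estimates "
                "may be unstable (>= 10^4 recommended)", stacklevel=2)
        if self.grid is None:
            self.grid, self.pdf_vals = _binned_density(
                self.samples, self.samples.max() if self.samples.size else 1.0)

    def pdf(self, t) -> np.ndarray:
        return _eval_binned(np.asarray(t, dtype=float), self.grid, self.pdf_vals)

    def cdf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.searchsorted(self.samples, t, side="right") / self.samples.size


def _binned_density(samples: np.ndarray, t_max: float,
                    n_bins: int = 80) -> tuple[np.ndarray, np.ndarray]:
    """Laplace-smoothed histogram density on [0, t_max].

    The +0.5 pseudo-count per bin keeps the likelihood finite for
    observations that fall in empty null bins.
    """
    edges = np.linspace(0.0, max(t_max, 1.0), n_bins + 1)
    inside = samples[(samples >= edges[0]) & (samples <= edges[-1])]
    counts, _ = np.histogram(inside, bins=edges)
    counts = counts + 0.5
    widths = np.diff(edges)
    dens = counts / (counts.sum() * widths)
    return edges, dens


def _eval_binned(t: np.ndarray, edges: np.ndarray,
                 dens: np.ndarray) -> np.ndarray:
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1,
                  0, len(dens) - 1)
    out = dens[idx]
    return np.where((t < edges[0]) | (t > edges[-1]), 0.0, out)


def uniform_null_from_epochs(epochs: Sequence[tuple[float, np.ndarray]],
                             n_sim: int, seed: int,
                             presses_per_epoch: int = 5) -> NullDistribution:
    """Uniform-pressing null from explicit (duration, onsets) epochs.

    Each simulated replicate picks an epoch, draws press times uniform
    over its timeline, and records T2 for presses after the first token.
    """
    rng = np.random.default_rng(seed)
    durations = np.array([d for d, _ in epochs])
    lats: list[np.ndarray] = []
    for _ in range(n_sim):
        j = rng.integers(0, len(epochs))
        dur, onsets = durations[j], epochs[j][1]
        if dur <= 0 or len(onsets) == 0:
            continue
        tp = rng.uniform(0.0, dur, size=presses_per_epoch)
        tp = tp[tp >= onsets[0]]
        if tp.size:
            idx = np.searchsorted(onsets, tp, side="right") - 1
            lats.append(tp - onsets[idx])
    samples = np.concatenate(lats) if lats else np.empty(0)
    return NullDistribution(method="uniform_time", samples=samples,
                            n_sim=n_sim, seed=seed)


def permutation_null_from_epochs(epochs_with_presses, n_sim: int,
                                 seed: int) -> NullDistribution:
    """Re-pair observed presses with token streams of other epochs.

    ``epochs_with_presses``: list of (duration, onsets, press_times), all
    relative to epoch start.  Each replicate re-pairs each epoch's press
    times with the token onsets of a randomly selected *different* epoch,
    destroying any press-token coupling while preserving both marginals.
    """
    rng = np.random.default_rng(seed)
    n_ep = len(epochs_with_presses)
    if n_ep < 2:
        raise ValueError("permutation null needs >= 2 epochs")
    lats: list[np.ndarray] = []
    for _ in range(n_sim):
        for i, (_, _, presses) in enumerate(epochs_with_presses):
            if len(presses) == 0:
                continue
            j = rng.integers(0, n_ep - 1)
            if j >= i:
                j += 1
            dur_j, onsets_j, _ = epochs_with_presses[j]
            tp = np.asarray(presses, dtype=float)
            tp = tp[(tp <= dur_j)]
            if len(onsets_j) == 0:
                continue
            tp = tp[tp >= onsets_j[0]]
            if tp.size:
                idx = np.searchsorted(onsets_j, tp, side="right") - 1
                lats.append(tp - np.asarray(onsets_j)[idx])
    samples = np.concatenate(lats) if lats else np.empty(0)
    return NullDistribution(method="permutation", samples=samples,
                            n_sim=n_sim, seed=seed)


def build_null_distribution(config: TaskConfig, method: str = "uniform_time",
                            n_sim: int = 5000, seed: int = 0,
                            observed: Optional[Sequence[ExposureLatencySet]] = None,
                            presses_per_epoch: int = 5) -> NullDistribution:
    """Construct a token-independence null for T2 latencies.

    ``uniform_time`` simulates epoch timelines from the task timing model
    and presses uniformly over them; ``permutation`` requires observed
    latency sets with epoch metadata and re-pairs presses across epochs.
    """
    if method == "uniform_time":
        rng = np.random.default_rng(seed)
        epochs = []
        for _ in range(min(n_sim, 2000)):
            onsets, _, dur = _task2_token_schedule(config, rng)
            epochs.append((dur, onsets))
        return uniform_null_from_epochs(epochs, n_sim, seed + 1,
                                        presses_per_epoch=presses_per_epoch)
    if method == "permutation":
        if not observed:
            raise ValueError("permutation null requires observed latency sets")
        raise NotImplementedError(
            "use permutation_null_from_epochs with per-epoch press times")
    raise ValueError(f"unknown null method {method!r}")


# ---------------------------------------------------------------------------
# KS tests
# ---------------------------------------------------------------------------

def ks_one_sample(latencies: np.ndarray, null: NullDistribution):
    """One-sample KS test of observed T2 against the empirical null cdf."""
    latencies = np.asarray(latencies, dtype=float)
    if latencies.size < 5:
        raise ValueError("need >= 5 observations for a KS test")
    return st.ks_1samp(latencies, null.cdf)


def group_comparison(latencies_a: np.ndarray, latencies_b: np.ndarray,
                     means_a: Sequence[float], means_b: Sequence[float]):
    """Two-sample KS on pooled T2 plus a t test on per-participant means."""
    a = np.asarray(latencies_a, dtype=float)
    b = np.asarray(latencies_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("need >= 5 observations per sample")
    ks = st.ks_2samp(a, b)
    tt = st.ttest_ind(np.asarray(means_a, float), np.asarray(means_b, float))
    return {"ks_statistic": float(ks.statistic), "ks_p": float(ks.pvalue),
            "t_statistic": float(tt.statistic), "t_p": float(tt.pvalue)}


# ---------------------------------------------------------------------------
# Mixture model
# ---------------------------------------------------------------------------

def _unpack(x: np.ndarray, variant: str,
            groups: Sequence[str]) -> dict[str, dict[str, float]]:
    split = VARIANTS[variant]
    out: dict[str, dict[str, float]] = {g: {} for g in groups}
    i = 0
    for name in PARAM_NAMES:
        if name in split:
            vals = {g: x[i + j] for j, g in enumerate(groups)}
            i += len(groups)
        else:
            vals = {g: x[i] for g in groups}
            i += 1
        for g in groups:
            v = vals[g]
            if name == "w":
                v = 1.0 / (1.0 + np.exp(-v))
            elif name in ("sigma", "lam"):
                v = np.exp(v)
            out[g][name] = float(v)
    return out


def _pack(params: Mapping[str, Mapping[str, float]], variant: str,
          groups: Sequence[str]) -> np.ndarray:
    split = VARIANTS[variant]
    x: list[float] = []
    g0 = groups[0]
    for name in PARAM_NAMES:
        source = groups if name in split else (g0,)
        for g in source:
            v = params[g][name]
            if name == "w":
                v = np.clip(v, 1e-6, 1 - 1e-6)
                v = np.log(v / (1 - v))
            elif name in ("sigma", "lam"):
                v = np.log(max(v, 1e-12))
            x.append(float(v))
    return np.asarray(x)


def _n_params(variant: str, n_groups: int) -> int:
    return len(PARAM_NAMES) + len(VARIANTS[variant]) * (n_groups - 1)


#: box constraints in transformed space; the exGauss component models a
#: simple reaction to the token, so its parameters are kept on a
#: reaction-time scale (mu <= 3 s, sigma <= 500 ms, 1 ms <= tau <= 2 s) —
#: without these an arbitrarily broad exGauss can mimic the null itself
#: and the mixture weight loses identifiability
_BOUNDS = {"w": (-12.0, 12.0), "mu": (0.0, 3000.0),
           "sigma": (np.log(1.0), np.log(500.0)),
           "lam": (np.log(5e-4), np.log(1.0))}


def _bounds_vector(variant: str, n_groups: int) -> list[tuple[float, float]]:
    out = []
    for name in PARAM_NAMES:
        reps = n_groups if name in VARIANTS[variant] else 1
        out.extend([_BOUNDS[name]] * reps)
    return out


@dataclass
class ExposureMixtureResults:
    """MLE fit of the weighted null + exGauss exposure-time model."""

    variant: str
    groups: tuple[str, ...]
    params: dict[str, dict[str, float]]
    log_likelihood: float
    n_obs: int
    n_params: int
    bic: float
    converged: bool
    flags: list[str] = field(default_factory=list)
    lbf_vs_reference: Optional[float] = None
    t_window: tuple[float, float] = (0.0, np.inf)
    seed: int = 0

    def summary(self) -> str:
        lines = [f"Exposure mixture fit: variant={self.variant} "
                 f"(k={self.n_params}, n={self.n_obs})",
                 f"  logL = {self.log_likelihood:.2f}   BIC = {self.bic:.2f}"]
        if self.lbf_vs_reference is not None:
            lines.append(f"  LBF vs reference = {self.lbf_vs_reference:.2f}")
        for g in self.groups:
            p = self.params[g]
            lines.append(
                f"  [{g}] w={p['w']:.3f}  mu={p['mu']:.1f} ms  "
                f"sigma={p['sigma']:.1f} ms  lam={p['lam']:.3g} /ms "
                f"(tau={1.0 / p['lam']:.0f} ms)")
        if not self.converged:
            lines.append("  WARNING: optimizer did not converge")
        for fl in self.flags:
            lines.append(f"  NOTE: {fl}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({
            "variant": self.variant, "groups": list(self.groups),
            "params": self.params, "log_likelihood": self.log_likelihood,
            "n_obs": self.n_obs, "n_params": self.n_params, "bic": self.bic,
            "lbf_vs_reference": self.lbf_vs_reference,
            "converged": self.converged, "flags": self.flags}, indent=2)


class ExposureMixtureModel:
    """Likelihood model for grouped T2 exposure latencies.

    Parameters
    ----------
    latencies_by_group
        Mapping group label -> array of T2 latencies (ms), e.g.
        ``{"control": ..., "patient": ...}``.
    null
        Token-independence null supplying the ``f_null`` component.
    t_max
        Upper edge of the analysis window; defaults to the largest
        observed latency.  Both mixture components are renormalized over
        ``[0, t_max]`` so the truncated likelihood is proper.
    """

    def __init__(self, latencies_by_group: Mapping[str, np.ndarray],
                 null: NullDistribution, t_max: Optional[float] = None):
        self.groups = tuple(latencies_by_group)
        if not self.groups:
            raise ValueError("need at least one group")
        self.data = {g: np.asarray(v, dtype=float)
                     for g, v in latencies_by_group.items()}
        for g, v in self.data.items():
            if v.size < 10:
                raise ValueError(f"group {g!r} has too few latencies ({v.size})")
            if (v < 0).any():
                raise ValueError(f"group {g!r} has negative latencies")
        self.null = null
        if t_max is None:
            t_max = float(max(v.max() for v in self.data.values()))
        self.t_max = t_max
        self.data = {g: v[v <= t_max] for g, v in self.data.items()}
        self.n_obs = int(sum(v.size for v in self.data.values()))
        # null density renormalized over the analysis window
        edges, dens = _binned_density(null.samples, t_max)
        self._f_null = {g: _eval_binned(v, edges, dens)
                        for g, v in self.data.items()}

    @classmethod
    def from_latency_sets(cls, sets_by_group: Mapping[str, Sequence[ExposureLatencySet]],
                          null: NullDistribution, **kw) -> "ExposureMixtureModel":
        pooled = {g: np.concatenate([s.latencies for s in sets])
                  for g, sets in sets_by_group.items()}
        return cls(pooled, null, **kw)

    # -- likelihood --------------------------------------------------------

    def _nll(self, x: np.ndarray, variant: str) -> float:
        params = _unpack(x, variant, self.groups)
        total = 0.0
        for g in self.groups:
            p = params[g]
            z = float(exgauss_cdf(self.t_max, p["mu"], p["sigma"], p["lam"])
                      - exgauss_cdf(0.0, p["mu"], p["sigma"], p["lam"]))
            if z < 1e-12:
                return 1e12
            fe = exgauss_pdf(self.data[g], p["mu"], p["sigma"], p["lam"]) / z
            dens = p["w"] * self._f_null[g] + (1.0 - p["w"]) * fe
            total -= float(np.sum(np.log(np.maximum(dens, 1e-300))))
        if not np.isfinite(total):
            return 1e12
        return total

    def _moment_start(self) -> np.ndarray:
        pooled = np.concatenate(list(self.data.values()))
        m, s = float(pooled.mean()), float(pooled.std())
        skew = float(st.skew(pooled)) if pooled.size > 2 else 0.5
        tau = s * max(skew / 2.0, 0.05) ** (1.0 / 3.0)
        tau = float(np.clip(tau, 1.0, 10 * s + 1.0))
        sigma0 = float(np.sqrt(max(s**2 - tau**2, (0.1 * s + 1.0) ** 2)))
        mu0 = max(m - tau, 1.0)
        base = {"w": 0.5, "mu": mu0, "sigma": sigma0, "lam": 1.0 / tau}
        return _pack({g: base for g in self.groups}, "combined", self.groups)

    def _expand_start(self, x_combined: np.ndarray, variant: str) -> np.ndarray:
        params = _unpack(x_combined, "combined", self.groups)
        return _pack(params, variant, self.groups)

    def fit(self, variant: str = "combined", n_starts: int = 10,
            seed: int = 0,
            extra_starts: Sequence[np.ndarray] = ()) -> ExposureMixtureResults:
        """Maximum-likelihood fit by multi-start bounded optimization.

        ``w`` is optimized on the logit scale, ``sigma`` and ``lam`` on the
        log scale; ``n_starts`` seeded jitters around a moment-based start
        (plus any ``extra_starts``) guard against local optima.
        """
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; "
                             f"choose from {sorted(VARIANTS)}")
        rng = np.random.default_rng(seed)
        base = self._moment_start()
        base_v = self._expand_start(base, variant)
        starts = [base_v] + [np.asarray(s, float) for s in extra_starts]
        for _ in range(max(n_starts - len(starts), 0)):
            starts.append(base_v + rng.normal(0.0, 0.6, size=base_v.size))
        bounds = _bounds_vector(variant, len(self.groups))
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        starts = [np.clip(x0, lo, hi) for x0 in starts]

        best = None
        n_ok = 0
        for x0 in starts:
            try:
                res = opt.minimize(self._nll, x0, args=(variant,),
                                   method="L-BFGS-B", bounds=bounds)
            except Exception:
                continue
            if np.isfinite(res.fun):
                n_ok += 1
                if best is None or res.fun < best.fun:
                    best = res
        if best is None:
            return ExposureMixtureResults(
                variant=variant, groups=self.groups,
                params={g: {} for g in self.groups},
                log_likelihood=np.nan, n_obs=self.n_obs,
                n_params=_n_params(variant, len(self.groups)),
                bic=np.nan, converged=False,
                flags=["optimizer failed on every restart"], seed=seed,
                t_window=(0.0, self.t_max))

        params = _unpack(best.x, variant, self.groups)
        ll = -float(best.fun)
        k = _n_params(variant, len(self.groups))
        bic = k * np.log(self.n_obs) - 2.0 * ll
        flags = []
        for g in self.groups:
            if params[g]["w"] > 0.995:
                flags.append(
                    f"group {g!r}: w at upper bound; exGauss parameters "
                    "unidentifiable")
        return ExposureMixtureResults(
            variant=variant, groups=self.groups, params=params,
            log_likelihood=ll, n_obs=self.n_obs, n_params=k, bic=bic,
            converged=bool(best.success) and n_ok > 0, flags=flags,
            seed=seed, t_window=(0.0, self.t_max))

    def plot_fit(self, results: "ExposureMixtureResults", ax=None,
                 bins: int = 40):
        """Overlay the fitted mixture density on the T2 histograms.

        One panel-less axis; groups are drawn as step histograms with the
        fitted density curves on top.  Returns the matplotlib axes.
        """
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        grid = np.linspace(0.0, self.t_max, 400)
        edges, dens = _binned_density(self.null.samples, self.t_max)
        f_null = _eval_binned(grid, edges, dens)
        for g in self.groups:
            p = results.params[g]
            z = float(exgauss_cdf(self.t_max, p["mu"], p["sigma"], p["lam"])
                      - exgauss_cdf(0.0, p["mu"], p["sigma"], p["lam"]))
            fe = exgauss_pdf(grid, p["mu"], p["sigma"], p["lam"]) / max(z, 1e-12)
            mix = p["w"] * f_null + (1 - p["w"]) * fe
            ax.hist(self.data[g], bins=bins, density=True, histtype="step",
                    label=f"{g} (n={self.data[g].size})")
            ax.plot(grid, mix, label=f"{g} fit")
        ax.plot(grid, f_null, "k--", alpha=0.5, label="null")
        ax.set_xlabel("time since last token onset (ms)")
        ax.set_ylabel("density (1/ms)")
        ax.legend(fontsize=8)
        return ax

    def fit_all(self, variants: Optional[Sequence[str]] = None,
                n_starts: int = 10, seed: int = 0
                ) -> dict[str, ExposureMixtureResults]:
        """Fit the combined model plus all requested split variants.

        Split variants start from the combined solution (among other
        starts), so their likelihood can never fall below the combined
        model's — the nested-model ordering holds by construction.
        """
        if variants is None:
            variants = list(VARIANTS)
        fits: dict[str, ExposureMixtureResults] = {}
        combined = self.fit("combined", n_starts=n_starts, seed=seed)
        fits["combined"] = combined
        x_comb = (_pack(combined.params, "combined", self.groups)
                  if combined.params[self.groups[0]] else None)
        for variant in variants:
            if variant == "combined":
                continue
            extra = []
            if x_comb is not None:
                extra.append(self._expand_start(x_comb, variant))
            fits[variant] = self.fit(variant, n_starts=n_starts,
                                     seed=seed + 1, extra_starts=extra)
        return fits


def compare_models(fits: Mapping[str, ExposureMixtureResults],
                   reference: str = "combined") -> pd.DataFrame:
    """BIC-based model comparison with log Bayes factors.

    ``bic = n_params * ln(n_obs) - 2 * logL``;
    ``LBF = 0.5 * (BIC_ref - BIC)``.  The table is sorted by LBF and flags
    whether the best model beats the second best decisively
    (|delta LBF| > 3).
    """
    if reference not in fits:
        raise ValueError(f"reference {reference!r} not among fits")
    n_obs = {f.n_obs for f in fits.values()}
    if len(n_obs) != 1:
        raise ValueError("all fits must be computed on identical data")
    bic_ref = fits[reference].bic
    rows = []
    for name, f in fits.items():
        lbf = 0.5 * (bic_ref - f.bic)
        f.lbf_vs_reference = float(lbf)
        rows.append({"variant": name, "n_params": f.n_params,
                     "log_likelihood": f.log_likelihood, "bic": f.bic,
                     "lbf": float(lbf), "converged": f.converged})
    table = pd.DataFrame(rows).sort_values("lbf", ascending=False,
                                           ignore_index=True)
    if len(table) > 1:
        gap = table["lbf"].iloc[0] - table["lbf"].iloc[1]
        table.attrs["decisive"] = bool(abs(gap) > 3.0)
        table.attrs["lbf_gap"] = float(gap)
    return table


def lbf_from_bic(bic_reference: float, bic: float) -> float:
    """Log Bayes factor of a model against a reference, from BICs."""
    return 0.5 * (bic_reference - bic)
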