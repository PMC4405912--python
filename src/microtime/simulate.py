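"""Synthetic longitudinal microbiome communities.

Each OTU's log10 absolute abundance follows a mean-reverting
Ornstein-Uhlenbeck (OU) process; sequencing is emulated by multinomial read
sampling from each day's fractional abundances at realistic depths.  A
community can be built from two joined OU regimes (a regime shift halfway
through, emulating a perturbation such as an enteric infection), and binary
host-metadata series with injected lagged effects on chosen OTUs provide a
ground-truth harness for the association pipeline.

The OU process uses the exact discretization

    S_{i+1} = S_i e^{-lam dt} + mu (1 - e^{-lam dt})
              + sigma sqrt((1 - e^{-2 lam dt}) / (2 lam)) eps_i

whose stationary law is Normal(mu, sigma^2 / (2 lam)).  Maximum-likelihood
parameter recovery exploits the equivalence with a Gaussian AR(1):
``a = e^{-lam dt}`` from least squares of S_{i+1} on S_i with intercept
``b``, then ``lam = -ln(a)/dt``, ``mu = b/(1-a)`` and
``sigma^2 = Var(resid) * 2 lam / (1 - a^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import MetadataSeries, OtuTimeSeries


@dataclass
class OUParams:
    """Ornstein-Uhlenbeck parameters on the log10-abundance scale.

    lam : mean-reversion rate per day (> 0)
    mu : long-run mean (log10 fractional abundance)
    sigma : fluctuation scale (> 0 for a stochastic process)
    delta : time step in days (daily sampling: 1)
    """

    lam: float
    mu: float
    sigma: float
    delta: float = 1.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")

    @property
    def stationary_std(self) -> float:
        return self.sigma / np.sqrt(2.0 * self.lam)


@dataclass
class SyntheticCommunity:
    """A simulated community with its sequencing-run emulation.

    ``abundances`` are absolute (linear-scale) per-day, per-OTU values;
    ``true_load`` their per-day totals; ``counts`` the multinomially sampled
    reads at per-day ``depths``.
    """

    abundances: pd.DataFrame  # days x OTUs, > 0
    true_load: pd.Series
    counts: pd.DataFrame
    depths: pd.Series
    seed: int
    params: list[OUParams] = field(default_factory=list)

    @property
    def otu_ids(self) -> pd.Index:
        return self.abundances.columns

    def to_otu_time_series(self, **kwargs) -> OtuTimeSeries:
        return OtuTimeSeries(counts=self.counts, **kwargs)


def simulate_ou(
    params: OUParams, n: int, s0: float | None = None, seed=None
) -> np.ndarray:
    """Simulate ``n`` points of an OU process via its exact discretization.

    ``s0`` defaults to a draw from the stationary distribution, so the
    returned series is stationary from the first point.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    a = np.exp(-params.lam * params.delta)
    noise = params.sigma * np.sqrt((1.0 - a**2) / (2.0 * params.lam))
    s = np.empty(n)
    s[0] = rng.normal(params.mu, params.stationary_std) if s0 is None else s0
    eps = rng.standard_normal(n - 1)
    for i in range(n - 1):
        s[i + 1] = s[i] * a + params.mu * (1.0 - a) + noise * eps[i]
    return s


def fit_ou_ml(series, delta: float = 1.0) -> OUParams:
    """Maximum-likelihood OU parameters through the AR(1) equivalence."""
    s = np.asarray(series, dtype=float)
    if s.size < 10:
        raise ValueError("series too short to fit (need >= 10 points)")
    if np.ptp(s) == 0:
        raise ValueError("constant series")
    x, y = s[:-1], s[1:]
    xc = x - x.mean()
    a = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
    if not 0.0 < a < 1.0:
        raise ValueError(f"fitted AR coefficient a={a:.3f} is not mean-reverting")
    b = float(y.mean() - a * x.mean())
    resid = y - (a * x + b)
    lam = -np.log(a) / delta
    mu = b / (1.0 - a)
    sigma2 = resid.var() * 2.0 * lam / (1.0 - a**2)
    return OUParams(lam=lam, mu=mu, sigma=float(np.sqrt(sigma2)), delta=delta)


def draw_ou_params(
    n_otus: int,
    rng,
    lam_range=(0.1, 1.0),
    mu_range=(-6.0, -1.0),
    sigma_range=(0.05, 0.5),
) -> list[OUParams]:
    """Draw per-OTU OU parameters from realistic log10-abundance ranges."""
    return [
        OUParams(
            lam=rng.uniform(*lam_range),
            mu=rng.uniform(*mu_range),
            sigma=rng.uniform(*sigma_range),
        )
        for _ in range(n_otus)
    ]


def sample_reads(abundances_row, depth: int, seed=None) -> np.ndarray:
    """Multinomial sequencing draw from one day's absolute abundances."""
    a = np.asarray(abundances_row, dtype=float)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if (a <= 0).any():
        raise ValueError("abundances must be positive")
    rng = np.random.default_rng(seed)
    return rng.multinomial(int(depth), a / a.sum())


def simulate_community(
    params_list: list[OUParams],
    regime2_params: list[OUParams] | None = None,
    n_per_regime: int = 50,
    depths_pool=(10_000, 100_000),
    seed: int | None = None,
) -> SyntheticCommunity:
    """Simulate a community and its sequencing runs.

    Per OTU, one OU segment of ``n_per_regime`` log10-abundance points is
    simulated from ``params_list``; if ``regime2_params`` is given a second
    segment is simulated from it (starting from the first segment's
    endpoint's regime-2 stationary draw) and joined, giving a regime shift
    halfway through.  Abundances are ``10**S``; read depths are drawn
    uniformly from ``depths_pool`` (an inclusive ``(low, high)`` integer
    range, or an explicit pool of observed depths to resample).
    """
    if not params_list:
        raise ValueError("params_list is empty")
    if regime2_params is not None and len(regime2_params) != len(params_list):
        raise ValueError("regime2_params must match params_list length")
    rng = np.random.default_rng(seed)
    n_otus = len(params_list)
    n_days = n_per_regime * (2 if regime2_params is not None else 1)
    logab = np.empty((n_days, n_otus))
    for k, p in enumerate(params_list):
        seg = simulate_ou(p, n_per_regime, seed=rng)
        if regime2_params is not None:
            seg2 = simulate_ou(regime2_params[k], n_per_regime, seed=rng)
            seg = np.concatenate([seg, seg2])
        logab[:, k] = seg
    otu_ids = pd.Index([f"OTU_{k:04d}" for k in range(n_otus)], name="otu_id")
    days = pd.Index(range(n_days), name="day")
    abundances = pd.DataFrame(10.0 ** logab, index=days, columns=otu_ids)
    depths_pool = np.asarray(depths_pool, dtype=np.int64)
    if depths_pool.size == 2 and depths_pool[0] < depths_pool[1]:
        depths = rng.integers(depths_pool[0], depths_pool[1] + 1, size=n_days)
    else:
        depths = rng.choice(depths_pool, size=n_days, replace=True)
    counts = _sample_counts(abundances.to_numpy(), depths, rng)
    return SyntheticCommunity(
        abundances=abundances,
        true_load=abundances.sum(axis=1).rename("true_load"),
        counts=pd.DataFrame(counts, index=days, columns=otu_ids),
        depths=pd.Series(depths, index=days, name="depth"),
        seed=-1 if seed is None else int(seed),
        params=list(params_list),
    )


def _sample_counts(abundances: np.ndarray, depths, rng) -> np.ndarray:
    fracs = abundances / abundances.sum(axis=1, keepdims=True)
    return np.vstack(
        [rng.multinomial(int(d), f) for d, f in zip(depths, fracs)]
    ).astype(np.int64)


def simulate_metadata_effects(
    community: SyntheticCommunity,
    target_otus,
    effect_size: float,
    lag: int = 1,
    base_prob: float = 0.5,
    seed: int | None = None,
):
    """Inject a lagged binary host-factor effect into a community.

    A daily Bernoulli(``base_prob``) metadata series is drawn; on days where
    it is 1, the log10 abundance of ``target_otus`` at day ``t + lag`` is
    shifted by ``effect_size`` (log10 units) and reads are re-sampled at the
    original depths.  Returns ``(metadata, modified_community, truth)`` where
    ``truth`` records the planted targets, lag and effect size.
    """
    if not -7 <= lag <= 7:
        raise ValueError("lag must be within [-7, 7]")
    target_otus = pd.Index(target_otus)
    missing = target_otus.difference(community.otu_ids)
    if len(missing):
        raise ValueError(f"target OTUs not in community: {list(missing)}")
    rng = np.random.default_rng(seed)
    n_days = len(community.abundances)
    driver = (rng.random(n_days) < base_prob).astype(float)
    logab = np.log10(community.abundances.to_numpy().copy())
    cols = community.otu_ids.get_indexer(target_otus)
    for t in np.flatnonzero(driver):
        u = t + lag
        if 0 <= u < n_days:
            logab[u, cols] += effect_size
    abundances = pd.DataFrame(
        10.0 ** logab, index=community.abundances.index, columns=community.otu_ids
    )
    counts = _sample_counts(abundances.to_numpy(), community.depths.to_numpy(), rng)
    modified = SyntheticCommunity(
        abundances=abundances,
        true_load=abundances.sum(axis=1).rename("true_load"),
        counts=pd.DataFrame(counts, index=abundances.index, columns=community.otu_ids),
        depths=community.depths.copy(),
        seed=-1 if seed is None else int(seed),
        params=community.params,
    )
    metadata = MetadataSeries(
        name="synthetic_driver",
        values=pd.Series(driver, index=abundances.index),
        category="synthetic",
    )
    truth = {"targets": list(target_otus), "lag": lag, "effect_size": effect_size}
    return metadata, modified, truth
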