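"""Plateau, critical times, saturation diagnostics and revisitation.

Past a certain time the mean divergence of an evolving gene population
from its ancestor stops growing: it has explored the available polymorphic
space and settles at a steady-state plateau D_inf.  The critical times
tcrit50 and tcrit90 mark the generations at which divergence reaches 50%
and 90% of D_inf; beyond them sequence dissimilarity progressively
decouples from phylogenetic time.  This module estimates those quantities
from simulated trajectories, characterises the steady-state divergence
distribution, measures the collapse of the time-divergence correlation,
and estimates the probability that two independent lineages revisit each
other's sequences.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .constrained_space import (
    MutationModel,
    PolymorphismProfile,
    encode_sequence,
    site_stationary_distributions,
)
from .evolver import (
    DivergenceTrajectory,
    SimulationConfig,
    evolve,
    mutate_batch,
)
from .exhaustion import MINUTES_PER_YEAR, TimeScale


class NotSaturatedError(RuntimeError):
    """The trajectory shows no steady-state window (still in linear range)."""


class CrossingNotReachedError(RuntimeError):
    """The trajectory never reaches the requested fraction of the plateau."""


class StationarityError(RuntimeError):
    """Post-tcrit90 snapshots differ more than the stationarity tolerance."""


@dataclass
class CriticalTimes:
    plateau: float
    plateau_sd: float
    tcrit50: float
    tcrit90: float
    tcrit50_years: Optional[float] = None
    tcrit90_years: Optional[float] = None
    config_digest: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.plateau <= 1:
            raise ValueError("plateau must lie in (0, 1]")
        if not 0 < self.tcrit50 < self.tcrit90:
            raise ValueError("need 0 < tcrit50 < tcrit90")

    def to_json(self, path: Union[str, Path]) -> None:
        payload = asdict(self)
        payload["units"] = "generations"
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def estimate_plateau(
    traj: DivergenceTrajectory,
    window_fraction: float = 0.2,
    alpha: float = 0.05,
    flatness_tolerance: float = 0.02,
) -> tuple[float, float]:
    """Steady-state mean divergence and SD from the terminal window.

    The terminal ``window_fraction`` of samples qualifies as a plateau when
    the OLS slope's (1 - alpha) confidence interval contains zero, or when
    the fitted total drift across the window is below
    ``flatness_tolerance`` of the window mean (a guard against the slope
    test flagging negligible-but-significant drift in long windows).
    Slope standard errors are Newey-West (HAC): under birth-death
    demography the copies share genealogy and the trajectory wanders with
    long autocorrelation, which makes iid-error slope tests spuriously
    significant on genuinely stationary windows.
    Raises :class:`NotSaturatedError` otherwise, or when the plateau is 0
    (nothing ever diverged).
    """
    n = len(traj.generations)
    w = max(3, int(math.ceil(window_fraction * n)))
    if n < w:
        raise NotSaturatedError("trajectory too short for a plateau window")
    t = traj.generations[-w:]
    d = traj.mean_divergence[-w:]
    mean_d = float(d.mean())
    if mean_d <= 0:
        raise NotSaturatedError("divergence never left zero")
    if np.ptp(d) == 0:
        return mean_d, float(traj.sd_divergence[-w:].mean())
    X = sm.add_constant(t)
    maxlags = max(1, w // 5)
    fit = sm.OLS(d, X).fit(cov_type="HAC", cov_kwds={"maxlags": maxlags})
    slope = float(fit.params[1])
    stderr = float(fit.bse[1])
    tcrit = stats.t.ppf(1 - alpha / 2, w - 2)
    ci_lo = slope - tcrit * stderr
    ci_hi = slope + tcrit * stderr
    drift = abs(slope) * (t[-1] - t[0])
    if not (ci_lo <= 0 <= ci_hi or drift < flatness_tolerance * mean_d):
        raise NotSaturatedError(
            f"terminal window still drifting (slope {slope:.3g}, "
            f"CI [{ci_lo:.3g}, {ci_hi:.3g}])"
        )
    return mean_d, float(traj.sd_divergence[-w:].mean())


def find_tcrit(
    traj: DivergenceTrajectory, d_inf: float, fraction: float
) -> float:
    """First generation at which divergence reaches ``fraction * d_inf``.

    The mean trajectory is first smoothed with an isotonic (monotone
    non-decreasing) fit -- the expectation is monotone, so this suppresses
    Monte-Carlo jitter at the crossing -- then the crossing is located by
    linear interpolation between samples.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    target = fraction * d_inf
    t = traj.generations
    iso = IsotonicRegression(increasing=True)
    d = iso.fit_transform(t, traj.mean_divergence)
    above = np.flatnonzero(d >= target)
    if above.size == 0:
        raise CrossingNotReachedError(
            f"trajectory never reaches {fraction:.0%} of plateau {d_inf:.4g}"
        )
    i = int(above[0])
    if i == 0:
        return float(t[0])
    t0, t1 = t[i - 1], t[i]
    d0, d1 = d[i - 1], d[i]
    if d1 == d0:
        return float(t1)
    return float(t0 + (target - d0) / (d1 - d0) * (t1 - t0))


def critical_times(
    traj: DivergenceTrajectory,
    timescale: Optional[TimeScale] = None,
    **plateau_kwargs,
) -> CriticalTimes:
    """Plateau plus tcrit50/tcrit90 summary for one trajectory.

    Generation-to-years conversion is opt-in: it needs an organism's
    generation time, for which there is no sensible universal default.
    """
    d_inf, sd = estimate_plateau(traj, **plateau_kwargs)
    t50 = find_tcrit(traj, d_inf, 0.5)
    t90 = find_tcrit(traj, d_inf, 0.9)
    years50 = years90 = None
    if timescale is not None:
        per_year = timescale.generation_time_minutes / MINUTES_PER_YEAR
        years50, years90 = t50 * per_year, t90 * per_year
    return CriticalTimes(
        plateau=d_inf,
        plateau_sd=sd,
        tcrit50=t50,
        tcrit90=t90,
        tcrit50_years=years50,
        tcrit90_years=years90,
        config_digest=traj.config_digest,
    )


@dataclass
class SteadyStateDistribution:
    """Histogram of per-copy divergences to the ancestor past tcrit90."""

    bin_edges: np.ndarray
    densities: np.ndarray
    n_samples: int
    window: tuple[int, int]
    max_tv_distance: float = 0.0

    @property
    def masses(self) -> np.ndarray:
        return self.densities * np.diff(self.bin_edges)

    def to_tsv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "density": self.densities,
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _divergences(pop: np.ndarray, anc: np.ndarray) -> np.ndarray:
    return np.mean(pop != anc, axis=1)


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """TV distance between two discrete probability vectors."""
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def tv_noise_bound(n1: int, n2: int, bins: int) -> float:
    """Cauchy-Schwarz bound on the expected TV between two empirical
    histograms drawn from the same law (n1, n2 samples over ``bins``)."""
    return 0.5 * math.sqrt(bins * (1.0 / n1 + 1.0 / n2))


def steady_state_distribution(
    snapshots: dict[int, np.ndarray],
    ancestor: str,
    tcrit90: float,
    bins: int = 30,
    tv_tolerance: Optional[float] = None,
) -> SteadyStateDistribution:
    """Pooled divergence distribution across post-tcrit90 snapshots.

    Snapshots at or before tcrit90 are rejected.  When two snapshots are
    separated by at least tcrit90/2 their binned distributions must agree
    within ``tv_tolerance`` total-variation distance (stationarity is part
    of the contract); :class:`StationarityError` otherwise.  The default
    tolerance is ``max(0.1, tv_noise_bound(...))``: 0.1 is the scientific
    bound, but with few copies per snapshot the sampling-noise floor of
    the TV statistic exceeds it and the gate would reject stationary
    distributions; pass ``tv_tolerance=0.1`` explicitly to enforce the
    strict bound on suitably large snapshots.
    """
    if not snapshots:
        raise ValueError("no snapshots provided")
    bad = [g for g in snapshots if g <= tcrit90]
    if bad:
        raise ValueError(
            f"snapshots at generations {sorted(bad)} are not past tcrit90={tcrit90:.4g}"
        )
    anc = encode_sequence(ancestor)
    edges = np.linspace(0.0, 1.0, bins + 1)
    per_snap = {g: _divergences(pop, anc) for g, pop in snapshots.items()}
    pooled = np.concatenate(list(per_snap.values()))
    densities, _ = np.histogram(pooled, bins=edges, density=True)

    max_tv = 0.0
    gens = sorted(per_snap)
    tol = tv_tolerance
    for i, gi in enumerate(gens):
        for gj in gens[i + 1 :]:
            if gj - gi >= tcrit90 / 2:
                pi, _ = np.histogram(per_snap[gi], bins=edges)
                pj, _ = np.histogram(per_snap[gj], bins=edges)
                tv = total_variation(pi / pi.sum(), pj / pj.sum())
                max_tv = max(max_tv, tv)
                if tol is None:
                    tol = max(0.1, tv_noise_bound(len(per_snap[gi]), len(per_snap[gj]), bins))
    if tol is not None and max_tv > tol:
        raise StationarityError(
            f"snapshots differ by TV {max_tv:.3f} > tolerance {tol:.3f}"
        )
    return SteadyStateDistribution(
        bin_edges=edges,
        densities=densities,
        n_samples=len(pooled),
        window=(min(gens), max(gens)),
        max_tv_distance=max_tv,
    )


def time_divergence_correlation(
    trajectories: Sequence[DivergenceTrajectory],
    window_edges: Sequence[float],
) -> pd.DataFrame:
    """Pearson correlation of generation vs divergence, per time window.

    Points from all replicates falling in each ``[left, right)`` window are
    pooled; the resulting decay curve quantifies how the inferability of
    time from divergence collapses as the plateau is approached.  Needs at
    least 20 replicates.
    """
    if len(trajectories) < 20:
        raise ValueError("need >= 20 replicate trajectories")
    edges = np.asarray(window_edges, dtype=float)
    rows = []
    gen = np.concatenate([t.generations for t in trajectories])
    div = np.concatenate([t.mean_divergence for t in trajectories])
    for left, right in zip(edges[:-1], edges[1:]):
        m = (gen >= left) & (gen < right)
        n_pts = int(m.sum())
        if n_pts >= 3 and np.ptp(gen[m]) > 0 and np.ptp(div[m]) > 0:
            r = float(stats.pearsonr(gen[m], div[m]).statistic)
        else:
            r = float("nan")
        rows.append(
            {"window_left": left, "window_right": right, "correlation": r, "n_points": n_pts}
        )
    return pd.DataFrame(rows)


def stationary_match_probability(
    profile: PolymorphismProfile,
    model: MutationModel,
    threshold: float = 0.0,
) -> float:
    """Exact P(divergence <= threshold) for two independent stationary sequences.

    Sites are independent at stationarity; the per-site mismatch
    probability is ``1 - sum_b pi_b**2`` and the mismatch-count law is the
    Poisson-binomial obtained by direct convolution.  Tractable for any L;
    the exhaustive reference for tiny free spaces.
    """
    pis = site_stationary_distributions(profile, model)
    mismatch = 1.0 - (pis**2).sum(axis=1)
    pmf = np.array([1.0])
    for m in mismatch:
        pmf = np.convolve(pmf, [1.0 - m, m])
    k_max = int(math.floor(threshold * profile.length + 1e-9))
    return float(pmf[: k_max + 1].sum())


@dataclass
class RevisitationEstimate:
    probability: float
    se: float
    n_pairs: int


def revisitation_probability(
    config_a: SimulationConfig,
    config_b: SimulationConfig,
    threshold: float,
    n_pairs: int,
    seed: int = 0,
    sample_generations: Optional[Sequence[int]] = None,
) -> RevisitationEstimate:
    """Monte-Carlo probability that two independent lineages meet.

    Both lineages must share the polymorphism profile and mutation model
    (they are the same gene).  A replicate pair counts as a revisitation
    when the minimum cross-lineage divergence -- minimised over all copy
    pairs and over the sampled generations -- is at or below ``threshold``.
    By default only the terminal generation is sampled, so with a horizon
    past saturation the estimate targets the stationary meeting
    probability; pass explicit ``sample_generations`` to scan a path.
    Reported with the binomial standard error.
    """
    if not np.array_equal(config_a.profile.allowed, config_b.profile.allowed):
        raise ValueError("lineages must share the polymorphism profile")
    if (config_a.model.mu, config_a.model.kappa) != (
        config_b.model.mu,
        config_b.model.kappa,
    ):
        raise ValueError("lineages must share the mutation model")
    if threshold >= 1.0:
        return RevisitationEstimate(probability=1.0, se=0.0, n_pairs=n_pairs)

    horizon = min(config_a.generations, config_b.generations)
    if sample_generations is None:
        sample_generations = [horizon]
    samples = sorted(set(int(g) for g in sample_generations))
    if any(g < 1 or g > horizon for g in samples):
        raise ValueError("sample_generations must lie in [1, horizon]")

    simple = all(
        c.population_size == 1 and c.duplication_rate == 0 and c.extinction_rate == 0
        for c in (config_a, config_b)
    )
    rng = np.random.default_rng(seed)
    L = config_a.profile.length
    if simple:
        # batch path: all replicate pairs evolve as two (n_pairs, L) blocks
        anc_a = encode_sequence(config_a.ancestor)
        anc_b = encode_sequence(config_b.ancestor)
        pop_a = np.tile(anc_a, (n_pairs, 1)).astype(np.uint8)
        pop_b = np.tile(anc_b, (n_pairs, 1)).astype(np.uint8)
        allowed = config_a.profile.allowed
        mu, kappa = config_a.model.mu, config_a.model.kappa
        best = np.full(n_pairs, np.inf)
        sample_set = set(samples)
        for gen in range(1, max(samples) + 1):
            mutate_batch(pop_a, allowed, mu, kappa, rng)
            mutate_batch(pop_b, allowed, mu, kappa, rng)
            if gen in sample_set:
                div = np.mean(pop_a != pop_b, axis=1)
                best = np.minimum(best, div)
        hits = int((best <= threshold + 1e-12).sum())
    else:
        hits = 0
        for i in range(n_pairs):
            res_a = evolve(_reseeded(config_a, int(rng.integers(2**31))), samples)
            res_b = evolve(_reseeded(config_b, int(rng.integers(2**31))), samples)
            best = math.inf
            for g in samples:
                a, b = res_a.snapshots[g], res_b.snapshots[g]
                cross = np.mean(a[:, None, :] != b[None, :, :], axis=2)
                best = min(best, float(cross.min()))
            if best <= threshold + 1e-12:
                hits += 1
    p = hits / n_pairs
    se = math.sqrt(max(p * (1 - p), 1.0 / n_pairs) / n_pairs)
    return RevisitationEstimate(probability=p, se=se, n_pairs=n_pairs)


def _reseeded(config: SimulationConfig, seed: int) -> SimulationConfig:
    return SimulationConfig(
        ancestor=config.ancestor,
        profile=config.profile,
        model=config.model,
        generations=config.generations,
        population_size=config.population_size,
        duplication_rate=config.duplication_rate,
        extinction_rate=config.extinction_rate,
        seed=seed,
        record_every=config.record_every,
    )
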