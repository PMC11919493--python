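"""Forward-time stochastic evolution of a population of gene copies.

Each generation: (1) birth-death demography -- every copy duplicates with
probability ``duplication_rate`` and dies with probability
``extinction_rate``; the population is capped at ``population_size`` by
uniform down-sampling and rescued from total extinction by keeping one
uniformly chosen pre-step copy; (2) every site of every copy mutates
independently with probability ``mu``, the replacement drawn from the
Ti/Tv-biased kernel, and proposals landing outside the site's allowed set
are rejected (the copy keeps its state) -- the simplest implementation of
purifying constraint; (3) divergence from the founding ancestor is
recorded at the sampling stride.

Divergence is substitution-only (proportion of differing sites); indels,
HGT and recombination are out of scope.  Runs are bit-reproducible given
the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .constrained_space import (
    MutationModel,
    PolymorphismProfile,
    TRANSITION_PARTNER,
    decode_sequence,
    encode_sequence,
)


def pairwise_divergence(
    seq_a: Union[str, np.ndarray], seq_b: Union[str, np.ndarray]
) -> float:
    """Proportion of differing sites (Hamming distance / L)."""
    a = encode_sequence(seq_a) if isinstance(seq_a, str) else np.asarray(seq_a)
    b = encode_sequence(seq_b) if isinstance(seq_b, str) else np.asarray(seq_b)
    if a.shape != b.shape:
        raise ValueError(f"sequence lengths differ: {a.shape} vs {b.shape}")
    if a.size == 0:
        return 0.0
    return float(np.mean(a != b))


@dataclass(frozen=True)
class SimulationConfig:
    ancestor: str
    profile: PolymorphismProfile
    model: MutationModel
    generations: int
    population_size: int = 200
    duplication_rate: float = 0.0
    extinction_rate: float = 0.0
    seed: int = 0
    record_every: Optional[int] = None

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        for name in ("duplication_rate", "extinction_rate"):
            r = getattr(self, name)
            if not 0 <= r < 1:
                raise ValueError(f"{name} must be in [0, 1), got {r}")
        anc = encode_sequence(self.ancestor)
        if len(anc) != self.profile.length:
            raise ValueError(
                f"ancestor length {len(anc)} != profile length {self.profile.length}"
            )
        if not self.profile.allowed[np.arange(len(anc)), anc].all():
            bad = np.flatnonzero(~self.profile.allowed[np.arange(len(anc)), anc])
            raise ValueError(
                f"ancestor state not in allowed set at sites {list(bad + 1)}"
            )

    @property
    def stride(self) -> int:
        if self.record_every is not None:
            if self.record_every < 1:
                raise ValueError("record_every must be >= 1")
            return self.record_every
        return max(1, self.generations // 2000)

    def digest(self) -> str:
        """Reproducibility fingerprint over seed and parameters."""
        payload = json.dumps(
            {
                "ancestor": self.ancestor.upper().replace("U", "T"),
                "allowed": self.profile.allowed.astype(int).tolist(),
                "mu": self.model.mu,
                "kappa": self.model.kappa,
                "generations": self.generations,
                "population_size": self.population_size,
                "duplication_rate": self.duplication_rate,
                "extinction_rate": self.extinction_rate,
                "seed": self.seed,
                "record_every": self.stride,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class DivergenceTrajectory:
    """Per-sample mean/SD divergence from the ancestor across copies."""

    generations: np.ndarray
    mean_divergence: np.ndarray
    sd_divergence: np.ndarray
    population_sizes: np.ndarray
    config_digest: str = ""

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=float)
        self.mean_divergence = np.asarray(self.mean_divergence, dtype=float)
        self.sd_divergence = np.asarray(self.sd_divergence, dtype=float)
        self.population_sizes = np.asarray(self.population_sizes, dtype=int)
        n = len(self.generations)
        if not (
            len(self.mean_divergence) == len(self.sd_divergence) == len(self.population_sizes) == n
        ):
            raise ValueError("trajectory columns must have equal length")

    def to_tsv(self, path: Union[str, Path]) -> None:
        df = pd.DataFrame(
            {
                "generation": self.generations.astype(int),
                "mean_divergence": self.mean_divergence,
                "sd_divergence": self.sd_divergence,
                "pop_size": self.population_sizes,
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# config_digest={self.config_digest}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "DivergenceTrajectory":
        digest = ""
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# config_digest="):
                digest = first.strip().split("=", 1)[1]
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        return cls(
            generations=df["generation"].to_numpy(),
            mean_divergence=df["mean_divergence"].to_numpy(),
            sd_divergence=df["sd_divergence"].to_numpy(),
            population_sizes=df["pop_size"].to_numpy(),
            config_digest=digest,
        )


@dataclass
class SimulationResult:
    trajectory: DivergenceTrajectory
    final_population: np.ndarray  # (n_copies, L) uint8 codes
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)

    def final_sequences(self, rna: bool = False) -> list[str]:
        return [decode_sequence(row, rna=rna) for row in self.final_population]


def mutate_batch(
    pop: np.ndarray,
    allowed: np.ndarray,
    mu: float,
    kappa: float,
    rng: np.random.Generator,
) -> None:
    """One generation of per-site Bernoulli(mu) mutation, in place.

    Proposals use the Ti/Tv kernel; those outside the site's allowed set
    are rejected, so the effective substitution rate is reduced on
    constrained sites.
    """
    n, L = pop.shape
    hit = rng.random((n, L)) < mu
    rows, cols = np.nonzero(hit)
    if rows.size == 0:
        return
    cur = pop[rows, cols].astype(np.int64)
    is_ti = rng.random(rows.size) < kappa / (kappa + 2.0)
    tv_side = rng.integers(0, 2, rows.size)
    tv_target = np.where(tv_side == 0, (cur + 1) % 4, (cur + 3) % 4)
    proposal = np.where(is_ti, TRANSITION_PARTNER[cur], tv_target)
    ok = allowed[cols, proposal]
    pop[rows[ok], cols[ok]] = proposal[ok].astype(np.uint8)


def _birth_death(
    pop: np.ndarray,
    dup: float,
    ext: float,
    cap: int,
    rng: np.random.Generator,
) -> np.ndarray:
    n = pop.shape[0]
    born = rng.random(n) < dup
    survive = rng.random(n) >= ext
    parts = [pop[survive]]
    if born.any():
        parts.append(pop[born])
    new = np.concatenate(parts) if len(parts) > 1 else parts[0]
    if new.shape[0] == 0:
        # extinction rescue: one uniformly chosen pre-step copy survives
        new = pop[rng.integers(0, n)][None, :].copy()
    if new.shape[0] > cap:
        keep = rng.choice(new.shape[0], size=cap, replace=False)
        new = new[keep]
    return new


def evolve(
    config: SimulationConfig,
    snapshot_generations: Sequence[int] = (),
) -> SimulationResult:
    """Run the forward simulation and record the divergence trajectory.

    ``snapshot_generations`` asks for full population snapshots (copies of
    the sequence matrix) at the given generations, e.g. for steady-state
    distribution estimates.
    """
    rng = np.random.default_rng(config.seed)
    anc = encode_sequence(config.ancestor)
    L = len(anc)
    pop = np.tile(anc, (config.population_size, 1)).astype(np.uint8)
    allowed = config.profile.allowed
    mu, kappa = config.model.mu, config.model.kappa
    dup, ext = config.duplication_rate, config.extinction_rate
    stride = config.stride
    want_snap = set(int(g) for g in snapshot_generations)

    gens, means, sds, sizes = [0], [0.0], [0.0], [pop.shape[0]]
    snapshots: dict[int, np.ndarray] = {}
    if 0 in want_snap:
        snapshots[0] = pop.copy()
    for gen in range(1, config.generations + 1):
        if dup > 0 or ext > 0:
            pop = _birth_death(pop, dup, ext, config.population_size, rng)
        mutate_batch(pop, allowed, mu, kappa, rng)
        if gen % stride == 0 or gen == config.generations:
            div = np.mean(pop != anc, axis=1)
            gens.append(gen)
            means.append(float(div.mean()))
            sds.append(float(div.std(ddof=0)))
            sizes.append(pop.shape[0])
        if gen in want_snap:
            snapshots[gen] = pop.copy()

    traj = DivergenceTrajectory(
        generations=np.array(gens),
        mean_divergence=np.array(means),
        sd_divergence=np.array(sds),
        population_sizes=np.array(sizes),
        config_digest=config.digest(),
    )
    return SimulationResult(trajectory=traj, final_population=pop, snapshots=snapshots)


def ensemble_trajectories(
    config: SimulationConfig, n_replicates: int
) -> list[DivergenceTrajectory]:
    """Independent replicate runs seeded ``seed + i`` for i in 0..n-1."""
    out = []
    for i in range(n_replicates):
        cfg = SimulationConfig(
            ancestor=config.ancestor,
            profile=config.profile,
            model=config.model,
            generations=config.generations,
            population_size=config.population_size,
            duplication_rate=config.duplication_rate,
            extinction_rate=config.extinction_rate,
            seed=config.seed + i,
            record_every=config.record_every,
        )
        out.append(evolve(cfg).trajectory)
    return out


def ensemble_mean_trajectory(
    trajectories: list[DivergenceTrajectory],
) -> DivergenceTrajectory:
    """Average replicate trajectories sample-wise.

    Critical times are defined on the expected divergence; a single run
    under birth-death demography wanders genealogically around it, so the
    plateau is estimated on the replicate mean.  ``sd_divergence`` keeps
    the mean within-population SD (the spread across extant copies), not
    the spread between replicates.
    """
    if not trajectories:
        raise ValueError("no trajectories to average")
    gens = trajectories[0].generations
    for t in trajectories[1:]:
        if not np.array_equal(t.generations, gens):
            raise ValueError("replicates must share the sampling grid")
    return DivergenceTrajectory(
        generations=gens,
        mean_divergence=np.mean([t.mean_divergence for t in trajectories], axis=0),
        sd_divergence=np.mean([t.sd_divergence for t in trajectories], axis=0),
        population_sizes=np.round(
            np.mean([t.population_sizes for t in trajectories], axis=0)
        ).astype(int),
        config_digest="+".join(t.config_digest for t in trajectories[:1])
        + f"(x{len(trajectories)})",
    )


def expected_divergence(
    profile: PolymorphismProfile,
    model: MutationModel,
    ancestor: str,
    generations: Sequence[int],
) -> np.ndarray:
    """Exact expected divergence from the ancestor at the given generations.

    Computed by powering the allowed-set-restricted 4x4 kernel per site
    (rejected proposals fold into the diagonal).  Serves as the closed-form
    reference for Jukes-Cantor (kappa = 1) and Kimura two-parameter
    dynamics, exact for the discrete per-generation process.
    """
    anc = encode_sequence(ancestor)
    L = profile.length
    base = model.matrix
    gens = np.asarray(list(generations), dtype=int)
    # per distinct allowed-set/ancestor-state pattern, power once
    out = np.zeros((len(gens), L))
    patterns: dict[tuple, np.ndarray] = {}
    for i in range(L):
        states = tuple(np.flatnonzero(profile.allowed[i]))
        key = (states, int(anc[i]))
        if key not in patterns:
            idx = list(states)
            sub = base[np.ix_(idx, idx)].copy()
            np.fill_diagonal(sub, 0.0)
            np.fill_diagonal(sub, 1.0 - sub.sum(axis=1))
            pos = idx.index(int(anc[i]))
            probs = np.zeros(len(gens))
            for j, t in enumerate(gens):
                probs[j] = 1.0 - np.linalg.matrix_power(sub, int(t))[pos, pos]
            patterns[key] = probs
        out[:, i] = patterns[key]
    return out.mean(axis=1)
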