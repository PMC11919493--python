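"""End-to-end orchestration: references -> profile -> space -> simulation -> tcrit.

A single flat ``key = value`` configuration drives the whole analysis and
is echoed verbatim into the output directory; every artifact carries the
configuration digest and seed, and re-running the same configuration
reproduces every numeric output bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .constrained_space import (
    MutationModel,
    PolymorphismProfile,
    decode_sequence,
    effective_space,
    profile_from_alignment,
    read_fasta_alignment,
)
from .critical_time import (
    CriticalTimes,
    SteadyStateDistribution,
    critical_times,
    steady_state_distribution,
)
from .evolver import SimulationConfig, SimulationResult, evolve
from .exhaustion import TimeScale
from .synthetic_data import GeneratorSpec, generate_reference_alignment, write_fasta

log = logging.getLogger("polyspace")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Flat, fully serializable run configuration."""

    mode: str = "synthetic"  # "synthetic" | "fasta"
    fasta: str = ""
    length: int = 120
    fraction_variable: float = 0.42
    states_per_variable_site: int = 4
    depth: int = 50
    mu: float = 1.5e-3
    kappa: float = 4.0
    population_size: int = 200
    duplication_rate: float = 0.0
    extinction_rate: float = 0.0
    generations: int = 6000
    record_every: int = 0  # 0 -> automatic stride
    generation_time_minutes: float = 0.0  # 0 -> no year conversion
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "fasta"):
            raise ValueError("mode must be 'synthetic' or 'fasta'")
        if self.mode == "fasta" and not self.fasta:
            raise ValueError("fasta mode requires a fasta path")

    def items(self) -> list[tuple[str, object]]:
        return [(f.name, getattr(self, f.name)) for f in fields(self)]

    def digest(self) -> str:
        payload = "\n".join(f"{k}={v!r}" for k, v in sorted(self.items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_file(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            "".join(f"{k} = {v}\n" for k, v in self.items())
        )

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        kwargs: dict[str, object] = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = casts[types[key]](raw)
        return cls(**kwargs)


@dataclass
class RunResult:
    config: RunConfig
    profile: PolymorphismProfile
    ancestor: str
    effective_space: object
    simulation: SimulationResult
    critical: CriticalTimes
    distribution: Optional[SteadyStateDistribution]
    outdir: Path
    partial: list[str] = field(default_factory=list)


def _consensus(profile: PolymorphismProfile) -> str:
    codes = np.argmax(profile.frequencies, axis=1).astype(np.uint8)
    return decode_sequence(codes)


def run_analysis(config: RunConfig, outdir: Union[str, Path]) -> RunResult:
    """Execute every stage in order, writing the artifact bundle.

    Artifacts: references.fasta (synthetic mode), profile.tsv,
    effective_space.json, trajectory.tsv, final_population.fasta,
    critical_times.json, steady_state.tsv, config.txt.  Stage failures
    propagate as :class:`PipelineStageError` naming the stage; stages that
    could not produce an artifact are listed in ``RunResult.partial``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    partial: list[str] = []

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                if exc is None:
                    log.info("stage=%s digest=%s wall=%.2fs", name, digest, dt)
                    return False
                raise PipelineStageError(name, exc) from exc

        return _Timer()

    config.to_file(outdir / "config.txt")

    with stage("references"):
        if config.mode == "synthetic":
            refset = generate_reference_alignment(
                GeneratorSpec(
                    length=config.length,
                    fraction_variable=config.fraction_variable,
                    states_per_variable_site=config.states_per_variable_site,
                    depth=config.depth,
                    seed=config.seed,
                )
            )
            sequences = refset.sequences
            ancestor = refset.ancestor
            write_fasta(sequences, outdir / "references.fasta")
        else:
            sequences = read_fasta_alignment(config.fasta)
            ancestor = None

    with stage("profile"):
        profile = profile_from_alignment(sequences)
        if ancestor is None:
            ancestor = _consensus(profile)
        profile.to_tsv(outdir / "profile.tsv")

    with stage("effective_space"):
        model = MutationModel(mu=config.mu, kappa=config.kappa)
        eff = effective_space(profile, model)
        (outdir / "effective_space.json").write_text(
            json.dumps(
                {
                    "Le": eff.le,
                    "ke": eff.ke,
                    "log10_size": eff.log10_size,
                    "epistasis_modelled": False,
                    "config_digest": digest,
                },
                indent=2,
            )
            + "\n"
        )

    with stage("simulate"):
        sim_config = SimulationConfig(
            ancestor=ancestor,
            profile=profile,
            model=model,
            generations=config.generations,
            population_size=config.population_size,
            duplication_rate=config.duplication_rate,
            extinction_rate=config.extinction_rate,
            seed=config.seed,
            record_every=config.record_every or None,
        )
        snap_gens = sorted(
            {int(round(f * config.generations)) for f in (0.7, 0.8, 0.9, 1.0)}
        )
        result = evolve(sim_config, snapshot_generations=snap_gens)
        result.trajectory.to_tsv(outdir / "trajectory.tsv")
        write_fasta(result.final_sequences(), outdir / "final_population.fasta", prefix="copy")

    with stage("critical_times"):
        ts = (
            TimeScale(generation_time_minutes=config.generation_time_minutes)
            if config.generation_time_minutes > 0
            else None
        )
        crit = critical_times(result.trajectory, timescale=ts)
        crit.to_json(outdir / "critical_times.json")

    with stage("steady_state"):
        post = {g: p for g, p in result.snapshots.items() if g > crit.tcrit90}
        if post:
            dist = steady_state_distribution(post, ancestor, crit.tcrit90)
            dist.to_tsv(outdir / "steady_state.tsv")
        else:
            dist = None
            partial.append("steady_state")
            log.warning("no snapshots past tcrit90=%.4g; steady_state skipped", crit.tcrit90)

    return RunResult(
        config=config,
        profile=profile,
        ancestor=ancestor,
        effective_space=eff,
        simulation=result,
        critical=crit,
        distribution=dist,
        outdir=outdir,
        partial=partial,
    )
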