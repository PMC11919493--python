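"""Generator of 5S-rRNA-like reference alignments with known truth.

The 5S ribosomal RNA gene is ~120 nt, widely conserved in length and
structure yet variable in sequence: a natural testbed for constrained
polymorphic spaces.  This module emulates such reference sets with
controlled statistical structure -- a chosen fraction of variable sites,
per-site allowed-state sets of chosen size, optional GC bias -- and
returns the generating truth profile alongside, so downstream profile
recovery can be validated exactly.  It emulates the statistics of real
reference alignments; it does not model secondary-structure covariation
between paired stem sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .constrained_space import PolymorphismProfile, decode_sequence


@dataclass(frozen=True)
class GeneratorSpec:
    """Controls for the reference-alignment generator.

    Defaults emulate a 5S-like gene: 120 nt with 42% of sites variable,
    which places the downstream free-variable-site divergence plateau near
    0.75 * 0.42 ~ 0.31.
    """

    length: int = 120
    fraction_variable: float = 0.42
    states_per_variable_site: Union[int, tuple[int, int]] = 4
    gc_bias: float | None = None
    depth: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0 <= self.fraction_variable <= 1:
            raise ValueError("fraction_variable must lie in [0, 1]")
        s = self.states_per_variable_site
        lo, hi = (s, s) if isinstance(s, int) else s
        if not 2 <= lo <= hi <= 4:
            raise ValueError("states_per_variable_site must lie in 2..4")
        if self.gc_bias is not None and not 0 < self.gc_bias < 1:
            raise ValueError("gc_bias must lie in (0, 1)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")

    @property
    def n_variable(self) -> int:
        # nearest-integer allocation of fraction_variable * length
        return int(np.floor(self.fraction_variable * self.length + 0.5))


@dataclass
class ReferenceSet:
    sequences: list[str]
    profile: PolymorphismProfile
    ancestor: str


def generate_reference_alignment(spec: GeneratorSpec) -> ReferenceSet:
    """Draw a reference alignment plus its generating truth.

    Invariant sites are fixed at the ancestor state; each variable site
    gets an allowed set containing the ancestor state plus randomly chosen
    alternatives, and every reference sequence draws its state from that
    set at the (uniform) truth frequencies.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    if spec.gc_bias is None:
        composition = np.full(4, 0.25)
    else:
        g = spec.gc_bias
        composition = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    ancestor = rng.choice(4, size=L, p=composition).astype(np.uint8)

    variable_sites = np.sort(rng.choice(L, size=spec.n_variable, replace=False))
    s = spec.states_per_variable_site
    lo, hi = (s, s) if isinstance(s, int) else s

    allowed = np.zeros((L, 4), dtype=bool)
    allowed[np.arange(L), ancestor] = True
    for i in variable_sites:
        n_states = int(rng.integers(lo, hi + 1))
        others = [b for b in range(4) if b != ancestor[i]]
        extra = rng.choice(others, size=n_states - 1, replace=False)
        allowed[i, extra] = True
    freqs = allowed / allowed.sum(axis=1, keepdims=True)
    profile = PolymorphismProfile(allowed=allowed, frequencies=freqs)

    seqs = np.tile(ancestor, (spec.depth, 1))
    for i in variable_sites:
        states = np.flatnonzero(allowed[i])
        seqs[:, i] = rng.choice(states, size=spec.depth, p=freqs[i, states])
    return ReferenceSet(
        sequences=[decode_sequence(row) for row in seqs],
        profile=profile,
        ancestor=decode_sequence(ancestor),
    )


def write_fasta(
    sequences: Sequence[str],
    path: Union[str, Path],
    rna: bool = False,
    prefix: str = "ref",
) -> None:
    """Write sequences as 60-column-wrapped multi-FASTA; RNA output uses U."""
    records = []
    for i, s in enumerate(sequences, start=1):
        out = s.replace("T", "U") if rna else s
        records.append(SeqRecord(Seq(out), id=f"{prefix}_{i:04d}", description=""))
    seqio_write(records, str(path), "fasta")
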