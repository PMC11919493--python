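"""The effective polymorphic space of a gene under constraint and bias.

Purifying selection limits which nucleotides each site can carry; the
per-site allowed sets read off a reference alignment form a
*polymorphism profile*.  Mutational bias (transitions over transversions,
ratio kappa) further concentrates the exploration of the allowed states.
Together they shrink the naive ``4**L`` space to an effective space
``ke**Le`` with effective length ``Le`` (number of variable sites) and an
effective base ``ke`` between 1 and 4.

Internally the canonical alphabet is DNA (A, C, G, T); RNA input (U) is
mapped to T at I/O so 5S rRNA references and DNA sequences interoperate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

NUCLEOTIDES = "ACGT"
_CODE = {c: i for i, c in enumerate(NUCLEOTIDES)}

# purines A(0)/G(2), pyrimidines C(1)/T(3): the transition partner of a
# base code b is b XOR 2, its transversions are the opposite-parity pair.
TRANSITION_PARTNER = np.array([2, 3, 0, 1], dtype=np.int64)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA/RNA string to uint8 codes (A=0, C=1, G=2, T/U=3)."""
    s = seq.upper().replace("U", "T")
    try:
        return np.array([_CODE[c] for c in s], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide symbol {exc.args[0]!r} in sequence") from exc


def decode_sequence(codes: np.ndarray, rna: bool = False) -> str:
    alphabet = "ACGU" if rna else NUCLEOTIDES
    return "".join(alphabet[int(c)] for c in codes)


def build_substitution_matrix(mu: float, kappa: float) -> np.ndarray:
    """Kimura-style single-generation substitution kernel.

    Per generation a site mutates with probability ``mu``; given a
    mutation, the transition is chosen with probability ``kappa/(kappa+2)``
    and each transversion with ``1/(kappa+2)``.  ``kappa = 1`` recovers the
    uniform (Jukes-Cantor-like) kernel.  Rows sum to 1.
    """
    if not 0 <= mu < 1:
        raise ValueError(f"mu must be in [0, 1), got {mu}")
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    p = np.zeros((4, 4))
    for a in range(4):
        ti = TRANSITION_PARTNER[a]
        for b in range(4):
            if b == a:
                continue
            p[a, b] = mu * (kappa if b == ti else 1.0) / (kappa + 2.0)
        p[a, a] = 1.0 - p[a].sum()
    return p


@dataclass(frozen=True)
class MutationModel:
    """Per-site substitution model with rate ``mu`` and Ti/Tv ratio ``kappa``."""

    mu: float
    kappa: float = 4.0
    matrix: np.ndarray = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = build_substitution_matrix(self.mu, self.kappa)
        object.__setattr__(self, "matrix", m)

    @property
    def transition_given_mutation(self) -> float:
        return self.kappa / (self.kappa + 2.0)


@dataclass(frozen=True)
class PolymorphismProfile:
    """Per-site allowed nucleotides and their observed frequencies.

    ``allowed`` is an (L, 4) boolean matrix; ``frequencies`` an (L, 4)
    matrix that is zero outside allowed states and sums to 1 per site.
    A site with a single allowed state is invariant.
    """

    allowed: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        allowed = np.asarray(self.allowed, dtype=bool)
        freqs = np.asarray(self.frequencies, dtype=float)
        if allowed.ndim != 2 or allowed.shape[1] != 4:
            raise ValueError("allowed must have shape (L, 4)")
        if freqs.shape != allowed.shape:
            raise ValueError("frequencies must match allowed in shape")
        if not allowed.any(axis=1).all():
            raise ValueError("every site must allow at least one nucleotide")
        if (freqs[~allowed] != 0).any():
            raise ValueError("frequencies must be zero outside allowed states")
        if not np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("frequencies must sum to 1 per site")
        object.__setattr__(self, "allowed", allowed)
        object.__setattr__(self, "frequencies", freqs)

    @property
    def length(self) -> int:
        return self.allowed.shape[0]

    @property
    def variable_mask(self) -> np.ndarray:
        return self.allowed.sum(axis=1) > 1

    @property
    def n_variable(self) -> int:
        return int(self.variable_mask.sum())

    def allowed_sets(self) -> list[frozenset[str]]:
        return [
            frozenset(NUCLEOTIDES[b] for b in range(4) if self.allowed[i, b])
            for i in range(self.length)
        ]

    @classmethod
    def free(cls, length: int) -> "PolymorphismProfile":
        """All sites free, uniform frequencies (no purifying constraint)."""
        allowed = np.ones((length, 4), dtype=bool)
        return cls(allowed=allowed, frequencies=np.full((length, 4), 0.25))

    def to_tsv(self, path: Union[str, Path]) -> None:
        sets = self.allowed_sets()
        rows = []
        for i in range(self.length):
            states = "".join(sorted(sets[i]))
            freqs = ",".join(
                f"{self.frequencies[i, _CODE[c]]:.6g}" for c in sorted(sets[i])
            )
            rows.append((i + 1, states, freqs))
        pd.DataFrame(rows, columns=["site", "allowed_states", "frequencies"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "PolymorphismProfile":
        df = pd.read_csv(path, sep="\t", dtype={"allowed_states": str})
        L = len(df)
        allowed = np.zeros((L, 4), dtype=bool)
        freqs = np.zeros((L, 4))
        for i, row in df.iterrows():
            states = row["allowed_states"]
            fvals = [float(x) for x in str(row["frequencies"]).split(",")]
            for c, f in zip(states, fvals):
                allowed[i, _CODE[c]] = True
                freqs[i, _CODE[c]] = f
        freqs /= freqs.sum(axis=1, keepdims=True)
        return cls(allowed=allowed, frequencies=freqs)


def read_fasta_alignment(path: Union[str, Path]) -> list[str]:
    """Read a plain multi-FASTA alignment (wrapped or unwrapped, any case)."""
    seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return seqs


def profile_from_alignment(alignment: Iterable[str]) -> PolymorphismProfile:
    """Polymorphism profile observed in a gap-free equal-length alignment.

    Per site, the allowed set is the set of observed nucleotides and the
    frequencies are the observed proportions.  Order of sequences is
    irrelevant.  Gaps are rejected: indels are out of scope.
    """
    seqs = list(alignment)
    if len(seqs) < 2:
        raise ValueError("alignment must contain at least 2 sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    mat = np.stack([encode_sequence(s) for s in seqs])
    L = mat.shape[1]
    counts = np.zeros((L, 4))
    for b in range(4):
        counts[:, b] = (mat == b).sum(axis=0)
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return PolymorphismProfile(allowed=counts > 0, frequencies=freqs)


@dataclass(frozen=True)
class EffectiveSpace:
    """The constrained polymorphic space ``ke**Le``."""

    le: float
    ke: float
    log10_size: float

    def __post_init__(self) -> None:
        if self.le < 0:
            raise ValueError("Le must be >= 0")
        if self.ke < 1:
            raise ValueError("ke must be >= 1")


def _site_accessibility_entropy(allowed_row: np.ndarray, kappa: float) -> float:
    """Mean entropy (nats) of the rate-weighted accessibility distribution.

    From each allowed origin state the accessible states are weighted by
    their relative substitution rates: the origin and its transition
    partner carry weight ``kappa``, transversion targets weight 1 (the
    origin keeps its transition-class weight because on mutational
    timescales the chain mixes within the transition pair first).  The
    entropy is averaged over allowed origins.  At ``kappa = 1`` this gives
    ``log |allowed|``; as ``kappa -> inf`` a fully free site tends to its
    transition pair, entropy ``log 2``.
    """
    states = np.flatnonzero(allowed_row)
    entropies = []
    for a in states:
        w = np.zeros(4)
        for b in states:
            if b == a or b == TRANSITION_PARTNER[a]:
                w[b] = kappa
            else:
                w[b] = 1.0
        w = w[states]
        p = w / w.sum()
        entropies.append(float(-(p * np.log(p)).sum()))
    return float(np.mean(entropies))


def effective_space(
    profile: PolymorphismProfile, model: MutationModel
) -> EffectiveSpace:
    """Effective length and base of the constrained space.

    ``Le`` counts the variable sites (allowed set of size >= 2); ``ke`` is
    the perplexity (exp of mean entropy in nats) of the per-variable-site
    accessibility distribution under the model's Ti/Tv bias -- an
    effective-alphabet measure between 1 and 4 that equals the allowed-set
    size at ``kappa = 1`` and shrinks toward the transition-pair size as
    bias grows.
    """
    var = profile.variable_mask
    le = int(var.sum())
    if le == 0:
        return EffectiveSpace(le=0.0, ke=1.0, log10_size=0.0)
    mean_entropy = float(
        np.mean(
            [
                _site_accessibility_entropy(profile.allowed[i], model.kappa)
                for i in np.flatnonzero(var)
            ]
        )
    )
    ke = math.exp(mean_entropy)
    return EffectiveSpace(le=float(le), ke=ke, log10_size=le * math.log10(ke))


def site_stationary_distributions(
    profile: PolymorphismProfile, model: MutationModel
) -> np.ndarray:
    """Stationary distribution of the allowed-set-restricted kernel, per site.

    Proposals landing outside the allowed set are rejected (the state is
    kept), which preserves the kernel's symmetry; the stationary law is
    computed numerically from the restricted 4x4 kernel.  Returns (L, 4).
    """
    out = np.zeros((profile.length, 4))
    base = model.matrix
    for i in range(profile.length):
        states = np.flatnonzero(profile.allowed[i])
        if len(states) == 1:
            out[i, states[0]] = 1.0
            continue
        sub = base[np.ix_(states, states)].copy()
        np.fill_diagonal(sub, 0.0)
        np.fill_diagonal(sub, 1.0 - sub.sum(axis=1))
        vals, vecs = np.linalg.eig(sub.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, k])
        pi = np.abs(pi) / np.abs(pi).sum()
        out[i, states] = pi
    return out
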