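"""Seeded synthetic proteomes and pair sets with a planted interaction signal.

The generator emulates the shape of a real benchmark — variable-length
sequences over the 20-letter alphabet and two pair classes — while planting a
controllable, learnable signal: *interface motifs*.  The proteome is split
into three disjoint pools:

* an **A pool** and a **B pool** whose members each receive (with probability
  ``signal_strength``) several copies of one motif of a complementary motif
  pair; positive (interacting) pairs are drawn as (A-pool, B-pool) couples, so
  an interacting pair tends to carry co-occurring complementary motifs;
* a **background pool** with no planted motifs, from which negative pairs are
  drawn.

At ``signal_strength = 0`` nothing is planted and the two classes are
statistically exchangeable; at 1 every positive pair carries both motifs.
Motif co-occurrence perturbs the conjoint-triad channel directly (rare
class-triples) and the autocovariance channel weakly — the intended signal
path for the downstream autoencoders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .sequence_io import (
    STANDARD_AMINO_ACIDS,
    LabeledPairSet,
    PairExample,
    ProteinRecord,
    write_fasta,
    write_pairs,
)


class SynthesisError(ValueError):
    pass


#: Complementary motif pairs (consecutive entries pair up).  W/C/M-heavy
#: 5-mers are vanishingly rare under a uniform background, so a planted copy
#: is unambiguous evidence.
DEFAULT_MOTIF_LIBRARY = ["WCWCW", "MCWCM", "WWMCW", "CMWWC"]


@dataclass
class SynthesisConfig:
    """Generation settings; defaults give a clearly separable benchmark.

    ``motif_library`` holds complementary pairs as consecutive entries
    (entry 0 plants into A-pool partners, entry 1 into B-pool partners, etc.);
    ``motif_copies`` copies are planted per carrying protein, emulating
    repeated short linear interface motifs.  ``background`` is a length-20
    probability vector over the alphabetical residue order (None = uniform).
    """

    n_proteins: int = 400
    length_range: tuple[int, int] = (50, 250)
    n_pos: int = 1000
    n_neg: int = 1000
    motif_library: list[str] = field(default_factory=lambda: list(DEFAULT_MOTIF_LIBRARY))
    motif_copies: int = 3
    signal_strength: float = 1.0
    background: list[float] | None = None
    lag: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo <= self.lag:
            raise SynthesisError(
                f"minimum length ({lo}) must exceed lag ({self.lag})"
            )
        if lo < 3 or hi < lo:
            raise SynthesisError(f"invalid length_range {self.length_range}")
        if not (0.0 <= self.signal_strength <= 1.0):
            raise SynthesisError("signal_strength must be in [0, 1]")
        if len(self.motif_library) < 2 or len(self.motif_library) % 2:
            raise SynthesisError("motif_library must hold complementary pairs (even length >= 2)")
        for m in self.motif_library:
            if not m or any(c not in STANDARD_AMINO_ACIDS for c in m):
                raise SynthesisError(f"motif {m!r} uses non-standard residues")
            if len(m) > lo:
                raise SynthesisError(f"motif {m!r} longer than the shortest sequence")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or np.any(bg < 0) or not np.isclose(bg.sum(), 1.0):
                raise SynthesisError("background must be a length-20 probability vector")
        if self.n_proteins < 8:
            raise SynthesisError("need at least 8 proteins to form the three pools")

    def to_yaml(self, path: str | Path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        data["length_range"] = list(self.length_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthesisConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["length_range"] = tuple(data["length_range"])
        return cls(**data)


#: A skewed residue composition (roughly SwissProt-like frequencies) to
#: stress CT/AC normalization; pass as ``background=SKEWED_BACKGROUND``.
SKEWED_BACKGROUND = [
    0.083, 0.014, 0.055, 0.067, 0.039, 0.071, 0.023, 0.059, 0.058, 0.097,
    0.024, 0.040, 0.047, 0.039, 0.055, 0.066, 0.053, 0.069, 0.011, 0.030,
]


def _rng(config: SynthesisConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _pools(config: SynthesisConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic pool membership: first quarter A, second quarter B,
    remaining half background."""
    n = config.n_proteins
    q = n // 4
    idx = np.arange(n)
    return idx[:q], idx[q : 2 * q], idx[2 * q :]


def _planting_plan(config: SynthesisConfig) -> dict[int, str]:
    """Which protein index receives which motif (seeded stream 1)."""
    rng = _rng(config, 1)
    pool_a, pool_b, _ = _pools(config)
    n_motif_pairs = len(config.motif_library) // 2
    plan: dict[int, str] = {}
    for pool, offset in ((pool_a, 0), (pool_b, 1)):
        for i in pool:
            if rng.random() < config.signal_strength:
                pair_idx = int(rng.integers(n_motif_pairs))
                plan[int(i)] = config.motif_library[2 * pair_idx + offset]
            else:
                rng.integers(n_motif_pairs)  # keep the stream aligned
    return plan


def _plant(seq: list[str], motif: str, copies: int, rng: np.random.Generator) -> None:
    for _ in range(copies):
        start = int(rng.integers(0, len(seq) - len(motif) + 1))
        seq[start : start + len(motif)] = list(motif)


def generate_proteome(config: SynthesisConfig) -> list[ProteinRecord]:
    """Draw ``n_proteins`` sequences and plant motifs per the seeded plan."""
    rng = _rng(config, 0)
    lo, hi = config.length_range
    bg = None if config.background is None else np.asarray(config.background)
    alphabet = np.array(list(STANDARD_AMINO_ACIDS))
    plan = _planting_plan(config)
    plant_rng = _rng(config, 3)

    records = []
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(alphabet, size=length, p=bg))
        if i in plan:
            _plant(seq, plan[i], config.motif_copies, plant_rng)
        records.append(ProteinRecord(id=f"SYN{i:05d}", sequence="".join(seq)))
    return records


def _sample_cross_pairs(
    rng: np.random.Generator, left: np.ndarray, right: np.ndarray, n: int
) -> list[tuple[int, int]]:
    total = len(left) * len(right)
    if n > total:
        raise SynthesisError(f"requested {n} pairs but only {total} distinct ones exist")
    flat = rng.choice(total, size=n, replace=False)
    return [(int(left[f // len(right)]), int(right[f % len(right)])) for f in flat]


def _sample_within_pairs(
    rng: np.random.Generator, pool: np.ndarray, n: int
) -> list[tuple[int, int]]:
    m = len(pool)
    total = m * (m - 1)
    if n > total:
        raise SynthesisError(f"requested {n} pairs but only {total} distinct ones exist")
    flat = rng.choice(total, size=n, replace=False)
    out = []
    for f in flat:
        i, j = divmod(int(f), m - 1)
        if j >= i:
            j += 1
        out.append((int(pool[i]), int(pool[j])))
    return out


def generate_pairs(proteome: list[ProteinRecord], config: SynthesisConfig) -> LabeledPairSet:
    """Sample ``n_pos`` positive (A-pool x B-pool) and ``n_neg`` negative
    (background-pool) ordered pairs, never duplicating an ordered pair."""
    if not proteome:
        raise SynthesisError("empty proteome")
    rng = _rng(config, 2)
    pool_a, pool_b, pool_bg = _pools(config)
    pos = _sample_cross_pairs(rng, pool_a, pool_b, config.n_pos)
    neg = _sample_within_pairs(rng, pool_bg, config.n_neg)
    ids = [p.id for p in proteome]
    return LabeledPairSet(
        positives=[PairExample(ids[a], ids[b], True) for a, b in pos],
        negatives=[PairExample(ids[a], ids[b], False) for a, b in neg],
    )


def generate_dataset(config: SynthesisConfig) -> tuple[list[ProteinRecord], LabeledPairSet]:
    proteome = generate_proteome(config)
    return proteome, generate_pairs(proteome, config)


def write_dataset(
    proteome: list[ProteinRecord],
    pairs: LabeledPairSet,
    config: SynthesisConfig,
    directory: str | Path,
) -> None:
    """Emit proteins.fasta, pairs.tsv and the config (with its seed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta(proteome, directory / "proteins.fasta")
    write_pairs(pairs, directory / "pairs.tsv")
    config.to_yaml(directory / "synthesis.yaml")


def motif_count_classifier(
    proteome: list[ProteinRecord], pairs: list[PairExample], config: SynthesisConfig
) -> list[bool]:
    """Brute-force oracle: call a pair positive iff both partners contain any
    library motif.  Used to verify the planted signal is present, not part of
    the learning pipeline."""
    seqs = {p.id: p.sequence for p in proteome}

    def has_motif(pid: str) -> bool:
        return any(m in seqs[pid] for m in config.motif_library)

    return [has_motif(p.id_a) and has_motif(p.id_b) for p in pairs]
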