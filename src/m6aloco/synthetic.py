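"""Synthetic labeled sequence windows with motif signal and chromosome confounding.

The generator emulates the structure of a base-resolution m6A benchmark:
fixed-length windows centered on an adenosine, chromosome labels, a ~1:5
positive:negative imbalance, and positives enriched for the degenerate
DRACH consensus ([AGT][AG]AC[ACT]) near the window center.  Two knobs
control what a model can learn:

* ``motif_insert_prob_pos`` / ``motif_insert_prob_neg`` — how often a
  concrete DRACH instance is planted near the center of positives and
  negatives; the gap between them is the genuine, chromosome-independent
  signal.
* ``confound_strength`` (gamma in [0,1]) — a chromosome-specific background
  base-composition shift.  With :func:`make_confounded_pair` the class
  label is additionally coupled to which composition group a chromosome
  belongs to, creating a shortcut feature that generalizes *within* but not
  *across* chromosomes: random splits reward it, leave-one-chromosome-out
  splits expose it.

Everything is driven by a single seed and reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np

from .io import Dataset, SequenceRecord

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
DRACH = "DRACH"
BASES = np.array(list("ACGT"))


class SynthConfigError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Generator settings; defaults are desk-scale (hundreds of records,
    201-nt windows).  ``paper_scale`` switches to the benchmark's shape."""

    n_pos: int = 300
    n_neg: int = 1500
    L: int = 201
    chromosomes: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 7))
    chromosome_weights: tuple[float, ...] | None = None
    motif: str = DRACH
    motif_insert_prob_pos: float = 0.9
    motif_insert_prob_neg: float = 0.1
    center_jitter: int = 5
    confound_strength: float = 0.0
    motif_exclusive: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.L < len(self.motif):
            raise SynthConfigError(f"L={self.L} shorter than motif {self.motif!r}")
        for p in (self.motif_insert_prob_pos, self.motif_insert_prob_neg):
            if not 0 <= p <= 1:
                raise SynthConfigError(f"motif insert probability {p} outside [0,1]")
        if not 0 <= self.confound_strength <= 1:
            raise SynthConfigError(f"confound_strength {self.confound_strength} outside [0,1]")
        if len(self.chromosomes) < 1:
            raise SynthConfigError("at least one chromosome label required")
        if self.chromosome_weights is not None:
            w = np.asarray(self.chromosome_weights, dtype=float)
            if len(w) != len(self.chromosomes) or not np.isclose(w.sum(), 1.0):
                raise SynthConfigError("chromosome weights must match labels and sum to 1")
        bad = set(self.motif) - set(IUPAC)
        if bad:
            raise SynthConfigError(f"motif contains non-IUPAC codes {sorted(bad)}")

    @classmethod
    def paper_scale(cls, seed: int = 0, **overrides) -> "SynthConfig":
        """Benchmark-shaped preset: 10,424 / 54,949 windows of 2001 nt over
        chr1..chr23 (a full run takes substantial CPU time)."""
        kw = dict(
            n_pos=10424,
            n_neg=54949,
            L=2001,
            chromosomes=tuple(f"chr{i}" for i in range(1, 24)),
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict:
        return asdict(self)


def sample_motif_instance(motif: str, rng: np.random.Generator) -> str:
    """A concrete realization of a degenerate IUPAC consensus (uniform over
    the compatible letters at each position)."""
    return "".join(IUPAC[c][rng.integers(len(IUPAC[c]))] for c in motif)


def _chromosome_background(cfg: SynthConfig, signs: np.ndarray) -> np.ndarray:
    """Per-chromosome base probabilities (n_chrom, 4) over (A,C,G,T).

    ``signs`` (+1/-1 per chromosome) pushes composition toward GC (+1) or
    AT (-1) by 0.15 * gamma of probability mass per base.
    """
    shift = 0.15 * cfg.confound_strength
    probs = np.full((len(cfg.chromosomes), 4), 0.25)
    probs[:, [1, 2]] += signs[:, None] * shift  # C, G
    probs[:, [0, 3]] -= signs[:, None] * shift  # A, T
    return probs


def _make_records(
    cfg: SynthConfig,
    chrom_of: np.ndarray,
    labels: np.ndarray,
    bg_probs: np.ndarray,
    rng: np.random.Generator,
    tag: str,
) -> list[SequenceRecord]:
    center = cfg.L // 2
    m = len(cfg.motif)
    records = []
    for i, (ci, lab) in enumerate(zip(chrom_of, labels)):
        codes = rng.choice(4, size=cfg.L, p=bg_probs[ci])
        seq = BASES[codes]
        if cfg.motif_exclusive:
            # strictly separable background: resample any chance occurrence
            # of the consensus so the motif appears only where inserted
            for _ in range(200):
                hits = motif_match_positions("".join(seq), cfg.motif)
                if not hits:
                    break
                for h in hits:
                    seq[h : h + m] = BASES[rng.choice(4, size=m, p=bg_probs[ci])]
        # positives get a central A (the putative methylated adenosine)
        if lab == 1:
            seq[center] = "A"
        p_ins = cfg.motif_insert_prob_pos if lab == 1 else cfg.motif_insert_prob_neg
        if rng.random() < p_ins:
            jitter = int(rng.integers(-cfg.center_jitter, cfg.center_jitter + 1))
            # place the motif so its central A (position 2 of DRACH) sits at
            # center + jitter, clipped inside the window
            start = min(max(center + jitter - 2, 0), cfg.L - m)
            inst = sample_motif_instance(cfg.motif, rng)
            seq[start : start + m] = list(inst)
        records.append(
            SequenceRecord(
                id=f"{tag}{'pos' if lab == 1 else 'neg'}{i:06d}",
                chromosome=cfg.chromosomes[ci],
                sequence="".join(seq),
                label=int(lab),
            )
        )
    return records


def generate(cfg: SynthConfig) -> Dataset:
    """Generate a labeled dataset under ``cfg`` (seeded, reproducible).

    Chromosome assignment is independent of the label; the composition
    shift (when gamma > 0) differs across chromosomes but carries no label
    information, so only the motif gap is learnable signal.
    """
    rng = np.random.default_rng(cfg.seed)
    n_chrom = len(cfg.chromosomes)
    signs = np.where(np.arange(n_chrom) % 2 == 0, 1.0, -1.0)
    bg = _chromosome_background(cfg, signs)
    weights = (
        np.full(n_chrom, 1.0 / n_chrom)
        if cfg.chromosome_weights is None
        else np.asarray(cfg.chromosome_weights)
    )
    labels = np.concatenate([np.ones(cfg.n_pos, dtype=int), np.zeros(cfg.n_neg, dtype=int)])
    chrom_of = rng.choice(n_chrom, size=len(labels), p=weights)
    records = _make_records(cfg, chrom_of, labels, bg, rng, tag="syn-")
    return Dataset(records, cfg.L, provenance=f"synthetic:{cfg.to_dict()}")


def make_confounded_pair(cfg: SynthConfig) -> Dataset:
    """Generate a dataset whose label is partially predictable from the
    chromosome-specific background composition.

    Chromosomes alternate between a GC-shifted and an AT-shifted group
    (shift 0.15 * gamma per base); a positive record lands in the
    GC-shifted group with probability (1 + gamma) / 2 (negatives
    symmetrically in the AT-shifted group).  Motif insertion probabilities
    are equalized across classes here, so the composition shortcut is the
    *only* learnable signal: models score well under random splits (which
    share chromosomes between train and test) and fall to chance under
    leave-one-chromosome-out evaluation.
    """
    # gamma = 0 is allowed: it degenerates to an unconfounded control with
    # the same construction, useful as a negative control for the RS/LOCO gap
    if len(cfg.chromosomes) < 3:
        raise SynthConfigError("confounded construction needs >= 3 chromosomes")
    cfg = replace(
        cfg,
        motif_insert_prob_neg=cfg.motif_insert_prob_pos,  # no motif signal gap
    )
    rng = np.random.default_rng(cfg.seed)
    n_chrom = len(cfg.chromosomes)
    signs = np.where(np.arange(n_chrom) % 2 == 0, 1.0, -1.0)
    bg = _chromosome_background(cfg, signs)
    gamma = cfg.confound_strength
    labels = np.concatenate([np.ones(cfg.n_pos, dtype=int), np.zeros(cfg.n_neg, dtype=int)])
    gc_group = np.nonzero(signs > 0)[0]
    at_group = np.nonzero(signs < 0)[0]
    p_match = (1 + gamma) / 2
    chrom_of = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        preferred, other = (gc_group, at_group) if lab == 1 else (at_group, gc_group)
        group = preferred if rng.random() < p_match else other
        chrom_of[i] = group[rng.integers(len(group))]
    records = _make_records(cfg, chrom_of, labels, bg, rng, tag="conf-")
    return Dataset(records, cfg.L, provenance=f"synthetic-confounded:{cfg.to_dict()}")


def gc_content(seq: str) -> float:
    n = sum(1 for c in seq if c in "GC")
    return n / len(seq)


def motif_match_positions(seq: str, motif: str = DRACH) -> list[int]:
    """Start positions where the degenerate consensus matches (brute scan)."""
    sets = [set(IUPAC[c]) for c in motif]
    m = len(motif)
    return [
        i
        for i in range(len(seq) - m + 1)
        if all(seq[i + j] in sets[j] for j in range(m))
    ]
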