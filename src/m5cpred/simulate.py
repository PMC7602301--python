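"""Synthetic cytosine-centered fragment datasets with controllable signal.

Real m5C benchmark sets are pairs of fragment classes (modified /
unmodified) that differ by position-specific nucleotide enrichment around
the central cytosine and/or by global compositional bias.  This generator
emulates that structure: negatives are drawn i.i.d. from a background
nucleotide distribution at every non-center position; positives start from
the same background and may additionally carry

* ``pwm_effect``: per-position probability boosts (position -> nucleotide
  -> added mass, renormalized) — a position-specific motif;
* ``composition_shift``: a global tilt of the background applied at every
  position — a compositional signal with no positional anchor;
* ``gap_motif``: a gapped nucleotide pair (n1, K intervening positions,
  n2) planted at a random valid location with a given probability.

Both classes share the central C by construction.  Everything is
deterministic under the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_core import (
    ALPHABET,
    LabeledDataset,
    RNAFragment,
    RNASequence,
    write_fasta,
)

_NUCS = "ACGU"


def _normalize_probs(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (4,) or (p < 0).any() or p.sum() <= 0:
        raise ValueError(f"invalid probability vector {p!r}")
    return p / p.sum()


@dataclass(frozen=True)
class GapMotif:
    """A gapped pair n1 x{K} n2 planted in positives with probability p."""

    gap: int
    pair: tuple[str, str]
    prob: float = 1.0

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if any(n not in _NUCS for n in self.pair):
            raise ValueError(f"pair must be over {_NUCS}")
        if not 0 <= self.prob <= 1:
            raise ValueError("prob must be in [0, 1]")


@dataclass
class SyntheticSpec:
    """Generation parameters for a labeled fragment dataset.

    Defaults mirror the shape of a small published benchmark: 200+200
    training fragments of width 41 (lambda = 20) on a uniform background.
    """

    n_pos: int = 200
    n_neg: int = 200
    lambda_flank: int = 20
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    pwm_effect: dict[int, dict[str, float]] = field(default_factory=dict)
    composition_shift: dict[str, float] = field(default_factory=dict)
    gap_motif: GapMotif | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if self.lambda_flank < 1:
            raise ValueError("lambda_flank must be >= 1")
        _normalize_probs(self.background)
        width = 2 * self.lambda_flank + 1
        for pos in self.pwm_effect:
            if not 1 <= pos <= width:
                raise ValueError(f"pwm_effect position {pos} outside 1..{width}")
            if pos == self.lambda_flank + 1:
                raise ValueError("pwm_effect cannot target the central C")

    def to_json(self) -> dict:
        return {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "lambda_flank": self.lambda_flank,
            "background": list(self.background),
            "pwm_effect": {str(k): v for k, v in self.pwm_effect.items()},
            "composition_shift": dict(self.composition_shift),
            "gap_motif": (
                {"gap": self.gap_motif.gap, "pair": list(self.gap_motif.pair),
                 "prob": self.gap_motif.prob}
                if self.gap_motif else None
            ),
            "seed": self.seed,
        }


def _tilted(base: np.ndarray, shift: dict[str, float]) -> np.ndarray:
    p = base.copy()
    for nuc, mass in shift.items():
        p[_NUCS.index(nuc)] += mass
    if (p < 0).any():
        raise ValueError("composition shift drives a probability negative")
    return p / p.sum()


def _class_position_probs(spec: SyntheticSpec, positive: bool) -> np.ndarray:
    """(width, 4) per-position sampling distribution for one class."""
    width = 2 * spec.lambda_flank + 1
    base = _normalize_probs(spec.background)
    if positive and spec.composition_shift:
        base = _tilted(base, spec.composition_shift)
    probs = np.tile(base, (width, 1))
    if positive:
        for pos_1b, boosts in spec.pwm_effect.items():
            p = probs[pos_1b - 1].copy()
            for nuc, mass in boosts.items():
                p[_NUCS.index(nuc)] += mass
            probs[pos_1b - 1] = p / p.sum()
    return probs


def _sample_class(
    spec: SyntheticSpec, n: int, positive: bool, rng: np.random.Generator
) -> list[RNAFragment]:
    width = 2 * spec.lambda_flank + 1
    center = spec.lambda_flank
    probs = _class_position_probs(spec, positive)
    # inverse-CDF sampling per position, vectorized over fragments
    cdf = np.cumsum(probs, axis=1)
    u = rng.random((n, width))
    codes = (u[:, :, None] > cdf[None, :, :]).sum(axis=2)  # (n, width) in 0..3
    codes[:, center] = 1  # central C
    if positive and spec.gap_motif is not None:
        m = spec.gap_motif
        span = m.gap + 1
        starts = [
            s for s in range(width - span)
            if s != center and s + span != center
        ]
        if not starts:
            raise ValueError("gap motif does not fit around the central C")
        plant = rng.random(n) < m.prob
        chosen = rng.integers(0, len(starts), size=n)
        for i in np.where(plant)[0]:
            s = starts[chosen[i]]
            codes[i, s] = _NUCS.index(m.pair[0])
            codes[i, s + span] = _NUCS.index(m.pair[1])
    label = "pos" if positive else "neg"
    fragments = []
    for i in range(n):
        window = "".join(_NUCS[c] for c in codes[i])
        fragments.append(
            RNAFragment(
                parent_id=f"syn_{label}_{i}",
                center_pos_1based=center + 1,
                window=window,
                lambda_flank=spec.lambda_flank,
            )
        )
    return fragments


def generate_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Draw a labeled fragment dataset; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    pos = _sample_class(spec, spec.n_pos, True, rng)
    neg = _sample_class(spec, spec.n_neg, False, rng)
    labels = np.concatenate([np.ones(spec.n_pos, int), np.zeros(spec.n_neg, int)])
    return LabeledDataset(
        fragments=pos + neg, labels=labels, lambda_flank=spec.lambda_flank
    )


def write_benchmark_layout(
    data: LabeledDataset,
    out_dir: str | Path,
    test_fraction: float,
    seed: int = 42,
    spec: SyntheticSpec | None = None,
) -> dict[str, Path]:
    """Write a stratified train/test x pos/neg FASTA layout.

    Returns the four file paths (plus a manifest when a spec is given).
    Membership is disjoint; the split is stratified by class.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}
    split_idx: dict[str, np.ndarray] = {}
    for label, name in ((1, "pos"), (0, "neg")):
        idx = np.where(data.labels == label)[0]
        n_test = int(round(test_fraction * len(idx)))
        if n_test < 1 or n_test >= len(idx):
            raise ValueError(f"test_fraction {test_fraction} leaves an empty split")
        perm = rng.permutation(idx)
        split_idx[f"test_{name}"] = np.sort(perm[:n_test])
        split_idx[f"train_{name}"] = np.sort(perm[n_test:])
    for key, idx in split_idx.items():
        seqs = [
            RNASequence(id=data.fragments[i].parent_id, residues=data.fragments[i].window)
            for i in idx
        ]
        path = out_dir / f"{key}.fasta"
        write_fasta(seqs, path)
        paths[key] = path
    if spec is not None:
        manifest = out_dir / "manifest.json"
        manifest.write_text(json.dumps(
            {"spec": spec.to_json(), "test_fraction": test_fraction,
             "split_seed": seed},
            indent=2,
        ))
        paths["manifest"] = manifest
    return paths
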