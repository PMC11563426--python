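"""Synthetic labelled peptide datasets with a tunable compositional class signal.

The generator emulates the shape of a curated MHC-II binder benchmark — two
classes of short peptides (default 8–25 residues) at a configurable
imbalance (default 394 positive : 848 negative) — without claiming any
biological realism beyond residue composition:

1. A shared baseline residue propensity vector (natural amino-acid background
   frequencies) is shifted by +delta (total probability mass, spread over a
   designated residue subset, default the charged residues DEHKR) for the
   positive class and by -delta for the negative class.
2. Each peptide draws its own composition from a Dirichlet centred on its
   class propensity (``concentration`` controls within-class dispersion),
   then samples residues i.i.d. per position.

``delta = 0`` makes the classes exchangeable in distribution, so any
classifier's cross-validated AUC must sit near 0.5 — the pipeline's null
calibration. Because the signal is purely compositional, every encoder in
:mod:`pepstack.encoders` can expose it, and its strength is graded by delta.
Generation is a pure function of the spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from pepstack.encoders import EncoderSpec
from pepstack.peptide_io import ALPHABET, LabeledDataset, PeptideSequence

#: background amino-acid frequencies (approximate natural abundance, in
#: canonical order A,C,D,...,Y), normalised to sum to 1
BACKGROUND = np.array([
    0.0825, 0.0138, 0.0545, 0.0672, 0.0386, 0.0707, 0.0227, 0.0591, 0.0580,
    0.0965, 0.0241, 0.0406, 0.0474, 0.0393, 0.0553, 0.0663, 0.0535, 0.0686,
    0.0110, 0.0292,
])
BACKGROUND = BACKGROUND / BACKGROUND.sum()

#: residues whose propensity is shifted between classes (charged residues)
DEFAULT_SHIFT_RESIDUES = ("D", "E", "H", "K", "R")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic two-class peptide dataset.

    ``delta`` is the total probability mass moved onto (positives) or off
    (negatives) the shifted residue subset; ``concentration`` is the Dirichlet
    concentration governing within-class compositional dispersion (higher =
    tighter around the class propensity).
    """

    n_pos: int = 394
    n_neg: int = 848
    length_range: tuple[int, int] = (8, 25)
    delta: float = 0.1
    concentration: float = 50.0
    shift_residues: tuple[str, ...] = DEFAULT_SHIFT_RESIDUES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        bad = [r for r in self.shift_residues if r not in ALPHABET]
        if bad or not self.shift_residues or len(self.shift_residues) >= 20:
            raise ValueError(f"invalid shift residue subset {self.shift_residues}")


def class_propensities(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Residue propensity vectors (positive class, negative class).

    delta/|subset| is added per subset residue for positives (removed for
    negatives), with the complement adjusted proportionally; values are
    floored at 1e-4 and renormalised, so extreme deltas stay valid
    distributions.
    """
    in_subset = np.array([a in spec.shift_residues for a in ALPHABET])
    out = []
    for sign in (+1.0, -1.0):
        p = BACKGROUND.copy()
        shift = sign * spec.delta
        p[in_subset] += shift / in_subset.sum()
        # rebalance the complement proportionally to keep sum at 1
        comp_mass = p[~in_subset].sum()
        p[~in_subset] *= (comp_mass - shift) / comp_mass
        p = np.clip(p, 1e-4, None)
        out.append(p / p.sum())
    return out[0], out[1]


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Generate a labelled dataset (positives first, then negatives)."""
    rng = np.random.default_rng(spec.seed)
    p_pos, p_neg = class_propensities(spec)
    lo, hi = spec.length_range
    alphabet = np.array(list(ALPHABET))
    sequences: list[PeptideSequence] = []
    labels: list[int] = []
    for cls, n, prop in ((1, spec.n_pos, p_pos), (0, spec.n_neg, p_neg)):
        tag = "pos" if cls == 1 else "neg"
        for i in range(n):
            comp = rng.dirichlet(spec.concentration * prop)
            L = int(rng.integers(lo, hi + 1))
            residues = "".join(rng.choice(alphabet, size=L, p=comp))
            sequences.append(PeptideSequence(f"{tag}_{i + 1:05d}", residues))
            labels.append(cls)
    return LabeledDataset(sequences, np.array(labels, dtype=int))


def signal_curve(
    deltas: list[float],
    template: SyntheticSpec,
    model=None,
    encoders: list[EncoderSpec] | None = None,
    n_seeds: int = 5,
    protocol: str = "split80_20",
) -> list[tuple[float, float]]:
    """Mean held-out AUC of a model as a function of the class effect size.

    For each delta, ``n_seeds`` datasets are generated from the template
    (seeds template.seed .. template.seed + n_seeds - 1), the model is
    evaluated under ``protocol``, and the mean AUC recorded. AUC is
    non-decreasing in delta up to sampling noise, rising from ~0.5 at
    delta = 0 — the acceptance surface for the learning stack.
    """
    from pepstack.evaluation import run_protocol  # deferred: avoids cycle

    if len(deltas) < 1:
        raise ValueError("at least one delta value is required")
    encoders = encoders or [EncoderSpec("AAC")]
    points = []
    for delta in deltas:
        aucs = []
        for s in range(n_seeds):
            spec = replace(template, delta=float(delta), seed=template.seed + s)
            report = run_protocol(
                generate(spec), encoders, model=model, protocol=protocol,
                seed=spec.seed,
            )
            aucs.append(report.aggregate["auc"])
        points.append((float(delta), float(np.mean(aucs))))
    return points
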