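"""Minority-class oversampling for imbalanced peptide feature matrices.

Both methods create synthetic minority points by linear interpolation

    s = x_i + lam * (x_k - x_i),   lam ~ Uniform(0, 1),

where x_i is a minority point and x_k one of its k nearest minority
neighbours. They differ only in how many synthetics each minority point is
allotted:

* **SMOTE** spreads the total evenly across minority points.
* **ADASYN** allots proportionally to the density ratio r_i = (number of
  majority points among x_i's k nearest neighbours in the full data) / k, so
  points near the class boundary — whose neighbourhoods are majority-
  dominated — receive more synthetics, adaptively shifting the decision
  boundary toward the hard examples.

Distances are Euclidean on the encoded features without rescaling:
composition features are already commensurate in [0, 1]. An optional min-max
scaler (applied for neighbour search only) is available and off by default.

Every synthetic row's generating pair (i, k) is recorded in the returned
:class:`ResampledDataset`, making the interpolation contract auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from pepstack.encoders import FeatureMatrix


class BalancingError(ValueError):
    """Input unsuitable for oversampling (single class, minority too small)."""


@dataclass
class ResampledDataset:
    """A feature matrix + labels after oversampling, with per-row provenance.

    Original rows come first, verbatim and in input order; synthetic rows
    follow. ``provenance`` flags each row ``original`` or ``synthetic``;
    ``pairs`` holds, for each synthetic row, the row indices (into the
    original matrix) of its generating pair (x_i, x_k) and the drawn lam.
    """

    matrix: FeatureMatrix
    labels: np.ndarray
    provenance: np.ndarray  # array of {"original","synthetic"}
    seed: int
    method: str  # {"ADASYN", "SMOTE", "none"}
    pairs: np.ndarray  # shape (n_synthetic, 2), int row indices
    lams: np.ndarray  # shape (n_synthetic,)

    def __post_init__(self) -> None:
        if len(self.provenance) != self.matrix.shape[0]:
            raise ValueError("provenance length must equal row count")

    @property
    def n_synthetic(self) -> int:
        return int((self.provenance == "synthetic").sum())


def _validate(m: FeatureMatrix, labels: np.ndarray, k: int) -> tuple[np.ndarray, int, int]:
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != m.shape[0]:
        raise BalancingError("labels length must match matrix rows")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise BalancingError("both classes must be present")
    minority = int(classes[np.argmin(counts)])
    majority = int(classes[np.argmax(counts)])
    if counts.min() < k + 1:
        raise BalancingError(
            f"minority class has {counts.min()} members; needs >= k+1 = {k + 1}"
        )
    return labels, minority, majority


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allotments g_i with sum exactly ``total``, proportional to weights.

    Floors the real allotments and distributes the remaining units to the
    largest fractional parts (ties broken by lower index, deterministic).
    """
    if total <= 0 or weights.sum() == 0:
        return np.zeros(len(weights), dtype=int)
    w = weights / weights.sum()
    real = w * total
    g = np.floor(real).astype(int)
    short = total - g.sum()
    if short > 0:
        frac = real - np.floor(real)
        order = np.lexsort((np.arange(len(w)), -frac))
        g[order[:short]] += 1
    return g


def interpolate(xi: np.ndarray, xk: np.ndarray, lam: float) -> np.ndarray:
    """The oversampling rule s = x_i + lam (x_k - x_i).

    The endpoints are exact: lam = 0 returns x_i and lam = 1 returns x_k
    bit-for-bit (the algebraic form loses the last bit in floating point).
    """
    if lam == 0.0:
        return np.array(xi, dtype=float, copy=True)
    if lam == 1.0:
        return np.array(xk, dtype=float, copy=True)
    return xi + lam * (xk - xi)


def _interpolate(
    X_min: np.ndarray,
    allot: np.ndarray,
    nn_min: np.ndarray,
    min_rows: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw synthetics: for each minority point i, allot[i] interpolations
    toward uniformly chosen minority neighbours. Returns (rows, pairs, lams)."""
    synth, pairs, lams = [], [], []
    for i in range(len(X_min)):
        for _ in range(allot[i]):
            j = nn_min[i][rng.integers(0, nn_min.shape[1])]
            lam = rng.uniform(0.0, 1.0)
            synth.append(interpolate(X_min[i], X_min[j], lam))
            pairs.append((min_rows[i], min_rows[j]))
            lams.append(lam)
    if not synth:
        d = X_min.shape[1]
        return np.empty((0, d)), np.empty((0, 2), dtype=int), np.empty(0)
    return np.asarray(synth), np.asarray(pairs, dtype=int), np.asarray(lams)


def _assemble(
    m: FeatureMatrix,
    labels: np.ndarray,
    minority: int,
    synth: np.ndarray,
    pairs: np.ndarray,
    lams: np.ndarray,
    seed: int,
    method: str,
) -> ResampledDataset:
    n_orig, n_syn = m.shape[0], synth.shape[0]
    values = np.vstack([m.values, synth])
    row_ids = list(m.row_ids) + [f"syn_{method.lower()}_{i:05d}" for i in range(n_syn)]
    out_labels = np.concatenate([labels, np.full(n_syn, minority, dtype=int)])
    provenance = np.array(["original"] * n_orig + ["synthetic"] * n_syn)
    return ResampledDataset(
        matrix=FeatureMatrix(row_ids, list(m.col_names), values),
        labels=out_labels,
        provenance=provenance,
        seed=seed,
        method=method,
        pairs=pairs,
        lams=lams,
    )


def _neighbour_space(X: np.ndarray, scale: bool) -> np.ndarray:
    if not scale:
        return X
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (X - lo) / span


def adasyn_oversample(
    m: FeatureMatrix,
    labels: np.ndarray,
    k: int = 5,
    target_ratio: float = 1.0,
    seed: int = 0,
    scale: bool = False,
) -> ResampledDataset:
    """Adaptive synthetic oversampling of the minority class.

    Generates G = round(N_maj * target_ratio) - N_min synthetics, allotted
    across minority points proportionally to the fraction of majority points
    among each point's k nearest neighbours in the full data (largest-
    remainder rounding, so the total is exact). Interpolation partners are
    minority-class neighbours. Deterministic given ``seed``.
    """
    labels, minority, majority = _validate(m, labels, k)
    rng = np.random.default_rng(seed)
    X = m.values
    min_rows = np.flatnonzero(labels == minority)
    n_min, n_maj = len(min_rows), int((labels == majority).sum())
    G = int(round(n_maj * target_ratio)) - n_min
    if G <= 0:
        return _assemble(m, labels, minority, np.empty((0, X.shape[1])),
                         np.empty((0, 2), dtype=int), np.empty(0), seed, "ADASYN")
    Xs = _neighbour_space(X, scale)
    X_min_s = Xs[min_rows]
    # density ratio from k nearest neighbours in the FULL data (self excluded)
    nn_all = NearestNeighbors(n_neighbors=k + 1).fit(Xs)
    _, idx_all = nn_all.kneighbors(X_min_s)
    neigh = idx_all[:, 1:]
    r = (labels[neigh] == majority).sum(axis=1) / k
    if r.sum() == 0:  # no boundary points: fall back to uniform allotment
        r = np.ones(n_min)
    allot = _largest_remainder(r, G)
    # interpolation partners from k nearest MINORITY neighbours
    nn_min = NearestNeighbors(n_neighbors=k + 1).fit(X_min_s)
    _, idx_min = nn_min.kneighbors(X_min_s)
    synth, pairs, lams = _interpolate(X[min_rows], allot, idx_min[:, 1:], min_rows, rng)
    return _assemble(m, labels, minority, synth, pairs, lams, seed, "ADASYN")


def smote_oversample(
    m: FeatureMatrix,
    labels: np.ndarray,
    k: int = 5,
    target_ratio: float = 1.0,
    seed: int = 0,
    scale: bool = False,
) -> ResampledDataset:
    """SMOTE: identical interpolation, uniform allotment across minority points."""
    labels, minority, majority = _validate(m, labels, k)
    rng = np.random.default_rng(seed)
    X = m.values
    min_rows = np.flatnonzero(labels == minority)
    n_min, n_maj = len(min_rows), int((labels == majority).sum())
    G = int(np.ceil(n_maj * target_ratio)) - n_min
    if G <= 0:
        return _assemble(m, labels, minority, np.empty((0, X.shape[1])),
                         np.empty((0, 2), dtype=int), np.empty(0), seed, "SMOTE")
    Xs = _neighbour_space(X, scale)
    nn_min = NearestNeighbors(n_neighbors=k + 1).fit(Xs[min_rows])
    _, idx_min = nn_min.kneighbors(Xs[min_rows])
    allot = _largest_remainder(np.ones(n_min), G)
    synth, pairs, lams = _interpolate(X[min_rows], allot, idx_min[:, 1:], min_rows, rng)
    return _assemble(m, labels, minority, synth, pairs, lams, seed, "SMOTE")


def no_resample(m: FeatureMatrix, labels: np.ndarray, seed: int = 0) -> ResampledDataset:
    """Pass-through: matrix returned bit-for-bit, method recorded as none."""
    labels = np.asarray(labels, dtype=int)
    return ResampledDataset(
        matrix=m,
        labels=labels,
        provenance=np.array(["original"] * m.shape[0]),
        seed=seed,
        method="none",
        pairs=np.empty((0, 2), dtype=int),
        lams=np.empty(0),
    )


def oversample(
    m: FeatureMatrix,
    labels: np.ndarray,
    method: str = "ADASYN",
    k: int = 5,
    target_ratio: float = 1.0,
    seed: int = 0,
    scale: bool = False,
) -> ResampledDataset:
    """Dispatch on ``method`` in {"ADASYN", "SMOTE", "none"}."""
    if method == "ADASYN":
        return adasyn_oversample(m, labels, k, target_ratio, seed, scale)
    if method == "SMOTE":
        return smote_oversample(m, labels, k, target_ratio, seed, scale)
    if method == "none":
        return no_resample(m, labels, seed)
    raise BalancingError(f"unknown oversampling method: {method!r}")
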