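"""Composition-based peptide feature encoders.

Every encoder is a pure function from a peptide to a fixed-length, named
feature vector; identical parameters always yield identical feature names,
regardless of the input peptide, so columns are comparable across datasets.
Vector lengths under default parameters:

====================  ======  ==========================================
encoder               length  description
====================  ======  ==========================================
AAC                       20  amino-acid composition
DPC                      400  dipeptide composition
TPC                     8000  tripeptide composition
CKSAAP (gap_max=3)      1600  k-spaced amino-acid pair composition
PAAC (lambda=2)           22  pseudo-amino-acid composition
APAAC (lambda=2)          24  amphiphilic pseudo-amino-acid composition
CTDC                      39  CTD composition (13 properties x 3 groups)
CTriad                   343  conjoint-triad class 3-mers (7^3 bins)
Moran (nlag=2)             2  Moran autocorrelation of hydrophobicity
RAACC                      4  reduced-alphabet (4-cluster) composition
====================  ======  ==========================================

Feature names follow ``<ENCODER>.<key>`` (``AAC.A``, ``DPC.AC``,
``CKSAAP.g1.AC``, ``CTDC.polarity.G2`` ...), which fixes column identity
across runs and makes concatenated matrices self-describing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from pepstack.peptide_io import ALPHABET, LabeledDataset, PeptideSequence
from pepstack._property_tables import (
    CONJOINT_TRIAD_CLASSES,
    CTD_PROPERTIES,
    HYDROPHILICITY,
    HYDROPHOBICITY,
    RAAC_SCHEMES,
    SIDE_CHAIN_MASS,
    standardized,
)

_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
_PAIRS = ["".join(p) for p in itertools.product(ALPHABET, repeat=2)]
_TRIPLES = ["".join(t) for t in itertools.product(ALPHABET, repeat=3)]

# standardized property vectors in canonical residue order
_H1 = np.array([standardized(HYDROPHOBICITY)[a] for a in ALPHABET])
_H2 = np.array([standardized(HYDROPHILICITY)[a] for a in ALPHABET])
_M = np.array([standardized(SIDE_CHAIN_MASS)[a] for a in ALPHABET])
_MORAN_PROPERTIES: dict[str, np.ndarray] = {
    "hydrophobicity": _H1,
    "hydrophilicity": _H2,
    "side_chain_mass": _M,
}


class EncodingError(ValueError):
    """A peptide fails an encoder's length precondition or a spec is invalid."""


def _codes(residues: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX[c] for c in residues), dtype=np.intp, count=len(residues))


# ---------------------------------------------------------------------------
# individual encoders: each returns a 1-D float vector; *_names returns the
# matching column keys (without the encoder prefix)


def encode_aac(residues: str) -> np.ndarray:
    """Per-residue frequency: count of each amino acid divided by length."""
    if not residues:
        raise EncodingError("AAC requires length >= 1")
    v = np.bincount(_codes(residues), minlength=20).astype(float)
    return v / len(residues)


def encode_dpc(residues: str) -> np.ndarray:
    """Ordered adjacent-pair frequency, denominator L - 1."""
    L = len(residues)
    if L < 2:
        raise EncodingError("DPC requires length >= 2")
    c = _codes(residues)
    v = np.bincount(c[:-1] * 20 + c[1:], minlength=400).astype(float)
    return v / (L - 1)


def encode_tpc(residues: str) -> np.ndarray:
    """Ordered adjacent-triple frequency, denominator L - 2."""
    L = len(residues)
    if L < 3:
        raise EncodingError("TPC requires length >= 3")
    c = _codes(residues)
    v = np.bincount(c[:-2] * 400 + c[1:-1] * 20 + c[2:], minlength=8000).astype(float)
    return v / (L - 2)


def encode_cksaap(residues: str, gap_max: int = 3) -> np.ndarray:
    """Pair composition at residue separations 0..gap_max.

    Block for gap g counts positions i with pair (s[i], s[i+g+1]), normalised
    by the number of such positions (L - g - 1); each block sums to 1.
    """
    L = len(residues)
    if gap_max < 0:
        raise EncodingError("gap_max must be >= 0")
    if L < gap_max + 2:
        raise EncodingError(
            f"CKSAAP with gap_max={gap_max} requires length >= {gap_max + 2}"
        )
    c = _codes(residues)
    blocks = []
    for g in range(gap_max + 1):
        step = g + 1
        pairs = c[: L - step] * 20 + c[step:]
        blocks.append(np.bincount(pairs, minlength=400).astype(float) / (L - step))
    return np.concatenate(blocks)


def _paac_theta(c: np.ndarray, lam: int) -> np.ndarray:
    """Sequence-order correlation factors theta_1..theta_lam.

    theta_d averages, over all residue pairs d apart, the mean squared
    difference of the three standardized properties (hydrophobicity,
    hydrophilicity, side-chain mass).
    """
    L = len(c)
    thetas = np.empty(lam)
    for d in range(1, lam + 1):
        a, b = c[: L - d], c[d:]
        corr = (
            (_H1[b] - _H1[a]) ** 2 + (_H2[b] - _H2[a]) ** 2 + (_M[b] - _M[a]) ** 2
        ) / 3.0
        thetas[d - 1] = corr.mean()
    return thetas


def encode_paac(residues: str, lam: int = 2, w: float = 0.05) -> np.ndarray:
    """Chou's pseudo-amino-acid composition: 20 + lambda components.

    The first 20 components are residue frequencies and the last ``lam`` are
    weighted sequence-order factors; all share the denominator
    1 + w * sum(theta), so the vector sums to 1 (theta is nonnegative by
    construction). ``lam = 0`` reduces exactly to AAC.
    """
    L = len(residues)
    if lam < 0:
        raise EncodingError("lambda must be >= 0")
    if L <= lam:
        raise EncodingError(f"PAAC with lambda={lam} requires length > {lam}")
    c = _codes(residues)
    f = np.bincount(c, minlength=20).astype(float) / L
    theta = _paac_theta(c, lam)
    denom = 1.0 + w * theta.sum()
    return np.concatenate([f / denom, w * theta / denom])


def encode_apaac(residues: str, lam: int = 2, w: float = 0.05) -> np.ndarray:
    """Amphiphilic pseudo-amino-acid composition: 20 + 2*lambda components.

    Separate hydrophobicity and hydrophilicity correlation chains contribute
    tau_1..tau_2lam (tau_{2d-1} from hydrophobicity products at lag d,
    tau_{2d} from hydrophilicity); shared denominator 1 + w * sum(tau).
    """
    L = len(residues)
    if lam < 0:
        raise EncodingError("lambda must be >= 0")
    if L <= lam:
        raise EncodingError(f"APAAC with lambda={lam} requires length > {lam}")
    c = _codes(residues)
    f = np.bincount(c, minlength=20).astype(float) / L
    taus = np.empty(2 * lam)
    for d in range(1, lam + 1):
        a, b = c[: L - d], c[d:]
        taus[2 * d - 2] = (_H1[a] * _H1[b]).mean()
        taus[2 * d - 1] = (_H2[a] * _H2[b]).mean()
    denom = 1.0 + w * taus.sum()
    return np.concatenate([f / denom, w * taus / denom])


_CTD_GROUP_CODE: dict[str, np.ndarray] = {}
for _prop, _groups in CTD_PROPERTIES.items():
    code = np.empty(20, dtype=np.intp)
    for gi, members in enumerate(_groups):
        for aa in members:
            code[_AA_INDEX[aa]] = gi
    _CTD_GROUP_CODE[_prop] = code


def encode_ctdc(residues: str) -> np.ndarray:
    """CTD composition: group frequencies for 13 physicochemical properties.

    Each property partitions the alphabet into 3 groups; the three features
    per property are the fractions of sequence residues in each group and sum
    to 1.
    """
    if not residues:
        raise EncodingError("CTDC requires length >= 1")
    c = _codes(residues)
    L = len(residues)
    out = np.empty(39)
    for pi, prop in enumerate(CTD_PROPERTIES):
        g = _CTD_GROUP_CODE[prop][c]
        out[3 * pi : 3 * pi + 3] = np.bincount(g, minlength=3) / L
    return out


_CT_CLASS_CODE = np.empty(20, dtype=np.intp)
for _ci, _members in enumerate(CONJOINT_TRIAD_CLASSES):
    for _aa in _members:
        _CT_CLASS_CODE[_AA_INDEX[_aa]] = _ci


def encode_ctriad(
    residues: str, normalization: str = "minmax"
) -> np.ndarray:
    """Conjoint-triad descriptor: counts of residue-class 3-mers (7^3 bins).

    Residues map to 7 classes grouped by dipole and side-chain volume; every
    window of 3 consecutive residues increments one of the 343 class-triple
    bins. ``minmax`` normalisation rescales counts to (c - min) / max over the
    bins (the descriptor's original convention); ``frequency`` divides by the
    window count L - 2.
    """
    L = len(residues)
    if L < 3:
        raise EncodingError("CTriad requires length >= 3")
    cls = _CT_CLASS_CODE[_codes(residues)]
    bins = cls[:-2] * 49 + cls[1:-1] * 7 + cls[2:]
    counts = np.bincount(bins, minlength=343).astype(float)
    if normalization == "minmax":
        mx = counts.max()
        return (counts - counts.min()) / mx if mx > 0 else counts
    if normalization == "frequency":
        return counts / (L - 2)
    raise EncodingError(f"unknown CTriad normalization: {normalization!r}")


def encode_moran(
    residues: str, nlag: int = 2, property_set: tuple[str, ...] = ("hydrophobicity",)
) -> np.ndarray:
    """Moran spatial autocorrelation of residue properties at lags 1..nlag.

    I(d) = [(1/(L-d)) sum_i (x_i - xbar)(x_{i+d} - xbar)]
           / [(1/L) sum_i (x_i - xbar)^2],
    with x the standardized property value along the chain and xbar its
    sequence mean. Zero property variance (homopolymers) yields 0 at every
    lag by convention.
    """
    L = len(residues)
    if nlag < 1:
        raise EncodingError("nlag must be >= 1")
    if L <= nlag:
        raise EncodingError(f"Moran with nlag={nlag} requires length > {nlag}")
    unknown = [p for p in property_set if p not in _MORAN_PROPERTIES]
    if unknown:
        raise EncodingError(f"unknown Moran properties: {unknown}")
    c = _codes(residues)
    out = np.empty(nlag * len(property_set))
    k = 0
    for prop in property_set:
        x = _MORAN_PROPERTIES[prop][c]
        xbar = x.mean()
        dev = x - xbar
        var = (dev**2).mean()
        for d in range(1, nlag + 1):
            if var == 0.0:
                out[k] = 0.0
            else:
                out[k] = (dev[: L - d] * dev[d:]).mean() / var
            k += 1
    return out


def encode_raacc(residues: str, cluster_scheme: str = "standard4") -> np.ndarray:
    """Composition over a reduced amino-acid alphabet (cluster frequencies)."""
    if not residues:
        raise EncodingError("RAACC requires length >= 1")
    clusters = RAAC_SCHEMES.get(cluster_scheme)
    if clusters is None:
        raise EncodingError(f"unknown cluster scheme: {cluster_scheme!r}")
    joined = "".join(clusters)
    if sorted(joined) != sorted(ALPHABET):
        raise EncodingError(f"scheme {cluster_scheme!r} is not a partition of the alphabet")
    code = np.empty(20, dtype=np.intp)
    for ci, members in enumerate(clusters):
        for aa in members:
            code[_AA_INDEX[aa]] = ci
    g = code[_codes(residues)]
    return np.bincount(g, minlength=len(clusters)) / len(residues)


# ---------------------------------------------------------------------------
# registry

@dataclass(frozen=True)
class _EncoderDef:
    fn: Callable[..., np.ndarray]
    defaults: dict
    names: Callable[[dict], list[str]]
    min_length: Callable[[dict], int]


def _ctdc_names(_: dict) -> list[str]:
    return [f"{p}.G{g}" for p in CTD_PROPERTIES for g in (1, 2, 3)]


_REGISTRY: dict[str, _EncoderDef] = {
    "AAC": _EncoderDef(encode_aac, {}, lambda p: list(ALPHABET), lambda p: 1),
    "DPC": _EncoderDef(encode_dpc, {}, lambda p: list(_PAIRS), lambda p: 2),
    "TPC": _EncoderDef(encode_tpc, {}, lambda p: list(_TRIPLES), lambda p: 3),
    "CKSAAP": _EncoderDef(
        encode_cksaap,
        {"gap_max": 3},
        lambda p: [f"g{g}.{pr}" for g in range(p["gap_max"] + 1) for pr in _PAIRS],
        lambda p: p["gap_max"] + 2,
    ),
    "PAAC": _EncoderDef(
        encode_paac,
        {"lam": 2, "w": 0.05},
        lambda p: list(ALPHABET) + [f"theta{i}" for i in range(1, p["lam"] + 1)],
        lambda p: p["lam"] + 1,
    ),
    "APAAC": _EncoderDef(
        encode_apaac,
        {"lam": 2, "w": 0.05},
        lambda p: list(ALPHABET) + [f"tau{i}" for i in range(1, 2 * p["lam"] + 1)],
        lambda p: p["lam"] + 1,
    ),
    "CTDC": _EncoderDef(encode_ctdc, {}, _ctdc_names, lambda p: 1),
    "CTriad": _EncoderDef(
        encode_ctriad,
        {"normalization": "minmax"},
        lambda p: [f"{i}{j}{k}" for i in range(1, 8) for j in range(1, 8) for k in range(1, 8)],
        lambda p: 3,
    ),
    "Moran": _EncoderDef(
        encode_moran,
        {"nlag": 2, "property_set": ("hydrophobicity",)},
        lambda p: [f"{prop}.lag{d}" for prop in p["property_set"] for d in range(1, p["nlag"] + 1)],
        lambda p: p["nlag"] + 1,
    ),
    "RAACC": _EncoderDef(
        encode_raacc,
        {"cluster_scheme": "standard4"},
        lambda p: [f"c{i}" for i in range(1, len(RAAC_SCHEMES[p["cluster_scheme"]]) + 1)],
        lambda p: 1,
    ),
}


def list_encoders() -> list[str]:
    """Names of all registered encoders."""
    return list(_REGISTRY)


@dataclass(frozen=True)
class EncoderSpec:
    """An encoder name plus descriptor-specific parameters.

    Unspecified parameters take the registry defaults (CKSAAP gap_max=3,
    PAAC/APAAC lambda=2 w=0.05, Moran nlag=2 on hydrophobicity, RAACC
    4-cluster scheme).
    """

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _REGISTRY:
            raise EncodingError(
                f"unknown encoder {self.name!r}; available: {sorted(_REGISTRY)}"
            )
        d = _REGISTRY[self.name]
        unknown = set(self.params) - set(d.defaults)
        if unknown:
            raise EncodingError(f"{self.name}: unknown parameter(s) {sorted(unknown)}")
        # freeze merged params so the spec is hashable and self-contained
        merged = {**d.defaults, **self.params}
        object.__setattr__(self, "params", merged)

    @property
    def feature_names(self) -> list[str]:
        d = _REGISTRY[self.name]
        return [f"{self.name}.{k}" for k in d.names(self.params)]

    @property
    def vector_length(self) -> int:
        return len(self.feature_names)

    @property
    def min_length(self) -> int:
        """Shortest peptide this encoder accepts."""
        return _REGISTRY[self.name].min_length(self.params)

    def encode(self, residues: str) -> np.ndarray:
        return _REGISTRY[self.name].fn(residues, **self.params)

    def to_dict(self) -> dict:
        p = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.params.items()}
        return {"name": self.name, "params": p}

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderSpec":
        p = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.get("params", {}).items()}
        return cls(d["name"], p)


@dataclass
class FeatureMatrix:
    """Named, ordered feature columns over a set of peptides."""

    row_ids: list[str]
    col_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.row_ids), len(self.col_names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.row_ids)} rows / {len(self.col_names)} columns"
            )
        if len(set(self.col_names)) != len(self.col_names):
            raise ValueError("duplicate column names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_names)

    def reorder_columns(self, names: list[str]) -> "FeatureMatrix":
        """Return a matrix with columns realigned to ``names`` by name.

        Raises with an explicit listing of missing/extra columns on mismatch.
        """
        missing = [n for n in names if n not in set(self.col_names)]
        extra = [n for n in self.col_names if n not in set(names)]
        if missing or extra:
            raise ValueError(
                f"feature columns do not match: missing={missing[:5]}"
                f"{'...' if len(missing) > 5 else ''}, extra={extra[:5]}"
                f"{'...' if len(extra) > 5 else ''}"
            )
        idx = [self.col_names.index(n) for n in names]
        return FeatureMatrix(self.row_ids, list(names), self.values[:, idx])


def encode_peptide(
    peptide: PeptideSequence | str, spec: EncoderSpec
) -> pd.Series:
    """Encode a single peptide; returns a named feature vector."""
    residues = peptide.residues if isinstance(peptide, PeptideSequence) else peptide
    return pd.Series(spec.encode(residues), index=spec.feature_names)


def encode_dataset(
    dataset: LabeledDataset, specs: list[EncoderSpec]
) -> FeatureMatrix:
    """Encode every peptide with every spec; concatenate columns in spec order.

    All sequences are checked against every encoder's length precondition
    up front; failures are reported together with the offending peptide ids.
    """
    if not specs:
        raise EncodingError("at least one encoder spec is required")
    offending: list[str] = []
    for spec in specs:
        m = spec.min_length
        offending += [s.id for s in dataset.sequences if len(s) < m]
    if offending:
        raise EncodingError(
            f"sequence(s) too short for requested encoders: {sorted(set(offending))}"
        )
    col_names = [n for spec in specs for n in spec.feature_names]
    n = len(dataset)
    values = np.empty((n, len(col_names)))
    for i, s in enumerate(dataset.sequences):
        values[i] = np.concatenate([spec.encode(s.residues) for spec in specs])
    return FeatureMatrix([s.id for s in dataset.sequences], col_names, values)
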