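"""Sequence feature encodings for m5C site prediction.

Six feature families turn a cytosine-centered window of length L = 2*lambda
+ 1 into a numeric vector:

* **KNF** (k-nucleotide frequency): frequencies of all 4^K k-mers,
  ``N(kmer) / (L - K + 1)``.  The standard K = 4 reporting variant is called
  "4NF" in reports.
* **KSNPF** (k-spaced nucleotide pair frequency): frequencies of the 16
  ordered nucleotide pairs separated by exactly K positions.
* **PSNP** (position-specific nucleotide propensity): per-position lookup
  into ``X = M+ - M-``, the difference between the per-position nucleotide
  frequency matrices of the positive and negative training classes.
* **KSPSDP** (k-spaced position-specific dinucleotide propensity): the
  gapped-dinucleotide analogue of PSNP; K = 0 is the classic PSDP.
* **PseDNC** (pseudo dinucleotide composition): dinucleotide frequencies
  augmented with lambda_pse tiered correlation factors computed from three
  z-scored physicochemical properties of RNA dinucleotides (free energy,
  hydrophilicity, stacking energy).
* **CPD** (chemical property with density): per position, a 3-bit chemical
  code (ring structure, hydrogen bonding, functional group) plus the
  cumulative-prefix density of the nucleotide at that position.

'N' is a padding symbol, not a nucleotide: it is excluded from all counts,
has zero propensity, a zero chemical triple and zero density.

PSNP/KSPSDP matrices are *fitted* on labeled training data; the
:class:`PropensityModel` carries a fingerprint of the fragments it was
fitted on so cross-validation code can prove the held-out fold never leaked
into the matrices used to encode it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .sequence_core import CODE_N, LabeledDataset, RNAFragment

FamilyName = Literal["KNF", "KSNPF", "PSNP", "KSPSDP", "PseDNC", "CPD"]

FAMILIES: tuple[FamilyName, ...] = ("KNF", "KSNPF", "PSNP", "KSPSDP", "PseDNC", "CPD")

_DINUCS = [a + b for a in "ACGU" for b in "ACGU"]


# ---------------------------------------------------------------------------
# Physicochemical property table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhysChemTable:
    """Free energy / hydrophilicity / stacking energy of the 16 RNA
    dinucleotides, raw and z-scored per property across the 16 values."""

    values: pd.DataFrame       # 16 x 3, indexed AA..UU in code order
    normalized: pd.DataFrame   # same shape, each column mean 0 / SD 1

    @classmethod
    def default(cls) -> "PhysChemTable":
        with resources.files("m5cpred.data").joinpath("physchem_rna.csv").open() as fh:
            df = pd.read_csv(fh, index_col="dinucleotide")
        df = df.loc[_DINUCS]
        norm = (df - df.mean()) / df.std(ddof=0)
        return cls(values=df, normalized=norm)

    def normalized_array(self) -> np.ndarray:
        """(16, 3) z-scored property matrix in dinucleotide code order."""
        return self.normalized.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Propensity matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PropensityModel:
    """Fitted position-specific propensity matrices.

    ``psnp`` has shape (4, 2*lambda+1): column i is the difference between
    positive- and negative-class nucleotide frequencies at position i.  The
    center column is identically zero because both classes carry C there.
    ``kspsdp[K]`` has shape (16, 2*lambda - K) over gapped dinucleotides.
    ``fitted_on`` is the fingerprint of the training fragments (leakage
    guard).
    """

    psnp: np.ndarray
    kspsdp: dict[int, np.ndarray]
    lambda_flank: int
    fitted_on: str

    @classmethod
    def zeros(cls, lambda_flank: int, gaps: Iterable[int] = ()) -> "PropensityModel":
        width = 2 * lambda_flank + 1
        return cls(
            psnp=np.zeros((4, width)),
            kspsdp={k: np.zeros((16, 2 * lambda_flank - k)) for k in gaps},
            lambda_flank=lambda_flank,
            fitted_on="zeros",
        )


def _position_frequencies(codes: np.ndarray) -> np.ndarray:
    """(4, L) per-position nucleotide frequencies; 'N' contributes to no row
    and is excluded from the column normalizer."""
    n, L = codes.shape
    counts = np.zeros((4, L))
    for a in range(4):
        counts[a] = (codes == a).sum(axis=0)
    denom = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(denom > 0, counts / denom, 0.0)
    return freq


def _gapped_dinuc_ids(codes: np.ndarray, K: int) -> np.ndarray:
    """(n, L-K-1) gapped-dinucleotide ids (a*4+b); 16 marks an 'N' member."""
    a = codes[:, : codes.shape[1] - K - 1]
    b = codes[:, K + 1 :]
    ids = a.astype(int) * 4 + b.astype(int)
    ids[(a == CODE_N) | (b == CODE_N)] = 16
    return ids


def _gapped_frequencies(codes: np.ndarray, K: int) -> np.ndarray:
    """(16, L-K-1) per-start-position gapped dinucleotide frequencies."""
    ids = _gapped_dinuc_ids(codes, K)
    n, width = ids.shape
    counts = np.zeros((16, width))
    for d in range(16):
        counts[d] = (ids == d).sum(axis=0)
    denom = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, counts / denom, 0.0)


def fit_propensities(train: LabeledDataset, gaps: Sequence[int] = ()) -> PropensityModel:
    """Fit PSNP and per-gap KSPSDP matrices as M(+) - M(-).

    Each column of M(+/-) is the nucleotide (or gapped-dinucleotide)
    frequency distribution at that position within the positive (negative)
    class, normalized over non-'N' occurrences.
    """
    if train.n_pos == 0 or train.n_neg == 0:
        raise ValueError("propensity requires both classes")
    codes = train.code_matrix()
    pos = codes[train.labels == 1]
    neg = codes[train.labels == 0]
    psnp = _position_frequencies(pos) - _position_frequencies(neg)
    kspsdp = {}
    for k in gaps:
        if not 0 <= k <= 2 * train.lambda_flank - 1:
            raise ValueError(f"gap K={k} out of range for lambda={train.lambda_flank}")
        kspsdp[int(k)] = _gapped_frequencies(pos, k) - _gapped_frequencies(neg, k)
    return PropensityModel(
        psnp=psnp,
        kspsdp=kspsdp,
        lambda_flank=train.lambda_flank,
        fitted_on=train.fingerprint(),
    )


# ---------------------------------------------------------------------------
# Batch encoders (operate on the (n, L) uint8 code matrix)
# ---------------------------------------------------------------------------


def _knf_batch(codes: np.ndarray, K: int) -> np.ndarray:
    n, L = codes.shape
    if not 1 <= K <= 6:
        raise ValueError("K must be in 1..6")
    if K >= L:
        raise ValueError(f"K={K} must be smaller than window length {L}")
    n_windows = L - K + 1
    ids = np.zeros((n, n_windows), dtype=np.int64)
    valid = np.ones((n, n_windows), dtype=bool)
    for j in range(K):
        col = codes[:, j : j + n_windows].astype(np.int64)
        valid &= col != CODE_N
        ids = ids * 4 + np.where(col == CODE_N, 0, col)
    dim = 4**K
    rows = np.repeat(np.arange(n), n_windows).reshape(n, n_windows)
    flat = (rows * dim + ids)[valid]
    counts = np.bincount(flat, minlength=n * dim).reshape(n, dim).astype(float)
    return counts / n_windows


def _ksnpf_batch(
    codes: np.ndarray, K: int, denominator: str = "window"
) -> np.ndarray:
    n, L = codes.shape
    if not 0 <= K <= L - 2:
        raise ValueError(f"K={K} out of range 0..{L - 2}")
    ids = _gapped_dinuc_ids(codes, K)
    rows = np.broadcast_to(np.arange(n)[:, None], ids.shape)
    valid = ids < 16
    flat = (rows * 16 + ids)[valid]
    counts = np.bincount(flat, minlength=n * 16).reshape(n, 16).astype(float)
    if denominator == "window":
        denom = L - K + 1
    elif denominator == "count":
        denom = L - K - 1
    else:
        raise ValueError("denominator must be 'window' or 'count'")
    return counts / denom


def _lookup_with_zero_row(matrix: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Per-column lookup; the sentinel id (last row) maps to 0."""
    augmented = np.vstack([matrix, np.zeros((1, matrix.shape[1]))])
    cols = np.broadcast_to(np.arange(matrix.shape[1]), ids.shape)
    return augmented[ids, cols]


def _psnp_batch(codes: np.ndarray, model: PropensityModel) -> np.ndarray:
    ids = codes.astype(int)  # N = 4 hits the appended zero row
    return _lookup_with_zero_row(model.psnp, ids)


def _kspsdp_batch(codes: np.ndarray, model: PropensityModel, K: int) -> np.ndarray:
    if K not in model.kspsdp:
        raise ValueError(f"gap K={K} was not fitted (available: {sorted(model.kspsdp)})")
    ids = _gapped_dinuc_ids(codes, K)  # N member = 16 -> zero row
    return _lookup_with_zero_row(model.kspsdp[K], ids)


def _psednc_batch(
    codes: np.ndarray, lambda_pse: int, w: float, table: PhysChemTable
) -> np.ndarray:
    n, L = codes.shape
    if not 0 <= lambda_pse <= L - 2:
        raise ValueError(f"lambda_pse={lambda_pse} out of range 0..{L - 2}")
    if w <= 0:
        raise ValueError("w must be > 0")
    props = table.normalized_array()  # (16, 3)
    ids = _gapped_dinuc_ids(codes, 0)  # adjacent dinucleotides; 16 = invalid
    valid = ids < 16
    out = np.zeros((n, 16 + lambda_pse))
    for r in range(n):
        v = valid[r]
        d = ids[r][v]
        if d.size == 0:
            continue
        freq = np.bincount(d, minlength=16).astype(float) / d.size
        thetas = np.zeros(lambda_pse)
        for j in range(1, lambda_pse + 1):
            left = ids[r, : L - 1 - j]
            right = ids[r, j:]
            ok = (left < 16) & (right < 16)
            if ok.any():
                diff = props[left[ok]] - props[right[ok]]
                thetas[j - 1] = np.mean((diff**2).mean(axis=1))
        denom = freq.sum() + w * thetas.sum()
        out[r, :16] = freq / denom
        out[r, 16:] = w * thetas / denom
    return out


_CHEM_CODE = np.array(
    [
        [1, 1, 1],  # A: purine, amino, weak H-bond
        [1, 0, 0],  # C: pyrimidine, amino, strong H-bond
        [0, 1, 0],  # G: purine, keto, strong H-bond
        [0, 0, 1],  # U: pyrimidine, keto, weak H-bond
        [0, 0, 0],  # N: padding
    ],
    dtype=float,
)


def _cpd_batch(codes: np.ndarray) -> np.ndarray:
    n, L = codes.shape
    chem = _CHEM_CODE[codes]  # (n, L, 3)
    cums = np.stack([np.cumsum(codes == a, axis=1) for a in range(4)])  # (4, n, L)
    rows = np.broadcast_to(np.arange(n)[:, None], codes.shape)
    cols = np.broadcast_to(np.arange(L), codes.shape)
    clipped = np.minimum(codes, 3).astype(int)
    density = cums[clipped, rows, cols] / (np.arange(L) + 1)
    density = np.where(codes == CODE_N, 0.0, density)
    return np.concatenate([chem, density[:, :, None]], axis=2).reshape(n, 4 * L)


# ---------------------------------------------------------------------------
# Per-fragment convenience encoders
# ---------------------------------------------------------------------------


def encode_knf(frag: RNAFragment, K: int) -> np.ndarray:
    """Frequencies of all 4^K k-mers; k-mers touching 'N' are not counted."""
    return _knf_batch(frag.codes()[None, :], K)[0]


def encode_ksnpf(frag: RNAFragment, K: int, denominator: str = "window") -> np.ndarray:
    """Frequencies of the 16 nucleotide pairs with exactly K intervening
    positions.  The default denominator L-K+1 follows the published formula;
    ``denominator='count'`` divides by the actual pair count L-K-1."""
    return _ksnpf_batch(frag.codes()[None, :], K, denominator)[0]


def encode_psnp(frag: RNAFragment, model: PropensityModel) -> np.ndarray:
    """Per-position propensity lookup; length 2*lambda+1, center always 0."""
    if model.lambda_flank != frag.lambda_flank:
        raise ValueError("fragment and propensity model disagree on lambda_flank")
    return _psnp_batch(frag.codes()[None, :], model)[0]


def encode_kspsdp(frag: RNAFragment, model: PropensityModel, K: int) -> np.ndarray:
    """Gapped-dinucleotide propensity lookup; length 2*lambda - K."""
    if model.lambda_flank != frag.lambda_flank:
        raise ValueError("fragment and propensity model disagree on lambda_flank")
    return _kspsdp_batch(frag.codes()[None, :], model, K)[0]


def encode_psednc(
    frag: RNAFragment,
    lambda_pse: int = 2,
    w: float = 0.1,
    table: PhysChemTable | None = None,
) -> np.ndarray:
    """Pseudo dinucleotide composition with lambda_pse correlation tiers."""
    table = table or PhysChemTable.default()
    return _psednc_batch(frag.codes()[None, :], lambda_pse, w, table)[0]


def encode_cpd(frag: RNAFragment) -> np.ndarray:
    """Chemical-property triple + prefix density per position (length 4L)."""
    return _cpd_batch(frag.codes()[None, :])[0]


# ---------------------------------------------------------------------------
# Feature specification and matrix assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilyDescriptor:
    """One feature family plus its parameters."""

    family: FamilyName
    K: int | None = None
    lambda_pse: int = 2
    w: float = 0.1

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in ("KNF", "KSNPF", "KSPSDP") and self.K is None:
            raise ValueError(f"{self.family} requires K")

    @property
    def key(self) -> tuple:
        return (self.family, self.K)

    @property
    def needs_propensity(self) -> bool:
        return self.family in ("PSNP", "KSPSDP")

    @property
    def name(self) -> str:
        """Report-style name: KNF(4)->'4NF', KSNPF(5)->'5SNPF',
        KSPSDP(1)->'1SPSDP'; parameter-free families keep their own name."""
        if self.family == "KNF":
            return f"{self.K}NF"
        if self.family == "KSNPF":
            return f"{self.K}SNPF"
        if self.family == "KSPSDP":
            return f"{self.K}SPSDP"
        return self.family

    def dim(self, lambda_flank: int) -> int:
        width = 2 * lambda_flank + 1
        if self.family == "KNF":
            return 4**self.K
        if self.family == "KSNPF":
            return 16
        if self.family == "PSNP":
            return width
        if self.family == "KSPSDP":
            return 2 * lambda_flank - self.K
        if self.family == "PseDNC":
            return 16 + self.lambda_pse
        return 4 * width  # CPD

    @classmethod
    def parse(cls, name: str, lambda_pse: int = 2, w: float = 0.1) -> "FamilyDescriptor":
        """Parse report-style names: 'PSNP', 'CPD', 'PseDNC', '4NF',
        '5SNPF', '1SPSDP' (case-insensitive)."""
        s = name.strip()
        upper = s.upper()
        if upper == "PSNP":
            return cls("PSNP")
        if upper == "CPD":
            return cls("CPD")
        if upper == "PSEDNC":
            return cls("PseDNC", lambda_pse=lambda_pse, w=w)
        for suffix, family in (("SNPF", "KSNPF"), ("SPSDP", "KSPSDP"), ("NF", "KNF")):
            if upper.endswith(suffix):
                prefix = upper[: -len(suffix)]
                if prefix.isdigit():
                    return cls(family, K=int(prefix))
        raise ValueError(f"cannot parse feature family name {name!r}")


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered list of feature families to concatenate."""

    families: tuple[FamilyDescriptor, ...]

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("feature spec must contain at least one family")
        keys = [d.key for d in self.families]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate (family, K) descriptors in spec: {keys}")

    def __iter__(self):
        return iter(self.families)

    def __len__(self) -> int:
        return len(self.families)

    @property
    def needs_propensity(self) -> bool:
        return any(d.needs_propensity for d in self.families)

    @property
    def propensity_gaps(self) -> tuple[int, ...]:
        return tuple(d.K for d in self.families if d.family == "KSPSDP")

    @property
    def name(self) -> str:
        return " + ".join(d.name for d in self.families)

    def dim(self, lambda_flank: int) -> int:
        return sum(d.dim(lambda_flank) for d in self.families)

    def with_family(self, desc: FamilyDescriptor) -> "FeatureSpec":
        return FeatureSpec(self.families + (desc,))

    @classmethod
    def parse(cls, names: Sequence[str], lambda_pse: int = 2, w: float = 0.1) -> "FeatureSpec":
        return cls(tuple(FamilyDescriptor.parse(n, lambda_pse, w) for n in names))


@dataclass
class FeatureMatrix:
    """Numeric design matrix with per-column provenance
    (family name, parameter, index-within-family)."""

    data: np.ndarray
    column_provenance: list[tuple[str, object, int]]

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != len(self.column_provenance):
            raise ValueError("data shape and provenance length disagree")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{fam}[{param}]:{i}" if param is not None else f"{fam}:{i}"
                for fam, param, i in self.column_provenance]
        return pd.DataFrame(self.data, columns=cols)


def _encode_family_batch(
    codes: np.ndarray,
    desc: FamilyDescriptor,
    model: PropensityModel | None,
    table: PhysChemTable,
    ksnpf_denominator: str,
) -> np.ndarray:
    if desc.family == "KNF":
        return _knf_batch(codes, desc.K)
    if desc.family == "KSNPF":
        return _ksnpf_batch(codes, desc.K, ksnpf_denominator)
    if desc.family == "PSNP":
        return _psnp_batch(codes, model)
    if desc.family == "KSPSDP":
        return _kspsdp_batch(codes, model, desc.K)
    if desc.family == "PseDNC":
        return _psednc_batch(codes, desc.lambda_pse, desc.w, table)
    return _cpd_batch(codes)


def build_feature_matrix(
    data: LabeledDataset,
    spec: FeatureSpec,
    model: PropensityModel | None = None,
    table: PhysChemTable | None = None,
    ksnpf_denominator: str = "window",
) -> FeatureMatrix:
    """Concatenate the encodings of every family in spec order.

    A fitted :class:`PropensityModel` is required iff the spec contains
    PSNP or KSPSDP.
    """
    if spec.needs_propensity and model is None:
        raise ValueError("spec contains PSNP/KSPSDP but no PropensityModel given")
    if model is not None and model.lambda_flank != data.lambda_flank:
        raise ValueError("dataset and propensity model disagree on lambda_flank")
    table = table or PhysChemTable.default()
    codes = data.code_matrix()
    blocks = []
    provenance: list[tuple[str, object, int]] = []
    for desc in spec:
        block = _encode_family_batch(codes, desc, model, table, ksnpf_denominator)
        blocks.append(block)
        param = desc.K if desc.family in ("KNF", "KSNPF", "KSPSDP") else (
            desc.lambda_pse if desc.family == "PseDNC" else None
        )
        provenance.extend((desc.name, param, i) for i in range(block.shape[1]))
    return FeatureMatrix(data=np.hstack(blocks), column_provenance=provenance)
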