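"""Sequence-composition encoders: AAC, DPC and Chou's PseAAC.

Amino-acid composition (AAC) is the 20-vector of per-residue percentage
frequencies.  Di-peptide composition (DPC) counts the 400 ordered residue
pairs over the L-1 overlapping windows.  Pseudo-amino-acid composition
(PseAAC) extends the residue fractions with lambda sequence-order
correlation factors T_k, where T_k averages a physicochemical dissimilarity
Theta over residue pairs k positions apart:

    Theta(r1, r2) = ((H1'(r2)-H1'(r1))^2 + (H2'(r2)-H2'(r1))^2
                     + (M'(r2)-M'(r1))^2) / 3
    T_k = mean_i Theta(R_i, R_{i+k})
    PseAAC_u = f_u / (1 + w * sum_k T_k)          for u = 1..20
    PseAAC_{20+k} = w * T_k / (1 + w * sum_k T_k)  for k = 1..lambda

with H1/H2/M the hydrophobicity, hydrophilicity and side-chain-mass scales
normalized to zero mean and unit population variance over the 20 residues,
and f_u the residue fractions (so the full vector sums to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import ALPHABET, LabeledDataset, ProteinRecord

_RESIDUE_INDEX = {ch: i for i, ch in enumerate(ALPHABET)}
#: 400 ordered dipeptides, row-major: AA, AC, ..., YY.
DIPEPTIDES = [a + b for a in ALPHABET for b in ALPHABET]

DEFAULT_LAMBDA = 5
DEFAULT_WEIGHT = 0.05


# ---------------------------------------------------------------------------
# physicochemical properties


def normalize_property(raw: np.ndarray) -> np.ndarray:
    """Standardize 20 per-residue values to mean 0, population sd 1."""
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (20,):
        raise ValueError("expected exactly 20 per-residue values")
    if not np.isfinite(raw).all():
        raise ValueError("property values must be finite")
    sd = raw.std()  # population sd (ddof=0)
    if sd == 0:
        raise ValueError("property values are all equal (zero variance)")
    return (raw - raw.mean()) / sd


@dataclass(frozen=True)
class PropertyTable:
    """Hydrophobicity, hydrophilicity and side-chain mass per residue.

    Raw values follow :data:`~protclass.sequence_io.ALPHABET` order; the
    normalized variants (mean 0, population sd 1) are derived on
    construction and are what Theta consumes.
    """

    hydrophobicity: np.ndarray
    hydrophilicity: np.ndarray
    side_chain_mass: np.ndarray
    normalized: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        norm = np.vstack(
            [
                normalize_property(self.hydrophobicity),
                normalize_property(self.hydrophilicity),
                normalize_property(self.side_chain_mass),
            ]
        )
        object.__setattr__(self, "normalized", norm)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PropertyTable":
        """Load a 4-column TSV: residue, H1, H2, M (one row per residue)."""
        df = pd.read_csv(
            path, sep="\t", comment="#",
            names=["residue", "h1", "h2", "m"], dtype={"residue": str},
        )
        if sorted(df["residue"]) != sorted(ALPHABET):
            raise ValueError("property table must cover exactly the 20 canonical residues")
        df = df.set_index("residue").loc[list(ALPHABET)]
        return cls(
            df["h1"].to_numpy(float),
            df["h2"].to_numpy(float),
            df["m"].to_numpy(float),
        )

    @classmethod
    def default(cls) -> "PropertyTable":
        """The canonical tables shipped with the package."""
        with resources.as_file(
            resources.files("protclass").joinpath("data/physicochemical.tsv")
        ) as path:
            return cls.from_tsv(path)


def theta(r1: str, r2: str, props: PropertyTable) -> float:
    """Physicochemical dissimilarity between two residues (>= 0, symmetric)."""
    try:
        i, j = _RESIDUE_INDEX[r1], _RESIDUE_INDEX[r2]
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
    diff = props.normalized[:, j] - props.normalized[:, i]
    return float((diff**2).mean())


def correlation_factor(seq: ProteinRecord | str, k: int, props: PropertyTable) -> float:
    """Sequence-order correlation factor T_k (mean Theta at lag k)."""
    sequence = seq.sequence if isinstance(seq, ProteinRecord) else seq
    L = len(sequence)
    if not 1 <= k < L:
        raise ValueError(f"lag k must satisfy 1 <= k < L={L}, got {k}")
    idx = _encode(sequence)
    # Theta expanded: mean over the three normalized properties of the
    # squared difference, vectorized over all L-k pairs.
    diffs = props.normalized[:, idx[k:]] - props.normalized[:, idx[:-k]]
    return float((diffs**2).mean(axis=0).mean())


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_RESIDUE_INDEX[ch] for ch in sequence], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# encoders


def compute_aac(seq: ProteinRecord | str) -> np.ndarray:
    """Amino-acid composition: percentage frequency per residue (sums to 100)."""
    sequence = seq.sequence if isinstance(seq, ProteinRecord) else seq
    if not sequence:
        raise ValueError("empty sequence")
    idx = _encode(sequence)
    counts = np.bincount(idx, minlength=20).astype(float)
    return 100.0 * counts / len(sequence)


def compute_dpc(seq: ProteinRecord | str, mode: str = "fraction") -> np.ndarray:
    """Di-peptide composition over the L-1 overlapping windows.

    ``mode="fraction"`` divides counts by L-1 (vector sums to 1, the
    community definition); ``mode="per400"`` divides by the number of
    dipeptide types, 400, so the vector sums to (L-1)/400.
    """
    if mode not in ("fraction", "per400"):
        raise ValueError(f"dpc mode must be 'fraction' or 'per400', got {mode!r}")
    sequence = seq.sequence if isinstance(seq, ProteinRecord) else seq
    L = len(sequence)
    if L < 2:
        raise ValueError("DPC needs at least 2 residues")
    idx = _encode(sequence)
    pair_codes = idx[:-1] * 20 + idx[1:]
    counts = np.bincount(pair_codes, minlength=400).astype(float)
    return counts / (L - 1 if mode == "fraction" else 400)


def compute_pseaac(
    seq: ProteinRecord | str,
    lam: int = DEFAULT_LAMBDA,
    w: float = DEFAULT_WEIGHT,
    props: PropertyTable | None = None,
) -> np.ndarray:
    """Pseudo-amino-acid composition: (20 + lambda)-vector summing to 1.

    With lambda = 0 this reduces exactly to the AAC fractions.
    """
    sequence = seq.sequence if isinstance(seq, ProteinRecord) else seq
    L = len(sequence)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if L <= lam:
        raise ValueError(
            f"sequence length {L} must exceed lambda={lam}; "
            "use a smaller lambda or a longer sequence"
        )
    if lam > 0 and w <= 0:
        raise ValueError("weight w must be positive when lambda > 0")
    if props is None:
        props = PropertyTable.default()
    fractions = compute_aac(sequence) / 100.0
    t = np.array([correlation_factor(sequence, k, props) for k in range(1, lam + 1)])
    denom = 1.0 + w * t.sum()  # sum of fractions is 1 by construction
    return np.concatenate([fractions, w * t]) / denom


# ---------------------------------------------------------------------------
# schemes and matrices

SCHEME_NAMES = ("AAC", "DPC", "PseAAC")


@dataclass(frozen=True)
class FeatureScheme:
    """Which encoder produced a feature matrix, with its parameters."""

    name: str
    lam: int | None = None
    w: float | None = None
    dpc_mode: str | None = None

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise ValueError(f"unknown scheme {self.name!r}; choose from {SCHEME_NAMES}")
        if self.name == "PseAAC":
            if self.lam is None or self.lam < 0:
                raise ValueError("PseAAC requires a non-negative lambda")
            if self.lam > 0 and (self.w is None or self.w <= 0):
                raise ValueError("PseAAC requires a positive weight w")
        if self.name == "DPC" and self.dpc_mode not in ("fraction", "per400"):
            raise ValueError("DPC requires dpc_mode 'fraction' or 'per400'")

    @property
    def dimension(self) -> int:
        return {"AAC": 20, "DPC": 400}.get(self.name, 20 + (self.lam or 0))

    @property
    def feature_names(self) -> list[str]:
        if self.name == "AAC":
            return [f"AAC_{ch}" for ch in ALPHABET]
        if self.name == "DPC":
            return [f"DPC_{dp}" for dp in DIPEPTIDES]
        return [f"PAAC_{i}" for i in range(1, self.dimension + 1)]

    def encode(self, seq: ProteinRecord | str, props: PropertyTable | None = None) -> np.ndarray:
        if self.name == "AAC":
            return compute_aac(seq)
        if self.name == "DPC":
            return compute_dpc(seq, self.dpc_mode)
        return compute_pseaac(seq, self.lam, self.w, props)

    def to_dict(self) -> dict:
        return {"name": self.name, "lam": self.lam, "w": self.w, "dpc_mode": self.dpc_mode}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScheme":
        return cls(d["name"], d.get("lam"), d.get("w"), d.get("dpc_mode"))


def aac_scheme() -> FeatureScheme:
    return FeatureScheme("AAC")


def dpc_scheme(mode: str = "fraction") -> FeatureScheme:
    return FeatureScheme("DPC", dpc_mode=mode)


def pseaac_scheme(lam: int = DEFAULT_LAMBDA, w: float = DEFAULT_WEIGHT) -> FeatureScheme:
    return FeatureScheme("PseAAC", lam=lam, w=w)


@dataclass
class FeatureMatrix:
    """n x d feature matrix with row ids, optional labels and its scheme."""

    ids: list[str]
    values: np.ndarray
    scheme: FeatureScheme
    labels: np.ndarray | None = None
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("one id per row required")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("row ids must be unique")
        if self.feature_names is None:
            self.feature_names = self.scheme.feature_names
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature-name count must equal column count")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.values.shape[0],):
                raise ValueError("one label per row required")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, indices) -> "FeatureMatrix":
        idx = np.asarray(indices)
        return FeatureMatrix(
            [self.ids[i] for i in idx],
            self.values[idx],
            self.scheme,
            None if self.labels is None else self.labels[idx],
            list(self.feature_names),
        )

    def subset_columns(self, names: list[str]) -> "FeatureMatrix":
        pos = {name: i for i, name in enumerate(self.feature_names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise ValueError(f"unknown feature names: {missing[:5]}")
        cols = [pos[n] for n in names]
        return FeatureMatrix(
            list(self.ids), self.values[:, cols], self.scheme, self.labels, list(names)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "id", self.ids)
        if self.labels is not None:
            df.insert(1, "label", self.labels)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, scheme: FeatureScheme | None = None) -> "FeatureMatrix":
        """Read a matrix written by :meth:`to_csv`; the scheme is recovered
        from the feature-column names when not given explicitly."""
        df = pd.read_csv(path)
        if "id" not in df.columns:
            raise ValueError(f"{path}: missing 'id' column")
        labels = df["label"].to_numpy(int) if "label" in df.columns else None
        feature_cols = [c for c in df.columns if c not in ("id", "label")]
        if scheme is None:
            scheme = _infer_scheme(feature_cols)
        return cls(
            df["id"].astype(str).tolist(),
            df[feature_cols].to_numpy(float),
            scheme,
            labels,
            feature_cols,
        )


def _infer_scheme(feature_cols: list[str]) -> FeatureScheme:
    prefixes = {c.split("_")[0] for c in feature_cols}
    if prefixes == {"AAC"}:
        return aac_scheme()
    if prefixes == {"DPC"}:
        return dpc_scheme()
    if prefixes == {"PAAC"}:
        lam = max(0, len(feature_cols) - 20)
        return pseaac_scheme(lam=lam)
    raise ValueError(f"cannot infer encoding scheme from columns {sorted(prefixes)}")


def featurize_dataset(
    ds: LabeledDataset,
    scheme: FeatureScheme,
    props: PropertyTable | None = None,
) -> FeatureMatrix:
    """Encode every record of a dataset; one row per record, dataset order.

    A sequence failing the scheme's length precondition aborts the whole
    featurization with an error naming the record — rows are never silently
    dropped.
    """
    if scheme.name == "PseAAC" and props is None:
        props = PropertyTable.default()
    rows = []
    for rec in ds.records:
        try:
            rows.append(scheme.encode(rec, props) if scheme.name == "PseAAC" else scheme.encode(rec))
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
    return FeatureMatrix(
        [r.id for r in ds.records], np.vstack(rows), scheme, ds.labels.copy()
    )
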