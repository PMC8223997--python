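"""Conjoint Triad (CT) and Autocovariance (AC) sequence descriptors.

A protein of any length is mapped to a fixed vector of length
``k = 343 + m*lag``:

* **CT** — residues are grouped into 7 physicochemical classes (Shen grouping
  by default); a window of size 3 slides over the sequence and the counts of
  the 7^3 = 343 ordered class triples are normalized per protein.
* **AC** — for each of the ``m`` property scales (standardized to zero mean /
  unit variance over the 20 residues) and each offset ``d = 1..lag``, the
  autocovariance of the property along the sequence:

      AC(j, d) = (1/(L-d)) * sum_{i=1..L-d} (P_j(a_i) - mean_j)(P_j(a_{i+d}) - mean_j)

  where ``mean_j`` is the property mean over *this* sequence.  ``lag`` must be
  smaller than the sequence length.

The per-protein feature vector is the concatenation [AC | CT], and a pair is
represented by concatenating the two protein vectors (2k values).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import STANDARD_AMINO_ACIDS, ProteinRecord, clean_sequence

#: Shen's canonical grouping of the 20 amino acids into 7 classes by dipole
#: and side-chain volume: {A,G,V} {I,L,F,P} {Y,M,T,S} {H,N,Q,W} {R,K} {D,E} {C}.
SHEN_CLASS_MAP: dict[str, int] = {
    **dict.fromkeys("AGV", 1),
    **dict.fromkeys("ILFP", 2),
    **dict.fromkeys("YMTS", 3),
    **dict.fromkeys("HNQW", 4),
    **dict.fromkeys("RK", 5),
    **dict.fromkeys("DE", 6),
    "C": 7,
}

CT_DIM = 343  # 7**3 ordered class triples


class DescriptorError(ValueError):
    """Raised when a sequence violates a descriptor precondition."""


def load_property_table(path: str | Path) -> pd.DataFrame:
    """Load an m x 20 amino-acid property table.

    Tab-separated, first column the scale name, header row the 20 residue
    letters (any order).  Returns a DataFrame indexed by scale name with
    columns reordered to the alphabetical residue order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = set(df.columns)
    expected = set(STANDARD_AMINO_ACIDS)
    if cols != expected:
        raise DescriptorError(
            f"property table must have exactly the 20 standard residue columns; "
            f"missing={sorted(expected - cols)} extra={sorted(cols - expected)}"
        )
    df = df[list(STANDARD_AMINO_ACIDS)].astype(float)
    if not np.isfinite(df.to_numpy()).all():
        raise DescriptorError("property table contains non-finite values")
    return df


def default_property_table() -> pd.DataFrame:
    """The bundled 14-scale table (hydrophobicity x2, hydrophilicity, net
    charge index, polarity x2, polarizability, SASA, side-chain volume,
    flexibility, accessibility, exposed surface, turn propensity, antigenic
    propensity)."""
    with resources.as_file(
        resources.files("autoppi").joinpath("data/aa_properties.tsv")
    ) as p:
        return load_property_table(p)


@dataclass
class DescriptorConfig:
    """Featurization settings.

    Parameters
    ----------
    lag:
        Maximum position offset for AC; every featurized sequence must be
        longer than ``lag``.
    property_table:
        m x 20 DataFrame of property scales (defaults to the bundled 14).
    ct_normalization:
        ``"minmax"`` (iFeature-style, (f - min)/max) or
        ``"relative_frequency"`` (f / (L-2)).
    class_map:
        residue -> class index in 1..7; defaults to the Shen grouping.
    """

    lag: int = 30
    property_table: pd.DataFrame = field(default_factory=default_property_table)
    ct_normalization: str = "minmax"
    class_map: dict[str, int] = field(default_factory=lambda: dict(SHEN_CLASS_MAP))

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise DescriptorError("lag must be >= 1")
        if self.ct_normalization not in ("minmax", "relative_frequency"):
            raise DescriptorError(
                f"unknown ct_normalization {self.ct_normalization!r}"
            )
        if set(self.class_map) != set(STANDARD_AMINO_ACIDS):
            raise DescriptorError("class_map must cover exactly the 20 standard residues")
        if set(self.class_map.values()) != set(range(1, 8)):
            raise DescriptorError("class_map must use exactly the 7 classes 1..7")
        if self.property_table.shape[0] < 1:
            raise DescriptorError("property table needs at least one scale")
        if set(self.property_table.columns) != set(STANDARD_AMINO_ACIDS):
            raise DescriptorError(
                "property table must have exactly the 20 standard residue columns"
            )
        self.property_table = self.property_table[list(STANDARD_AMINO_ACIDS)]

    @property
    def n_properties(self) -> int:
        return int(self.property_table.shape[0])

    @property
    def k(self) -> int:
        """Per-protein feature length, 343 + m*lag."""
        return CT_DIM + self.n_properties * self.lag

    def fingerprint(self) -> str:
        """Stable hash of everything that affects feature values."""
        payload = json.dumps(
            {
                "lag": self.lag,
                "ct_normalization": self.ct_normalization,
                "class_map": {a: self.class_map[a] for a in STANDARD_AMINO_ACIDS},
                "scales": list(map(str, self.property_table.index)),
                "values": np.round(self.property_table.to_numpy(), 12).tolist(),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def standardized_table(self) -> np.ndarray:
        """Property matrix z-scored per scale over the 20 residues (ddof=0)."""
        mat = self.property_table.to_numpy(dtype=float)
        mean = mat.mean(axis=1, keepdims=True)
        std = mat.std(axis=1, keepdims=True)
        if np.any(std == 0):
            raise DescriptorError("a property scale is constant over the 20 residues")
        return (mat - mean) / std


@dataclass(frozen=True)
class FeatureVector:
    """A protein's fixed-length representation plus its config fingerprint."""

    protein_id: str
    values: np.ndarray
    config_fingerprint: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise DescriptorError(f"non-finite feature values for {self.protein_id!r}")


def _class_indices(seq: str, class_map: dict[str, int]) -> np.ndarray:
    return np.fromiter((class_map[c] - 1 for c in seq), dtype=np.int64, count=len(seq))


def ct_features(seq: str, config: DescriptorConfig) -> np.ndarray:
    """Normalized conjoint-triad frequencies (length 343).

    The triple (c1, c2, c3) maps to index (c1-1)*49 + (c2-1)*7 + (c3-1).
    """
    if len(seq) < 3:
        raise DescriptorError(
            f"sequence of length {len(seq)} has no window of size 3"
        )
    cls = _class_indices(seq, config.class_map)
    idx = cls[:-2] * 49 + cls[1:-1] * 7 + cls[2:]
    counts = np.bincount(idx, minlength=CT_DIM).astype(float)
    if config.ct_normalization == "minmax":
        return (counts - counts.min()) / counts.max()
    return counts / (len(seq) - 2)


def ac_features(seq: str, config: DescriptorConfig) -> np.ndarray:
    """Autocovariance descriptor (length m*lag, property-major then lag)."""
    L = len(seq)
    if L <= config.lag:
        raise DescriptorError(
            f"lag ({config.lag}) must be smaller than the sequence length ({L})"
        )
    table = config.standardized_table()  # (m, 20)
    res_idx = np.fromiter(
        (STANDARD_AMINO_ACIDS.index(c) for c in seq), dtype=np.int64, count=L
    )
    prof = table[:, res_idx]  # (m, L) property profile along the sequence
    centered = prof - prof.mean(axis=1, keepdims=True)
    out = np.empty((config.n_properties, config.lag), dtype=float)
    for d in range(1, config.lag + 1):
        out[:, d - 1] = (centered[:, :-d] * centered[:, d:]).sum(axis=1) / (L - d)
    return out.ravel()


def protein_features(record: ProteinRecord, config: DescriptorConfig) -> FeatureVector:
    """Featurize one protein: clean, then concatenate [AC | CT]."""
    seq = clean_sequence(record.sequence)
    try:
        ac = ac_features(seq, config)
        ct = ct_features(seq, config)
    except DescriptorError as e:
        raise DescriptorError(f"protein {record.id!r}: {e}") from e
    return FeatureVector(
        protein_id=record.id,
        values=np.concatenate([ac, ct]),
        config_fingerprint=config.fingerprint(),
    )


def pair_vector(fa: FeatureVector, fb: FeatureVector) -> np.ndarray:
    """Concatenate two protein feature vectors into the 2k pair representation."""
    if fa.config_fingerprint != fb.config_fingerprint:
        raise DescriptorError(
            f"feature vectors of {fa.protein_id!r} and {fb.protein_id!r} "
            "were computed under different descriptor configs"
        )
    return np.concatenate([fa.values, fb.values])


def featurize_proteins(
    records: list[ProteinRecord], config: DescriptorConfig
) -> dict[str, FeatureVector]:
    """Featurize a protein set, keyed by id."""
    return {r.id: protein_features(r, config) for r in records}


def feature_matrix(features: dict[str, FeatureVector]) -> pd.DataFrame:
    """Stack features into a DataFrame (rows = proteins) for export/inspection."""
    ids = list(features)
    mat = np.vstack([features[i].values for i in ids])
    return pd.DataFrame(mat, index=pd.Index(ids, name="protein_id"))


def write_feature_matrix(features: dict[str, FeatureVector], path: str | Path) -> None:
    feature_matrix(features).to_csv(path, sep="\t", float_format="%.10g")
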