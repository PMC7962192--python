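"""Window feature encoders: binary one-hot, AAindex, CKSAAP, and K-mer.

Every encoder maps a window of length 2*w+1 over {20 amino acids, '-', 'X'}
to a fixed-dimension named feature vector:

* binary  — 21-letter one-hot per position (20 amino acids + the gap),
  (2w+1) x 21 features; an unknown residue ('X') yields an all-zero block.
* aaindex — one physicochemical value per position per property table,
  (2w+1) x n_properties features; '-' and 'X' contribute 0 (tables are
  z-scored over the 20 letters, so 0 is the standardized mean).
* cksaap  — composition of k-spaced amino-acid pairs: frequencies of ordered
  standard-letter pairs (a, b) at distance k+1, 400 pairs per k; pairs
  touching '-' or 'X' are skipped while the denominator stays the number of
  pair slots, 2w+1-k-1, so heavily padded windows have smaller block sums.
* kmer    — frequencies of contiguous K-letter words over the 20-letter
  alphabet, 20**K features per K, denominator 2w+1-K+1.

Feature names and column order are canonical (positions ascending, letters
alphabetical with '-' last, k/K ascending) so selected-subset files are
portable across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .sequence_io import AA20, GAP, UNKNOWN, SiteWindow

ALPHABET21 = AA20 + GAP  # binary-encoder alphabet; gap is the 21st letter

#: identifiers of the bundled default 15-property set
DEFAULT_PROPERTY_SET = (
    "HYDROPATHY_KD",
    "RESIDUE_MASS",
    "RESIDUE_VOLUME",
    "POLARITY_GRANTHAM",
    "ISOELECTRIC_POINT",
    "NET_CHARGE_PH7",
    "AROMATICITY",
    "ALIPHATICITY",
    "HBOND_DONORS",
    "HBOND_ACCEPTORS",
    "HELIX_CHOUFASMAN",
    "SHEET_CHOUFASMAN",
    "TURN_CHOUFASMAN",
    "HYDROPHILICITY_HW",
    "SURFACE_AREA",
)

SCHEMES = ("binary", "aaindex", "cksaap", "kmer")


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class EncodingSpec:
    """Parameters of one encoding scheme.

    w is the half-window (window length 2*w+1); k_values are CKSAAP gap
    lengths; K_values are k-mer word lengths; property_set names the AAindex
    properties used by the aaindex scheme.
    """

    scheme: str
    w: int = 20
    k_values: tuple[int, ...] = (0, 1, 2, 3, 4)
    K_values: tuple[int, ...] = (1, 2, 3)
    property_set: tuple[str, ...] = DEFAULT_PROPERTY_SET
    raw_counts: bool = False

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise EncodingError(f"unknown scheme {self.scheme!r}")
        if any(k < 0 for k in self.k_values):
            raise EncodingError("k_values must be non-negative")
        if any(K < 1 for K in self.K_values):
            raise EncodingError("K_values must be >= 1")

    @property
    def window_length(self) -> int:
        return 2 * self.w + 1

    def n_features(self) -> int:
        if self.scheme == "binary":
            return self.window_length * 21
        if self.scheme == "aaindex":
            return self.window_length * len(self.property_set)
        if self.scheme == "cksaap":
            return len(self.k_values) * 400
        return sum(20**K for K in self.K_values)

    def feature_names(self) -> list[str]:
        """Canonical column order for this scheme."""
        if self.scheme == "binary":
            return [
                f"bin_p{p}_{a}"
                for p in range(1, self.window_length + 1)
                for a in ALPHABET21
            ]
        if self.scheme == "aaindex":
            return [
                f"aai_p{p}_{prop}"
                for p in range(1, self.window_length + 1)
                for prop in self.property_set
            ]
        if self.scheme == "cksaap":
            return [
                f"cks_k{k}_{a}{b}"
                for k in self.k_values
                for a in AA20
                for b in AA20
            ]
        return [
            f"kmer_K{K}_{''.join(word)}"
            for K in self.K_values
            for word in product(AA20, repeat=K)
        ]


@dataclass(frozen=True)
class PropertyTable:
    """One amino-acid property: a value per standard letter, 0 for '-'/'X'."""

    property_id: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [a for a in AA20 if a not in self.values]
        if missing:
            raise EncodingError(
                f"property {self.property_id!r} missing letters {missing}"
            )

    def standardized(self) -> "PropertyTable":
        """Z-score the 20 letter values (population sd)."""
        vals = np.array([self.values[a] for a in AA20], dtype=float)
        sd = vals.std()
        if sd == 0:
            raise EncodingError(f"property {self.property_id!r} is constant")
        z = (vals - vals.mean()) / sd
        return PropertyTable(self.property_id, dict(zip(AA20, z.tolist())))

    def value(self, letter: str) -> float:
        if letter in (GAP, UNKNOWN):
            return 0.0
        return self.values[letter]


# AAindex1 I-line column order: two rows of ten letters each.
_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTWYV"


def parse_aaindex(path: str | Path) -> list[PropertyTable]:
    """Parse an AAindex1 flat file (H accession lines, I value matrices)."""
    tables: list[PropertyTable] = []
    accession = None
    collecting = False
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("H "):
                accession = line[2:].strip()
            elif line.startswith("I "):
                collecting = True
                rows = []
            elif collecting and line.startswith((" ", "\t")):
                rows.append([float(tok) for tok in line.split()])
            elif line.startswith("//"):
                if accession is None or len(rows) != 2:
                    raise EncodingError("malformed AAindex record")
                values = dict(zip(_AAINDEX_ROW1, rows[0]))
                values.update(zip(_AAINDEX_ROW2, rows[1]))
                tables.append(PropertyTable(accession, values))
                accession, collecting, rows = None, False, []
    return tables


def load_default_properties() -> list[PropertyTable]:
    """The bundled 15-property set (z-scored)."""
    ref = resources.files("prednts.data") / "default_properties.txt"
    with resources.as_file(ref) as path:
        tables = parse_aaindex(path)
    return [t.standardized() for t in tables]


def _window_string(window: SiteWindow | str) -> str:
    return window.residues if isinstance(window, SiteWindow) else window


def encode_binary(window: SiteWindow | str, spec: EncodingSpec) -> np.ndarray:
    s = _window_string(window)
    if len(s) != spec.window_length:
        raise EncodingError(
            f"window length {len(s)} != 2w+1 = {spec.window_length}"
        )
    vec = np.zeros(len(s) * 21)
    warned = False
    for i, aa in enumerate(s):
        j = ALPHABET21.find(aa)
        if j >= 0:
            vec[i * 21 + j] = 1.0
        elif not warned:
            warnings.warn(f"unencodable residue {aa!r}: zero block", stacklevel=2)
            warned = True
    return vec


def encode_aaindex(
    window: SiteWindow | str,
    spec: EncodingSpec,
    tables: Sequence[PropertyTable],
) -> np.ndarray:
    s = _window_string(window)
    if len(s) != spec.window_length:
        raise EncodingError(
            f"window length {len(s)} != 2w+1 = {spec.window_length}"
        )
    if len(tables) != len(spec.property_set):
        raise EncodingError(
            f"{len(tables)} tables for {len(spec.property_set)} properties"
        )
    return np.array([t.value(aa) for aa in s for t in tables])


def encode_cksaap(window: SiteWindow | str, spec: EncodingSpec) -> np.ndarray:
    s = _window_string(window)
    L = len(s)
    if L <= max(spec.k_values) + 1:
        raise EncodingError("window too short for requested k values")
    idx = {a: i for i, a in enumerate(AA20)}
    blocks = []
    for k in spec.k_values:
        counts = np.zeros(400)
        n_slots = L - k - 1
        for i in range(n_slots):
            a, b = s[i], s[i + k + 1]
            if a in idx and b in idx:
                counts[idx[a] * 20 + idx[b]] += 1.0
        blocks.append(counts if spec.raw_counts else counts / n_slots)
    return np.concatenate(blocks)


def encode_kmer(window: SiteWindow | str, spec: EncodingSpec) -> np.ndarray:
    s = _window_string(window)
    L = len(s)
    if L < max(spec.K_values):
        raise EncodingError("window too short for requested K values")
    idx = {a: i for i, a in enumerate(AA20)}
    blocks = []
    for K in spec.K_values:
        counts = np.zeros(20**K)
        n_slots = L - K + 1
        for i in range(n_slots):
            word = s[i : i + K]
            code = 0
            ok = True
            for c in word:
                if c not in idx:
                    ok = False
                    break
                code = code * 20 + idx[c]
            if ok:
                counts[code] += 1.0
        blocks.append(counts if spec.raw_counts else counts / n_slots)
    return np.concatenate(blocks)


def encode_window(
    window: SiteWindow | str,
    spec: EncodingSpec,
    tables: Sequence[PropertyTable] | None = None,
) -> np.ndarray:
    if spec.scheme == "binary":
        return encode_binary(window, spec)
    if spec.scheme == "aaindex":
        if tables is None:
            tables = load_default_properties()
        return encode_aaindex(window, spec, tables)
    if spec.scheme == "cksaap":
        return encode_cksaap(window, spec)
    return encode_kmer(window, spec)


def encode_dataset(
    windows: Sequence[SiteWindow],
    spec: EncodingSpec,
    tables: Sequence[PropertyTable] | None = None,
) -> pd.DataFrame:
    """Encode windows into a named feature matrix (rows in input order).

    The index carries (protein_id, position) row identifiers.
    """
    lengths = {len(_window_string(sw)) for sw in windows}
    if len(lengths) > 1:
        raise EncodingError(f"mixed window lengths {sorted(lengths)}")
    if spec.scheme == "aaindex" and tables is None:
        tables = load_default_properties()
    names = spec.feature_names()
    if not windows:
        return pd.DataFrame(np.empty((0, len(names))), columns=names)
    rows = np.stack([encode_window(sw, spec, tables) for sw in windows])
    index = pd.MultiIndex.from_tuples(
        [
            (sw.protein_id, sw.center_position)
            if isinstance(sw, SiteWindow)
            else (f"w{i}", 0)
            for i, sw in enumerate(windows)
        ],
        names=["protein_id", "position"],
    )
    return pd.DataFrame(rows, columns=names, index=index)


class WindowEncoder(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer: windows -> named feature matrix.

    Parameters mirror EncodingSpec; ``transform`` accepts a sequence of
    SiteWindow (or bare window strings) and returns a DataFrame.
    """

    def __init__(
        self,
        scheme: str = "binary",
        w: int = 20,
        k_values: tuple[int, ...] = (0, 1, 2, 3, 4),
        K_values: tuple[int, ...] = (1, 2, 3),
        property_set: tuple[str, ...] = DEFAULT_PROPERTY_SET,
        raw_counts: bool = False,
    ):
        self.scheme = scheme
        self.w = w
        self.k_values = k_values
        self.K_values = K_values
        self.property_set = property_set
        self.raw_counts = raw_counts

    def _spec(self) -> EncodingSpec:
        return EncodingSpec(
            scheme=self.scheme,
            w=self.w,
            k_values=tuple(self.k_values),
            K_values=tuple(self.K_values),
            property_set=tuple(self.property_set),
            raw_counts=self.raw_counts,
        )

    def fit(self, X: Sequence[SiteWindow], y=None) -> "WindowEncoder":
        spec = self._spec()
        if self.scheme == "aaindex":
            tables = {t.property_id: t for t in load_default_properties()}
            missing = [p for p in spec.property_set if p not in tables]
            if missing:
                raise EncodingError(f"unknown properties {missing}")
            self.tables_ = [tables[p] for p in spec.property_set]
        else:
            self.tables_ = None
        self.feature_names_out_ = spec.feature_names()
        return self

    def transform(self, X: Sequence[SiteWindow]) -> pd.DataFrame:
        if not hasattr(self, "feature_names_out_"):
            self.fit(X)
        return encode_dataset(X, self._spec(), self.tables_)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.feature_names_out_, dtype=object)
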