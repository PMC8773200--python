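"""The six amino-acid descriptor families.

Given a peptide of length :math:`N` over the 20-letter alphabet the families
are:

``AAC``
    amino-acid composition, :math:`f(i) = N(i)/N` — 20 values.
``DPC``
    dipeptide composition, :math:`D(rs) = N_{rs}/(N-1)` over the 400 ordered
    pairs.
``CTD``
    composition / transition / distribution over 3-group physicochemical
    partitions of the alphabet (7 attributes x 21 values = 147).
``SOC``
    sequence-order-coupling numbers
    :math:`\\tau_d = \\sum_{i=1}^{N-d} d_{i,i+d}^2` for lags
    :math:`d = 1..n_{lag}`, per 20x20 residue distance matrix.
``QSO``
    quasi-sequence-order: the 20 type-1 components :math:`X_r = f_r / S` and
    the lag components :math:`X_d = w\\,\\tau_{d-20}/S`, sharing the
    denominator :math:`S = \\sum_r f_r + w \\sum_d \\tau_d` (so the full
    vector sums to 1).
``AutoC``
    Moreau-Broto, Moran and Geary autocorrelation of per-residue property
    scales, lags :math:`l = 1..maxlag`. Property values are z-scored over
    the alphabet before use; zero-variance sequences return 0 for Moran and
    Geary by convention.

:func:`encode` concatenates the enabled families in the fixed order
AAC, DPC, CTD, QSO, SOC, AutoC with deterministic, family-prefixed column
names, returning a :class:`pandas.DataFrame` (the package's FeatureMatrix)
indexed by peptide id.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DescriptorError
from .io import ALPHABET, AA_INDEX, LabeledDataset, encode_indices

FAMILIES = ("AAC", "DPC", "CTD", "QSO", "SOC", "AutoC")
AUTOC_KINDS = ("moreau_broto", "moran", "geary")
_AUTOC_PREFIX = {"moreau_broto": "MoreauBrotoAutoC", "moran": "MoranAutoC",
                 "geary": "GearyAutoC"}

#: The eight property scales used by the autocorrelation family.
DEFAULT_AUTOC_PROPERTIES = (
    "hydrophobicity", "flexibility", "polarizability", "free_energy",
    "asa", "volume", "steric", "mutability",
)
DEFAULT_DISTANCE_MATRICES = ("grantham", "pseaac3")


# ---------------------------------------------------------------------------
# vendored constants

@dataclass(frozen=True)
class PropertyTable:
    """A named per-residue numeric scale (one value per alphabet letter)."""

    name: str
    values: Mapping[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        if set(self.values) != set(ALPHABET):
            raise ConfigError(
                f"property table {self.name!r} must cover exactly the 20 "
                "standard residues"
            )

    def as_array(self) -> np.ndarray:
        return np.array([float(self.values[a]) for a in ALPHABET])

    def standardized(self) -> np.ndarray:
        """Z-score over the 20 alphabet values (population SD)."""
        v = self.as_array()
        sd = v.std()
        if sd == 0:
            raise ConfigError(f"property table {self.name!r} is constant")
        return (v - v.mean()) / sd


@dataclass(frozen=True)
class DistanceMatrix:
    """A named 20x20 amino-acid distance matrix, indexed in alphabet order."""

    name: str
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (20, 20) or not np.isfinite(d).all() or (d < 0).any():
            raise ConfigError(
                f"distance matrix {self.name!r} must be 20x20, finite, >= 0"
            )
        object.__setattr__(self, "d", d)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.d[AA_INDEX[a], AA_INDEX[b]])


@dataclass(frozen=True)
class GroupScheme:
    """A partition of the alphabet into exactly 3 disjoint residue classes."""

    property_name: str
    groups: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(self.groups) != 3:
            raise ConfigError(
                f"scheme {self.property_name!r}: need exactly 3 groups"
            )
        joined = "".join(self.groups)
        if sorted(joined) != sorted(ALPHABET):
            raise ConfigError(
                f"scheme {self.property_name!r}: groups must partition the "
                "20-letter alphabet"
            )

    def labels(self, indices: np.ndarray) -> np.ndarray:
        """Map residue indices to group labels 0/1/2."""
        lut = np.empty(20, dtype=np.int64)
        for g, members in enumerate(self.groups):
            for aa in members:
                lut[AA_INDEX[aa]] = g
        return lut[indices]


def _data_text(filename: str) -> str:
    return resources.files("il10pep.data").joinpath(filename).read_text()


def _load_property_tables() -> dict[str, PropertyTable]:
    lines = [ln for ln in _data_text("autoc_properties.tsv").splitlines()
             if ln and not ln.startswith("#")]
    header = lines[0].split("\t")
    names = header[1:]
    columns: dict[str, dict[str, float]] = {n: {} for n in names}
    for ln in lines[1:]:
        parts = ln.split("\t")
        aa = parts[0]
        for name, raw in zip(names, parts[1:]):
            columns[name][aa] = float(raw)
    return {n: PropertyTable(n, vals, source="see data file header")
            for n, vals in columns.items()}


def _load_distance_matrix(name: str) -> DistanceMatrix:
    lines = [ln for ln in _data_text(f"{name}.txt").splitlines()
             if ln and not ln.startswith("#")]
    order = lines[0].split()
    if order != list(ALPHABET):
        raise ConfigError(f"matrix file {name}: unexpected residue order")
    d = np.zeros((20, 20))
    for ln in lines[1:]:
        parts = ln.split()
        i = AA_INDEX[parts[0]]
        d[i] = [float(x) for x in parts[1:]]
    return DistanceMatrix(name, d)


def _load_group_schemes() -> tuple[GroupScheme, ...]:
    lines = [ln for ln in _data_text("ctd_groups.tsv").splitlines()
             if ln and not ln.startswith("#")]
    schemes = []
    for ln in lines[1:]:
        attr, g1, g2, g3 = ln.split("\t")
        schemes.append(GroupScheme(attr, (g1, g2, g3)))
    return tuple(schemes)


_PROPERTY_TABLES = _load_property_tables()
_DISTANCE_CACHE: dict[str, DistanceMatrix] = {}
_GROUP_SCHEMES = _load_group_schemes()


def load_property_table(name: str) -> PropertyTable:
    try:
        return _PROPERTY_TABLES[name]
    except KeyError:
        raise ConfigError(
            f"unknown property table {name!r}; available: "
            f"{sorted(_PROPERTY_TABLES)}"
        ) from None


def load_distance_matrix(name: str) -> DistanceMatrix:
    if name not in _DISTANCE_CACHE:
        if name not in DEFAULT_DISTANCE_MATRICES:
            raise ConfigError(
                f"unknown distance matrix {name!r}; available: "
                f"{list(DEFAULT_DISTANCE_MATRICES)}"
            )
        _DISTANCE_CACHE[name] = _load_distance_matrix(name)
    return _DISTANCE_CACHE[name]


def default_group_schemes() -> tuple[GroupScheme, ...]:
    return _GROUP_SCHEMES


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class DescriptorConfig:
    """Every tunable of the descriptor stage.

    Default lags: ``autoc_maxlag=4`` (the printed autocorrelation lag
    range), ``qso_maxlag=soc_nlag=8`` so the defaults work at the
    benchmark's mean length of 16. ``wide()`` raises all lags to 30 (the
    common descriptor-platform default) for long peptides; :func:`encode`
    fails loudly whenever a lag reaches any sequence's length.
    """

    families: tuple[str, ...] = FAMILIES
    qso_weight: float = 0.1
    qso_maxlag: int = 8
    soc_nlag: int = 8
    autoc_maxlag: int = 4
    autoc_properties: tuple[str, ...] = DEFAULT_AUTOC_PROPERTIES
    autoc_kinds: tuple[str, ...] = AUTOC_KINDS
    distance_matrices: tuple[str, ...] = DEFAULT_DISTANCE_MATRICES

    def __post_init__(self) -> None:
        bad = [f for f in self.families if f not in FAMILIES]
        if bad:
            raise ConfigError(f"unknown families {bad}; choose from {FAMILIES}")
        if self.qso_weight <= 0:
            raise ConfigError("qso_weight must be > 0")
        for attr in ("qso_maxlag", "soc_nlag", "autoc_maxlag"):
            if getattr(self, attr) < 1:
                raise ConfigError(f"{attr} must be >= 1")
        bad = [k for k in self.autoc_kinds if k not in AUTOC_KINDS]
        if bad:
            raise ConfigError(f"unknown autocorrelation kinds {bad}")
        for name in self.autoc_properties:
            load_property_table(name)
        for name in self.distance_matrices:
            load_distance_matrix(name)
        # canonicalise family order
        object.__setattr__(
            self, "families",
            tuple(f for f in FAMILIES if f in set(self.families)),
        )

    @classmethod
    def wide(cls, lag: int = 30, **kw) -> "DescriptorConfig":
        """Long-peptide preset: raise every lag to *lag* (default 30)."""
        return cls(qso_maxlag=lag, soc_nlag=lag, autoc_maxlag=lag, **kw)

    def replace(self, **kw) -> "DescriptorConfig":
        return replace(self, **kw)

    @property
    def min_length(self) -> int:
        """Smallest peptide length the configured lags allow."""
        need = 2 if "DPC" in self.families or "CTD" in self.families else 1
        if "QSO" in self.families:
            need = max(need, self.qso_maxlag + 1)
        if "SOC" in self.families:
            need = max(need, self.soc_nlag + 1)
        if "AutoC" in self.families:
            need = max(need, self.autoc_maxlag + 1)
        return need


# ---------------------------------------------------------------------------
# per-family computations (each takes a validated sequence string)

def aac(sequence: str) -> np.ndarray:
    """Amino-acid composition: 20 residue frequencies, summing to 1."""
    idx = encode_indices(sequence)
    return np.bincount(idx, minlength=20) / idx.size


def dpc(sequence: str) -> np.ndarray:
    """Dipeptide composition: 400 ordered-pair frequencies, summing to 1."""
    idx = encode_indices(sequence)
    if idx.size < 2:
        raise DescriptorError(
            f"DPC undefined for length-1 sequence {sequence!r}"
        )
    pairs = idx[:-1] * 20 + idx[1:]
    return np.bincount(pairs, minlength=400) / (idx.size - 1)


def _distribution_points(positions: np.ndarray, n: int) -> list[float]:
    """CTD 'D' block for one group: positions of the 1st, ceil(25%), ceil(50%),
    ceil(75%) and last occurrence, as 100*position/N (1-based)."""
    if positions.size == 0:
        return [0.0] * 5
    ng = positions.size
    out = []
    for pct in (0, 25, 50, 75, 100):
        k = 1 if pct == 0 else int(np.ceil(pct * ng / 100.0))
        out.append(100.0 * positions[k - 1] / n)
    return out


def ctd(sequence: str,
        schemes: Sequence[GroupScheme] | None = None) -> np.ndarray:
    """Composition/transition/distribution vector (21 values per scheme).

    Per scheme: 3 group fractions; 3 unordered adjacent-pair transition
    frequencies (divisor N-1); 5 distribution points per group.
    """
    if schemes is None:
        schemes = default_group_schemes()
    idx = encode_indices(sequence)
    n = idx.size
    if n < 2:
        raise DescriptorError(
            f"CTD transitions undefined for length-1 sequence {sequence!r}"
        )
    out = []
    for scheme in schemes:
        g = scheme.labels(idx)
        comp = np.bincount(g, minlength=3) / n
        out.extend(comp)
        pairs = np.stack([g[:-1], g[1:]])
        lo, hi = pairs.min(axis=0), pairs.max(axis=0)
        for a, b in ((0, 1), (0, 2), (1, 2)):
            out.append(np.sum((lo == a) & (hi == b)) / (n - 1))
        for grp in range(3):
            positions = np.flatnonzero(g == grp) + 1  # 1-based
            out.extend(_distribution_points(positions, n))
    return np.asarray(out, dtype=float)


def soc(sequence: str, dmatrix: DistanceMatrix, nlag: int) -> np.ndarray:
    """Sequence-order-coupling numbers tau_d for d = 1..nlag."""
    idx = encode_indices(sequence)
    n = idx.size
    if nlag >= n:
        raise DescriptorError(
            f"SOC nlag={nlag} requires length >= {nlag + 1}, sequence "
            f"{sequence!r} has length {n}"
        )
    d2 = dmatrix.d ** 2
    return np.array([d2[idx[:-lag], idx[lag:]].sum()
                     for lag in range(1, nlag + 1)])


def qso(sequence: str, dmatrix: DistanceMatrix, maxlag: int,
        w: float = 0.1) -> np.ndarray:
    """Quasi-sequence-order vector of length 20 + maxlag, summing to 1."""
    tau = soc(sequence, dmatrix, maxlag)
    f = aac(sequence)
    denom = f.sum() + w * tau.sum()
    return np.concatenate([f / denom, w * tau / denom])


def autocorrelation(sequence: str, table: PropertyTable, maxlag: int,
                    kind: str = "moreau_broto",
                    standardize: bool = True) -> np.ndarray:
    """Lagged autocorrelation of a property scale along the sequence.

    ``moreau_broto``: averaged product form ``AC(l) = mean(P_i * P_{i+l})``.
    ``moran``: lagged covariance over sequence variance (1/N normaliser).
    ``geary``: half mean squared lag difference over sample variance
    (1/(N-1) normaliser). Zero-variance sequences return 0 for Moran and
    Geary by convention.
    """
    if kind not in AUTOC_KINDS:
        raise ConfigError(f"unknown autocorrelation kind {kind!r}")
    idx = encode_indices(sequence)
    n = idx.size
    if maxlag >= n:
        raise DescriptorError(
            f"autocorrelation maxlag={maxlag} requires length >= "
            f"{maxlag + 1}, sequence {sequence!r} has length {n}"
        )
    values = table.standardized() if standardize else table.as_array()
    p = values[idx]
    pbar = p.mean()
    out = np.empty(maxlag)
    for lag in range(1, maxlag + 1):
        a, b = p[:-lag], p[lag:]
        if kind == "moreau_broto":
            out[lag - 1] = (a * b).mean()
        elif kind == "moran":
            den = np.sum((p - pbar) ** 2) / n
            out[lag - 1] = 0.0 if den < 1e-12 else \
                ((a - pbar) * (b - pbar)).mean() / den
        else:  # geary
            den = np.sum((p - pbar) ** 2) / (n - 1)
            out[lag - 1] = 0.0 if den < 1e-12 else \
                np.sum((a - b) ** 2) / (2 * (n - lag)) / den
    return out


# ---------------------------------------------------------------------------
# dataset encoding

def _ctd_names(schemes: Sequence[GroupScheme]) -> list[str]:
    names = []
    for s in schemes:
        base = f"CTD.{s.property_name}"
        names += [f"{base}.C.g{g}" for g in (1, 2, 3)]
        names += [f"{base}.T.{a}{b}" for a, b in ((1, 2), (1, 3), (2, 3))]
        for g in (1, 2, 3):
            names += [f"{base}.D.g{g}.p{p}" for p in (0, 25, 50, 75, 100)]
    return names


def column_names(config: DescriptorConfig) -> list[str]:
    """Deterministic column names for :func:`encode` under *config*."""
    names: list[str] = []
    for family in config.families:
        if family == "AAC":
            names += [f"AAC.{a}" for a in ALPHABET]
        elif family == "DPC":
            names += [f"DPC.{a}{b}"
                      for a, b in itertools.product(ALPHABET, repeat=2)]
        elif family == "CTD":
            names += _ctd_names(default_group_schemes())
        elif family == "QSO":
            for m in config.distance_matrices:
                names += [f"QSO.{m}.Xr.{a}" for a in ALPHABET]
                names += [f"QSO.{m}.Xd.lag{d}"
                          for d in range(1, config.qso_maxlag + 1)]
        elif family == "SOC":
            for m in config.distance_matrices:
                names += [f"SOC.{m}.lag{d}"
                          for d in range(1, config.soc_nlag + 1)]
        elif family == "AutoC":
            for kind in config.autoc_kinds:
                prefix = _AUTOC_PREFIX[kind]
                for prop in config.autoc_properties:
                    names += [f"{prefix}.{prop}.lag{l}"
                              for l in range(1, config.autoc_maxlag + 1)]
    return names


def encode_peptide(sequence: str, config: DescriptorConfig) -> np.ndarray:
    """Descriptor vector for one validated sequence."""
    blocks: list[np.ndarray] = []
    for family in config.families:
        if family == "AAC":
            blocks.append(aac(sequence))
        elif family == "DPC":
            blocks.append(dpc(sequence))
        elif family == "CTD":
            blocks.append(ctd(sequence))
        elif family == "QSO":
            blocks += [qso(sequence, load_distance_matrix(m),
                           config.qso_maxlag, config.qso_weight)
                       for m in config.distance_matrices]
        elif family == "SOC":
            blocks += [soc(sequence, load_distance_matrix(m), config.soc_nlag)
                       for m in config.distance_matrices]
        elif family == "AutoC":
            for kind in config.autoc_kinds:
                blocks += [autocorrelation(sequence, load_property_table(p),
                                           config.autoc_maxlag, kind)
                           for p in config.autoc_properties]
    return np.concatenate(blocks) if blocks else np.zeros(0)


def encode(dataset: LabeledDataset,
           config: DescriptorConfig | None = None) -> pd.DataFrame:
    """Encode every peptide; a pure function of (dataset, config).

    Per-peptide failures (too-short sequences for the configured lags) are
    aggregated into a single :class:`DescriptorError` listing offending ids.
    """
    if config is None:
        config = DescriptorConfig()
    names = column_names(config)
    rows = np.empty((len(dataset), len(names)))
    failures = []
    for i, peptide in enumerate(dataset.peptides):
        try:
            rows[i] = encode_peptide(peptide.sequence, config)
        except DescriptorError as exc:
            failures.append(f"{peptide.id}: {exc}")
    if failures:
        shown = "; ".join(failures[:10])
        more = f" (+{len(failures) - 10} more)" if len(failures) > 10 else ""
        raise DescriptorError(
            f"{len(failures)} peptide(s) failed descriptor encoding: "
            f"{shown}{more}"
        )
    if not np.isfinite(rows).all():
        raise DescriptorError("non-finite descriptor values produced")
    return pd.DataFrame(rows, index=pd.Index(dataset.ids, name="row_id"),
                        columns=names)


def write_features(features: pd.DataFrame, path) -> None:
    """Write a feature matrix as CSV (first column ``row_id``)."""
    features.to_csv(path, index_label="row_id")


def read_features(path) -> pd.DataFrame:
    """Read a feature matrix written by :func:`write_features`."""
    return pd.read_csv(path, index_col="row_id")
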