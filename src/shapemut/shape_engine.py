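"""DNA shape features, profiles, and the k-mer lookup predictor.

The catalogue holds the 14 structural features commonly used to describe
sequence-dependent B-DNA geometry: six base-pair-step (inter-base-pair)
parameters (Shift, Slide, Rise, Tilt, Roll, HelT), six intra-base-pair
parameters (Shear, Stretch, Stagger, Buckle, ProT, Opening), and two
minor-groove features, minor groove width (MGW) and minor-groove
electrostatic potential (EP).  For a sequence of length n, each step
parameter yields a vector of length n-1; each intra-base-pair and groove
parameter a vector of length n.

Prediction is delegated to a pluggable backend satisfying the
:class:`ShapePredictor` contract.  The bundled backend is a k-mer
central-value lookup table (:class:`KmerShapeTable`), the same family as
classical pentamer shape tables: a width-k window slides along the
sequence and the table supplies the value of the central base pair (or
central step) of each window.  Any user-supplied table in the documented
text format plugs in; :func:`synth_table` generates seeded synthetic tables
that satisfy reverse-complement parity by construction.

Reverse-complement parity
-------------------------
Reading the duplex on the opposite strand reverses each profile and, for
features whose sign convention is tied to strand direction (Shift, Tilt,
Shear, Buckle), negates it.  A lookup table is *parity-consistent* when
``value(revcomp(w)) == parity * value(w)`` for every k-mer ``w``; prediction
from such a table is automatically reverse-complement equivariant at all
positions with full window context.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    InvalidWindowError,
    MissingKmerError,
    ParityError,
    TableFormatError,
    UnknownFeatureError,
)
from .seq_encoding import ALPHABET, NucleotideSequence


class FeatureClass(Enum):
    INTER_BP = "inter_bp"
    INTRA_BP = "intra_bp"
    GROOVE = "groove"


class Parity(Enum):
    """Sign behavior under strand flip; value is the sign factor."""

    SYMMETRIC = 1
    ANTISYMMETRIC = -1


@dataclass(frozen=True)
class ShapeFeature:
    name: str
    klass: FeatureClass
    parity: Parity

    @property
    def vector_length_offset(self) -> int:
        """0 for per-base-pair features, -1 for per-step features."""
        return -1 if self.klass is FeatureClass.INTER_BP else 0


_INTER = FeatureClass.INTER_BP
_INTRA = FeatureClass.INTRA_BP
_GROOVE = FeatureClass.GROOVE
_SYM = Parity.SYMMETRIC
_ANTI = Parity.ANTISYMMETRIC

# Standard base-pair / base-pair-step nomenclature; translational and
# rotational parameters defined about the x-axis (Shift, Tilt, Shear,
# Buckle) change sign on strand flip.
_CATALOGUE: Tuple[ShapeFeature, ...] = (
    ShapeFeature("Shift", _INTER, _ANTI),
    ShapeFeature("Slide", _INTER, _SYM),
    ShapeFeature("Rise", _INTER, _SYM),
    ShapeFeature("Tilt", _INTER, _ANTI),
    ShapeFeature("Roll", _INTER, _SYM),
    ShapeFeature("HelT", _INTER, _SYM),
    ShapeFeature("Shear", _INTRA, _ANTI),
    ShapeFeature("Stretch", _INTRA, _SYM),
    ShapeFeature("Stagger", _INTRA, _SYM),
    ShapeFeature("Buckle", _INTRA, _ANTI),
    ShapeFeature("ProT", _INTRA, _SYM),
    ShapeFeature("Opening", _INTRA, _SYM),
    ShapeFeature("MGW", _GROOVE, _SYM),
    ShapeFeature("EP", _GROOVE, _SYM),
)
_BY_NAME: Dict[str, ShapeFeature] = {f.name: f for f in _CATALOGUE}

# Rough B-DNA central values and spreads used by the synthetic-table
# generator (translations in Angstrom, rotations in degrees, EP in kT/e).
# Antisymmetric features are centered at zero, as parity requires.
_SYNTH_SCALE: Dict[str, Tuple[float, float]] = {
    "Shift": (0.0, 0.35),
    "Slide": (-0.2, 0.45),
    "Rise": (3.32, 0.20),
    "Tilt": (0.0, 2.5),
    "Roll": (2.0, 4.5),
    "HelT": (34.3, 3.0),
    "Shear": (0.0, 0.25),
    "Stretch": (0.0, 0.12),
    "Stagger": (0.0, 0.25),
    "Buckle": (0.0, 6.0),
    "ProT": (-11.0, 4.5),
    "Opening": (1.5, 3.0),
    "MGW": (5.1, 0.6),
    "EP": (-4.5, 1.5),
}


def feature_catalogue() -> List[ShapeFeature]:
    """The full 14-feature catalogue, in canonical order."""
    return list(_CATALOGUE)


def feature_by_name(name: str) -> ShapeFeature:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise UnknownFeatureError(
            f"unknown shape feature {name!r}; valid names: "
            + ", ".join(f.name for f in _CATALOGUE)
        ) from None


def resolve_features(names: Iterable[str]) -> List[ShapeFeature]:
    return [feature_by_name(n) for n in names]


@dataclass
class ShapeProfile:
    """Per-feature shape vectors predicted for one sequence.

    Step-parameter vectors have length ``n - 1`` (value i describes the step
    between base pairs i and i+1, 1-based); all other vectors have length
    ``n``.
    """

    n: int
    values: Dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, feature_name: str) -> np.ndarray:
        return self.values[feature_name]

    def __contains__(self, feature_name: str) -> bool:
        return feature_name in self.values

    @property
    def features(self) -> List[str]:
        return list(self.values)

    def expected_length(self, feature_name: str) -> int:
        return self.n + feature_by_name(feature_name).vector_length_offset


# --- k-mer coding helpers -------------------------------------------------

def encode_kmer(kmer: str) -> int:
    """Base-4 code of a k-mer (A=0, C=1, G=2, T=3; 5' base most significant)."""
    code = 0
    for b in kmer:
        code = code * 4 + "ACGT".index(b)
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def _rc_permutation(k: int) -> np.ndarray:
    """Permutation p with p[code(w)] == code(revcomp(w)) for all 4^k k-mers."""
    codes = np.arange(4**k)
    digits = np.empty((4**k, k), dtype=np.int64)
    c = codes.copy()
    for j in range(k - 1, -1, -1):
        digits[:, j] = c % 4
        c //= 4
    rc_digits = 3 - digits[:, ::-1]
    out = np.zeros(4**k, dtype=np.int64)
    for j in range(k):
        out = out * 4 + rc_digits[:, j]
    return out


class ShapePredictor:
    """Structural contract for shape-prediction backends.

    A predictor must implement ``provides(features) -> bool`` and
    ``predict(sequence, features=None) -> ShapeProfile`` whose output obeys
    the n / n-1 vector-length contract for the input length.
    :class:`KmerShapeTable` is the bundled implementation; any object with
    the same two methods (e.g. a wrapper around an external deep-learning
    predictor) can be passed wherever a predictor is expected.
    """

    def provides(self, features: Iterable[str]) -> bool:  # pragma: no cover
        raise NotImplementedError

    def predict(
        self, sequence, features: Optional[Sequence[str]] = None
    ) -> ShapeProfile:  # pragma: no cover
        raise NotImplementedError


def _check_k(k: int) -> None:
    if k % 2 == 0 or k < 1:
        raise InvalidWindowError(f"window width k must be odd and positive, got {k}")


class KmerShapeTable:
    """k-mer -> central-value lookup predictor backend.

    For every feature it provides, the table maps each of the 4^k k-mers to
    the feature value at the window's central base pair.  For step features
    the stored value describes the steps flanking the central base pair;
    prediction averages the two windows centered on a step's endpoints
    (see :func:`predict_shape`).

    Parameters
    ----------
    k
        Odd window width.
    values
        Map from feature name to a float array of length 4^k indexed by
        k-mer code (:func:`encode_kmer`).
    edge_policy
        How the (k-1)/2 positions at each sequence end, whose windows
        overhang the sequence, are handled:

        ``"mean"`` (default)
            Average the table over all k-mers consistent with the
            in-sequence part of the window (marginal mean over the missing
            flank positions).  Preserves the n / n-1 length contract.
        ``"nan"``
            Emit NaN at overhanging positions.
        ``"trim"``
            Omit overhanging positions entirely; vectors shrink by
            (k-1)/2 on each side and the length contract no longer holds.
    """

    def __init__(
        self,
        k: int,
        values: Dict[str, np.ndarray],
        edge_policy: str = "mean",
    ):
        _check_k(k)
        if edge_policy not in ("mean", "nan", "trim"):
            raise ValueError(f"unknown edge policy {edge_policy!r}")
        self.k = k
        self.edge_policy = edge_policy
        self.values: Dict[str, np.ndarray] = {}
        for name, arr in values.items():
            feature_by_name(name)  # validates the name
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (4**k,):
                raise MissingKmerError(
                    f"feature {name!r}: expected {4**k} values for k={k}, "
                    f"got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise TableFormatError(f"feature {name!r}: non-finite values")
            self.values[name] = arr
        self._marginal_cache: Dict[Tuple[str, int, int], np.ndarray] = {}

    # -- contract ----------------------------------------------------------

    @property
    def features(self) -> List[str]:
        return list(self.values)

    def provides(self, features: Iterable[str]) -> bool:
        return set(features) <= set(self.values)

    def predict(
        self, sequence, features: Optional[Sequence[str]] = None
    ) -> ShapeProfile:
        return predict_shape(sequence, self, features=features)

    # -- lookup ------------------------------------------------------------

    def value(self, feature: str, kmer: str) -> float:
        self._require(feature)
        return float(self.values[feature][encode_kmer(kmer)])

    def _require(self, feature: str) -> None:
        if feature not in self.values:
            raise MissingKmerError(
                f"table does not provide feature {feature!r} "
                f"(has: {', '.join(self.values) or 'none'})"
            )

    def _marginal(self, feature: str, miss_left: int, miss_right: int) -> np.ndarray:
        """Table averaged over `miss_left` 5' and `miss_right` 3' window slots."""
        key = (feature, miss_left, miss_right)
        if key not in self._marginal_cache:
            arr = self.values[feature].reshape((4,) * self.k)
            axes = tuple(range(miss_left)) + tuple(
                range(self.k - miss_right, self.k)
            )
            self._marginal_cache[key] = arr.mean(axis=axes).reshape(-1)
        return self._marginal_cache[key]

    # -- consistency checks ------------------------------------------------

    def parity_violations(self, atol: float = 1e-6) -> List[str]:
        """Names of provided features violating reverse-complement parity."""
        perm = _rc_permutation(self.k)
        bad = []
        for name, arr in self.values.items():
            sign = feature_by_name(name).parity.value
            if not np.allclose(arr[perm], sign * arr, atol=atol):
                bad.append(name)
        return bad

    def __eq__(self, other) -> bool:
        if not isinstance(other, KmerShapeTable):
            return NotImplemented
        return (
            self.k == other.k
            and set(self.values) == set(other.values)
            and all(
                np.array_equal(self.values[f], other.values[f]) for f in self.values
            )
        )

    # -- serialization -----------------------------------------------------

    def write(self, path) -> None:
        """Write the tab-separated table dialect (fixed 6-decimal floats)."""
        names = sorted(self.values)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("kmer\t" + "\t".join(names) + "\n")
            for code in range(4**self.k):
                row = [decode_kmer(code, self.k)]
                row += [f"{self.values[f][code]:.6f}" for f in names]
                fh.write("\t".join(row) + "\n")


def synth_table(
    k: int,
    features: Iterable[str],
    seed: int,
    edge_policy: str = "mean",
) -> KmerShapeTable:
    """Seeded synthetic lookup table, parity-consistent by construction.

    Per feature, a raw value g(w) is drawn for every k-mer from a normal
    distribution around the feature's B-DNA central value; the stored value
    is the parity-symmetrized ``(g(w) + parity * g(revcomp(w))) / 2``.
    Each feature's draw is seeded by (seed, catalogue index), so the values
    of a feature do not depend on which other features are requested.
    """
    _check_k(k)
    if k not in (3, 5, 7):
        raise InvalidWindowError(f"supported window widths are 3, 5, 7; got {k}")
    perm = _rc_permutation(k)
    values: Dict[str, np.ndarray] = {}
    for name in dict.fromkeys(features):  # preserve order, drop duplicates
        feat = feature_by_name(name)
        loc, scale = _SYNTH_SCALE[name]
        idx = next(i for i, f in enumerate(_CATALOGUE) if f.name == name)
        rng = np.random.default_rng([int(seed) % (2**31), idx])
        g = rng.normal(loc, scale, size=4**k)
        values[name] = (g + feat.parity.value * g[perm]) / 2.0
    return KmerShapeTable(k, values, edge_policy=edge_policy)


def predict_shape(
    sequence,
    table: KmerShapeTable,
    features: Optional[Sequence[str]] = None,
) -> ShapeProfile:
    """Predict shape vectors for a sequence with a k-mer lookup table.

    A width-k window slides along the sequence.  Per-base-pair features take
    the looked-up value of the window centered on each base pair.  Step
    features take the mean of the two windows centered on the step's two
    endpoint base pairs: an odd window has no strand-symmetric central step,
    and averaging the two endpoint-centered windows is what makes prediction
    exactly reverse-complement equivariant under a parity-consistent table
    (the same device classical pentamer shape tables use for step
    parameters).  Windows overhanging the sequence ends follow the table's
    edge policy.
    """
    s = NucleotideSequence(sequence)
    if features is None:
        features = table.features
    for f in features:
        table._require(f)
    n, k = len(s), table.k
    h = (k - 1) // 2
    codes = s.codes()
    pow4 = 4 ** np.arange(k - 1, -1, -1)

    # window codes for all fully-interior windows, start positions 0..n-k
    if n >= k:
        win = np.lib.stride_tricks.sliding_window_view(codes, k)
        interior_codes = win @ pow4
    else:
        interior_codes = np.empty(0, dtype=np.int64)

    out: Dict[str, np.ndarray] = {}
    for name in features:
        feat = feature_by_name(name)
        # value of the window centered on every base pair 1..n
        center = np.full(n, np.nan)
        if n >= k:
            center[h : h + n - k + 1] = table.values[name][interior_codes]
        if table.edge_policy == "mean":
            for c in range(1, n + 1):
                start = c - h - 1
                if 0 <= start <= n - k:
                    continue
                lo, hi = max(start, 0), min(start + k, n)
                miss_left, miss_right = lo - start, start + k - hi
                marg = table._marginal(name, miss_left, miss_right)
                m = k - miss_left - miss_right
                code = int(codes[lo:hi] @ (4 ** np.arange(m - 1, -1, -1)))
                center[c - 1] = marg[code]
        # "nan"/"trim": overhanging centers stay NaN here
        if feat.klass is FeatureClass.INTER_BP:
            vec = (center[:-1] + center[1:]) / 2.0
        else:
            vec = center
        if table.edge_policy == "trim":
            vec = vec[~np.isnan(vec)]
        out[name] = vec
    return ShapeProfile(n=n, values=out)


def read_kmer_table(path, on_parity: str = "warn") -> KmerShapeTable:
    """Read a k-mer table file.

    Format: UTF-8 text, tab-separated; first non-comment line is
    ``kmer<TAB>feature1<TAB>feature2...``; one row per k-mer; '#' lines are
    comments; row order irrelevant.  k is inferred from the k-mer strings.
    Completeness (all 4^k k-mers per feature) is enforced;
    reverse-complement parity violations are reported as warnings by
    default (``on_parity="error"`` raises, ``"ignore"`` skips the check).
    """
    if on_parity not in ("warn", "error", "ignore"):
        raise ValueError(f"on_parity must be warn/error/ignore, got {on_parity!r}")
    path = Path(path)
    header: Optional[List[str]] = None
    rows: Dict[str, List[float]] = {}
    k: Optional[int] = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                if parts[0].strip().lower() != "kmer":
                    raise TableFormatError(
                        f"{path}:{lineno}: header must start with 'kmer'"
                    )
                header = [p.strip() for p in parts[1:]]
                if not header:
                    raise TableFormatError(f"{path}:{lineno}: no feature columns")
                for name in header:
                    feature_by_name(name)
                continue
            kmer = parts[0].strip().upper()
            if k is None:
                k = len(kmer)
                try:
                    _check_k(k)
                except InvalidWindowError as e:
                    raise TableFormatError(f"{path}:{lineno}: {e}") from None
            if len(kmer) != k:
                raise TableFormatError(
                    f"{path}:{lineno}: mixed k-mer widths ({len(kmer)} vs {k})"
                )
            if set(kmer) - set(ALPHABET):
                raise TableFormatError(f"{path}:{lineno}: invalid k-mer {kmer!r}")
            if kmer in rows:
                raise TableFormatError(f"{path}:{lineno}: duplicate k-mer {kmer!r}")
            if len(parts) - 1 != len(header):
                raise TableFormatError(
                    f"{path}:{lineno}: expected {len(header)} values, "
                    f"got {len(parts) - 1}"
                )
            try:
                rows[kmer] = [float(v) for v in parts[1:]]
            except ValueError:
                raise TableFormatError(
                    f"{path}:{lineno}: non-numeric value in row {kmer!r}"
                ) from None
    if header is None or k is None:
        raise TableFormatError(f"{path}: no table content found")
    if len(rows) < 4**k:
        missing = next(
            decode_kmer(c, k)
            for c in range(4**k)
            if decode_kmer(c, k) not in rows
        )
        raise MissingKmerError(
            f"{path}: table incomplete for k={k}: {len(rows)}/{4 ** k} k-mers "
            f"(e.g. missing {missing!r})"
        )
    values = {name: np.empty(4**k) for name in header}
    for kmer, vals in rows.items():
        code = encode_kmer(kmer)
        for name, v in zip(header, vals):
            values[name][code] = v
    table = KmerShapeTable(k, values)
    if on_parity != "ignore":
        bad = table.parity_violations()
        if bad:
            msg = (
                f"{path}: reverse-complement parity violated for feature(s): "
                + ", ".join(bad)
            )
            if on_parity == "error":
                raise ParityError(msg)
            warnings.warn(msg, stacklevel=2)
    return table
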