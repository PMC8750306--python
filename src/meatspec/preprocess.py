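"""Spectral pre-processing operators and serialisable operator chains.

Every operator is a pure, deterministic transform of a scan × channel matrix.
Operators that learn state (MSC/EMSC reference spectrum, column centering
statistics, OSC components) fit that state on training rows only and apply it
unchanged to any other rows, so chains are leak-free by construction.

A :class:`PreprocessSpec` is an ordered list of ``(operator_id, params)``
steps with a canonical string form such as ``snv|savgol(d=1,p=2,w=11)`` —
the combo identifier used throughout screening reports.

Operator registry
-----------------
======== ==========================================================
id       operator
======== ==========================================================
snv      standard normal variate (row-wise standardisation)
detrend  row-wise polynomial baseline removal
msc      multiplicative scatter correction (mean / median-ratio / weighted)
emsc     extended MSC with polynomial wavelength terms
savgol   Savitzky–Golay smoothing / derivatives
gapseg   Norris gap-segment derivative (orders 1 and 2)
center   column mean- or median-centering (fitted on training rows)
osc      orthogonal signal correction (requires class indicators)
dwt      discrete-wavelet detail coefficients on a 128-point resample
quarter  contiguous quarter-spectrum selection
======== ==========================================================
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Any, ClassVar, Sequence

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import savgol_filter

from .errors import ConfigError, DimensionError, FitError, ValidationError

# ---------------------------------------------------------------------------
# functional operators
# ---------------------------------------------------------------------------


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row to mean 0, sample std 1 (ddof=1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise DimensionError("snv requires at least 2 channels per row")
    sd = X.std(axis=1, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValidationError(f"snv: zero-variance row(s) {zero.tolist()}")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def _index_vandermonde(n_channels: int, degree: int) -> np.ndarray:
    # scaled channel position in [-1, 1] for conditioning
    lam = np.linspace(-1.0, 1.0, n_channels)
    return np.vander(lam, degree + 1, increasing=True)


def detrend(X: np.ndarray, degree: int = 2) -> np.ndarray:
    """Subtract the least-squares polynomial (in channel position) per row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if degree < 0:
        raise ConfigError("detrend degree must be >= 0")
    if degree >= X.shape[1]:
        raise ConfigError(
            f"detrend degree {degree} needs more than {X.shape[1]} channels"
        )
    V = _index_vandermonde(X.shape[1], degree)
    coefs, *_ = np.linalg.lstsq(V, X.T, rcond=None)
    return X - (V @ coefs).T


def msc(
    X: np.ndarray,
    mode: str = "mean",
    reference: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    ``mode='mean'`` fits ``x = a + b·ref`` per row (optionally with channel
    ``weights``) and returns ``(x − a)/b``; ``mode='median_ratio'`` returns
    ``x / median(x/ref)``.  With no ``reference`` the mean of ``X`` itself is
    used (self-referenced fit; stateful use goes through the chain API).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.size != X.shape[1]:
        raise DimensionError("reference length does not match channel count")
    if mode in ("mean", "mean_reference", "weighted"):
        w = np.ones(X.shape[1]) if weights is None else np.asarray(weights, dtype=float)
        if w.size != X.shape[1] or np.any(w < 0) or not np.any(w > 0):
            raise ConfigError("weights must be non-negative, not all zero, one per channel")
        # weighted LS of x on [1, ref], closed form via 2x2 normal equations
        sw, swr = w.sum(), (w * ref).sum()
        swr2 = (w * ref * ref).sum()
        det = sw * swr2 - swr**2
        if det <= 0:
            raise FitError("msc: degenerate reference (constant under weights)")
        sx = X @ w
        sxr = X @ (w * ref)
        a = (swr2 * sx - swr * sxr) / det
        b = (sw * sxr - swr * sx) / det
        if np.any(b == 0):
            raise FitError(f"msc: zero slope for row(s) {np.flatnonzero(b == 0).tolist()}")
        return (X - a[:, None]) / b[:, None]
    if mode == "median_ratio":
        if np.any(ref == 0):
            raise FitError("msc median_ratio: reference contains zeros")
        ratio = np.median(X / ref, axis=1)
        if np.any(ratio == 0):
            raise FitError("msc median_ratio: zero median ratio")
        return X / ratio[:, None]
    raise ConfigError(f"unknown msc mode {mode!r}")


def emsc(
    X: np.ndarray, poly_degree: int = 2, reference: np.ndarray | None = None
) -> np.ndarray:
    """Extended MSC: fit ``x = a + b·ref + Σ c_k λ^k`` and return the
    polynomial-corrected, slope-normalised spectrum ``(x − a − Σ c_k λ^k)/b``.

    λ is the channel position affinely scaled to [−1, 1].  ``poly_degree=0``
    reduces exactly to plain mean-reference MSC.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if poly_degree < 0:
        raise ConfigError("emsc poly_degree must be >= 0")
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.size != X.shape[1]:
        raise DimensionError("reference length does not match channel count")
    V = _index_vandermonde(X.shape[1], poly_degree)  # columns 1, λ, λ², ...
    design = np.column_stack([V, ref])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FitError("emsc: rank-deficient design (reference collinear with polynomial)")
    coefs, *_ = np.linalg.lstsq(design, X.T, rcond=None)  # (deg+2) × n_rows
    b = coefs[-1]
    if np.any(b == 0):
        raise FitError(f"emsc: zero slope for row(s) {np.flatnonzero(b == 0).tolist()}")
    baseline = (V @ coefs[:-1]).T
    return (X - baseline) / b[:, None]


def savgol(X: np.ndarray, window: int = 11, polyorder: int = 2, deriv: int = 0) -> np.ndarray:
    """Savitzky–Golay filtering per row; derivatives are per channel step.

    Edges are handled by polynomial-fit extrapolation within the edge windows
    (``mode='interp'``).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if window % 2 == 0 or window < 3:
        raise ConfigError(f"savgol window must be odd and >= 3, got {window}")
    if not (window > polyorder >= deriv >= 0):
        raise ConfigError(
            f"savgol requires window > polyorder >= deriv >= 0, got "
            f"window={window}, polyorder={polyorder}, deriv={deriv}"
        )
    if window > X.shape[1]:
        raise ConfigError("savgol window exceeds channel count")
    return savgol_filter(X, window, polyorder, deriv=deriv, delta=1.0, axis=1, mode="interp")


def _segment_means(X: np.ndarray, segment: int) -> tuple[np.ndarray, int]:
    """Sliding segment means; returns (means, lo) with mean j centred at
    channel ``j + lo`` where ``lo = (segment-1)//2``."""
    sw = sliding_window_view(X, segment, axis=1)
    return sw.mean(axis=-1), (segment - 1) // 2


def gap_segment_derivative(
    X: np.ndarray, gap: int = 5, segment: int = 5, order: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Norris-style gap-segment derivative.

    With ``s(i)`` the mean over the segment-length window centred at channel
    ``i``:

    * order 1: ``D(i) = [s(i+h) − s(i−h)] / (2h)`` with
      ``h = ceil(gap/2) + floor(segment/2)`` (channel units);
    * order 2: ``D(i) = [s(i+g) − 2 s(i) + s(i−g)] / g²`` with
      ``g = gap + segment − 1``.

    Channels whose stencil leaves the row are trimmed; the returned mask
    (length ``n_channels``) marks the surviving channels.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if gap < 1 or segment < 1:
        raise ConfigError("gap and segment must be >= 1")
    if order not in (1, 2):
        raise ConfigError(f"gap-segment order must be 1 or 2, got {order}")
    n = X.shape[1]
    s, lo = _segment_means(X, segment)  # s[:, j] is centred at channel j + lo
    hi = segment - 1 - lo
    if order == 1:
        h = -(-gap // 2) + segment // 2  # ceil(gap/2) + floor(segment/2)
        first, last = lo + h, n - 1 - hi - h
        if first > last:
            raise DimensionError("gap-segment stencil wider than the row")
        idx = np.arange(first, last + 1)
        D = (s[:, idx + h - lo] - s[:, idx - h - lo]) / (2.0 * h)
    else:
        g = gap + segment - 1
        first, last = lo + g, n - 1 - hi - g
        if first > last:
            raise DimensionError("gap-segment stencil wider than the row")
        idx = np.arange(first, last + 1)
        D = (s[:, idx + g - lo] - 2.0 * s[:, idx - lo] + s[:, idx - g - lo]) / float(g * g)
    mask = np.zeros(n, dtype=bool)
    mask[first : last + 1] = True
    return D, mask


def dwt_features(
    X: np.ndarray,
    family: str = "daub_short",
    level_lo: int = 5,
    level_hi: int = 7,
    interp_points: int = 128,
) -> np.ndarray:
    """Detail coefficients of a dyadic DWT on a linearly resampled spectrum.

    Each row is interpolated onto ``interp_points`` equally spaced positions
    spanning the row, decomposed with periodic extension, and the detail
    coefficients of levels ``level_lo..level_hi`` are concatenated (ascending
    level).  ``daub_short`` is the 2-tap Daubechies (Haar) wavelet;
    ``la8`` the 8-tap least-asymmetric (symlet) wavelet.  Defaults give 7
    features (Haar, levels 5–7 of 128 points); ``la8`` levels 3–5 give 28.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    wavelets = {"daub_short": "haar", "la8": "sym4"}
    if family not in wavelets:
        raise ConfigError(f"unknown wavelet family {family!r}; expected {sorted(wavelets)}")
    max_level = int(np.log2(interp_points))
    if 2**max_level != interp_points:
        raise ConfigError("interp_points must be a power of two")
    if not (1 <= level_lo <= level_hi <= max_level):
        raise ConfigError(
            f"levels must satisfy 1 <= lo <= hi <= log2({interp_points}) = {max_level}"
        )
    pos = np.linspace(0.0, X.shape[1] - 1.0, interp_points)
    base = np.arange(X.shape[1], dtype=float)
    Z = np.vstack([np.interp(pos, base, row) for row in X])
    with warnings.catch_warnings():
        # periodization keeps dyadic lengths exact; pywt warns about boundary
        # effects at deep levels, which are part of the intended transform
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(Z, wavelets[family], mode="periodization", level=level_hi, axis=1)
    # coeffs = [cA_hi, cD_hi, cD_hi-1, ..., cD_1]
    details = [coeffs[level_hi - l + 1] for l in range(level_lo, level_hi + 1)]
    return np.hstack(details)


def split_quarters(X: np.ndarray, quarter: int | str = "full") -> np.ndarray:
    """Select one contiguous quarter of the channels (floor-balanced), or all."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if quarter in ("full", 0, "0"):
        return X
    q = int(quarter)
    if not 1 <= q <= 4:
        raise ConfigError(f"quarter must be 'full' or 1..4, got {quarter!r}")
    parts = np.array_split(np.arange(X.shape[1]), 4)
    return X[:, parts[q - 1]]


# ---------------------------------------------------------------------------
# orthogonal signal correction
# ---------------------------------------------------------------------------


@dataclass
class OSCModel:
    """Fitted OSC filter: per component a weight vector (scores ``t = X w``)
    and a loading vector used for deflation ``X ← X − t pᵀ``."""

    weights: np.ndarray  # p × k
    loadings: np.ndarray  # p × k
    removed_variance: np.ndarray  # per-component ‖t pᵀ‖²


def osc_fit(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    n_components: int = 1,
    max_iter: int = 50,
    tol: float = 1e-12,
) -> OSCModel:
    """Extract components of maximal X-variance orthogonal to the response.

    Each component starts from the first principal score of the (deflated)
    matrix, is projected onto the orthogonal complement of the columns of
    ``Y`` (``t ← t − Y (YᵀY)⁻¹ Yᵀ t``), and re-expressed through spectral
    weights ``w`` (least squares) so that new rows can be filtered by
    projection alone.  For wide matrices (channels ≫ rows, the spectral case)
    the re-expression is exact and scores are numerically orthogonal to every
    class indicator.
    """
    X = np.array(X_train, dtype=float)
    Y = np.atleast_2d(np.asarray(Y_train, dtype=float))
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != X.shape[0]:
        raise DimensionError("X and Y row counts differ")
    rank = np.linalg.matrix_rank(X)
    if n_components >= rank:
        raise FitError(f"osc: n_components={n_components} must be < rank(X)={rank}")
    W, P, removed = [], [], []
    for _ in range(n_components):
        # first principal score of current X
        U, s, _ = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
        t = U[:, 0] * s[0]
        for _ in range(max_iter):
            beta, *_ = np.linalg.lstsq(Y, t, rcond=None)
            t_orth = t - Y @ beta
            w, *_ = np.linalg.lstsq(X, t_orth, rcond=None)
            nw = np.linalg.norm(w)
            if nw == 0:
                raise FitError("osc: degenerate component (zero weights)")
            w = w / nw
            t_new = X @ w
            if np.linalg.norm(t_new - t) <= tol * max(1.0, np.linalg.norm(t)):
                t = t_new
                break
            t = t_new
        p = X.T @ t / (t @ t)
        X = X - np.outer(t, p)
        W.append(w)
        P.append(p)
        removed.append(float((t @ t) * (p @ p)))
    return OSCModel(np.column_stack(W), np.column_stack(P), np.asarray(removed))


def osc_apply(model: OSCModel, X: np.ndarray) -> np.ndarray:
    """Filter rows by sequentially projecting out each stored component."""
    X = np.array(np.atleast_2d(X), dtype=float)
    for k in range(model.weights.shape[1]):
        t = X @ model.weights[:, k]
        X = X - np.outer(t, model.loadings[:, k])
    return X


# ---------------------------------------------------------------------------
# chain steps
# ---------------------------------------------------------------------------


class Step:
    """One chain step.  Stateless steps ignore :meth:`fit`."""

    id: ClassVar[str]
    stateful: ClassVar[bool] = False
    requires_y: ClassVar[bool] = False

    def params(self) -> dict[str, Any]:
        return {}

    def fit(self, X: np.ndarray, Y: np.ndarray | None = None) -> "Step":
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class SNVStep(Step):
    id = "snv"

    def transform(self, X):
        return snv(X)


class DetrendStep(Step):
    id = "detrend"

    def __init__(self, deg: int = 2):
        self.deg = int(deg)

    def params(self):
        return {"deg": self.deg}

    def transform(self, X):
        return detrend(X, self.deg)


class MSCStep(Step):
    id = "msc"
    stateful = True

    def __init__(self, mode: str = "mean"):
        self.mode = str(mode)
        self.reference_: np.ndarray | None = None

    def params(self):
        return {"mode": self.mode}

    def fit(self, X, Y=None):
        self.reference_ = np.asarray(X, dtype=float).mean(axis=0)
        return self

    def transform(self, X):
        if self.reference_ is None:
            raise FitError("msc step not fitted")
        return msc(X, mode=self.mode, reference=self.reference_)


class EMSCStep(Step):
    id = "emsc"
    stateful = True

    def __init__(self, deg: int = 2):
        self.deg = int(deg)
        self.reference_: np.ndarray | None = None

    def params(self):
        return {"deg": self.deg}

    def fit(self, X, Y=None):
        self.reference_ = np.asarray(X, dtype=float).mean(axis=0)
        return self

    def transform(self, X):
        if self.reference_ is None:
            raise FitError("emsc step not fitted")
        return emsc(X, poly_degree=self.deg, reference=self.reference_)


class SavGolStep(Step):
    id = "savgol"

    def __init__(self, w: int = 11, p: int = 2, d: int = 0):
        self.w, self.p, self.d = int(w), int(p), int(d)

    def params(self):
        return {"w": self.w, "p": self.p, "d": self.d}

    def transform(self, X):
        return savgol(X, self.w, self.p, self.d)


class GapSegmentStep(Step):
    id = "gapseg"

    def __init__(self, gap: int = 5, seg: int = 5, order: int = 2):
        self.gap, self.seg, self.order = int(gap), int(seg), int(order)
        self.mask_: np.ndarray | None = None

    def params(self):
        return {"gap": self.gap, "seg": self.seg, "order": self.order}

    def transform(self, X):
        D, mask = gap_segment_derivative(X, self.gap, self.seg, self.order)
        self.mask_ = mask  # edge-trim mask, deterministic in the channel count
        return D


class CenterStep(Step):
    id = "center"
    stateful = True

    def __init__(self, mode: str = "mean"):
        if mode not in ("mean", "median"):
            raise ConfigError(f"center mode must be 'mean' or 'median', got {mode!r}")
        self.mode = mode
        self.stats_: np.ndarray | None = None

    def params(self):
        return {"mode": self.mode}

    def fit(self, X, Y=None):
        X = np.asarray(X, dtype=float)
        self.stats_ = X.mean(axis=0) if self.mode == "mean" else np.median(X, axis=0)
        return self

    def transform(self, X):
        if self.stats_ is None:
            raise FitError("center step not fitted")
        return np.asarray(X, dtype=float) - self.stats_


class OSCStep(Step):
    id = "osc"
    stateful = True
    requires_y = True

    def __init__(self, k: int = 1):
        self.k = int(k)
        self.model_: OSCModel | None = None

    def params(self):
        return {"k": self.k}

    def fit(self, X, Y=None):
        if Y is None:
            raise ConfigError("osc step requires training class indicators (Y_train)")
        self.model_ = osc_fit(X, Y, self.k)
        return self

    def transform(self, X):
        if self.model_ is None:
            raise FitError("osc step not fitted")
        return osc_apply(self.model_, X)


class DWTStep(Step):
    id = "dwt"

    def __init__(self, family: str = "daub_short", lo: int = 5, hi: int = 7):
        self.family, self.lo, self.hi = str(family), int(lo), int(hi)

    def params(self):
        return {"family": self.family, "lo": self.lo, "hi": self.hi}

    def transform(self, X):
        return dwt_features(X, self.family, self.lo, self.hi)


class QuarterStep(Step):
    id = "quarter"

    def __init__(self, q: int | str = "full"):
        self.q = q if q == "full" else int(q)

    def params(self):
        return {"q": self.q}

    def transform(self, X):
        return split_quarters(X, self.q)


REGISTRY: dict[str, type[Step]] = {
    cls.id: cls
    for cls in (
        SNVStep,
        DetrendStep,
        MSCStep,
        EMSCStep,
        SavGolStep,
        GapSegmentStep,
        CenterStep,
        OSCStep,
        DWTStep,
        QuarterStep,
    )
}

# ---------------------------------------------------------------------------
# PreprocessSpec and chain application
# ---------------------------------------------------------------------------

_STEP_RE = re.compile(r"^(?P<id>[a-z_]+)(?:\((?P<params>[^)]*)\))?$")


def _format_value(v: Any) -> str:
    if isinstance(v, bool):
        return str(v).lower()
    if isinstance(v, float) and v == int(v):
        return str(int(v))
    return str(v)


def _parse_value(s: str) -> Any:
    s = s.strip()
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        return s


@dataclass
class PreprocessSpec:
    """Ordered, parameterised chain of spectral operators.

    ``steps`` is a list of ``(operator_id, params)`` applied left to right.
    The canonical string (params sorted by key) identifies the combination in
    screening records, e.g. ``snv|gapseg(gap=5,order=2,seg=5)``.
    """

    steps: list[tuple[str, dict[str, Any]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for op_id, params in self.steps:
            if op_id not in REGISTRY:
                raise ConfigError(f"unknown operator {op_id!r}; known: {sorted(REGISTRY)}")
            REGISTRY[op_id](**params)  # parameter validation

    def canonical(self) -> str:
        parts = []
        for op_id, params in self.steps:
            full = REGISTRY[op_id](**params).params()
            if full:
                inner = ",".join(f"{k}={_format_value(v)}" for k, v in sorted(full.items()))
                parts.append(f"{op_id}({inner})")
            else:
                parts.append(op_id)
        return "|".join(parts) if parts else "raw"

    def __str__(self) -> str:
        return self.canonical()

    @classmethod
    def from_string(cls, text: str) -> "PreprocessSpec":
        text = text.strip()
        if text in ("", "raw"):
            return cls([])
        steps: list[tuple[str, dict[str, Any]]] = []
        for segment in text.split("|"):
            m = _STEP_RE.match(segment.strip())
            if m is None:
                raise ConfigError(f"cannot parse chain segment {segment!r}")
            params: dict[str, Any] = {}
            if m["params"]:
                for kv in m["params"].split(","):
                    if "=" not in kv:
                        raise ConfigError(f"malformed parameter {kv!r} in {segment!r}")
                    k, v = kv.split("=", 1)
                    params[k.strip()] = _parse_value(v)
            steps.append((m["id"], params))
        return cls(steps)

    def build(self) -> list[Step]:
        return [REGISTRY[op_id](**params) for op_id, params in self.steps]

    @property
    def is_stateless(self) -> bool:
        return not any(REGISTRY[op_id].stateful for op_id, _ in self.steps)

    @property
    def requires_y(self) -> bool:
        return any(REGISTRY[op_id].requires_y for op_id, _ in self.steps)


@dataclass
class FittedChain:
    """A chain whose stateful steps have been fitted on training rows."""

    spec: PreprocessSpec
    steps: list[Step]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        for step in self.steps:
            X = step.transform(X)
        return X


def fit_chain(
    spec: PreprocessSpec, X_train: np.ndarray, Y_train: np.ndarray | None = None
) -> tuple[FittedChain, np.ndarray]:
    """Fit every stateful step on training rows; return chain and transformed
    training matrix.  No other rows influence any fitted state."""
    if spec.requires_y and Y_train is None:
        raise ConfigError("chain contains osc but no Y_train was supplied")
    steps = spec.build()
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    for step in steps:
        step.fit(X, Y_train)
        X = step.transform(X)
    return FittedChain(spec, steps), X


def apply_chain(
    spec: PreprocessSpec,
    X_train: np.ndarray,
    X_test: np.ndarray,
    Y_train: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit on training rows only, then transform both partitions identically."""
    chain, Xtr = fit_chain(spec, X_train, Y_train)
    return Xtr, chain.transform(X_test)
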