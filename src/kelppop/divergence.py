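"""Pairwise and group-to-group divergence; sliding-window profiles.

Distances are computed over comparable sites only (pairwise deletion).  The
default model is the uncorrected proportion of differing sites (p-distance);
Jukes-Cantor (JC69), Kimura two-parameter (K2P) and Tamura three-parameter
(T92) corrections are available.  Between-group divergence Dxy is the mean
model distance over all cross-group pairs, with a standard error from a
seeded site (column) bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .alignment import Alignment, encode
from .errors import ArgumentError, SaturationError, UndefinedPairError

MODELS = ("p", "JC69", "K2P", "T92")


@dataclass
class PairwiseDistance:
    """Distance between two rows: raw proportions and the model correction.

    ``p`` is the proportion of differing comparable sites, split into the
    transition (``P``) and transversion (``Q``) proportions; ``d`` is the
    model-corrected distance (equal to ``p`` under the p model).  ``theta_gc``
    and ``h = 2*theta_gc*(1-theta_gc)`` are populated for T92 only.
    """

    p: float
    P: float
    Q: float
    d: float
    model: str
    sites: int
    theta_gc: float | None = None
    h: float | None = None


@dataclass
class DivergenceResult:
    dxy: float
    se: float
    n_pairs: int
    model: str


@dataclass
class WindowSpec:
    """Sliding-window geometry in alignment columns."""

    window: int
    step: int

    def __post_init__(self) -> None:
        if self.window < 1 or self.step < 1:
            raise ArgumentError("window and step must be >= 1")

    def starts(self, length: int) -> np.ndarray:
        """1-based window start columns over a region of *length* columns."""
        if self.window > length:
            raise ArgumentError(
                f"window {self.window} exceeds region length {length}"
            )
        return np.arange(1, length - self.window + 2, self.step)


@dataclass
class DivergenceProfile:
    """Windowed Dxy series; NaN marks windows with no comparable sites."""

    midpoints: np.ndarray
    values: np.ndarray
    sites_used: np.ndarray
    spec: WindowSpec


def _log_or_saturate(x: float, model: str, label: str) -> float:
    if x <= 0.0:
        raise SaturationError(f"{model} correction undefined for {label}")
    return math.log(x)


def _correct(p: float, P: float, Q: float, model: str, h: float | None,
             label: str = "pair") -> float:
    """Apply the model correction to raw proportions."""
    if model == "p":
        return p
    if model == "JC69":
        return -0.75 * _log_or_saturate(1.0 - 4.0 * p / 3.0, model, label)
    if model == "K2P":
        return (
            -0.5 * _log_or_saturate(1.0 - 2.0 * P - Q, model, label)
            - 0.25 * _log_or_saturate(1.0 - 2.0 * Q, model, label)
        )
    if model == "T92":
        assert h is not None
        if h == 0.0:
            raise SaturationError(f"T92 undefined: pair GC content 0 or 1 ({label})")
        return (
            -h * _log_or_saturate(1.0 - P / h - Q, model, label)
            - 0.5 * (1.0 - h) * _log_or_saturate(1.0 - 2.0 * Q, model, label)
        )
    raise ArgumentError(f"unknown model {model!r}")


def _as_codes(seq: str | np.ndarray) -> np.ndarray:
    if isinstance(seq, str):
        return encode(seq.upper())
    return np.asarray(seq, dtype=np.int8)


def pairwise_distance(
    a: str | np.ndarray, b: str | np.ndarray, model: str = "p"
) -> PairwiseDistance:
    """Model distance between two aligned rows (strings or code vectors).

    Transitions are A<->G and C<->T; everything else is a transversion.
    Raises :class:`UndefinedPairError` when no site is comparable and
    :class:`SaturationError` when a correction logarithm is undefined.
    """
    if model not in MODELS:
        raise ArgumentError(f"unknown model {model!r}")
    ca, cb = _as_codes(a), _as_codes(b)
    if ca.shape != cb.shape:
        raise ArgumentError("rows differ in length")
    valid = (ca >= 0) & (cb >= 0)
    sites = int(valid.sum())
    if sites == 0:
        raise UndefinedPairError("zero comparable sites")
    diff = valid & (ca != cb)
    # transition iff both codes in {A,G} (even) or both in {C,T} (odd)
    ts = diff & ((ca % 2) == (cb % 2))
    P = float(ts.sum()) / sites
    Q = float((diff & ~ts).sum()) / sites
    p = P + Q
    theta = h = None
    if model == "T92":
        gc = ((ca == 1) | (ca == 2))[valid].sum() + ((cb == 1) | (cb == 2))[valid].sum()
        theta = float(gc) / (2 * sites)
        h = 2.0 * theta * (1.0 - theta)
    d = _correct(p, P, Q, model, h)
    return PairwiseDistance(p=p, P=P, Q=Q, d=d, model=model, sites=sites,
                            theta_gc=theta, h=h)


def _pair_site_indicators(
    aln: Alignment, group_a: Iterable[str], group_b: Iterable[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Per cross-group pair, per column: comparable / transition / transversion."""
    a_ids, b_ids = list(group_a), list(group_b)
    if not a_ids or not b_ids:
        raise ArgumentError("both groups must be non-empty")
    if set(a_ids) & set(b_ids):
        raise ArgumentError("groups overlap")
    codes = {sid: aln.codes[aln.index(sid)] for sid in a_ids + b_ids}
    pairs = [(x, y) for x in a_ids for y in b_ids]
    L = aln.length
    valid = np.empty((len(pairs), L), dtype=bool)
    ts = np.empty((len(pairs), L), dtype=bool)
    tv = np.empty((len(pairs), L), dtype=bool)
    for k, (x, y) in enumerate(pairs):
        ca, cb = codes[x], codes[y]
        v = (ca >= 0) & (cb >= 0)
        diff = v & (ca != cb)
        t = diff & ((ca % 2) == (cb % 2))
        valid[k], ts[k], tv[k] = v, t, diff & ~t
    return valid, ts, tv, pairs


def _pair_distances(valid_n, ts_n, tv_n, model, h_pairs, pairs):
    """Vector of model distances from per-pair site counts."""
    d = np.empty(len(pairs))
    for k in range(len(pairs)):
        n = valid_n[k]
        if n == 0:
            raise UndefinedPairError(
                f"pair {pairs[k]} shares no comparable sites"
            )
        P, Q = ts_n[k] / n, tv_n[k] / n
        d[k] = _correct(P + Q, P, Q, model,
                        h_pairs[k] if h_pairs is not None else None,
                        label=str(pairs[k]))
    return d


def _pair_gc_h(aln: Alignment, pairs) -> np.ndarray:
    h = np.empty(len(pairs))
    for k, (x, y) in enumerate(pairs):
        ca = aln.codes[aln.index(x)]
        cb = aln.codes[aln.index(y)]
        v = (ca >= 0) & (cb >= 0)
        gc = ((ca == 1) | (ca == 2))[v].sum() + ((cb == 1) | (cb == 2))[v].sum()
        theta = gc / (2 * max(v.sum(), 1))
        h[k] = 2.0 * theta * (1.0 - theta)
    return h


def dxy(
    aln: Alignment,
    group_a: Iterable[str],
    group_b: Iterable[str],
    model: str = "p",
    bootstrap_reps: int = 1000,
    seed: int | None = None,
) -> DivergenceResult:
    """Between-group divergence: mean model distance over all cross pairs.

    The standard error is the standard deviation of Dxy across
    ``bootstrap_reps`` column-resampled replicates (``bootstrap_reps=0``
    skips the bootstrap and reports SE = NaN).
    """
    if model not in MODELS:
        raise ArgumentError(f"unknown model {model!r}")
    valid, ts, tv, pairs = _pair_site_indicators(aln, group_a, group_b)
    h_pairs = _pair_gc_h(aln, pairs) if model == "T92" else None
    d = _pair_distances(valid.sum(1), ts.sum(1), tv.sum(1), model, h_pairs, pairs)
    point = float(d.mean())
    if bootstrap_reps <= 0:
        return DivergenceResult(point, float("nan"), len(pairs), model)

    rng = np.random.default_rng(seed)
    L = aln.length
    # Column resampling as multinomial column weights: one matmul per matrix.
    weights = rng.multinomial(L, np.full(L, 1.0 / L), size=bootstrap_reps).T
    w = weights.astype(np.float64)
    vn = valid.astype(np.float64) @ w
    tn = ts.astype(np.float64) @ w
    qn = tv.astype(np.float64) @ w
    reps = np.empty(bootstrap_reps)
    for r in range(bootstrap_reps):
        try:
            dr = _pair_distances(vn[:, r], tn[:, r], qn[:, r], model,
                                 h_pairs, pairs)
        except (UndefinedPairError, SaturationError):
            reps[r] = np.nan
            continue
        reps[r] = dr.mean()
    se = float(np.nanstd(reps, ddof=1))
    return DivergenceResult(point, se, len(pairs), model)


def sliding_window_divergence(
    aln: Alignment,
    group_a: Iterable[str],
    group_b: Iterable[str],
    spec: WindowSpec,
    model: str = "p",
) -> DivergenceProfile:
    """Windowed Dxy along the alignment.

    Windows start at column 1 and advance by ``spec.step`` while they fit.
    Within a window, each cross pair contributes its model distance over the
    window's comparable sites; pairs with no comparable site in the window are
    left out of that window's mean, and a window where no pair is comparable
    is NaN.  Values are indexed by window midpoint.
    """
    starts = spec.starts(aln.length)
    valid, ts, tv, pairs = _pair_site_indicators(aln, group_a, group_b)
    h_pairs = _pair_gc_h(aln, pairs) if model == "T92" else None

    # prefix sums -> O(1) per-window counts
    cs_valid = np.concatenate(
        [np.zeros((len(pairs), 1), dtype=np.int64), valid.cumsum(1)], axis=1
    )
    cs_ts = np.concatenate(
        [np.zeros((len(pairs), 1), dtype=np.int64), ts.cumsum(1)], axis=1
    )
    cs_tv = np.concatenate(
        [np.zeros((len(pairs), 1), dtype=np.int64), tv.cumsum(1)], axis=1
    )

    lo = starts - 1
    hi = lo + spec.window
    vn = cs_valid[:, hi] - cs_valid[:, lo]  # (n_pairs, n_windows)
    tn = cs_ts[:, hi] - cs_ts[:, lo]
    qn = cs_tv[:, hi] - cs_tv[:, lo]

    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(vn > 0, tn / np.maximum(vn, 1), np.nan)
        Q = np.where(vn > 0, qn / np.maximum(vn, 1), np.nan)
        if model == "p":
            dmat = P + Q
        elif model == "JC69":
            dmat = -0.75 * np.log(1.0 - 4.0 * (P + Q) / 3.0)
        elif model == "K2P":
            dmat = -0.5 * np.log(1.0 - 2.0 * P - Q) - 0.25 * np.log(1.0 - 2.0 * Q)
        elif model == "T92":
            h = h_pairs[:, None]
            dmat = -h * np.log(1.0 - P / h - Q) - 0.5 * (1.0 - h) * np.log(
                1.0 - 2.0 * Q
            )
        else:
            raise ArgumentError(f"unknown model {model!r}")

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        values = np.nanmean(dmat, axis=0)
    sites = vn.mean(axis=0)
    midpoints = starts + (spec.window - 1) / 2.0
    return DivergenceProfile(midpoints, values, sites, spec)


def profile_frame(profile: DivergenceProfile):
    import pandas as pd

    return pd.DataFrame(
        {
            "midpoint": profile.midpoints,
            "dxy": profile.values,
            "sites_used": profile.sites_used,
        }
    )
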