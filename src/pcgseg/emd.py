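"""Empirical mode decomposition by iterative sifting.

EMD decomposes a signal x(n) into a small set of oscillatory intrinsic mode
functions (IMFs) plus a residual trend:

    x(n) = sum_i IMF_i(n) + r(n)

An IMF must (1) have extrema and zero-crossing counts differing by at most
one, and (2) have a locally zero-mean envelope: the mean of the cubic-spline
envelopes through its maxima and minima is approximately zero everywhere.

Sifting extracts one IMF: subtract the spline mean envelope from the signal
and repeat on the difference until the IMF criteria are met or the change
between iterations becomes negligible (Cauchy-style SD criterion, the
standard stopping rule).  The residual then restarts the procedure until it
is monotone or constant.

The segmentation pipeline keeps only the first IMF, which captures the
fastest oscillation — for a bandpassed heart-sound signal, the S1/S2
transients themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline


class MonotoneSignalError(ValueError):
    """Signal has too few extrema to construct spline envelopes."""


@dataclass(frozen=True)
class SiftConfig:
    """Stopping and boundary parameters for the sifting iteration.

    ``sd_threshold`` is the Cauchy criterion on the normalised squared change
    between successive sift iterates, sum((d_prev - d)**2) / sum(d_prev**2);
    0.2 is the classical recommendation.  ``boundary`` selects the envelope
    extension rule at the signal edges (only ``"mirror"`` is implemented:
    extrema are reflected about the first and last samples, which bounds the
    spline end swings).
    """

    max_sift_iterations: int = 100
    sd_threshold: float = 0.2
    boundary: str = "mirror"

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be positive")
        if self.max_sift_iterations < 1:
            raise ValueError("max_sift_iterations must be >= 1")
        if self.boundary != "mirror":
            raise ValueError(f"unsupported boundary rule {self.boundary!r}")


@dataclass(frozen=True)
class EmdResult:
    """Ordered IMFs plus residual; ``imfs[0]`` is the fastest mode."""

    imfs: tuple[np.ndarray, ...]
    residual: np.ndarray
    levels: int

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


@dataclass(frozen=True)
class ImfCheck:
    """Diagnostics from the two IMF criteria."""

    passed: bool
    n_extrema: int
    n_zero_crossings: int
    envelope_mean_max: float  # max |mean envelope|, absolute units


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima of ``x``.

    Detection is by strict sign change of the first difference; a flat
    plateau at an extremum contributes a single extremum at its midpoint
    (deterministic tie-break on flat tops).
    """
    x = np.asarray(x, dtype=float)
    d = np.diff(x)
    # collapse plateaus: consider only nonzero slopes, remember their positions
    nz = np.flatnonzero(d)
    if nz.size < 2:
        return np.array([], dtype=int), np.array([], dtype=int)
    s = np.sign(d[nz])
    turn = np.flatnonzero(s[1:] != s[:-1])
    maxima, minima = [], []
    for t in turn:
        left = nz[t] + 1  # first sample of the plateau (or the peak itself)
        right = nz[t + 1]  # last sample before the next slope
        idx = (left + right) // 2
        (maxima if s[t] > 0 else minima).append(idx)
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def _mirrored(idx: np.ndarray, vals: np.ndarray, n: int, k: int = 2):
    """Extend extrema by reflecting up to ``k`` of them about each signal edge."""
    m = min(k, idx.size)
    pre_i = -idx[:m][::-1]  # reflect about sample 0
    pre_v = vals[:m][::-1]
    post_i = 2 * (n - 1) - idx[-m:][::-1]  # reflect about the last sample
    post_v = vals[-m:][::-1]
    all_i = np.concatenate([pre_i, idx, post_i])
    all_v = np.concatenate([pre_v, vals, post_v])
    order = np.argsort(all_i, kind="stable")
    all_i, all_v = all_i[order], all_v[order]
    keep = np.concatenate(([True], np.diff(all_i) > 0))
    return all_i[keep], all_v[keep]


def spline_mean_envelope(x: np.ndarray, cfg: SiftConfig = SiftConfig()) -> np.ndarray:
    """Mean of the upper and lower cubic-spline envelopes of ``x``.

    The upper envelope interpolates the local maxima and the lower the local
    minima, both extended past the edges by mirroring extrema about the end
    samples.  Raises :class:`MonotoneSignalError` when there are fewer than
    two maxima or two minima, which is the caller's signal to stop
    decomposing.
    """
    x = np.asarray(x, dtype=float)
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise MonotoneSignalError(
            f"need >= 2 maxima and >= 2 minima, found {maxima.size} and {minima.size}"
        )
    n = x.size
    mi, mv = _mirrored(maxima, x[maxima], n)
    upper = CubicSpline(mi, mv)(np.arange(n))
    ni, nv = _mirrored(minima, x[minima], n)
    lower = CubicSpline(ni, nv)(np.arange(n))
    return (upper + lower) / 2.0


def check_imf(x: np.ndarray, cfg: SiftConfig = SiftConfig()) -> ImfCheck:
    """Test the two IMF criteria and report diagnostics.

    Passes iff |#extrema - #zero-crossings| <= 1 and the spline mean envelope
    stays within 5% of the signal's amplitude range.  Degenerate signals with
    too few extrema for an envelope (including the zero signal) pass on the
    count criterion alone.
    """
    x = np.asarray(x, dtype=float)
    maxima, minima = find_extrema(x)
    n_ext = maxima.size + minima.size
    sgn = np.sign(x[x != 0])
    n_zc = int(np.count_nonzero(sgn[1:] != sgn[:-1])) if sgn.size > 1 else 0
    count_ok = abs(n_ext - n_zc) <= 1
    rng = float(np.ptp(x))
    try:
        m = spline_mean_envelope(x, cfg)
        env_max = float(np.max(np.abs(m)))
        mean_ok = rng == 0 or env_max <= 0.05 * rng
    except MonotoneSignalError:
        env_max = float("nan")
        mean_ok = True  # criterion vacuous without envelopes
    return ImfCheck(
        passed=bool(count_ok and mean_ok),
        n_extrema=n_ext,
        n_zero_crossings=n_zc,
        envelope_mean_max=env_max,
    )


def sift_imf(
    x: np.ndarray, cfg: SiftConfig = SiftConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Extract one IMF from ``x`` by sifting; returns ``(imf, residual)``.

    Iterates d <- d - mean_envelope(d) until the IMF criteria hold and the
    SD stopping criterion is met (or the iteration cap is reached).  The
    identity ``x == imf + residual`` holds exactly by construction.
    """
    x = np.asarray(x, dtype=float)
    d = x
    for iteration in range(cfg.max_sift_iterations):
        try:
            m = spline_mean_envelope(d, cfg)
        except MonotoneSignalError:
            if iteration == 0:
                raise
            break
        d_prev = d
        d = d - m
        denom = float(np.sum(d_prev * d_prev))
        sd = float(np.sum(m * m)) / denom if denom > 0 else 0.0
        if sd < cfg.sd_threshold and check_imf(d, cfg).passed:
            break
    return d, x - d


def decompose(
    x: np.ndarray, levels: int = 3, cfg: SiftConfig = SiftConfig()
) -> EmdResult:
    """Full decomposition into at most ``levels - 1`` IMFs plus a residual.

    Sifting restarts on each successive residual and stops early once a
    residual is monotone or constant.  Degenerate inputs yield zero IMFs and
    ``residual == x``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    imfs: list[np.ndarray] = []
    residual = x.copy()
    for _ in range(levels - 1):
        try:
            imf, residual = sift_imf(residual, cfg)
        except MonotoneSignalError:
            break
        imfs.append(imf)
    return EmdResult(imfs=tuple(imfs), residual=residual, levels=levels)


def first_imf(x: np.ndarray, cfg: SiftConfig = SiftConfig(), levels: int = 3) -> np.ndarray:
    """First (fastest) IMF of ``x``; monotone inputs pass through unchanged.

    The passthrough emits a warning rather than an error so that degenerate
    stretches of signal do not abort a batch pipeline.
    """
    result = decompose(x, levels=levels, cfg=cfg)
    if result.imfs:
        return result.imfs[0]
    import warnings

    warnings.warn(
        "signal is monotone or constant; returning it unchanged", stacklevel=2
    )
    return np.asarray(x, dtype=float).copy()
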