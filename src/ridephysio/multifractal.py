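"""Direct estimation of the multifractal singularity spectrum.

The estimator computes, for each moment order q and box size eps, the
normalized q-weighted box measures

    mu_i(q, eps) = P_i(eps)^q / sum_j P_j(eps)^q

and obtains the Holder exponents ``alpha(q)`` and singularity dimensions
``f(q)`` as ordinary-least-squares slopes of

    sum_i mu_i log2 P_i   vs  log2 eps      -> alpha(q)
    sum_i mu_i log2 mu_i  vs  log2 eps      -> f(q)

across dyadic scales, avoiding a Legendre transform.  The spectrum width is
``max_q alpha(q) - min_q alpha(q)``.

For a time series, the box measure is built from absolute first differences
(local fluctuation mass); an already-normalized measure (e.g. a cascade) can
be passed through directly.  All q-power sums are evaluated in the log
domain with max-subtraction so extreme q never overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MFConfig",
    "MFSpectrum",
    "build_measure",
    "chhabra_jensen",
    "spectrum_width",
    "binomial_alpha",
    "binomial_f",
]


class DegenerateSeriesError(ValueError):
    """Raised when a series carries no fluctuation mass (all-constant)."""


def _default_q_grid(qmin: float = -5.0, qmax: float = 5.0, step: float = 0.25) -> np.ndarray:
    n = int(round((qmax - qmin) / step)) + 1
    return np.round(np.linspace(qmin, qmax, n), 10)


@dataclass
class MFConfig:
    """Moment orders, box sizes and regression-quality floor.

    ``scales`` are box sizes in samples; when None a dyadic ladder from 8
    samples up to N/8 is derived from the data length.  ``min_r2`` is
    diagnostic only: per-q regressions are reported, never censored.
    """

    q_grid: np.ndarray = field(default_factory=_default_q_grid)
    scales: list[int] | None = None
    min_r2: float = 0.9

    def __post_init__(self) -> None:
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        if not np.any(np.isclose(self.q_grid, 0.0)) or not np.any(
            np.isclose(self.q_grid, 1.0)
        ):
            raise ValueError("q_grid must contain q=0 and q=1")
        if not np.all(np.diff(self.q_grid) > 0):
            raise ValueError("q_grid must be strictly increasing")

    def resolve_scales(self, n: int) -> list[int]:
        if self.scales is not None:
            scales = sorted(int(s) for s in self.scales)
            if any(s < 1 for s in scales):
                raise ValueError("scales must be >= 1 sample")
        else:
            scales = []
            s = 8
            while n // s >= 8:
                scales.append(s)
                s *= 2
        usable = [s for s in scales if n // s >= 8]
        if len(usable) < 3:
            raise ValueError(
                f"fewer than 3 usable scales for length {n}: {usable}"
            )
        return usable


@dataclass
class MFSpectrum:
    """Estimated singularity spectrum with per-q regression diagnostics."""

    q_grid: np.ndarray
    alpha: np.ndarray
    f: np.ndarray
    r2_alpha: np.ndarray
    r2_f: np.ndarray
    scales: list[int]

    @property
    def width(self) -> float:
        return float(np.max(self.alpha) - np.min(self.alpha))


def build_measure(series: np.ndarray, scale: int, *, is_measure: bool = False) -> np.ndarray:
    """Box probabilities P_i(scale) of a series (or of a given measure).

    Series mode sums absolute first differences per box and normalizes; a
    trailing partial box is discarded.  Measure mode sums the given
    nonnegative cells per box.  Zero-mass boxes are retained here (callers
    drop them from q-sums).
    """
    x = np.asarray(series, dtype=float)
    if is_measure:
        mass = x
        if np.any(mass < 0):
            raise ValueError("measure cells must be nonnegative")
    else:
        mass = np.abs(np.diff(x))
    n_boxes = mass.size // scale
    if n_boxes < 1:
        raise ValueError(f"series too short for scale {scale}")
    total = mass[: n_boxes * scale].reshape(n_boxes, scale).sum(axis=1)
    s = total.sum()
    if s <= 0:
        raise DegenerateSeriesError("series has zero total fluctuation mass")
    return total / s


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and R^2 of y ~ x by ordinary least squares."""
    xm = x - x.mean()
    ym = y - y.mean()
    sxx = float(xm @ xm)
    slope = float(xm @ ym) / sxx
    ss_res = float(((ym - slope * xm) ** 2).sum())
    ss_tot = float(ym @ ym)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, r2

def chhabra_jensen(
    series: np.ndarray,
    config: MFConfig | None = None,
    *,
    is_measure: bool = False,
) -> MFSpectrum:
    """Estimate alpha(q), f(q) and the spectrum width of a series or measure.

    Raises :class:`DegenerateSeriesError` for constant input and ValueError
    when fewer than 3 scales are usable.
    """
    if config is None:
        config = MFConfig()
    x = np.asarray(series, dtype=float)
    n_mass = x.size if is_measure else x.size - 1
    scales = config.resolve_scales(n_mass)
    # truncate to the largest length divisible by the maximal scale
    max_scale = max(scales)
    usable = (n_mass // max_scale) * max_scale
    if not is_measure:
        x = x[: usable + 1]
    else:
        x = x[:usable]

    q = config.q_grid
    log2_eps = np.log2(np.asarray(scales, dtype=float))
    num_alpha = np.empty((q.size, len(scales)))
    num_f = np.empty((q.size, len(scales)))
    for j, eps in enumerate(scales):
        P = build_measure(x, eps, is_measure=is_measure)
        P = P[P > 0]  # zero-mass boxes carry no mu and blow up for q<0
        logP = np.log2(P)
        # log-domain q-weights with max-subtraction: mu = P^q / sum P^q
        w = q[:, None] * logP[None, :]
        w -= w.max(axis=1, keepdims=True)
        mu = np.exp2(w)
        mu /= mu.sum(axis=1, keepdims=True)
        num_alpha[:, j] = mu @ logP
        with np.errstate(divide="ignore", invalid="ignore"):
            log_mu = np.where(mu > 0, np.log2(np.where(mu > 0, mu, 1.0)), 0.0)
        num_f[:, j] = np.sum(mu * log_mu, axis=1)

    alpha = np.empty(q.size)
    f = np.empty(q.size)
    r2_a = np.empty(q.size)
    r2_f = np.empty(q.size)
    for i in range(q.size):
        alpha[i], r2_a[i] = _ols_slope(log2_eps, num_alpha[i])
        f[i], r2_f[i] = _ols_slope(log2_eps, num_f[i])
    return MFSpectrum(q_grid=q, alpha=alpha, f=f, r2_alpha=r2_a, r2_f=r2_f, scales=scales)


def spectrum_width(spec: MFSpectrum) -> float:
    """Width (max alpha - min alpha) of an estimated spectrum; >= 0."""
    w = spec.width
    if not np.isfinite(w):
        raise ValueError("degenerate spectrum: width undefined")
    return w


def binomial_alpha(q: np.ndarray, p: float) -> np.ndarray:
    """Closed-form alpha(q) of the two-scale binomial cascade."""
    q = np.asarray(q, dtype=float)
    pq = p ** q
    rq = (1 - p) ** q
    return -(pq * np.log(p) + rq * np.log(1 - p)) / ((pq + rq) * np.log(2))


def binomial_f(q: np.ndarray, p: float) -> np.ndarray:
    """Closed-form f(q) of the two-scale binomial cascade."""
    q = np.asarray(q, dtype=float)
    return q * binomial_alpha(q, p) + np.log2(p ** q + (1 - p) ** q)
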