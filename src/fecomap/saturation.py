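"""Novel-partner accumulation (rarefaction) curve with resampling and
logarithmic extrapolation.

Seeds are sampled one at a time without replacement in random order while the
cumulative number of distinct partners is recorded; the random order is
redrawn ``n_resamples`` times (default 50) and the curve summarised by its
mean and standard deviation per step. A logarithmic model y = a*ln(1 + b*t)
(which forces y(0) = 0) is least-squares fitted to the mean curve and
extrapolated to a target population size -- e.g. the full ~150-neuron sensory
organ -- to judge how complete a partial reconstruction's partner catalogue
is. The alternative form y = a*ln(t) + c is available by flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Set

import numpy as np
from scipy.optimize import curve_fit

from .core import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SaturationCurve:
    """Cumulative distinct-partner counts across resampled seed orders."""

    t: np.ndarray  # step 1..n
    mean: np.ndarray
    sd: np.ndarray
    curves: np.ndarray  # (n_resamples, n) per-resample cumulative counts
    n_resamples: int
    rng_seed: int


def novel_partner_curve(
    partner_sets: Mapping[str, Set[str]],
    n_resamples: int = 50,
    rng_seed: int = 0,
) -> SaturationCurve:
    """Rarefaction curve of distinct partners over random seed orderings.

    Every seed must have a defined (possibly empty) partner set. A single
    master seed spawns one RNG stream per resample, so individual resamples
    are reproducible independently of how many are drawn.
    """
    seeds = list(partner_sets)
    if not seeds:
        raise ValidationError("no seed neurons given")
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")
    n = len(seeds)
    streams = np.random.SeedSequence(rng_seed).spawn(n_resamples)
    curves = np.zeros((n_resamples, n), dtype=int)
    for r, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        order = rng.permutation(n)
        seen: set[str] = set()
        for step, idx in enumerate(order):
            seen |= set(partner_sets[seeds[idx]])
            curves[r, step] = len(seen)
    mean = curves.mean(axis=0)
    sd = curves.std(axis=0)  # population s.d. across resamples
    return SaturationCurve(
        np.arange(1, n + 1), mean, sd, curves, n_resamples, rng_seed
    )


@dataclass
class LogFit:
    """Fitted logarithmic saturation model and its extrapolation."""

    form: str
    a: float
    b: float  # slope parameter for "shifted"; offset c for "offset"
    target_n: int
    prediction: float
    fitted: np.ndarray
    residuals: np.ndarray
    degenerate: bool = False

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.form == "shifted":
            return self.a * np.log1p(self.b * t)
        return self.a * np.log(t) + self.b


def _shifted_log(t, a, b):
    return a * np.log1p(b * t)


def _offset_log(t, a, c):
    return a * np.log(t) + c


def fit_log_extrapolate(
    curve: SaturationCurve,
    target_n: int,
    form: str = "shifted",
) -> LogFit:
    """Fit the logarithmic model to the mean curve and extrapolate.

    A flat curve cannot be represented by a*ln(1+b*t) except in the b -> 0
    limit and is flagged as a degenerate fit (the prediction falls back to
    the terminal value). Non-convergence raises with diagnostics.
    """
    t = curve.t.astype(float)
    y = curve.mean.astype(float)
    if len(t) < 3:
        raise ValidationError("need at least 3 curve points to fit")
    if np.ptp(y) == 0:
        logger.warning("constant accumulation curve; logarithmic fit is degenerate")
        fitted = np.full_like(y, y[-1])
        return LogFit(
            form, float("nan"), 0.0, target_n, float(y[-1]), fitted, y - fitted, True
        )
    if form == "shifted":
        fn = _shifted_log
        p0 = (max(y[-1], 1.0) / np.log1p(t[-1]), 1.0)
        bounds = ((0.0, 1e-12), (np.inf, np.inf))
    elif form == "offset":
        fn = _offset_log
        p0 = (max(y[-1], 1.0) / np.log(t[-1] + 1), 0.0)
        bounds = ((-np.inf, -np.inf), (np.inf, np.inf))
    else:
        raise ValidationError(f"unknown fit form {form!r}")
    try:
        params, _ = curve_fit(fn, t, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as err:  # pragma: no cover - diagnostics path
        raise ValidationError(
            f"logarithmic fit did not converge (n={len(t)}, y_max={y.max():g}): {err}"
        ) from err
    a, b = float(params[0]), float(params[1])
    fitted = fn(t, a, b)
    fit = LogFit(form, a, b, target_n, float(fn(target_n, a, b)), fitted, y - fitted)
    fit.degenerate = form == "shifted" and b < 1e-8
    if fit.degenerate:
        logger.warning("fitted b ~ 0; curve is effectively linear over the range")
    return fit


class LogSaturationModel:
    """Estimator-style wrapper: fit(t, y), then predict(t).

    Exists so the saturation fit composes like the other stages; parameters
    are exposed as ``a_`` and ``b_`` after fitting.
    """

    def __init__(self, form: str = "shifted"):
        self.form = form

    def get_params(self, deep: bool = True) -> dict:
        return {"form": self.form}

    def set_params(self, **params) -> "LogSaturationModel":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, t, y):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        curve = SaturationCurve(t, y, np.zeros_like(y), y[None, :], 1, 0)
        fit = fit_log_extrapolate(curve, int(t[-1]), self.form)
        self.a_ = fit.a
        self.b_ = fit.b
        self.degenerate_ = fit.degenerate
        self._fit = fit
        return self

    def predict(self, t) -> np.ndarray:
        return self._fit.predict(t)
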