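"""Per-pixel forward models for the two time-domain contrast mechanisms.

In a time-resolved multimodal scan the inter-pulse delay is swept and the
demodulated signal recorded at each delay.  Two trace shapes occur:

* **Stimulated Raman scattering (SRS)** — a coherent process that exists only
  while pump and Stokes pulses overlap, so the trace is the pulse
  cross-correlation: a sharp Gaussian peak centred at zero delay.
* **Pump-probe (pigment) response** — absorbers such as melanin produce a
  transient-absorption component that decays on the sub-picosecond scale plus
  a photothermal plateau that persists for the whole scan.  Eumelanin-like
  pigment gives a positive trace, pheomelanin-like pigment a negative one.

The decay model is a single exponential plus a constant plateau, optionally
convolved with a Gaussian instrument response; this is the minimal form that
reproduces a fast decay settling onto a constant level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SRSParams",
    "PumpProbeParams",
    "DecayFit",
    "NoDecayError",
    "srs_response",
    "pump_probe_response",
    "fit_pump_probe_decay",
    "classify_pigment_sign",
]


class NoDecayError(ValueError):
    """Raised when a trace has no measurable decay (flat within the noise floor)."""


@dataclass(frozen=True)
class SRSParams:
    """Gaussian cross-correlation peak of the SRS channel.

    amplitude : peak signal (a.u., >= 0)
    t0        : peak delay (ps)
    width     : Gaussian sigma of the pulse cross-correlation (ps, > 0)
    """

    amplitude: float
    t0: float = 0.0
    width: float = 0.25

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")

    def to_dict(self) -> dict:
        return {"kind": "srs", **asdict(self)}


@dataclass(frozen=True)
class PumpProbeParams:
    """Exponential-decay-plus-plateau pump-probe response of pigment.

    a_ta      : transient-absorption amplitude (a.u., >= 0)
    tau       : decay constant (ps, > 0)
    a_pt      : photothermal plateau amplitude (a.u., >= 0)
    sign      : +1 eumelanin-like (positive trace), -1 pheomelanin-like
    t0        : onset delay (ps); stage zero-delay by default
    irf_width : Gaussian instrument-response sigma (ps, >= 0; 0 = ideal)
    """

    a_ta: float
    tau: float
    a_pt: float = 0.0
    sign: int = 1
    t0: float = 0.0
    irf_width: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.sign not in (+1, -1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")
        if self.a_ta < 0 or self.a_pt < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.a_ta + self.a_pt <= 0:
            raise ValueError("a_ta + a_pt must be > 0")
        if self.irf_width < 0:
            raise ValueError("irf_width must be >= 0")

    def to_dict(self) -> dict:
        return {"kind": "pump_probe", **asdict(self)}


@dataclass(frozen=True)
class DecayFit:
    """Result of a pump-probe decay fit: estimates plus fit diagnostics."""

    params: PumpProbeParams
    residual_norm: float
    converged: bool

    def __post_init__(self) -> None:
        if self.residual_norm < 0:
            raise ValueError("residual_norm must be >= 0")


def _check_delays(delays: np.ndarray) -> np.ndarray:
    delays = np.asarray(delays, dtype=float)
    if delays.ndim != 1 or delays.size == 0:
        raise ValueError("delay axis must be a non-empty 1-D vector")
    if not np.all(np.isfinite(delays)):
        raise ValueError("delay axis must be finite")
    if delays.size > 1 and not np.all(np.diff(delays) > 0):
        raise ValueError("delay axis must be strictly increasing")
    return delays


def srs_response(delays: np.ndarray, p: SRSParams) -> np.ndarray:
    """Gaussian SRS trace ``amplitude * exp(-(t - t0)^2 / (2 width^2))``."""
    t = _check_delays(delays)
    return p.amplitude * np.exp(-((t - p.t0) ** 2) / (2.0 * p.width**2))


def pump_probe_response(delays: np.ndarray, p: PumpProbeParams) -> np.ndarray:
    """Pump-probe trace: step onset at ``t0``, exponential decay onto a plateau.

    With ``irf_width == 0`` the trace is
    ``sign * (a_ta * exp(-(t - t0)/tau) + a_pt)`` for ``t >= t0`` and zero
    before the onset.  With a finite instrument response the same base signal
    is convolved with a unit-area Gaussian of sigma ``irf_width``; the
    convolution is evaluated in closed form (erfc), so the integral of the
    trace is preserved exactly.
    """
    t = _check_delays(delays) - p.t0
    base = np.where(t >= 0, p.a_ta * np.exp(np.minimum(-t / p.tau, 0.0)) + p.a_pt, 0.0)
    if p.irf_width == 0.0:
        return p.sign * base
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
        raise ValueError("IRF convolution requires a uniformly spaced delay axis")
    step = float(dt[0])
    radius = max(int(math.ceil(6.0 * p.irf_width / step)), 1)
    k = np.arange(-radius, radius + 1) * step
    kernel = np.exp(-(k * k) / (2.0 * p.irf_width**2))
    kernel /= kernel.sum()  # unit discrete sum: convolution preserves sum(signal)
    padded = np.pad(base, radius, mode="edge")
    return p.sign * np.convolve(padded, kernel, mode="valid")


def classify_pigment_sign(
    signal: np.ndarray,
    delays: np.ndarray | None = None,
    t0: float = 0.0,
    floor: float = 0.0,
) -> str:
    """Classify a pigment trace as ``"positive"`` (eumelanin-like) or
    ``"negative"`` (pheomelanin-like) from its post-onset integrated signal.

    Returns ``"indeterminate"`` when the magnitude of the integral is at or
    below ``floor``.  Used to pre-route pixels before phasor gating, because a
    signed trace makes the normalised phasor coordinates unstable.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size < 2:
        raise ValueError("signal must have length >= 2")
    if delays is None:
        integral = float(signal.sum())
    else:
        t = _check_delays(delays)
        post = t >= t0
        if post.sum() < 2:
            raise ValueError("fewer than 2 samples after onset")
        integral = float(np.trapezoid(signal[post], t[post]))
    if abs(integral) <= floor:
        return "indeterminate"
    return "positive" if integral > 0 else "negative"


def fit_pump_probe_decay(
    signal: np.ndarray,
    delays: np.ndarray,
    t0: float = 0.0,
    noise_floor: float = 1e-12,
    residual_threshold: float = 0.25,
) -> DecayFit:
    """Nonlinear least-squares fit of the decay-plus-plateau model to a trace.

    The sign is fixed from the post-onset mean before optimisation (a free
    sign creates a flip degeneracy).  Initialisation is deterministic: the
    plateau from the last samples, the decay amplitude from the first
    post-onset sample, and tau from the time at which the trace reaches 1/e
    of the peak-to-plateau excursion.  ``converged`` is False when the
    relative residual exceeds ``residual_threshold``.

    Raises
    ------
    NoDecayError
        If the post-onset dynamic range is at or below ``noise_floor``.
    """
    t = _check_delays(delays)
    y = np.asarray(signal, dtype=float)
    if y.shape != t.shape:
        raise ValueError("signal and delays must have the same length")
    if t.size < 8:
        raise ValueError("need at least 8 samples to fit a decay")

    post = t >= t0
    if post.sum() < 4:
        raise ValueError("need at least 4 post-onset samples")
    yp, tp = y[post], t[post]
    dyn = float(yp.max() - yp.min())
    if dyn <= noise_floor or abs(yp).max() <= noise_floor:
        raise NoDecayError("flat signal: dynamic range below the noise floor")
    sign = 1 if float(yp.mean()) >= 0 else -1
    w = sign * yp  # work on the positive-going trace

    # deterministic initial guess
    n_tail = max(2, tp.size // 10)
    plateau0 = max(float(w[-n_tail:].mean()), 0.0)
    peak0 = float(w.max())
    a_ta0 = max(peak0 - plateau0, noise_floor)
    excursion = peak0 - plateau0
    target = plateau0 + excursion / math.e
    below = np.nonzero(w <= target)[0]
    i_peak = int(np.argmax(w))
    after = below[below > i_peak]
    tau0 = float(tp[after[0]] - tp[i_peak]) if after.size else float(tp[-1] - tp[0]) / 4.0
    tau0 = max(tau0, float(np.diff(tp).min()))

    def resid(theta: np.ndarray) -> np.ndarray:
        a_ta, tau, a_pt = theta
        model = np.where(t - t0 >= 0, a_ta * np.exp(np.minimum(-(t - t0) / tau, 0.0)) + a_pt, 0.0)
        return model - sign * y

    sol = least_squares(
        resid,
        x0=np.array([a_ta0, tau0, plateau0]),
        bounds=([0.0, 1e-6, 0.0], [np.inf, np.inf, np.inf]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    a_ta, tau, a_pt = (float(v) for v in sol.x)
    residual_norm = float(np.linalg.norm(sol.fun))
    rel = residual_norm / max(float(np.linalg.norm(y)), noise_floor)
    converged = bool(sol.success) and rel <= residual_threshold
    params = PumpProbeParams(
        a_ta=max(a_ta, 0.0), tau=tau, a_pt=max(a_pt, 0.0), sign=sign, t0=t0, irf_width=0.0
    )
    return DecayFit(params=params, residual_norm=residual_norm, converged=converged)
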