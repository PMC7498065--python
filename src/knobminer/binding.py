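"""Single-cycle kinetics simulation/fitting, 4PL dose-response and Ki.

Single-cycle kinetics (SCK) injects an ascending concentration series over
the same surface without regeneration; under a 1:1 Langmuir model each
constant-concentration segment has the closed form

    R(t) = Req + (R0 - Req) * exp(-(kon*C + koff) * t),
    Req  = kon * C * Rmax / (kon * C + koff),

with C = 0 during dissociation.  Fitting recovers (kon, koff, Rmax) by
multi-start nonlinear least squares and reports KD = koff/kon, flagging
dissociation rates below the 1.0e-5 1/s instrument determination limit.

Steady-state FRET titrations are fitted with a four-parameter logistic
(4PL); competition IC50 values convert to inhibition constants with the
Cheng-Prusoff relation Ki = IC50 / (1 + [R]/KD), where [R] is the labelled
partner concentration (assays run at [R] = KDapp halve the IC50).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

KOFF_DETERMINATION_LIMIT = 1.0e-5   # 1/s
HILL_EXPECTED_RANGE = (0.5, 2.0)


@dataclass(frozen=True)
class KineticsModel:
    kon: float       # 1/(M s)
    koff: float      # 1/s
    rmax: float      # RU

    def __post_init__(self):
        if min(self.kon, self.koff, self.rmax) <= 0:
            raise ValueError("kon, koff and Rmax must be positive")

    @property
    def kd(self) -> float:
        return self.koff / self.kon


@dataclass(frozen=True)
class InjectionProtocol:
    concentrations: tuple[float, ...]   # M, strictly ascending
    contact_time: float = 230.0         # s
    final_dissociation_time: float = 1800.0   # s
    inter_injection_gap: float = 0.0    # s
    sampling_rate: float = 1.0          # Hz

    def __post_init__(self):
        c = self.concentrations
        if not c or any(x <= 0 for x in c) or list(c) != sorted(set(c)):
            raise ValueError("concentrations must be positive and strictly "
                             "ascending")
        if min(self.contact_time, self.final_dissociation_time,
               self.sampling_rate) <= 0 or self.inter_injection_gap < 0:
            raise ValueError("invalid protocol times")

    @property
    def segments(self) -> list[tuple[float, float]]:
        """(concentration, duration) pairs in execution order."""
        segs = []
        for i, c in enumerate(self.concentrations):
            segs.append((c, self.contact_time))
            if self.inter_injection_gap and i < len(self.concentrations) - 1:
                segs.append((0.0, self.inter_injection_gap))
        segs.append((0.0, self.final_dissociation_time))
        return segs

    @property
    def total_time(self) -> float:
        return sum(d for _, d in self.segments)


@dataclass(frozen=True)
class Sensorgram:
    time: np.ndarray        # s, strictly increasing
    response: np.ndarray    # RU
    protocol: InjectionProtocol


def make_sck_protocol(top_conc: float = 1e-6, n_injections: int = 7,
                      dilution: float = 3.0, **kwargs) -> InjectionProtocol:
    """Ascending series top/dilution^(n-1) ... top (defaults: 1 uM with six
    3-fold dilutions, i.e. down to 1.37 nM)."""
    if top_conc <= 0 or n_injections < 1 or dilution <= 1:
        raise ValueError("invalid protocol parameters")
    conc = tuple(top_conc / dilution ** (n_injections - 1 - i)
                 for i in range(n_injections))
    return InjectionProtocol(concentrations=conc, **kwargs)


PEPTIDE_PROTOCOL = make_sck_protocol()                       # 1800 s dissociation
FUSION_PROTOCOL = make_sck_protocol(final_dissociation_time=10_000.0)


def _model_response(times: np.ndarray, model: KineticsModel,
                    protocol: InjectionProtocol) -> np.ndarray:
    """Closed-form piecewise 1:1 Langmuir response on an arbitrary grid."""
    response = np.empty_like(times, dtype=float)
    r0 = 0.0
    t0 = 0.0
    for conc, duration in protocol.segments:
        k_obs = model.kon * conc + model.koff
        req = model.kon * conc * model.rmax / k_obs if conc > 0 else 0.0
        mask = (times >= t0) & (times < t0 + duration)
        response[mask] = req + (r0 - req) * np.exp(-k_obs * (times[mask] - t0))
        r0 = req + (r0 - req) * np.exp(-k_obs * duration)
        t0 += duration
    response[times >= t0] = r0
    return response


def simulate_sck(model: KineticsModel, protocol: InjectionProtocol,
                 noise_sd: float = 0.0, seed: int = 0) -> Sensorgram:
    """Simulate a reference-subtracted single-cycle sensorgram."""
    n = int(np.floor(protocol.total_time * protocol.sampling_rate)) + 1
    times = np.arange(n) / protocol.sampling_rate
    response = _model_response(times, model, protocol)
    if noise_sd > 0:
        response = response + np.random.default_rng(seed).normal(
            0.0, noise_sd, size=response.shape)
    return Sensorgram(time=times, response=response, protocol=protocol)


@dataclass(frozen=True)
class SckFit:
    model: KineticsModel | None
    kd: float | None
    rss: float
    standard_errors: dict = field(default_factory=dict)
    koff_below_limit: bool = False
    success: bool = True
    message: str = ""


def fit_sck(sensorgram: Sensorgram,
            protocol: InjectionProtocol | None = None,
            log_kon_grid: tuple[float, ...] = (3.0, 5.0, 7.0),
            log_koff_grid: tuple[float, ...] = (-5.0, -3.0, -1.0)) -> SckFit:
    """Fit (kon, koff, Rmax) to a sensorgram by multi-start least squares.

    Parameters are fitted in log10 space over a grid of association- and
    dissociation-rate starting points; ties are broken by lowest residual
    then lowest koff.  Non-finite residuals yield a failure report, not an
    exception.
    """
    protocol = protocol or sensorgram.protocol
    t, y = sensorgram.time, sensorgram.response
    rmax0 = max(float(np.max(y)), 1e-6)

    def residuals(theta: np.ndarray) -> np.ndarray:
        theta = np.clip(theta, -100.0, 100.0)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            model = KineticsModel(10.0 ** theta[0], 10.0 ** theta[1],
                                  10.0 ** theta[2])
            return _model_response(t, model, protocol) - y

    best = None
    for lk in log_kon_grid:
        for lo in log_koff_grid:
            try:
                sol = least_squares(residuals,
                                    x0=np.array([lk, lo, np.log10(rmax0)]),
                                    method="lm", xtol=1e-14, ftol=1e-14)
            except Exception:
                continue
            if not np.all(np.isfinite(sol.fun)):
                continue
            rss = float(np.sum(sol.fun ** 2))
            key = (rss, sol.x[1])
            if best is None or key < best[0]:
                best = (key, sol)
    if best is None:
        return SckFit(model=None, kd=None, rss=float("inf"), success=False,
                      message="all starts produced non-finite residuals")
    sol = best[1]
    model = KineticsModel(10.0 ** sol.x[0], 10.0 ** sol.x[1], 10.0 ** sol.x[2])
    rss = float(np.sum(sol.fun ** 2))
    dof = max(len(y) - 3, 1)
    sigma2 = rss / dof
    try:
        cov = sigma2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se_log = np.sqrt(np.diag(cov))
        ln10 = np.log(10.0)
        ses = {"kon": model.kon * ln10 * se_log[0],
               "koff": model.koff * ln10 * se_log[1],
               "rmax": model.rmax * ln10 * se_log[2]}
    except np.linalg.LinAlgError:
        ses = {}
    return SckFit(model=model, kd=model.kd, rss=rss, standard_errors=ses,
                  koff_below_limit=model.koff < KOFF_DETERMINATION_LIMIT)


# --------------------------------------------------------------------------
# 4PL dose-response and Cheng-Prusoff
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FretFit:
    bottom: float
    top: float
    midpoint: float     # M; KDapp for saturation, IC50 for competition
    hill: float
    hill_in_range: bool
    r_conc: float | None = None
    ki: float | None = None


def four_pl(x: np.ndarray, bottom: float, top: float, midpoint: float,
            hill: float) -> np.ndarray:
    """y = bottom + (top - bottom) / (1 + (x/midpoint)^(-hill)).

    Positive Hill slopes describe saturation; negative slopes inhibition.
    At x = midpoint the response is (top + bottom) / 2.
    """
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / midpoint) ** (-hill))


def subtract_background(y: np.ndarray, background_wells: np.ndarray,
                        ) -> np.ndarray:
    """Subtract the mean of designated background wells (e.g. signal at
    quenching concentrations of unlabelled competitor)."""
    return np.asarray(y, dtype=float) - float(np.mean(background_wells))


def fit_4pl(x, y) -> FretFit:
    """Fit a four-parameter logistic to a dose-response series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 points spanning the midpoint")
    if np.all(x == x[0]):
        raise ValueError("degenerate concentration series")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")

    def model(xv, bottom, top, log_mid, hill):
        return four_pl(xv, bottom, top, 10.0 ** log_mid, hill)

    mid0 = np.log10(np.exp(np.mean(np.log(x))))
    best = None
    for hill0 in (1.0, -1.0):
        try:
            popt, _ = curve_fit(model, x, y,
                                p0=[float(np.min(y)), float(np.max(y)),
                                    mid0, hill0],
                                maxfev=20000)
        except RuntimeError:
            continue
        rss = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise RuntimeError("4PL fit did not converge")
    bottom, top, log_mid, hill = best[1]
    if top < bottom:
        # canonical orientation: top is the high-signal asymptote
        bottom, top, hill = top, bottom, -hill
    lo, hi = HILL_EXPECTED_RANGE
    return FretFit(bottom=float(bottom), top=float(top),
                   midpoint=float(10.0 ** log_mid), hill=float(hill),
                   hill_in_range=bool(lo <= abs(hill) <= hi))


def cheng_prusoff(ic50: float, r_conc: float, kd_app: float) -> float:
    """Ki = IC50 / (1 + [R]/KDapp)."""
    if kd_app <= 0:
        raise ValueError("KDapp must be positive")
    if ic50 <= 0 or r_conc < 0:
        raise ValueError("IC50 must be positive and [R] non-negative")
    return ic50 / (1.0 + r_conc / kd_app)
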