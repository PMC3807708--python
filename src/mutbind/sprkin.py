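"""Surface-plasmon-resonance kinetics: the 1:1 Langmuir-with-drift model.

A pseudo-first-order bimolecular binding model with a linear baseline drift.
During association at analyte concentration C the bound response follows

    R(t) = Req (1 - exp(-(ka C + kd) t)),   Req = ka C Rmax / (ka C + kd),

and after the analyte is removed the dissociation decays as
R_end exp(-kd (t - t_assoc)). The instrument drift is modeled as a single
linear slope per curve, continuous across the phase boundary. Double
referencing subtracts the uncoated-interspot and reference-channel signals
before fitting. The fit shares ka, kd and Rmax globally across a
concentration series (one drift per curve) by nonlinear least squares.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "KineticParams",
    "Sensorgram",
    "FitResult",
    "simulate_sensorgram",
    "double_reference",
    "fit_langmuir_drift",
    "sensorgram_to_csv",
    "sensorgrams_from_csv",
]

DEFAULT_T_ASSOC = 90.0    # s
DEFAULT_T_DISSOC = 600.0  # s
DEFAULT_DT = 0.1          # s


@dataclass
class KineticParams:
    ka: float               # 1/(M s)
    kd_rate: float          # 1/s
    Rmax: float             # RU
    drift: float = 0.0      # RU/s
    R0: float = 0.0         # RU at phase start

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.kd_rate <= 0 or self.Rmax <= 0:
            raise ValueError("ka, kd_rate and Rmax must be positive")

    @property
    def Kd(self) -> float:
        return self.kd_rate / self.ka


@dataclass
class Sensorgram:
    time: np.ndarray
    response: np.ndarray
    phase: np.ndarray            # 'association' / 'dissociation' per point
    analyte_concentration: float # M
    channel: str = "active"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.phase = np.asarray(self.phase)
        if len(self.time) != len(self.response) or len(self.time) != len(self.phase):
            raise ValueError("time/response/phase length mismatch")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def t_assoc_end(self) -> float:
        assoc = self.time[self.phase == "association"]
        return float(assoc[-1]) if len(assoc) else 0.0


def _binding_curve(t, t_assoc, ka, kd, Rmax, C):
    """Bound-analyte response (drift-free part), continuous at t_assoc."""
    kobs = ka * C + kd
    req = ka * C * Rmax / kobs if kobs > 0 else 0.0
    assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc)))
    r_end = req * (1.0 - math.exp(-kobs * t_assoc))
    dissoc = r_end * np.exp(-kd * np.maximum(t - t_assoc, 0.0))
    return np.where(t <= t_assoc, assoc, dissoc)


def simulate_sensorgram(
    p: KineticParams,
    concentration: float,
    t_assoc: float = DEFAULT_T_ASSOC,
    t_dissoc: float = DEFAULT_T_DISSOC,
    dt: float = DEFAULT_DT,
    noise_sd: float = 0.0,
    seed: int | None = None,
    channel: str = "active",
) -> Sensorgram:
    """Simulate one Langmuir-with-drift sensorgram at ``concentration``.

    Defaults mirror a typical SPR protocol: 90 s association followed by
    10 min dissociation. Gaussian noise of sd ``noise_sd`` RU is added
    reproducibly for a given seed.
    """
    if t_assoc <= 0 or t_dissoc <= 0:
        raise ValueError("phase durations must be positive")
    if dt <= 0 or dt >= min(t_assoc, t_dissoc):
        raise ValueError("dt must be positive and smaller than each phase duration")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    t = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    binding = _binding_curve(t, t_assoc, p.ka, p.kd_rate, p.Rmax, concentration)
    response = binding + p.drift * t + p.R0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        response = response + rng.normal(0.0, noise_sd, size=t.shape)
    phase = np.where(t <= t_assoc, "association", "dissociation")
    return Sensorgram(
        time=t,
        response=response,
        phase=phase,
        analyte_concentration=concentration,
        channel=channel,
        meta={"t_assoc": t_assoc, "noise_sd": noise_sd, "seed": seed},
    )


def _resample(sg: Sensorgram, t: np.ndarray) -> np.ndarray:
    if t[0] < sg.time[0] - 1e-9 or t[-1] > sg.time[-1] + 1e-9:
        raise ValueError("channels do not overlap in time; cannot reference")
    return np.interp(t, sg.time, sg.response)


def double_reference(
    active: Sensorgram,
    reference_channel: Sensorgram,
    interspot: Sensorgram,
    reference_interspot: Sensorgram | None = None,
) -> Sensorgram:
    """Double referencing: corrected = active - interspot -
    (reference - reference's interspot). Removes bulk refractive-index and
    nonspecific-binding contributions. Channels on different grids are
    linearly resampled onto the active grid.
    """
    t = active.time
    inter = _resample(interspot, t)
    ref = _resample(reference_channel, t)
    ref_inter = _resample(reference_interspot, t) if reference_interspot is not None else inter
    corrected = active.response - inter - (ref - ref_inter)
    meta = dict(active.meta)
    meta["double_referenced"] = True
    return Sensorgram(
        time=t,
        response=corrected,
        phase=active.phase,
        analyte_concentration=active.analyte_concentration,
        channel="corrected",
        meta=meta,
    )


@dataclass
class FitResult:
    ka: float
    kd_rate: float
    Rmax: float
    drift: list[float]         # per curve, RU/s
    Kd: float
    residual_rms: float
    stderr: dict[str, float]
    converged: bool
    n_points: int = 0

    def to_json(self, path=None) -> str:
        payload = {
            "ka_per_M_s": self.ka,
            "kd_per_s": self.kd_rate,
            "Rmax_RU": self.Rmax,
            "drift_RU_s": self.drift,
            "Kd_M": self.Kd,
            "residual_rms_RU": self.residual_rms,
            "stderr": self.stderr,
            "converged": self.converged,
            "n_points": self.n_points,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _initial_guess(curves) -> tuple[float, float, float]:
    """Heuristic starting point: kd from log-linear dissociation tails,
    ka from the regression of observed rates on concentration."""
    kd_estimates = []
    for sg in curves:
        mask = sg.phase == "dissociation"
        t, r = sg.time[mask], sg.response[mask]
        if len(t) < 5:
            continue
        # use the earlier part of the decay where signal is well above noise
        r0 = r[0]
        keep = r > max(0.05 * abs(r0), 1e-12)
        if keep.sum() < 5:
            continue
        slope = np.polyfit(t[keep], np.log(np.abs(r[keep]) + 1e-12), 1)[0]
        if slope < 0:
            kd_estimates.append(-slope)
    kd0 = float(np.median(kd_estimates)) if kd_estimates else 1e-2

    kobs, concs, plateaus = [], [], []
    for sg in curves:
        if sg.analyte_concentration <= 0:
            continue
        mask = sg.phase == "association"
        t, r = sg.time[mask], sg.response[mask]
        plateau = np.percentile(r, 95)
        plateaus.append(plateau)
        target = 0.632 * plateau
        above = np.nonzero(r >= target)[0]
        if len(above) and above[0] > 0:
            kobs.append(1.0 / t[above[0]])
            concs.append(sg.analyte_concentration)
    if len(concs) >= 2:
        ka0 = max(np.polyfit(concs, kobs, 1)[0], 1e2)
    elif concs:
        ka0 = max((kobs[0] - kd0) / concs[0], 1e2)
    else:
        ka0 = 1e5
    rmax0 = max(plateaus) * 1.2 if plateaus else 100.0
    return float(ka0), float(kd0), float(max(rmax0, 1e-6))


def fit_langmuir_drift(
    curves,
    shared: bool = True,
    n_starts: int = 5,
    seed: int = 0,
    max_nfev: int = 2000,
) -> FitResult:
    """Global nonlinear least-squares fit of a concentration series.

    ka, kd and Rmax are shared across all curves; each curve gets its own
    drift slope. Multi-start initialization (log-uniform jitter around a
    data-derived guess) guards against local minima. Standard errors come
    from the Jacobian at the optimum. ``shared=False`` fits each curve
    independently and returns the fit of the concatenated single-curve
    results' best curve set — use it only for diagnostics.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to fit")
    if len({sg.analyte_concentration for sg in curves}) < 2:
        warnings.warn(
            "fitting a single concentration: ka and Rmax are weakly identifiable",
            stacklevel=2,
        )
    if not shared:
        return [fit_langmuir_drift([sg], shared=True, n_starts=n_starts, seed=seed)
                for sg in curves]

    t_list = [sg.time for sg in curves]
    r_list = [sg.response for sg in curves]
    ta_list = [sg.t_assoc_end for sg in curves]
    c_list = [sg.analyte_concentration for sg in curves]
    n_curves = len(curves)
    n_points = sum(len(t) for t in t_list)

    def residuals(x):
        ka, kd, rmax = np.exp(x[0]), np.exp(x[1]), np.exp(x[2])
        drifts = x[3:]
        res = []
        for t, r, ta, c, drift in zip(t_list, r_list, ta_list, c_list, drifts):
            model = _binding_curve(t, ta, ka, kd, rmax, c) + drift * t
            res.append(model - r)
        return np.concatenate(res)

    ka0, kd0, rmax0 = _initial_guess(curves)
    base = np.concatenate([[math.log(ka0), math.log(kd0), math.log(rmax0)],
                           np.zeros(n_curves)])
    rng = np.random.default_rng(seed)
    starts = [base]
    for _ in range(n_starts - 1):
        jitter = np.concatenate([rng.uniform(-math.log(10), math.log(10), 3),
                                 np.zeros(n_curves)])
        starts.append(base + jitter)

    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                residuals, x0, method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
                max_nfev=max_nfev,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-18 * n_points:
            break
    if best is None:
        raise RuntimeError(
            f"Langmuir-with-drift fit failed to converge from {n_starts} starts "
            f"({n_curves} curves, {n_points} points)"
        )

    ka, kd, rmax = np.exp(best.x[0]), np.exp(best.x[1]), np.exp(best.x[2])
    drifts = list(map(float, best.x[3:]))
    rms = float(np.sqrt(2 * best.cost / n_points))

    # standard errors from the Jacobian; delta method for the log parameters
    stderr: dict[str, float] = {}
    try:
        jac = best.jac
        n_par = jac.shape[1]
        dof = max(n_points - n_par, 1)
        s2 = 2 * best.cost / dof
        cov = s2 * np.linalg.inv(jac.T @ jac)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        stderr = {
            "ka": float(ka * se[0]),
            "kd_rate": float(kd * se[1]),
            "Rmax": float(rmax * se[2]),
        }
        for i in range(n_curves):
            stderr[f"drift_{i}"] = float(se[3 + i])
    except np.linalg.LinAlgError:
        stderr = {}

    return FitResult(
        ka=float(ka),
        kd_rate=float(kd),
        Rmax=float(rmax),
        drift=drifts,
        Kd=float(kd / ka),
        residual_rms=rms,
        stderr=stderr,
        converged=bool(best.success),
        n_points=n_points,
    )


# ---------------------------------------------------------------------------
# CSV I/O


def sensorgram_to_csv(sensorgrams, path) -> None:
    """Write sensorgrams as CSV: time_s, response_RU, phase,
    concentration_M, channel."""
    if isinstance(sensorgrams, Sensorgram):
        sensorgrams = [sensorgrams]
    with open(path, "w") as fh:
        fh.write("time_s,response_RU,phase,concentration_M,channel\n")
        for sg in sensorgrams:
            conc = float(sg.analyte_concentration)
            for t, r, ph in zip(sg.time, sg.response, sg.phase):
                fh.write(f"{float(t)!r},{float(r)!r},{ph},{conc!r},{sg.channel}\n")


def sensorgrams_from_csv(path) -> list[Sensorgram]:
    import pandas as pd

    df = pd.read_csv(path)
    required = ["time_s", "response_RU", "phase", "concentration_M", "channel"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out = []
    for (conc, channel), grp in df.groupby(["concentration_M", "channel"], sort=True):
        grp = grp.sort_values("time_s")
        out.append(
            Sensorgram(
                time=grp["time_s"].to_numpy(),
                response=grp["response_RU"].to_numpy(),
                phase=grp["phase"].to_numpy(),
                analyte_concentration=float(conc),
                channel=str(channel),
            )
        )
    return out
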