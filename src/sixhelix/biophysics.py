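"""SEC molecular-weight calibration and circular-dichroism melt analysis.

Size-exclusion side: the gel-phase distribution coefficient
Kav = (Ve - Vo) / (Vc - Vo) is linear in log10(MW) over the separation range
of a column; fitting standards gives a calibration line whose inverse turns an
elution volume into an apparent molecular weight, and dividing by the monomer
mass gives the oligomeric state.

CD side: raw ellipticity (mdeg) is converted to mean residue ellipticity
theta_MRE = (MW / (N - 1)) * (theta / (10 d c)) with pathlength d in cm and
concentration c in mg/mL; thermal melts are normalized to fraction unfolded in
[0, 1] and fitted to a sum of logistic transitions

    y(T) = sum_p f_p / (1 + exp((Tm_p - T) / k_p)),   sum f_p = 1,

by multi-start nonlinear least squares. A biphasic fit falls back to a single
transition when the second amplitude is not supported (F-test, alpha = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SecStandard:
    name: str
    mw: float          # Da
    ve: float          # mL

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("MW must be positive")


@dataclass
class SecCalibration:
    slope: float
    intercept: float
    r_squared: float
    vo: float
    vc: float


def compute_kav(ve: float, vo: float, vc: float) -> float:
    """Gel-phase distribution coefficient (Ve - Vo) / (Vc - Vo)."""
    if vc <= vo:
        raise ValueError("total column volume must exceed void volume")
    if ve < vo:
        raise ValueError("elution volume before the void volume")
    return (ve - vo) / (vc - vo)


def fit_calibration(standards: list[SecStandard], vo: float, vc: float) -> SecCalibration:
    """Least-squares line of Kav versus log10(MW) through >= 3 standards."""
    if len(standards) < 3:
        raise ValueError("need at least 3 standards")
    logmw = np.log10([s.mw for s in standards])
    if np.ptp(logmw) < 1e-12:
        raise ValueError("standards must span distinct molecular weights")
    kav = np.array([compute_kav(s.ve, vo, vc) for s in standards])
    res = stats.linregress(logmw, kav)
    return SecCalibration(slope=float(res.slope), intercept=float(res.intercept),
                          r_squared=float(res.rvalue**2), vo=vo, vc=vc)


def estimate_mw(kav: float, calibration: SecCalibration) -> float:
    """Invert the calibration line: MW = 10 ** ((Kav - intercept) / slope)."""
    if calibration.slope == 0:
        raise ValueError("degenerate calibration (zero slope)")
    return float(10.0 ** ((kav - calibration.intercept) / calibration.slope))


def infer_oligomer(apparent_mw: float, monomer_mw: float) -> tuple[int, float]:
    """Nearest-integer stoichiometry and the raw apparent/monomer ratio."""
    if apparent_mw <= 0 or monomer_mw <= 0:
        raise ValueError("molecular weights must be positive")
    ratio = apparent_mw / monomer_mw
    return int(round(ratio)), ratio


def mre_convert(theta_mdeg: float, mw: float, n_residues: int,
                pathlength_cm: float, conc_mg_ml: float) -> float:
    """Mean residue ellipticity (deg cm^2 dmol^-1) from raw ellipticity (mdeg)."""
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if mw <= 0 or pathlength_cm <= 0 or conc_mg_ml <= 0:
        raise ValueError("MW, pathlength and concentration must be positive")
    return (mw / (n_residues - 1)) * (theta_mdeg / (10.0 * pathlength_cm * conc_mg_ml))


@dataclass
class MeltCurve:
    temperatures: np.ndarray   # degC, strictly increasing
    signal: np.ndarray         # mdeg or normalized fraction unfolded
    ph: float | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, float)
        self.signal = np.asarray(self.signal, float)
        if self.temperatures.shape != self.signal.shape:
            raise ValueError("temperature and signal vectors differ in length")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class MeltFit:
    tm: list[float]
    amplitudes: list[float]
    slopes: list[float]
    stderr: dict[str, float | None]
    redchi: float
    n_phases: int
    ph: float | None = None


def normalize_melt(curve: MeltCurve) -> MeltCurve:
    """Affine map of the signal to [0, 1] with the folded baseline at 0.

    The folded baseline is the mean signal of the two lowest temperatures and
    the unfolded baseline the mean of the two highest - endpoint averages are
    unbiased under noise, unlike the global min/max. If the raw trace
    decreases on unfolding the map flips sign so 1 means unfolded.
    """
    y = curve.signal
    lo = float(np.mean(y[:2]))
    hi = float(np.mean(y[-2:]))
    if abs(hi - lo) < 1e-12 or np.ptp(y) < 1e-12:
        raise ValueError("constant signal cannot be normalized")
    norm = (y - lo) / (hi - lo)
    if norm[0] > norm[-1]:
        norm = 1.0 - norm
    return MeltCurve(curve.temperatures.copy(), norm, ph=curve.ph)


def _melt_model(t: np.ndarray, tms, slopes, fracs) -> np.ndarray:
    y = np.zeros_like(t, dtype=float)
    for tm, k, f in zip(tms, slopes, fracs):
        y += f / (1.0 + np.exp((tm - t) / k))
    return y


def fit_melt(curve: MeltCurve, phases: int = 2,
             reduce_if_insignificant: bool = True,
             alpha: float = 0.05) -> MeltFit:
    """Fit a normalized melt to a sum of 1 or 2 logistic transitions with
    amplitudes summing to 1; multi-start initialization over the temperature
    range; parameter standard errors from the covariance of the best fit."""
    t, y = curve.temperatures, curve.signal
    if len(t) < 8:
        raise ValueError("need at least 8 temperature points")
    if t[-1] - t[0] < 40:
        raise ValueError("melt must span at least 40 degC")
    if np.ptp(y) < 1e-3:
        raise ValueError("flat curve: no transition to fit")
    if phases not in (1, 2):
        raise ValueError("phases must be 1 or 2")

    def run(n_phases: int) -> lmfit.minimizer.MinimizerResult | None:
        grid = np.linspace(t[0] + 5, t[-1] - 5, 4)
        starts = ([(a,) for a in grid] if n_phases == 1
                  else [(a, b) for a in grid for b in grid if b > a + 5])
        best = None
        for tms0 in starts:
            params = lmfit.Parameters()
            for p in range(n_phases):
                params.add(f"tm{p}", value=tms0[p], min=t[0], max=t[-1])
                # transitions steeper than ~1 degC are unresolvable on a
                # 5 degC grid and would overfit single noisy points
                params.add(f"k{p}", value=2.0, min=1.0, max=30.0)
            if n_phases == 2:
                params.add("f0", value=0.5, min=0.0, max=1.0)

            def resid(params, n=n_phases):
                tms = [params[f"tm{p}"].value for p in range(n)]
                ks = [params[f"k{p}"].value for p in range(n)]
                fs = [params["f0"].value, 1 - params["f0"].value] if n == 2 else [1.0]
                return _melt_model(t, tms, ks, fs) - y

            try:
                out = lmfit.minimize(resid, params, method="leastsq")
            except Exception:
                continue
            if best is None or out.chisqr < best.chisqr:
                best = out
        return best

    best = run(phases)
    if best is None:
        raise RuntimeError("melt fit failed to converge from all starts")
    n_used = phases
    if phases == 2 and reduce_if_insignificant:
        single = run(1)
        f0 = best.params["f0"].value
        f0_err = best.params["f0"].stderr
        dtm = abs(best.params["tm0"].value - best.params["tm1"].value)
        minor = min(f0, 1 - f0)
        weak_amp = minor < 0.1 or (f0_err is not None and minor < 2.0 * f0_err)
        if single is not None and (weak_amp or dtm < 5.0):
            # second amplitude indistinguishable from zero, or transitions
            # closer than the temperature grid resolves: not a real transition
            best, n_used = single, 1
        elif single is not None:
            # F-test: does the 2nd transition significantly reduce chi^2?
            df2 = len(t) - 5
            df1 = len(t) - 2
            if best.chisqr <= 0 or df2 <= 0:
                f_p = 0.0
            else:
                f_stat = ((single.chisqr - best.chisqr) / (df1 - df2)) / (
                    best.chisqr / df2
                )
                f_p = 1.0 - stats.f.cdf(max(f_stat, 0.0), df1 - df2, df2)
            if f_p > alpha:
                best, n_used = single, 1

    p = best.params
    tms = [p[f"tm{i}"].value for i in range(n_used)]
    ks = [p[f"k{i}"].value for i in range(n_used)]
    fs = [p["f0"].value, 1 - p["f0"].value] if n_used == 2 else [1.0]
    order = np.argsort(tms)
    stderr = {name: (p[name].stderr if p[name].stderr is not None else None)
              for name in p}
    return MeltFit(
        tm=[float(tms[i]) for i in order],
        amplitudes=[float(fs[i]) for i in order],
        slopes=[float(ks[i]) for i in order],
        stderr=stderr,
        redchi=float(best.redchi),
        n_phases=n_used,
        ph=curve.ph,
    )


def tm_vs_ph(fits: list[MeltFit]) -> pd.DataFrame:
    """Sorted (pH, Tm, stderr) table for the dominant transition of each fit,
    with the max-min Tm spread attached as DataFrame attrs."""
    if len(fits) < 2:
        raise ValueError("need melts at >= 2 pH values")
    rows = []
    for fit in fits:
        if fit.ph is None:
            raise ValueError("every fit needs a pH label")
        i = int(np.argmax(fit.amplitudes))
        rows.append({"ph": fit.ph, "tm": fit.tm[i],
                     "stderr": fit.stderr.get(f"tm{i}")})
    df = pd.DataFrame(rows).sort_values("ph").reset_index(drop=True)
    df.attrs["tm_spread"] = float(df["tm"].max() - df["tm"].min())
    return df
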