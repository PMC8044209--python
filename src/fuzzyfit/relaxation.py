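"""Per-residue T1/T2 relaxation fitting and exchange-lifetime bounds.

Intensities from an interleaved relaxation series are fitted per residue to a
single exponential I(t) = I0·exp(−t/T) with no baseline offset.  The T1/T2
ratio profile (an approximate reporter of molecular tumbling time, hence of
time spent in the larger bound complex) carries first-order propagated errors

    σ_r = r · sqrt((σ1/T1)² + (σ2/T2)²)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

# delays (ms) as used for the disordered-activator datasets
T1_DELAYS_MS = np.array([10.0, 40.0, 80.0, 120.0, 160.0, 320.0, 640.0, 1000.0])
T2_DELAYS_MS = np.array([8.48, 16.96, 25.44, 33.92, 42.40, 50.88, 59.36, 67.84])


@dataclass
class RelaxationSeries:
    """Intensity decays: strictly increasing delays (ms) × residues."""

    delays: np.ndarray
    intensities: pd.DataFrame  # index residue_index, one column per delay
    kind: str  # "T1" | "T2"

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, float)
        if len(self.delays) < 4 or np.any(np.diff(self.delays) <= 0):
            raise ValueError("need >= 4 strictly increasing delays")
        if self.kind not in ("T1", "T2"):
            raise ValueError("kind must be 'T1' or 'T2'")
        df = pd.DataFrame(self.intensities)
        if df.shape[1] != len(self.delays):
            raise ValueError("intensity columns must match delays")
        # residues with incomplete decays are excluded up front
        self.intensities = df.dropna(axis=0)


@dataclass
class RelaxationFit:
    """Per-residue (I0, T, stderr) with non-convergent residues flagged."""

    table: pd.DataFrame  # index residue_index: I0, T_ms, T_stderr_ms, flagged
    kind: str

    def residues(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def good(self) -> pd.DataFrame:
        return self.table[~self.table["flagged"]]


def _decay(t, i0, T):
    return i0 * np.exp(-t / T)


def fit_exponential_decay(series: RelaxationSeries, max_T_factor: float = 100.0) -> RelaxationFit:
    """Two-parameter (I0, T) nonlinear least squares per residue.

    Standard errors come from the covariance of the fit.  Residues whose
    fitted T is non-positive, absurdly long (> ``max_T_factor`` × the longest
    delay, i.e. no measurable decay) or whose fit fails are flagged and later
    excluded from ratio profiles.
    """
    t = series.delays
    rows = {}
    t_cap = max_T_factor * t.max()
    for ridx, y in series.intensities.iterrows():
        y = y.to_numpy(float)
        i0_init = float(y[0]) if y[0] > 0 else float(np.max(np.abs(y)) or 1.0)
        # log-linear initial guess where intensities are positive
        pos = y > 0
        if pos.sum() >= 2:
            slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
            T_init = -1.0 / slope if slope < 0 else t_cap
        else:
            T_init = t.max()
        T_init = float(np.clip(T_init, t.min() / 10, t_cap))
        flagged, T_hat, T_err, i0_hat = False, np.nan, np.nan, np.nan
        try:
            popt, pcov = curve_fit(_decay, t, y, p0=[i0_init, T_init], maxfev=5000)
            i0_hat, T_hat = float(popt[0]), float(popt[1])
            T_err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.inf
            if not (0 < T_hat < t_cap) or not np.isfinite(T_err):
                flagged = True
        except (RuntimeError, ValueError):
            flagged = True
        rows[ridx] = (i0_hat, T_hat, T_err, flagged)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["I0", "T_ms", "T_stderr_ms", "flagged"])
    table.index.name = "residue_index"
    return RelaxationFit(table=table.sort_index(), kind=series.kind)


def relaxation_ratio_profile(t1: RelaxationFit, t2: RelaxationFit,
                             max_rel_err: float = 0.5) -> pd.DataFrame:
    """T1/T2 per shared residue with first-order propagated error.

    Residues flagged in either fit, or with relative stderr above
    ``max_rel_err`` in either T, are excluded.
    """
    a, b = t1.good(), t2.good()
    a = a[a["T_stderr_ms"] / a["T_ms"] <= max_rel_err]
    b = b[b["T_stderr_ms"] / b["T_ms"] <= max_rel_err]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared residues between T1 and T2 fits")
    r = a.loc[shared, "T_ms"] / b.loc[shared, "T_ms"]
    err = r * np.sqrt((a.loc[shared, "T_stderr_ms"] / a.loc[shared, "T_ms"]) ** 2
                      + (b.loc[shared, "T_stderr_ms"] / b.loc[shared, "T_ms"]) ** 2)
    out = pd.DataFrame({"residue_index": shared, "t1_over_t2": r.to_numpy(),
                        "t1_over_t2_err": err.to_numpy()})
    return out.sort_values("residue_index").reset_index(drop=True)


def bound_lifetime_upper(kex_lower: float) -> float:
    """Upper bound (ms) on the bound-state lifetime under fast exchange.

    With an exchange rate of at least ``kex_lower`` s⁻¹ the bound state can
    live no longer than 1/kex; returned in milliseconds.
    """
    if not kex_lower > 0:
        raise ValueError("exchange rate must be positive")
    return 1000.0 / kex_lower
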