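"""Chemical-shift perturbations, fast-exchange titration tracking and binding fits.

The combined amide CSP scales the ¹⁵N dimension by 1/5:

    Δδ_NH = sqrt(Δδ_H² + (Δδ_N / 5)²)

with signed components taken as (free − bound).  The Cα/Cβ CSP is

    Δδ_CaCb = 0.25 × [(Cα − Cβ)_free − (Cα − Cβ)_bound]

Fraction saturation of a labeled species A in the presence of total ligand B
comes from the exact quadratic solution of the single-site equilibrium,

    C = A + B + Kd,   [AB] = (C − sqrt(C² − 4·A·B)) / 2,   sat = [AB] / A

which is the only root satisfying 0 ≤ [AB] ≤ min(A, B).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from .nmr_io import PeakList, ShiftTable

HETERO_SCALE = 5.0  # ¹⁵N (and ¹³C, for trajectory matching only) divisor


@dataclass
class CSPProfile:
    """Per-residue chemical-shift-perturbation magnitudes between two states.

    ``data`` columns: residue_index, residue_type, csp and the signed
    components (delta_h/delta_x for NH; delta_cacb for CaCb).  ``omitted``
    lists residues present in only one input.
    """

    data: pd.DataFrame
    kind: str  # "NH" | "CaCb"
    omitted: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("NH", "CaCb"):
            raise ValueError("kind must be 'NH' or 'CaCb'")
        if (self.data["csp"] < 0).any():
            raise ValueError("csp must be >= 0")

    def __len__(self) -> int:
        return len(self.data)


def csp_amide(free: PeakList, bound: PeakList) -> CSPProfile:
    """Combined amide CSP between a free and a bound HN-N peak list."""
    f = free.data[free.data["atom_pair"] == "HN-N"].set_index("residue_index")
    b = bound.data[bound.data["atom_pair"] == "HN-N"].set_index("residue_index")
    if len(f) == 0 or len(b) == 0:
        raise ValueError("both peak lists must contain HN-N peaks")
    shared = f.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared residues between free and bound lists")
    omitted = sorted(f.index.symmetric_difference(b.index))
    dh = f.loc[shared, "shift1"] - b.loc[shared, "shift1"]
    dn = f.loc[shared, "shift2"] - b.loc[shared, "shift2"]
    csp = np.sqrt(dh**2 + (dn / HETERO_SCALE) ** 2)
    out = pd.DataFrame({
        "residue_index": shared,
        "residue_type": f.loc[shared, "residue_type"].to_numpy(),
        "csp": csp.to_numpy(),
        "delta_h": dh.to_numpy(),
        "delta_x": dn.to_numpy(),
    }).sort_values("residue_index").reset_index(drop=True)
    return CSPProfile(out, kind="NH", omitted=omitted)


def csp_cacb(free: ShiftTable, bound: ShiftTable) -> CSPProfile:
    """Scaled Cα−Cβ CSP; the signed component is stored, csp is its magnitude."""
    f, b = free.pivot(), bound.pivot()
    f = f.dropna(subset=["CA", "CB"])
    b = b.dropna(subset=["CA", "CB"])
    shared = f.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no residue with complete CA/CB in both states")
    delta = 0.25 * ((f.loc[shared, "CA"] - f.loc[shared, "CB"])
                    - (b.loc[shared, "CA"] - b.loc[shared, "CB"]))
    out = pd.DataFrame({
        "residue_index": shared,
        "residue_type": f.loc[shared, "residue_type"].to_numpy(),
        "csp": np.abs(delta.to_numpy()),
        "delta_cacb": delta.to_numpy(),
    }).sort_values("residue_index").reset_index(drop=True)
    omitted = sorted(f.index.symmetric_difference(b.index))
    return CSPProfile(out, kind="CaCb", omitted=omitted)


# ---------------------------------------------------------------------------
# Quadratic single-site equilibrium

def fraction_saturation(a_total, b_total, kd) -> float:
    """Fraction of species A bound, from the physical quadratic root.

    Parameters are total concentrations in μM.  Returns [AB]/A_total, which
    lies in [0, min(1, B/A)].
    """
    a = np.asarray(a_total, float)
    b = np.asarray(b_total, float)
    k = np.asarray(kd, float)
    if np.any(a <= 0) or np.any(b < 0) or np.any(k < 0):
        raise ValueError("require A_total > 0, B_total >= 0, Kd >= 0")
    c = a + b + k
    disc = np.maximum(c * c - 4.0 * a * b, 0.0)
    ab = 0.5 * (c - np.sqrt(disc))
    out = ab / a
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Titration series and fast-exchange tracking

@dataclass
class TitrationSeries:
    """Ordered titration points at constant labeled-species concentration."""

    points: list  # list of (ligand_total_uM, labeled_total_uM, PeakList)
    labeled_species: str = ""

    def __post_init__(self) -> None:
        lig = [p[0] for p in self.points]
        lab = [p[1] for p in self.points]
        if any(np.diff(lig) <= 0):
            raise ValueError("ligand_total must be strictly increasing")
        if len(set(np.round(lab, 9))) > 1:
            raise ValueError("labeled_total must be constant across points")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def labeled_total(self) -> float:
        return float(self.points[0][1])

    @property
    def ligand_totals(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], float)


def track_fast_exchange(series: TitrationSeries, jump_ceiling: float = 0.05) -> pd.DataFrame:
    """Link peaks across titration points by nearest neighbour in scaled ppm space.

    The matching metric is Euclidean distance in (¹H, X/5) ppm, with a per-step
    ``jump_ceiling`` (scaled ppm).  Assignments are taken from the first point
    only; later points are matched geometrically.  A point with no candidate
    within the ceiling is flagged ``unmatched``; a point with two candidates
    within the ceiling is flagged ``ambiguous`` and the peak is not guessed.

    Returns a long table: residue_index, ligand_total, shift1, shift2, flag.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 titration points")
    first = series.points[0][2].data
    rows = []
    # current position per (residue, atom_pair), in raw ppm
    current = {
        (r.residue_index, r.atom_pair): (r.shift1, r.shift2)
        for r in first.itertuples()
    }
    lost: set = set()
    for r in first.itertuples():
        rows.append((r.residue_index, r.atom_pair, series.points[0][0], r.shift1, r.shift2, "ok"))
    for lig, _lab, peaks in series.points[1:]:
        for pair, sub in peaks.data.groupby("atom_pair"):
            cand = sub[["shift1", "shift2"]].to_numpy()
            scaled = cand / np.array([1.0, HETERO_SCALE])
            for (ridx, rpair), (s1, s2) in current.items():
                if rpair != pair or (ridx, rpair) in lost:
                    continue
                here = np.array([s1, s2 / HETERO_SCALE])
                d = np.linalg.norm(scaled - here, axis=1)
                within = np.flatnonzero(d <= jump_ceiling)
                if len(within) == 0:
                    rows.append((ridx, rpair, lig, np.nan, np.nan, "unmatched"))
                    lost.add((ridx, rpair))
                elif len(within) > 1:
                    rows.append((ridx, rpair, lig, np.nan, np.nan, "ambiguous"))
                    lost.add((ridx, rpair))
                else:
                    j = within[0]
                    current[(ridx, rpair)] = (cand[j, 0], cand[j, 1])
                    rows.append((ridx, rpair, lig, cand[j, 0], cand[j, 1], "ok"))
    out = pd.DataFrame(rows, columns=["residue_index", "atom_pair", "ligand_total",
                                      "shift1", "shift2", "flag"])
    return out.sort_values(["residue_index", "ligand_total"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# One-site FP binding model (statsmodels-style Model / Results pair)

def _fp_model(x, bmax, kd, ns, background):
    return bmax * x / (kd + x) + ns * x + background


@dataclass
class BindingFit:
    """Fitted one-site parameters with standard errors."""

    kd: float
    bmax: float
    ns: float
    background: float
    kd_stderr: float
    bmax_stderr: float
    ns_stderr: float
    background_stderr: float
    model: str  # "fp_one_site" | "csp_quadratic"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError("Kd must be > 0")
        for e in (self.kd_stderr, self.bmax_stderr, self.ns_stderr, self.background_stderr):
            if e < 0:
                raise ValueError("standard errors must be >= 0")

    def predict(self, x):
        x = np.asarray(x, float)
        return _fp_model(x, self.bmax, self.kd, self.ns, self.background)

    def summary(self) -> str:
        lines = [f"{self.model} fit",
                 f"  Kd         = {self.kd:.4g} ± {self.kd_stderr:.2g} μM",
                 f"  Bmax       = {self.bmax:.4g} ± {self.bmax_stderr:.2g}",
                 f"  NS         = {self.ns:.4g} ± {self.ns_stderr:.2g} per μM",
                 f"  Background = {self.background:.4g} ± {self.background_stderr:.2g}"]
        for k, v in self.extras.items():
            if np.isscalar(v):
                lines.append(f"  {k} = {v}")
        return "\n".join(lines)


class OneSiteFPModel:
    """Total one-site binding model Y = Bmax·X/(Kd + X) + NS·X + Background.

    ``X`` are titrant concentrations (μM), ``Y`` arbitrary polarization units.
    """

    def __init__(self, x, y):
        self.x = np.asarray(x, float)
        self.y = np.asarray(y, float)
        if len(self.x) < 6:
            raise ValueError("need at least 6 titration points")
        if np.any(self.x < 0):
            raise ValueError("X must be >= 0")

    def fit(self) -> BindingFit:
        x, y = self.x, self.y
        params = lmfit.Parameters()
        params.add("bmax", value=float(y.max() - y.min()))
        params.add("kd", value=float(np.median(x[x > 0])) if np.any(x > 0) else 1.0)
        params.add("ns", value=0.0)
        params.add("background", value=float(y.min()))

        def resid(p):
            return _fp_model(x, p["bmax"], p["kd"], p["ns"], p["background"]) - y

        res = lmfit.minimize(resid, params, method="leastsq")
        if not res.success:
            raise RuntimeError("one-site FP fit did not converge")
        if res.params["kd"].value <= 0:
            # refit with log-parameterized Kd to enforce positivity
            params2 = res.params.copy()
            params2.add("log_kd", value=np.log(max(abs(res.params["kd"].value), 1e-6)))
            params2["kd"].set(expr="exp(log_kd)")
            res = lmfit.minimize(resid, params2, method="leastsq")
            if not res.success:
                raise RuntimeError("log-Kd refit did not converge")
        p = res.params

        def err(name):
            s = p[name].stderr
            return float(s) if s is not None and np.isfinite(s) else 0.0

        kd_med = np.median(x[x > 0]) if np.any(x > 0) else np.nan
        kd_hat = float(p["kd"].value)
        if np.isfinite(kd_hat) and (x.max() < kd_hat or x[x > 0].min() > kd_hat):
            import warnings
            warnings.warn("titration does not span the fitted Kd", stacklevel=2)
        return BindingFit(
            kd=kd_hat, bmax=float(p["bmax"].value), ns=float(p["ns"].value),
            background=float(p["background"].value),
            kd_stderr=err("kd"), bmax_stderr=err("bmax"), ns_stderr=err("ns"),
            background_stderr=err("background"), model="fp_one_site",
            extras={"redchi": float(res.redchi), "ndata": int(res.ndata),
                    "median_x": float(kd_med)},
        )


def fit_one_site_fp(x, y) -> BindingFit:
    return OneSiteFPModel(x, y).fit()


# ---------------------------------------------------------------------------
# Shared-Kd global fit of fast-exchange CSP titrations

class CSPTitrationModel:
    """Global fit CSP_i(L) = CSPmax_i · fraction_bound(labeled, L, Kd).

    Fraction bound of the labeled species comes from the quadratic single-site
    equilibrium; Kd is shared across residues, CSPmax is per-residue.
    Residues whose endpoint CSP falls below ``threshold`` (default 3× a median
    trajectory-roughness noise estimate) are excluded.
    """

    def __init__(self, series: TitrationSeries, trajectories: pd.DataFrame | None = None,
                 threshold: float | None = None):
        if len(series) < 4:
            raise ValueError("need at least 4 titration points")
        self.series = series
        self.traj = trajectories if trajectories is not None else track_fast_exchange(series)
        self.threshold = threshold

    def _per_residue_csp(self) -> pd.DataFrame:
        """CSP of each tracked residue at each point, relative to the first point."""
        t = self.traj[self.traj["flag"] == "ok"]
        out = []
        for (ridx, pair), sub in t.groupby(["residue_index", "atom_pair"]):
            sub = sub.sort_values("ligand_total")
            if len(sub) < len(self.series):
                continue  # lost peaks cannot enter the global fit
            dh = sub["shift1"].to_numpy() - sub["shift1"].iloc[0]
            dx = (sub["shift2"].to_numpy() - sub["shift2"].iloc[0]) / HETERO_SCALE
            csp = np.hypot(dh, dx)
            for lig, c in zip(sub["ligand_total"], csp):
                out.append((ridx, pair, lig, c))
        return pd.DataFrame(out, columns=["residue_index", "atom_pair", "ligand_total", "csp"])

    def fit(self, kd_init: float | None = None) -> BindingFit:
        table = self._per_residue_csp()
        if table.empty:
            raise ValueError("no fully tracked residues")
        end = table.groupby("residue_index")["csp"].last()
        if self.threshold is None:
            # noise estimate: median second-difference roughness of trajectories
            rough = []
            for _, sub in table.groupby("residue_index"):
                c = sub.sort_values("ligand_total")["csp"].to_numpy()
                if len(c) >= 3:
                    rough.append(np.median(np.abs(np.diff(c, 2))) / np.sqrt(6))
            noise = max(float(np.median(rough)) if rough else 0.0, 1e-4)
            threshold = 3.0 * noise
        else:
            threshold = self.threshold
        keep = end[end > threshold].index
        if len(keep) < 3:
            raise ValueError("fewer than 3 residues above the CSP threshold")
        table = table[table["residue_index"].isin(keep)]

        a = self.series.labeled_total
        ligs = table["ligand_total"].to_numpy()
        obs = table["csp"].to_numpy()
        ridx = table["residue_index"].to_numpy()
        res_ids = np.unique(ridx)
        pos = {r: i for i, r in enumerate(res_ids)}
        idx = np.array([pos[r] for r in ridx])

        params = lmfit.Parameters()
        params.add("kd", value=float(kd_init or np.median(self.series.ligand_totals[1:])),
                   min=1e-6)
        for r in res_ids:
            params.add(f"cmax_{r}", value=float(end[r]), min=0.0)

        def resid(p):
            fb = fraction_saturation(a, np.maximum(ligs, 0.0), p["kd"].value)
            cmax = np.array([p[f"cmax_{r}"].value for r in res_ids])
            return cmax[idx] * fb - obs

        res = lmfit.minimize(resid, params, method="leastsq")
        if not res.success:
            raise RuntimeError("global CSP fit did not converge")
        p = res.params
        kd_err = p["kd"].stderr
        cmax = {int(r): float(p[f"cmax_{r}"].value) for r in res_ids}
        return BindingFit(
            kd=float(p["kd"].value), bmax=float(max(cmax.values())), ns=0.0, background=0.0,
            kd_stderr=float(kd_err) if kd_err is not None and np.isfinite(kd_err) else 0.0,
            bmax_stderr=0.0, ns_stderr=0.0, background_stderr=0.0,
            model="csp_quadratic",
            extras={"csp_max": cmax, "threshold": threshold, "redchi": float(res.redchi)},
        )


def estimate_kd_from_csp(series: TitrationSeries, trajectories: pd.DataFrame | None = None,
                         threshold: float | None = None) -> BindingFit:
    return CSPTitrationModel(series, trajectories, threshold).fit()
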