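"""Paramagnetic relaxation enhancement (PRE) profiles from intensity pairs.

A nitroxide spin-label bleaches nearby resonances; the observable per residue
is the intensity ratio I_para/I_dia (1 = no PRE, 0 = fully bleached) with the
error propagated from the spectral noise of the two spectra,

    σ_ratio = ratio · sqrt((σ_para/I_para)² + (σ_dia/I_dia)²)

and the pseudo-relaxation rate used as a structural restraint,

    R2* = 1/I_para − 1/I_dia

computed on intensities normalized by the median diamagnetic intensity so the
rate is scale-free (``raw=True`` reproduces the literal unnormalized formula).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .nmr_io import PeakList


@dataclass
class SpinLabelSite:
    """A single-Cys TEMPO attachment site (e.g. mutation T860C)."""

    label_id: str
    attachment_residue: int
    mutation: str = ""
    label_type: str = "TEMPO"


@dataclass
class PREProfile:
    """Per-residue I_para/I_dia ratios, errors and pseudo-R2* for one label site.

    ``data`` columns: residue_index, atom_pair, ratio, ratio_err, r2_star,
    r2_star_err, bleached.  ``saturation`` is the bound fraction of the
    labeled species during the experiment (metadata; ratios are not corrected
    for it).
    """

    data: pd.DataFrame
    label: SpinLabelSite
    saturation: float = 1.0
    normalization: float = field(default=1.0)  # median I_dia used for R2*

    def __post_init__(self) -> None:
        if not 0.0 <= self.saturation <= 1.0:
            raise ValueError("saturation must be in [0, 1]")
        if (self.data["ratio_err"] < 0).any():
            raise ValueError("ratio_err must be >= 0")

    def __len__(self) -> int:
        return len(self.data)

    def unbleached(self) -> pd.DataFrame:
        return self.data[~self.data["bleached"]]


def pre_profile(para: PeakList, dia: PeakList, label: SpinLabelSite,
                saturation: float = 1.0, raw: bool = False) -> PREProfile:
    """PRE intensity-ratio profile from matched paramagnetic/diamagnetic lists.

    Residues whose paramagnetic intensity falls below 3× the spectral noise
    are bleached: the ratio is computed from the noise floor (I_para := 3σ)
    and flagged, which preserves their "strong PRE" rank without infinities
    in R2*.
    """
    p = para.data.set_index(["residue_index", "atom_pair"])
    d = dia.data.set_index(["residue_index", "atom_pair"])
    shared = p.index.intersection(d.index)
    if len(shared) == 0:
        raise ValueError("no matched residues between para and dia lists")
    ip = p.loc[shared, "intensity"].to_numpy(float)
    idia = d.loc[shared, "intensity"].to_numpy(float)
    if np.any(idia <= 0):
        raise ValueError("non-positive diamagnetic intensity")
    sp, sd = float(para.noise_level), float(dia.noise_level)

    bleached = ip < 3.0 * sp
    ip_eff = np.where(bleached, 3.0 * sp, ip)
    ratio = ip_eff / idia
    ratio_err = ratio * np.sqrt((sp / ip_eff) ** 2 + (sd / idia) ** 2)

    scale = 1.0 if raw else float(np.median(idia))
    ipn, idn = ip_eff / scale, idia / scale
    r2 = 1.0 / ipn - 1.0 / idn
    r2_err = np.sqrt((sp / scale / ipn**2) ** 2 + (sd / scale / idn**2) ** 2)

    out = pd.DataFrame({
        "residue_index": [i for i, _ in shared],
        "atom_pair": [a for _, a in shared],
        "ratio": ratio,
        "ratio_err": ratio_err,
        "r2_star": r2,
        "r2_star_err": r2_err,
        "bleached": bleached,
    }).sort_values(["atom_pair", "residue_index"]).reset_index(drop=True)
    return PREProfile(data=out, label=label, saturation=float(saturation),
                      normalization=scale)


def quantile_classes(profile: PREProfile) -> pd.Series:
    """Classify residues by PRE strength: ``top25`` / ``next25`` / ``rest``.

    Residues are ranked by increasing ratio (most affected = smallest ratio);
    the lowest quarter (n // 4 residues) is ``top25``, the next quarter
    ``next25``.  Ties are broken by residue index (lower index ranks as more
    affected).
    """
    df = profile.data
    if len(df) < 4:
        raise ValueError("need at least 4 residues to form quartiles")
    order = df.sort_values(["ratio", "residue_index"], kind="mergesort")
    n = len(order)
    k = n // 4
    labels = np.full(n, "rest", dtype=object)
    labels[:k] = "top25"
    labels[k:2 * k] = "next25"
    out = pd.Series(labels, index=pd.MultiIndex.from_frame(
        order[["residue_index", "atom_pair"]]), name="pre_class")
    return out.sort_index()


def correlate_profiles(p1: PREProfile, p2: PREProfile):
    """Pearson correlation of two PRE ratio profiles over shared residues.

    Bleached residues (in either profile) are excluded.  Returns
    (pearson_r, n, p_value).
    """
    a = p1.unbleached().set_index(["residue_index", "atom_pair"])["ratio"]
    b = p2.unbleached().set_index(["residue_index", "atom_pair"])["ratio"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared unbleached residues")
    r, p = stats.pearsonr(a.loc[shared], b.loc[shared])
    return float(r), int(len(shared)), float(p)
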