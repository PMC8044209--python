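"""Secondary-structure propensity from Cα/Cβ shifts vs. random-coil references.

The per-residue propensity is the deviation of the measured secondary-shift
difference from its sequence-specific random-coil value,

    Δδ(Cα−Cβ) = (Cα − Cβ)_measured − (Cα − Cβ)_random coil

Positive values indicate helical propensity (≈ +4 ppm for fully formed helix),
negative values β-strand.  Random-coil references come from a packaged base
table with nearest-neighbour corrections; see ``data/random_coil_base.tsv``
for provenance and version.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .nmr_io import ShiftTable

FULL_HELIX_PPM = 4.0  # Δδ(Cα−Cβ) of a fully formed helix


def _load(name: str) -> pd.DataFrame:
    with resources.files("fuzzyfit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


@dataclass
class RandomCoilTable:
    """Sequence-specific random-coil Cα/Cβ shifts (neighbour-corrected)."""

    table: pd.DataFrame  # residue_index, residue_type, rc_ca, rc_cb (NaN for Gly)
    temperature: float = 25.0
    ph: float = 6.5

    def __len__(self) -> int:
        return len(self.table)


def random_coil_reference(sequence: str, temperature: float = 25.0, ph: float = 6.5,
                          start_index: int = 1) -> RandomCoilTable:
    """Per-residue random-coil Cα/Cβ for a 1-letter sequence.

    Nearest-neighbour corrections are applied from the packaged coefficient
    table; terminal residues use truncated context (missing neighbours
    contribute nothing).  ``start_index`` sets construct numbering of the
    first residue.
    """
    sequence = sequence.strip().upper()
    if len(sequence) < 3:
        raise ValueError("need at least 3 residues for neighbour context")
    base = _load("random_coil_base.tsv").set_index("residue_type")
    corr = _load("random_coil_neighbors.tsv").set_index("residue_type")
    unknown = sorted(set(sequence) - set(base.index))
    if unknown:
        raise ValueError(f"unknown residue letter(s): {unknown}")

    rows = []
    for i, aa in enumerate(sequence):
        ca = float(base.loc[aa, "rc_ca"])
        cb = float(base.loc[aa, "rc_cb"])
        prev_aa = sequence[i - 1] if i > 0 else None
        next_aa = sequence[i + 1] if i < len(sequence) - 1 else None
        if prev_aa in corr.index:
            ca += float(corr.loc[prev_aa, "prev_ca"])
            cb += float(corr.loc[prev_aa, "prev_cb"])
        if next_aa in corr.index:
            ca += float(corr.loc[next_aa, "next_ca"])
            cb += float(corr.loc[next_aa, "next_cb"])
        rows.append((start_index + i, aa, ca, cb if aa != "G" else np.nan))
    table = pd.DataFrame(rows, columns=["residue_index", "residue_type", "rc_ca", "rc_cb"])
    return RandomCoilTable(table=table, temperature=temperature, ph=ph)


@dataclass
class SSPProfile:
    """Per-residue Δδ(Cα−Cβ) deviation from random coil (ppm)."""

    data: pd.DataFrame  # residue_index, residue_type, delta, helical_fraction

    def __len__(self) -> int:
        return len(self.data)


def ssp_profile(shifts: ShiftTable, rc: RandomCoilTable, smooth: bool = False) -> SSPProfile:
    """Unsmoothed secondary-structure-propensity profile.

    Residues lacking measured CA or CB (including glycines, which have no CB)
    are absent.  ``helical_fraction`` is the annotation delta/4 clipped to
    [−1, 1], from the ~4 ppm full-helix scale.  ``smooth`` applies an optional
    3-residue running mean (off by default).
    """
    wide = shifts.pivot().dropna(subset=["CA", "CB"])
    ref = rc.table.set_index("residue_index").dropna(subset=["rc_ca", "rc_cb"])
    shared = wide.index.intersection(ref.index)
    if len(shared) == 0:
        raise ValueError("no residue overlap between measured shifts and reference")
    delta = ((wide.loc[shared, "CA"] - wide.loc[shared, "CB"])
             - (ref.loc[shared, "rc_ca"] - ref.loc[shared, "rc_cb"]))
    out = pd.DataFrame({
        "residue_index": shared,
        "residue_type": wide.loc[shared, "residue_type"].to_numpy(),
        "delta": delta.to_numpy(),
    }).sort_values("residue_index").reset_index(drop=True)
    if smooth:
        out["delta"] = out["delta"].rolling(3, center=True, min_periods=1).mean()
    out["helical_fraction"] = np.clip(out["delta"] / FULL_HELIX_PPM, -1.0, 1.0)
    return SSPProfile(data=out)
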