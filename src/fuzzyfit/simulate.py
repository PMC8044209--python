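"""Synthetic fuzzy-complex data with known ground truth.

Everything the pipeline consumes can be generated here: a toy helical-bundle
partner with a short helical ligand bound in one or several rigid poses, PRE
intensity pairs per spin-label site, fast-exchange titration peak lists,
mono-exponential relaxation decays and FP titrations.  All generators are
deterministic for a fixed seed, and every simulate_* output fed back to its
analysis counterpart at zero noise recovers the generating parameters.

The default design mirrors a three-site spin-label study of a fuzzy
activator-coactivator complex: 3 label sites flanking the ligand's binding
region, ~60 observable partner residues, per-site saturations (0.9, 0.7, 0.5)
and 5% intensity noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import TitrationSeries, fraction_saturation
from .ensemble import (EnsembleFitConfig, Pose, PREForwardParams,
                       back_calculate_pre, random_surface_pose)
from .nmr_io import PEAK_COLUMNS, PeakList, Structure
from .relaxation import RelaxationSeries
from .pre import SpinLabelSite

DEFAULT_SATURATIONS = (0.9, 0.7, 0.5)
DEFAULT_INTENSITY_NOISE = 0.05

# idealized alpha-helix parameters
_HELIX_RADIUS = 2.3     # Å, CA distance from axis
_HELIX_RISE = 1.5       # Å per residue
_HELIX_TURN = 100.0     # degrees per residue


def ideal_helix(n_res: int, chain: str = "A", start_index: int = 1,
                origin=(0.0, 0.0, 0.0), reverse: bool = False,
                phase_deg: float = 0.0) -> Structure:
    """Idealized poly-alanine α-helix with N, CA, CB, C, O pseudo-backbone.

    CA atoms lie on the canonical helix (2.3 Å radius, 1.5 Å rise, 100°/turn);
    N/C are placed toward the neighbouring CA positions and CB radially
    outward.  Geometry is a toy rigid-body model, not a stereochemically
    refined backbone.
    """
    i = np.arange(n_res)
    theta = np.deg2rad(phase_deg + _HELIX_TURN * i)
    ca = np.stack([_HELIX_RADIUS * np.cos(theta),
                   _HELIX_RADIUS * np.sin(theta),
                   _HELIX_RISE * i], axis=1)
    if reverse:
        ca = ca[::-1] * np.array([1.0, -1.0, -1.0])
        ca[:, 2] -= ca[:, 2].min()
    ca = ca + np.asarray(origin, float)

    axis_xy = np.array(origin[:2], float) if not reverse else ca[:, :2].mean(axis=0)
    rows = []
    serial = 0
    for k in range(n_res):
        prev_dir = ca[k - 1] - ca[k] if k > 0 else ca[k] - ca[k + 1]
        next_dir = ca[k + 1] - ca[k] if k < n_res - 1 else ca[k] - ca[k - 1]
        n_pos = ca[k] + 1.46 * prev_dir / np.linalg.norm(prev_dir)
        c_pos = ca[k] + 1.52 * next_dir / np.linalg.norm(next_dir)
        radial = np.array([ca[k, 0] - axis_xy[0], ca[k, 1] - axis_xy[1], 0.0])
        nrm = np.linalg.norm(radial)
        radial = radial / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
        cb_pos = ca[k] + 1.53 * radial
        o_pos = c_pos + 1.23 * radial
        for name, pos in (("N", n_pos), ("CA", ca[k]), ("CB", cb_pos),
                          ("C", c_pos), ("O", o_pos)):
            serial += 1
            rows.append((serial, name, start_index + k, "A", chain,
                         pos[0], pos[1], pos[2]))
    cols = ["serial", "atom_name", "residue_index", "residue_type", "chain", "x", "y", "z"]
    return Structure(pd.DataFrame(rows, columns=cols), model_count=1, name="ideal_helix")


def make_toy_complex(seed: int, true_n_states: int, partner_size: int = 60):
    """Toy partner bundle + 12-residue ligand helix + true bound poses.

    The partner is a three-helix bundle (an idealized stand-in for a compact
    activator-binding domain with a surface groove); the ligand a short ideal
    helix.  ``true_n_states`` poses are placed on the partner surface with
    mutual centroid separations >= 8 Å.  Deterministic per seed.
    """
    if not 1 <= true_n_states <= 6:
        raise ValueError("true_n_states must lie in [1, 6]")
    per = partner_size // 3
    h1 = ideal_helix(per, chain="A", start_index=1, origin=(0, 0, 0))
    h2 = ideal_helix(per, chain="A", start_index=per + 1, origin=(10.0, 0, 0), reverse=True)
    h3 = ideal_helix(partner_size - 2 * per, chain="A", start_index=2 * per + 1,
                     origin=(5.0, 8.66, 0), phase_deg=180.0)
    atoms = pd.concat([h1.atoms, h2.atoms, h3.atoms], ignore_index=True)
    atoms["serial"] = np.arange(1, len(atoms) + 1)
    partner = Structure(atoms, model_count=1, name="toy_partner")

    ligand = ideal_helix(12, chain="B", start_index=1, origin=(0, 0, 0))
    lig_local = ligand.coords()
    lig_center = lig_local.mean(axis=0)

    rng = np.random.default_rng(seed)
    cfg = EnsembleFitConfig()
    partner_coords = partner.coords()
    poses: list[Pose] = []
    attempts = 0
    while len(poses) < true_n_states:
        attempts += 1
        if attempts > cfg.max_placement_attempts * true_n_states:
            raise RuntimeError("could not place mutually separated poses")
        pose = random_surface_pose(rng, partner_coords, lig_local - lig_center, cfg)
        # fold ligand centering into the transform so pose.apply acts on raw coords
        pose = Pose(pose.rotation, pose.translation - pose.rotation @ lig_center)
        centroid = pose.apply(lig_local).mean(axis=0)
        if all(np.linalg.norm(centroid - p.apply(lig_local).mean(axis=0)) >= 8.0
               for p in poses):
            poses.append(pose)
    return partner, ligand, poses


DEFAULT_LABEL_RESIDUES = (2, 6, 11)  # flanking and central positions on the 12-mer


@dataclass
class SyntheticTruth:
    """Generating parameters of a simulated fuzzy-complex dataset."""

    seed: int
    kd: float = 35.0                      # μM
    true_n_states: int = 3
    partner_size: int = 60
    label_sites: tuple = ()
    saturations: tuple = DEFAULT_SATURATIONS
    intensity_noise: float = DEFAULT_INTENSITY_NOISE
    peak_noise: float = 0.005             # ppm
    forward_params: PREForwardParams = field(default_factory=PREForwardParams)
    partner: Structure | None = None
    ligand: Structure | None = None
    true_poses: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.partner is None:
            self.partner, self.ligand, self.true_poses = make_toy_complex(
                self.seed, self.true_n_states, self.partner_size)
        if not self.label_sites:
            self.label_sites = tuple(
                SpinLabelSite(label_id=f"L{r}", attachment_residue=r, mutation=f"A{r}C")
                for r in DEFAULT_LABEL_RESIDUES)
        if len(self.saturations) != len(self.label_sites):
            raise ValueError("one saturation per label site")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "kd": self.kd, "true_n_states": self.true_n_states,
            "partner_size": self.partner_size,
            "label_sites": [vars(s) for s in self.label_sites],
            "saturations": list(self.saturations),
            "intensity_noise": self.intensity_noise, "peak_noise": self.peak_noise,
            "forward_params": vars(self.forward_params),
            "true_poses": [{"rotation": p.rotation.tolist(),
                            "translation": p.translation.tolist()}
                           for p in self.true_poses],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def simulate_pre(truth: SyntheticTruth, noise_seed: int | None = None) -> dict:
    """Paramagnetic/diamagnetic peak-list pairs, one per label site.

    Diamagnetic intensities sit around a common scale; paramagnetic
    intensities are I_dia × the population-mixed true ratio
    (sat · ratio_bound + (1 − sat), fast exchange on the PRE timescale), with
    seeded Gaussian noise at ``intensity_noise``.  ``noise_seed`` overrides
    the spectral-noise stream (default: derived from the truth seed), letting
    one truth be "measured" repeatedly with independent noise.  Returns
    {label_id: (para PeakList, dia PeakList)}.
    """
    entropy = truth.seed if noise_seed is None else int(noise_seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=entropy,
                                                       spawn_key=(101,)))
    scale = 1e6
    noise = truth.intensity_noise * scale
    out = {}
    for site, sat in zip(truth.label_sites, truth.saturations):
        pred = back_calculate_pre(truth.partner, truth.ligand, truth.true_poses,
                                  site, truth.forward_params, saturation=sat)
        ratios = pred.data["ratio"].to_numpy()
        residues = pred.data["residue_index"].to_numpy()
        rtypes = ["A"] * len(residues)
        n = len(residues)
        shifts_h = 7.8 + 0.8 * rng.random(n)
        shifts_n = 108.0 + 18.0 * rng.random(n)
        i_dia = scale + rng.normal(0.0, noise, n) if noise > 0 else np.full(n, scale)
        i_para = scale * ratios + (rng.normal(0.0, noise, n) if noise > 0 else 0.0)
        i_para = np.maximum(i_para, 0.0)
        base = pd.DataFrame({
            "residue_index": residues, "residue_type": rtypes, "atom_pair": "HN-N",
            "shift1": shifts_h, "shift2": shifts_n,
        })
        dia = PeakList(base.assign(intensity=i_dia)[PEAK_COLUMNS],
                       spectrum_id=f"{site.label_id}_dia",
                       noise_level=max(noise, 1e-9 * scale))
        para = PeakList(base.assign(intensity=i_para)[PEAK_COLUMNS],
                        spectrum_id=f"{site.label_id}_para",
                        noise_level=max(noise, 1e-9 * scale))
        out[site.label_id] = (para, dia)
    return out


def simulate_titration(kd: float, labeled_total: float, ligand_totals,
                       endpoint_deltas: pd.DataFrame, noise: float = 0.0,
                       seed: int = 0) -> TitrationSeries:
    """Fast-exchange titration series with quadratic population averaging.

    ``endpoint_deltas`` has columns residue_index, delta_h, delta_n (ppm,
    fully bound minus free).  Each point's shifts are
    free + fraction_bound × delta with seeded Gaussian ppm noise (the ¹⁵N
    noise is scaled ×5 so it is comparable in scaled space).
    """
    rng = np.random.default_rng(seed)
    res = endpoint_deltas["residue_index"].to_numpy(int)
    n = len(res)
    free_h = 7.9 + 0.6 * rng.random(n)
    free_n = 110.0 + 14.0 * rng.random(n)
    points = []
    for lig in ligand_totals:
        fb = fraction_saturation(labeled_total, float(lig), kd) if lig > 0 else 0.0
        h = free_h + fb * endpoint_deltas["delta_h"].to_numpy()
        x = free_n + fb * endpoint_deltas["delta_n"].to_numpy()
        if noise > 0:
            h = h + rng.normal(0.0, noise, n)
            x = x + rng.normal(0.0, 5.0 * noise, n)
        df = pd.DataFrame({
            "residue_index": res, "residue_type": "A", "atom_pair": "HN-N",
            "shift1": h, "shift2": x, "intensity": 1.0,
        })
        points.append((float(lig), float(labeled_total),
                       PeakList(df[PEAK_COLUMNS], spectrum_id=f"lig_{lig:g}",
                                noise_level=max(noise, 1e-9))))
    return TitrationSeries(points=points, labeled_species="toy_labeled")


def simulate_decays(T_ms, delays, noise: float = 0.0, seed: int = 0,
                    kind: str = "T2", i0: float = 1.0) -> RelaxationSeries:
    """Mono-exponential decays per residue; ``T_ms`` maps residue -> T (ms)."""
    rng = np.random.default_rng(seed)
    delays = np.asarray(delays, float)
    T = pd.Series(T_ms, dtype=float)
    data = {}
    for ridx, t_val in T.items():
        y = i0 * np.exp(-delays / t_val)
        if noise > 0:
            y = y + rng.normal(0.0, noise * i0, len(delays))
        data[int(ridx)] = y
    df = pd.DataFrame.from_dict(data, orient="index", columns=delays)
    df.index.name = "residue_index"
    return RelaxationSeries(delays=delays, intensities=df, kind=kind)


def simulate_fp(params, X, noise: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """One-site FP titration table; ``params`` = (Bmax, Kd, NS, Background)."""
    bmax, kd, ns, background = params
    rng = np.random.default_rng(seed)
    x = np.asarray(X, float)
    y = bmax * x / (kd + x) + ns * x + background
    if noise > 0:
        y = y + rng.normal(0.0, noise * max(abs(bmax), 1.0), len(x))
    return pd.DataFrame({"x_uM": x, "y_polarization": y})
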