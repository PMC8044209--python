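"""PRE-restrained rigid-body ensemble fitting and ensemble-size selection.

The question answered here is the operational test of fuzzy binding: can the
PRE profiles measured from spin-labels on a disordered ligand be explained by
a single bound orientation, or is an ensemble of simultaneous states needed?

The forward model predicts, for each observed partner resonance, the PRE rate
from the Solomon-Bloembergen transverse spectral term of a nitroxide,

    Γ2 = k_const · (4τc + 3τc / (1 + (ω_H τc)²)) · ⟨r⁻⁶⟩

with ⟨r⁻⁶⟩ the equal-weight average over ensemble members of the label-nucleus
distance, and converts it to an intensity ratio

    I_para/I_dia = R2,dia · exp(−Γ2 · t) / (R2,dia + Γ2).

Ensembles of 1-6 rigid-body ligand poses are refined against observed profiles
by seeded simulated annealing (Metropolis over per-member rotations and
translations, geometric temperature ladder, greedy quench), minimizing a
reduced-χ²-style PRE energy plus a soft-sphere clash penalty.  This is a
deliberate methodological simplification of full torsion-angle simulated
annealing with NOE/dihedral restraints: only the PRE restraints and rigid
bodies are kept, which preserves the ensemble-size model comparison while
remaining desk-scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nmr_io import Structure
from .pre import PREProfile, SpinLabelSite

ADEQUACY_RULE = "median pre_energy of the ten lowest-PRE-energy structures <= 2 x n_restraints"


@dataclass
class PREForwardParams:
    """Constants of the PRE forward model (all positive).

    tau_c_ns : effective correlation time of the label-nucleus vector (ns)
    t_evolution_ms : transverse evolution during detection (ms)
    k_const : dipolar constant, Å⁶ s⁻²  (nitroxide-¹H)
    larmor_h_mhz : ¹H Larmor frequency (MHz)
    r2_dia : diamagnetic transverse rate baseline (s⁻¹)
    """

    tau_c_ns: float = 8.0
    t_evolution_ms: float = 10.0
    k_const: float = 1.23e16
    larmor_h_mhz: float = 500.0
    r2_dia: float = 20.0

    def __post_init__(self) -> None:
        for name in ("tau_c_ns", "t_evolution_ms", "k_const", "larmor_h_mhz", "r2_dia"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def spectral_term(self) -> float:
        """k_const × (4τc + 3τc/(1+(ω_H τc)²)), in Å⁶ s⁻¹."""
        tau = self.tau_c_ns * 1e-9
        omega = 2.0 * np.pi * self.larmor_h_mhz * 1e6
        return self.k_const * (4.0 * tau + 3.0 * tau / (1.0 + (omega * tau) ** 2))

    def ratio_from_r6inv(self, r6inv):
        """Intensity ratio for a given ⟨r⁻⁶⟩ (Å⁻⁶)."""
        gamma2 = self.spectral_term * np.asarray(r6inv, float)
        t = self.t_evolution_ms * 1e-3
        return self.r2_dia * np.exp(-gamma2 * t) / (self.r2_dia + gamma2)


@dataclass
class Pose:
    """Rigid transform (rotation then translation, Å) of the ligand model."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


@dataclass
class EnsembleModel:
    """A fitted N-state rigid-body ensemble with its energies."""

    n_states: int
    members: list  # list of Pose
    weights: np.ndarray
    pre_energy: float
    clash_energy: float
    seed: int
    n_restraints: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_states <= 6:
            raise ValueError("n_states must lie in [1, 6]")
        w = np.asarray(self.weights, float)
        if len(w) != self.n_states or not np.allclose(w, 1.0 / self.n_states):
            raise ValueError("weights must be equal and sum to 1")
        if self.pre_energy < 0 or self.clash_energy < 0:
            raise ValueError("energies must be >= 0")
        self.weights = w

    @property
    def total_energy(self) -> float:
        return self.pre_energy + self.clash_energy


# ---------------------------------------------------------------------------
# Geometry helpers

def place_spin_label(structure: Structure, site: SpinLabelSite, offset: float = 6.0,
                     chain: str | None = None) -> np.ndarray:
    """Nitroxide pseudo-atom position for a TEMPO label at ``site``.

    Rigid single-conformer approximation: the label nitroxide sits ``offset`` Å
    beyond Cβ along the Cα→Cβ direction.  For glycine (no Cβ) a fixed local
    frame is used: the direction from the N/C backbone midpoint through Cα.
    """
    res = site.attachment_residue
    ca = structure.atom_xyz(res, "CA", chain)
    try:
        cb = structure.atom_xyz(res, "CB", chain)
        direction = cb - ca
        base = cb
    except KeyError:
        n = structure.atom_xyz(res, "N", chain)
        c = structure.atom_xyz(res, "C", chain)
        direction = ca - 0.5 * (n + c)
        base = ca
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError(f"degenerate geometry at residue {res}")
    return base + offset * direction / norm


def _observed_atom(atom_pair: str) -> str:
    # amide proton approximated by the backbone N position; CH groups by CA
    return "N" if atom_pair == "HN-N" else "CA"


def back_calculate_pre(partner: Structure, ligand: Structure, members,
                       site: SpinLabelSite, params: PREForwardParams | None = None,
                       residues=None, saturation: float = 1.0,
                       atom_pair: str = "HN-N") -> PREProfile:
    """Predicted PRE profile of the partner for one label site.

    ``members`` is a list of Pose transforms applied to the ligand; the label
    position is computed once in the ligand frame and transformed per member.
    ⟨r⁻⁶⟩ uses equal member weights.  ``saturation`` < 1 mixes the bound-state
    ratio with free (ratio 1) by linear population averaging.  Member-atom
    distances below 1 Å are sterically impossible and flagged.
    """
    params = params or PREForwardParams()
    if len(members) == 0:
        raise ValueError("need at least one ensemble member")
    label_local = place_spin_label(ligand, site)
    labels = np.stack([m.apply(label_local) for m in members])  # (m, 3)

    atoms = partner.residue_atoms(_observed_atom(atom_pair))
    if residues is not None:
        atoms = atoms[atoms["residue_index"].isin(list(residues))]
    if atoms.empty:
        raise ValueError("no observed atoms on the partner")
    coords = atoms[["x", "y", "z"]].to_numpy(float)  # (n, 3)

    d = np.linalg.norm(coords[None, :, :] - labels[:, None, :], axis=2)  # (m, n)
    steric = (d < 1.0).any(axis=0)
    d = np.maximum(d, 1.0)
    r6inv = np.mean(d ** -6, axis=0)
    ratio_bound = params.ratio_from_r6inv(r6inv)
    ratio = saturation * ratio_bound + (1.0 - saturation)
    # fully bleached predictions underflow to 0; floor them at machine tiny
    r2_star = 1.0 / np.maximum(ratio, 1e-16) - 1.0  # normalized I_dia = 1

    out = pd.DataFrame({
        "residue_index": atoms["residue_index"].to_numpy(),
        "atom_pair": atom_pair,
        "ratio": ratio,
        "ratio_err": 0.0,
        "r2_star": r2_star,
        "r2_star_err": 0.0,
        "bleached": False,
        "steric_clash": steric,
    })
    return PREProfile(data=out, label=site, saturation=float(saturation))


def pre_energy(predicted: PREProfile, observed: PREProfile,
               sigma_floor: float = 1e-12) -> float:
    """χ²-style restraint energy Σ ((R2*_pred − R2*_obs)/σ)² over matched residues.

    σ is the observed R2* error (ratio error propagated to the rate scale).
    Bleached residues contribute one-sided: their observed R2* is only a lower
    bound on the true PRE, so only under-prediction is penalized.
    """
    p = predicted.data.set_index(["residue_index", "atom_pair"])
    o = observed.data.set_index(["residue_index", "atom_pair"])
    shared = p.index.intersection(o.index)
    if len(shared) < 5:
        raise ValueError("need at least 5 matched residues")
    r_pred = p.loc[shared, "r2_star"].to_numpy(float)
    r_obs = o.loc[shared, "r2_star"].to_numpy(float)
    sigma = np.maximum(o.loc[shared, "r2_star_err"].to_numpy(float), sigma_floor)
    bleached = o.loc[shared, "bleached"].to_numpy(bool)
    resid = (r_pred - r_obs) / sigma
    resid[bleached] = np.minimum(resid[bleached], 0.0)  # penalize under-prediction only
    return float(np.sum(resid**2))


# ---------------------------------------------------------------------------
# Ensemble fitting

@dataclass
class EnsembleFitConfig:
    """Annealing schedule and energy-term configuration."""

    n_steps: int = 1500
    quench_steps: int = 400
    rot_max_deg: float = 20.0       # at the start; decays with temperature
    trans_max: float = 2.5          # Å, at the start
    move_decay: float = 0.1         # final move scale relative to start
    replace_prob: float = 0.1       # chance of re-seeding a member per step
    t_start_frac: float = 0.05      # T0 as a fraction of the initial energy
    t_end_frac: float = 1e-3        # Tf relative to T0
    clash_cutoff: float = 2.5       # Å, soft-sphere contact distance
    clash_weight: float = 10.0      # per-pair quadratic penalty weight
    placement_gap: tuple = (5.0, 10.0)   # Å beyond the partner surface
    contact_max: float = 16.0       # Å, max allowed min ligand-partner distance
    clash_min: float = 4.0          # Å, min allowed min ligand-partner distance
    adequacy_factor: float = 2.0    # threshold = factor × n_restraints
    plateau_improvement: float = 0.10
    max_placement_attempts: int = 500


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via a random quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def random_surface_pose(rng: np.random.Generator, partner_coords: np.ndarray,
                        ligand_local: np.ndarray, config: EnsembleFitConfig | None = None) -> Pose:
    """Place the (centered) ligand just outside the partner surface, random orientation."""
    config = config or EnsembleFitConfig()
    center = partner_coords.mean(axis=0)
    for _ in range(config.max_placement_attempts):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        support = np.max((partner_coords - center) @ u)
        gap = rng.uniform(*config.placement_gap)
        rot = random_rotation(rng)
        trans = center + (support + gap) * u
        pose = Pose(rot, trans)
        pts = pose.apply(ligand_local)
        dmin = np.min(np.linalg.norm(pts[:, None, :] - partner_coords[None, :, :], axis=2))
        if config.clash_min <= dmin <= config.contact_max:
            return pose
    raise RuntimeError("could not place ligand pose on the partner surface")


class _Evaluator:
    """Precomputed arrays for fast PRE + clash energy evaluation."""

    def __init__(self, observed, partner: Structure, ligand: Structure,
                 params: PREForwardParams, config: EnsembleFitConfig):
        self.params = params
        self.config = config
        self.profiles = list(observed)
        lig = ligand.atoms
        self.ligand_local = lig[["x", "y", "z"]].to_numpy(float)
        self.ligand_center = self.ligand_local.mean(axis=0)
        clash_sel = lig["atom_name"].isin(["CA", "CB"])
        self.ligand_clash = lig.loc[clash_sel, ["x", "y", "z"]].to_numpy(float)
        psel = partner.atoms["atom_name"].isin(["CA", "CB"])
        self.partner_clash = partner.atoms.loc[psel, ["x", "y", "z"]].to_numpy(float)
        self.partner_all = partner.coords()

        self.sites, self.coords, self.r2_obs, self.sigma, self.bleached, self.sat = \
            [], [], [], [], [], []
        self.n_restraints = 0
        for prof in self.profiles:
            pair = prof.data["atom_pair"].iloc[0]
            atoms = partner.residue_atoms(_observed_atom(pair)).set_index("residue_index")
            sub = prof.data[prof.data["residue_index"].isin(atoms.index)]
            if len(sub) < 5:
                raise ValueError("need at least 5 matched residues per profile")
            self.sites.append(place_spin_label(ligand, prof.label))
            self.coords.append(atoms.loc[sub["residue_index"], ["x", "y", "z"]].to_numpy(float))
            self.r2_obs.append(sub["r2_star"].to_numpy(float))
            self.sigma.append(np.maximum(sub["r2_star_err"].to_numpy(float), 1e-12))
            self.bleached.append(sub["bleached"].to_numpy(bool))
            self.sat.append(float(prof.saturation))
            self.n_restraints += len(sub)

    def energy(self, rotations: np.ndarray, translations: np.ndarray):
        """(pre_energy, clash_energy) for member transforms (m,3,3), (m,3)."""
        pre = 0.0
        for local, coords, r2o, sig, ble, sat in zip(
                self.sites, self.coords, self.r2_obs, self.sigma, self.bleached, self.sat):
            labels = rotations @ local + translations  # (m, 3)
            d = np.linalg.norm(coords[None, :, :] - labels[:, None, :], axis=2)
            d = np.maximum(d, 1.0)
            r6inv = np.mean(d ** -6, axis=0)
            ratio = sat * self.params.ratio_from_r6inv(r6inv) + (1.0 - sat)
            resid = ((1.0 / ratio - 1.0) - r2o) / sig
            resid[ble] = np.minimum(resid[ble], 0.0)
            pre += float(np.sum(resid**2))
        pts = np.einsum("mij,aj->mai", rotations, self.ligand_clash) + translations[:, None, :]
        d = np.linalg.norm(pts[:, :, None, :] - self.partner_clash[None, None, :, :], axis=3)
        overlap = np.maximum(self.config.clash_cutoff - d, 0.0)
        clash = self.config.clash_weight * float(np.sum(overlap**2))
        return pre, clash


class PREEnsembleModel:
    """Model object tying observed PRE profiles to a rigid-body ensemble fit.

    Parameters
    ----------
    observed : sequence of PREProfile (one per spin-label site)
    partner : fixed Structure whose resonances are observed
    ligand : Structure of the idealized disordered-ligand model (helix/beads)
    params, config : forward-model constants and annealing configuration
    """

    def __init__(self, observed, partner: Structure, ligand: Structure,
                 params: PREForwardParams | None = None,
                 config: EnsembleFitConfig | None = None):
        if isinstance(observed, PREProfile):
            observed = [observed]
        if len(observed) == 0:
            raise ValueError("need at least one observed PRE profile")
        self.observed = list(observed)
        self.partner = partner
        self.ligand = ligand
        self.params = params or PREForwardParams()
        self.config = config or EnsembleFitConfig()
        self._ev = _Evaluator(self.observed, partner, ligand, self.params, self.config)

    # -- fitting ------------------------------------------------------------

    def _initial_members(self, n_states: int, rng: np.random.Generator):
        rots, trans = [], []
        centered = self._ev.ligand_local - self._ev.ligand_center
        for _ in range(n_states):
            pose = random_surface_pose(rng, self._ev.partner_all, centered, self.config)
            # pose acts on centered coords; fold the centering into the transform
            rots.append(pose.rotation)
            trans.append(pose.translation - pose.rotation @ self._ev.ligand_center)
        return np.stack(rots), np.stack(trans)

    def fit(self, n_states: int, seed: int, init=None) -> EnsembleModel:
        """Seeded annealing + quench; deterministic for fixed seed and config.

        ``init`` optionally supplies starting member transforms (rotations,
        translations); otherwise members start at seeded random surface poses.
        """
        if not 1 <= n_states <= 6:
            raise ValueError("n_states must lie in [1, 6]")
        cfg = self.config
        rng = np.random.default_rng(seed)
        if init is None:
            rot, tra = self._initial_members(n_states, rng)
        else:
            rot, tra = (np.array(init[0], float).copy(), np.array(init[1], float).copy())
        pre, clash = self._ev.energy(rot, tra)
        e = pre + clash
        best = (e, pre, clash, rot.copy(), tra.copy())

        t0 = max(1.0, cfg.t_start_frac * e)
        tf = max(t0 * cfg.t_end_frac, 1e-9)
        n = max(cfg.n_steps, 1)
        cool = (tf / t0) ** (1.0 / n)
        temp = t0
        centered = self._ev.ligand_local - self._ev.ligand_center
        for step in range(n):
            frac = cfg.move_decay ** (step / n)  # 1 → move_decay
            j = int(rng.integers(n_states))
            new_rot, new_tra = rot.copy(), tra.copy()
            if rng.random() < cfg.replace_prob:
                try:
                    pose = random_surface_pose(rng, self._ev.partner_all, centered, cfg)
                    new_rot[j] = pose.rotation
                    new_tra[j] = pose.translation - pose.rotation @ self._ev.ligand_center
                except RuntimeError:
                    continue
            else:
                angle = np.deg2rad(cfg.rot_max_deg) * frac * rng.random()
                axis = rng.normal(size=3)
                dr = _axis_angle(axis, angle)
                # rotate about the member's own center of mass
                com = new_rot[j] @ self._ev.ligand_center + new_tra[j]
                new_rot[j] = dr @ new_rot[j]
                new_tra[j] = com - new_rot[j] @ self._ev.ligand_center \
                    + cfg.trans_max * frac * rng.uniform(-1, 1, 3)
            npre, nclash = self._ev.energy(new_rot, new_tra)
            ne = npre + nclash
            if ne < e or rng.random() < np.exp(-(ne - e) / temp):
                rot, tra, e, pre, clash = new_rot, new_tra, ne, npre, nclash
                if e < best[0]:
                    best = (e, pre, clash, rot.copy(), tra.copy())
            temp *= cool
        # greedy quench from the best state
        e, pre, clash, rot, tra = best
        for _ in range(cfg.quench_steps):
            j = int(rng.integers(n_states))
            new_rot, new_tra = rot.copy(), tra.copy()
            angle = np.deg2rad(cfg.rot_max_deg) * cfg.move_decay * rng.random()
            dr = _axis_angle(rng.normal(size=3), angle)
            com = new_rot[j] @ self._ev.ligand_center + new_tra[j]
            new_rot[j] = dr @ new_rot[j]
            new_tra[j] = com - new_rot[j] @ self._ev.ligand_center \
                + cfg.trans_max * cfg.move_decay * rng.uniform(-1, 1, 3)
            npre, nclash = self._ev.energy(new_rot, new_tra)
            if npre + nclash < e:
                rot, tra, e, pre, clash = new_rot, new_tra, npre + nclash, npre, nclash
        members = [Pose(r, t) for r, t in zip(rot, tra)]
        return EnsembleModel(n_states=n_states, members=members,
                             weights=np.full(n_states, 1.0 / n_states),
                             pre_energy=pre, clash_energy=clash, seed=int(seed),
                             n_restraints=self._ev.n_restraints)

    # -- size scan ----------------------------------------------------------

    def size_scan(self, sizes=range(1, 7), replicates: int = 10,
                  starting_models: int = 13, seed: int = 0) -> "SizeScanResult":
        """Fit every (size, starting model, replicate) and select the minimal size.

        Each starting model is an independent random initial placement; each
        replicate re-anneals from it with a fresh seeded stream, giving
        ``starting_models × replicates`` fitted structures per size.
        """
        sizes = sorted(set(int(s) for s in sizes))
        if not sizes or sizes[0] < 1 or sizes[-1] > 6:
            raise ValueError("sizes must be a non-empty subset of 1..6")
        if replicates < 2:
            raise ValueError("need at least 2 replicates")
        models: dict[int, list[EnsembleModel]] = {}
        for size in sizes:
            fits = []
            for sm in range(starting_models):
                start_rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=int(seed), spawn_key=(size, sm)))
                init = self._initial_members(size, start_rng)
                for rep in range(replicates):
                    child = np.random.SeedSequence(
                        entropy=int(seed), spawn_key=(size, sm, rep))
                    sub_seed = int(child.generate_state(1, np.uint32)[0] % (2**31))
                    fits.append(self.fit(size, seed=sub_seed, init=init))
            models[size] = fits
        return SizeScanResult.from_models(models, config=self.config,
                                          n_restraints=self._ev.n_restraints)


# ---------------------------------------------------------------------------
# Scan summaries

def _box_stats(values: np.ndarray) -> dict:
    """Box-plot statistics: quartile box, 1.5×IQR whiskers clipped to the data,
    and outliers counted outside median ± 1.5×IQR."""
    v = np.sort(np.asarray(values, float))
    q25, med, q75 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    whisker_lo = float(inside.min()) if len(inside) else float(v.min())
    whisker_hi = float(inside.max()) if len(inside) else float(v.max())
    outliers = int(np.sum((v < med - 1.5 * iqr) | (v > med + 1.5 * iqr)))
    return {"median": float(med), "q25": float(q25), "q75": float(q75),
            "whisker_lo": whisker_lo, "whisker_hi": whisker_hi,
            "n_outliers": outliers, "n": int(len(v))}


@dataclass
class SizeScanResult:
    """Replicate ensembles per size with box-plot summaries and model selection."""

    models: dict  # size -> list of EnsembleModel
    summary: pd.DataFrame
    minimal_adequate_size: int | None
    plateau_size: int | None
    adequacy_rule: str
    adequacy_threshold: float
    n_restraints: int

    @classmethod
    def from_models(cls, models: dict, config: EnsembleFitConfig | None = None,
                    n_restraints: int | None = None) -> "SizeScanResult":
        config = config or EnsembleFitConfig()
        if n_restraints is None:
            n_restraints = next(iter(models.values()))[0].n_restraints
        rows = []
        ten_low_median = {}
        for size in sorted(models):
            fits = models[size]
            if len(fits) < 2:
                raise ValueError("summaries need at least 2 replicates per size")
            total = np.array([m.total_energy for m in fits])
            pre = np.array([m.pre_energy for m in fits])
            ten = np.sort(pre)[:10]
            ten_low_median[size] = float(np.median(ten))
            for term, vals in (("total", total), ("pre", pre), ("pre_ten_lowest", ten)):
                rows.append({"n_states": size, "term": term, **_box_stats(vals)})
        summary = pd.DataFrame(rows)

        threshold = config.adequacy_factor * n_restraints
        minimal = next((s for s in sorted(models) if ten_low_median[s] <= threshold), None)
        plateau = None
        szs = sorted(models)
        for a, b in zip(szs, szs[1:]):
            ma, mb = ten_low_median[a], ten_low_median[b]
            if ma <= 0 or (ma - mb) / ma < config.plateau_improvement:
                plateau = a
                break
        if plateau is None and szs:
            plateau = szs[-1]
        return cls(models=models, summary=summary, minimal_adequate_size=minimal,
                   plateau_size=plateau, adequacy_rule=ADEQUACY_RULE,
                   adequacy_threshold=float(threshold), n_restraints=int(n_restraints))

    def n_structures(self, size: int) -> int:
        return len(self.models[size])


def fit_ensemble(observed, partner: Structure, ligand: Structure, n_states: int,
                 seed: int, params: PREForwardParams | None = None,
                 config: EnsembleFitConfig | None = None) -> EnsembleModel:
    return PREEnsembleModel(observed, partner, ligand, params, config).fit(n_states, seed)


def ensemble_size_scan(observed, partner: Structure, ligand: Structure,
                       sizes=range(1, 7), replicates: int = 10, starting_models: int = 13,
                       seed: int = 0, params: PREForwardParams | None = None,
                       config: EnsembleFitConfig | None = None) -> SizeScanResult:
    model = PREEnsembleModel(observed, partner, ligand, params, config)
    return model.size_scan(sizes=sizes, replicates=replicates,
                           starting_models=starting_models, seed=seed)


def summarize_energies(scan: SizeScanResult) -> pd.DataFrame:
    """Per-size box-plot summary table of total and PRE energies."""
    return scan.summary.copy()


def posed_structures(partner: Structure, ligand: Structure, model: EnsembleModel) -> list:
    """Partner + posed ligand Structures, one per ensemble member (for PDB output)."""
    out = []
    for pose in model.members:
        lig = ligand.atoms.copy()
        xyz = pose.apply(lig[["x", "y", "z"]].to_numpy(float))
        lig[["x", "y", "z"]] = xyz
        combined = pd.concat([partner.atoms, lig], ignore_index=True)
        combined["serial"] = np.arange(1, len(combined) + 1)
        out.append(Structure(combined, model_count=1, name="ensemble_member"))
    return out
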