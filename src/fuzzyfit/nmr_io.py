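"""Readers and writers for the delimited NMR formats used throughout the package.

Residue numbering is construct numbering, 1-based (e.g. a Gal4 828-881 construct
keeps residues 828-881).  Prolines and unassigned residues are simply absent
rows; no module renumbers.  All ppm values are stored unscaled -- heteronucleus
scaling (¹⁵N/5) happens only inside CSP computation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

ATOM_PAIRS = ("HN-N", "H-C")

PEAK_COLUMNS = ["residue_index", "residue_type", "atom_pair", "shift1", "shift2", "intensity"]
SHIFT_COLUMNS = ["residue_index", "residue_type", "atom", "shift"]
SHIFT_ATOMS = ("CA", "CB", "CO", "N", "HN")


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class PeakList:
    """Per-residue 2D resonance positions (ppm) and intensities for one spectrum.

    ``shift1`` is always the ¹H dimension; ``shift2`` the heteronucleus
    (¹⁵N for ``HN-N`` pairs, ¹³C for ``H-C``).
    """

    data: pd.DataFrame
    spectrum_id: str = ""
    noise_level: float = 1.0

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data, columns=PEAK_COLUMNS).copy()
        df["residue_index"] = df["residue_index"].astype(int)
        for c in ("shift1", "shift2", "intensity"):
            df[c] = df[c].astype(float)
        if not np.isfinite(df[["shift1", "shift2"]].to_numpy()).all():
            raise FormatError("non-finite chemical shift in peak list")
        bad = ~df["atom_pair"].isin(ATOM_PAIRS)
        if bad.any():
            raise FormatError(f"unknown atom_pair values: {sorted(df.loc[bad, 'atom_pair'])}")
        dup = df.duplicated(subset=["residue_index", "atom_pair"], keep=False)
        if dup.any():
            res = sorted(df.loc[dup, "residue_index"].unique())
            raise FormatError(f"duplicate peak for residue(s) {res}")
        if not self.noise_level > 0:
            raise FormatError("noise_level must be > 0")
        self.data = df.sort_values(["atom_pair", "residue_index"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def residues(self) -> np.ndarray:
        return self.data["residue_index"].to_numpy()


@dataclass
class ShiftTable:
    """Backbone chemical shifts (ppm), one row per (residue, atom)."""

    rows: pd.DataFrame
    source_state: str = "free"

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows, columns=SHIFT_COLUMNS).copy()
        df["residue_index"] = df["residue_index"].astype(int)
        df["shift"] = df["shift"].astype(float)
        bad = ~df["atom"].isin(SHIFT_ATOMS)
        if bad.any():
            raise FormatError(f"unknown atom name(s): {sorted(df.loc[bad, 'atom'].unique())}")
        dup = df.duplicated(subset=["residue_index", "atom"], keep=False)
        if dup.any():
            res = sorted(df.loc[dup, "residue_index"].unique())
            raise FormatError(f"duplicate shift for residue(s) {res}")
        gly_cb = (df["residue_type"] == "G") & (df["atom"] == "CB")
        if gly_cb.any():
            res = sorted(df.loc[gly_cb, "residue_index"].unique())
            raise FormatError(f"glycine cannot carry a CB shift (residue(s) {res})")
        if not np.isfinite(df["shift"].to_numpy()).all():
            raise FormatError("non-numeric shift value")
        self.rows = df.sort_values(["residue_index", "atom"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)

    def pivot(self, atoms=("CA", "CB")) -> pd.DataFrame:
        """Wide table residue_index x atom, residue_type carried along."""
        sub = self.rows[self.rows["atom"].isin(atoms)]
        wide = sub.pivot(index="residue_index", columns="atom", values="shift")
        wide = wide.reindex(columns=list(atoms))
        types = self.rows.drop_duplicates("residue_index").set_index("residue_index")["residue_type"]
        wide.insert(0, "residue_type", types.reindex(wide.index))
        return wide


@dataclass
class Structure:
    """Flat atom table for one model of a PDB file."""

    atoms: pd.DataFrame
    model_count: int = 1
    name: str = ""
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        cols = ["serial", "atom_name", "residue_index", "residue_type", "chain", "x", "y", "z"]
        df = pd.DataFrame(self.atoms, columns=cols).copy()
        df["residue_index"] = df["residue_index"].astype(int)
        if not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
            raise FormatError("non-finite coordinates")
        self.atoms = df.reset_index(drop=True)
        self._index = {
            (int(r.residue_index), r.atom_name, r.chain): i
            for i, r in enumerate(self.atoms.itertuples())
        }

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self, atom_name: str | None = None) -> np.ndarray:
        df = self.atoms if atom_name is None else self.atoms[self.atoms["atom_name"] == atom_name]
        return df[["x", "y", "z"]].to_numpy(float)

    def atom_xyz(self, residue_index: int, atom_name: str, chain: str | None = None) -> np.ndarray:
        if chain is None:
            chains = self.atoms["chain"].unique()
            if len(chains) != 1:
                raise KeyError("chain must be given for multi-chain structures")
            chain = chains[0]
        try:
            i = self._index[(int(residue_index), atom_name, chain)]
        except KeyError:
            raise KeyError(f"atom {atom_name} of residue {residue_index} (chain {chain}) absent") from None
        row = self.atoms.iloc[i]
        return np.array([row.x, row.y, row.z], float)

    def residue_atoms(self, atom_name: str) -> pd.DataFrame:
        """Sub-table of one named atom per residue, ordered by residue index."""
        sub = self.atoms[self.atoms["atom_name"] == atom_name]
        return sub.sort_values("residue_index").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Peak lists

_SPARKY_ASSIGN = re.compile(r"^([A-Za-z])(\d+)([A-Za-z][A-Za-z0-9]*)-([A-Za-z][A-Za-z0-9]*)$")


def _classify_pair(a1: str, a2: str):
    """Map a Sparky atom pair onto (atom_pair, which column is ¹H)."""
    kinds = {a1[0].upper(), a2[0].upper()}
    if kinds == {"H", "N"}:
        pair = "HN-N"
    elif kinds == {"H", "C"}:
        pair = "H-C"
    else:
        return None
    h_first = a1[0].upper() == "H"
    return pair, h_first


def read_peak_list(path, dialect: str = "sparky") -> PeakList:
    """Read a peak list in ``sparky`` (Assignment w1 w2 Height) or ``tsv`` dialect.

    Rows whose assignment cannot be parsed are skipped; a single warning
    reports how many were dropped.  Duplicate (residue, atom_pair) entries are
    an error naming the residue.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_peak_tsv(path)
    if dialect != "sparky":
        raise ValueError(f"unknown dialect {dialect!r}")

    rows, skipped = [], 0
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if toks[0].lower() == "assignment":
            continue
        m = _SPARKY_ASSIGN.match(toks[0]) if toks else None
        if m is None or len(toks) < 3:
            skipped += 1
            continue
        rtype, ridx, a1, a2 = m.group(1).upper(), int(m.group(2)), m.group(3), m.group(4)
        cls = _classify_pair(a1, a2)
        if cls is None:
            skipped += 1
            continue
        pair, h_first = cls
        try:
            w1, w2 = float(toks[1]), float(toks[2])
            height = float(toks[3]) if len(toks) > 3 else np.nan
        except ValueError:
            skipped += 1
            continue
        shift_h, shift_x = (w1, w2) if h_first else (w2, w1)
        rows.append((ridx, rtype, pair, shift_h, shift_x, height))
    if skipped:
        warnings.warn(f"{path.name}: skipped {skipped} unparsable row(s)", stacklevel=2)
    if not rows:
        raise FormatError(f"{path}: no parsable peak rows")
    return PeakList(pd.DataFrame(rows, columns=PEAK_COLUMNS), spectrum_id=path.stem)


def _read_peak_tsv(path: Path) -> PeakList:
    meta = {}
    for raw in path.read_text().splitlines():
        if raw.startswith("#") and "=" in raw:
            k, v = raw.lstrip("# ").split("=", 1)
            meta[k.strip()] = v.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: tsv peak list missing column(s) {missing}")
    if df.empty:
        raise FormatError(f"{path}: no parsable peak rows")
    return PeakList(
        df[PEAK_COLUMNS],
        spectrum_id=meta.get("spectrum_id", path.stem),
        noise_level=float(meta.get("noise_level", 1.0)),
    )


def write_peak_list(peaks: PeakList, path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# spectrum_id = {peaks.spectrum_id}\n")
        fh.write(f"# noise_level = {peaks.noise_level!r}\n")
        peaks.data.to_csv(fh, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Shift tables

def read_shift_table(path, source_state: str = "free") -> ShiftTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SHIFT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: shift table missing column(s) {missing}")
    return ShiftTable(df[SHIFT_COLUMNS], source_state=source_state)


def write_shift_table(table: ShiftTable, path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# chemical shifts in ppm\n")
        table.rows.to_csv(fh, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Structures

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
_AA1TO3 = {v: k for k, v in _AA3TO1.items()}


def read_structure(path, model: int = 1) -> Structure:
    """Read ATOM/HETATM records of one MODEL from a PDB file (via gemmi)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_pdb(str(path))
    n_models = len(st)
    if n_models == 0:
        raise FormatError(f"{path}: no ATOM records")
    if not 1 <= model <= n_models:
        raise FormatError(f"{path}: model {model} absent (file has {n_models})")
    rows = []
    serial = 0
    for chain in st[model - 1]:
        for res in chain:
            one = _AA3TO1.get(res.name.upper(), "X")
            for atom in res:
                serial += 1
                rows.append((serial, atom.name, res.seqid.num, one, chain.name,
                             atom.pos.x, atom.pos.y, atom.pos.z))
    if not rows:
        raise FormatError(f"{path}: no ATOM records")
    cols = ["serial", "atom_name", "residue_index", "residue_type", "chain", "x", "y", "z"]
    return Structure(pd.DataFrame(rows, columns=cols), model_count=n_models, name=path.stem)


def write_structure(models, path) -> Path:
    """Write one Structure or a list of Structures (multi-MODEL) as PDB."""
    if isinstance(models, Structure):
        models = [models]
    st = gemmi.Structure()
    st.name = models[0].name or "fuzzyfit"
    for k, mdl in enumerate(models, start=1):
        gm = gemmi.Model(k)
        for chain_name, sub in mdl.atoms.groupby("chain", sort=False):
            ch = gemmi.Chain(str(chain_name))
            for ridx, res_rows in sub.groupby("residue_index", sort=True):
                res = gemmi.Residue()
                res.seqid = gemmi.SeqId(int(ridx), " ")
                res.name = _AA1TO3.get(res_rows.iloc[0]["residue_type"], "ALA")
                for r in res_rows.itertuples():
                    at = gemmi.Atom()
                    at.name = r.atom_name
                    at.element = gemmi.Element(r.atom_name[0])
                    at.pos = gemmi.Position(r.x, r.y, r.z)
                    res.add_atom(at)
                ch.add_residue(res)
            gm.add_chain(ch)
        st.add_model(gm)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path


# ---------------------------------------------------------------------------
# Generic per-residue profile tables

def write_profile(profile, path, comment: str | None = None) -> Path:
    """Write any per-residue table (DataFrame or object with ``.data``/``.rows``).

    One row per residue, deterministic ordering by residue_index, tab-separated,
    '.' decimal.  Units belong in the column names or the comment line.
    """
    df = profile
    for attr in ("data", "rows"):
        if not isinstance(df, pd.DataFrame) and hasattr(df, attr):
            df = getattr(df, attr)
    if not isinstance(df, pd.DataFrame):
        raise TypeError("profile must be a DataFrame or carry one in .data/.rows")
    if df.empty:
        raise ValueError("refusing to write an empty profile")
    if "residue_index" in df.columns:
        df = df.sort_values("residue_index")
    path = Path(path)
    with path.open("w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_profile(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", comment="#")
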