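"""Structure and tunnel I/O: PDB → sphere model, radius tables, tunnel files.

Atoms become spheres (PDB coordinates + van der Waals radius), residues are
partitioned into an invariant main chain (N, Cα, C, O) and a rotatable side
chain, and tunnels are read from a small TSV/JSON dialect (columns
``t x y z r``).  Hydrogens are ignored throughout: their volume is small
against the sphere bounds the collision machinery works with.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .geometry import Axis
from .tunnel import TunnelProfile

#: (chain id, residue number, insertion code)
ResidueKey = tuple[str, int, str]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
_MAIN_CHAIN_NAMES = ("N", "CA", "C", "O")
#: Residues whose Cα–Cβ rotation is the identity or impossible: GLY has no
#: Cβ, ALA's side chain is the on-axis Cβ itself, PRO's ring closes onto the
#: backbone.  They contribute exactly one rotamer (the input pose).
NON_ROTATABLE_TYPES = {"GLY", "ALA", "PRO"}


class UnknownElementError(KeyError):
    """An atom's element has no entry in the active radius table."""


@dataclass(frozen=True)
class AtomSphere:
    """One heavy atom as a sphere in the PDB coordinate frame."""

    serial: int
    name: str
    element: str
    center: np.ndarray
    radius: float
    residue_key: ResidueKey

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.radius <= 0:
            raise ValueError(f"atom {self.name}: radius must be positive")

    @property
    def sphere(self):
        from .geometry import Sphere

        return Sphere(self.center, self.radius)


@dataclass(frozen=True)
class Residue:
    """A residue split into static main chain and rotatable side chain."""

    key: ResidueKey
    type: str
    main_chain: tuple[AtomSphere, ...]
    side_chain: tuple[AtomSphere, ...]
    axis: Axis | None
    rotatable: bool

    def atom(self, name: str) -> AtomSphere | None:
        for a in self.main_chain + self.side_chain:
            if a.name == name:
                return a
        return None

    @property
    def atoms(self) -> tuple[AtomSphere, ...]:
        return self.main_chain + self.side_chain


@dataclass(frozen=True)
class Molecule:
    """A protein model: ordered residues plus static hetero obstacles."""

    residues: tuple[Residue, ...]
    hetero_atoms: tuple[AtomSphere, ...] = ()

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue keys in molecule")
        object.__setattr__(
            self, "residues", tuple(sorted(self.residues, key=lambda r: r.key))
        )

    def residue(self, key: ResidueKey) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(key)


@dataclass(frozen=True)
class RadiusTable:
    """Element → van der Waals radius (Å) mapping, swappable via config."""

    radii: dict
    name: str = "custom"

    def __post_init__(self) -> None:
        norm = {str(k).upper(): float(v) for k, v in self.radii.items()}
        if any(v <= 0 for v in norm.values()):
            raise ValueError("all van der Waals radii must be positive")
        object.__setattr__(self, "radii", norm)

    def __contains__(self, element: str) -> bool:
        return element.upper() in self.radii

    def __getitem__(self, element: str) -> float:
        try:
            return self.radii[element.upper()]
        except KeyError:
            raise UnknownElementError(
                f"element {element!r} not in radius table {self.name!r}"
            ) from None


#: Bondi-style van der Waals radii (Å); heavy atoms of standard residues plus
#: common hetero elements.  Values feed the collision rule directly, so the
#: table is explicit and overridable rather than buried in code.
BONDI_RADII = RadiusTable(
    radii={
        "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
        "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
        "SE": 1.90, "B": 1.92, "ZN": 1.39, "CU": 1.40, "NI": 1.63,
        "FE": 2.00, "MN": 2.00, "MG": 1.73, "NA": 2.27, "K": 2.75,
        "CA": 2.31, "CO": 2.00, "MO": 2.10,
    },
    name="bondi",
)


def load_radius_table(path: str | Path) -> RadiusTable:
    """Read a radius table from JSON: ``{"C": 1.70, ...}``."""
    p = Path(path)
    data = json.loads(p.read_text())
    return RadiusTable(radii=data, name=p.stem)


def partition_residue(
    residue_atoms: Sequence[AtomSphere], residue_type: str
) -> Residue:
    """Split atoms into main chain (N, CA, C, O) and side chain; derive the
    Cα–Cβ rotation axis and the rotatable flag."""
    if not residue_atoms:
        raise ValueError("cannot partition an empty atom list")
    keys = {a.residue_key for a in residue_atoms}
    if len(keys) != 1:
        raise ValueError(f"atoms span multiple residues: {sorted(keys)}")
    names = [a.name for a in residue_atoms]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate atom names in residue {keys.pop()}: {dupes}")

    main = tuple(a for a in residue_atoms if a.name in _MAIN_CHAIN_NAMES)
    side = tuple(a for a in residue_atoms if a.name not in _MAIN_CHAIN_NAMES)
    by_name = {a.name: a for a in residue_atoms}
    axis = None
    if "CA" in by_name and "CB" in by_name:
        axis = Axis(by_name["CA"].center, by_name["CB"].center)
    rtype = residue_type.upper()
    rotatable = (
        rtype not in NON_ROTATABLE_TYPES and axis is not None and len(side) > 0
    )
    return Residue(
        key=next(iter(keys)),
        type=rtype,
        main_chain=main,
        side_chain=side,
        axis=axis,
        rotatable=rotatable,
    )


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties resolved toward altloc 'A' (smallest)."""
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc or "A"))[0]


def read_pdb(
    path: str | Path,
    model_index: int = 0,
    chains: Iterable[str] | None = None,
    table: RadiusTable = BONDI_RADII,
    include_hetero: bool = True,
) -> Molecule:
    """Parse a PDB file into the sphere model.

    Hydrogens and waters are dropped; alternate locations are resolved to the
    highest-occupancy conformer (ties → altloc 'A'); only ``model_index`` is
    read.  Non-water HETATM groups become static hetero obstacles when
    ``include_hetero`` is set, and are skipped entirely otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = gemmi.read_structure(str(path))
    if len(structure) == 0:
        raise ValueError(f"{path}: no models found")
    if model_index >= len(structure):
        raise ValueError(
            f"{path}: model index {model_index} out of range ({len(structure)} models)"
        )
    model = structure[model_index]
    chain_filter = set(chains) if chains is not None else None

    residues: list[Residue] = []
    hetero: list[AtomSphere] = []
    unknown: list[str] = []

    for chain in model:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        for res in chain:
            if res.name.upper() in _WATER_NAMES or res.is_water():
                continue
            key: ResidueKey = (
                chain.name,
                res.seqid.num,
                res.seqid.icode.strip() or "",
            )
            # drop hydrogens, resolve altlocs per atom name
            groups: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                groups.setdefault(atom.name, []).append(atom)
            spheres: list[AtomSphere] = []
            for name in groups:
                atom = _pick_altloc(groups[name])
                element = atom.element.name.upper()
                if element not in table:
                    unknown.append(f"{key}:{name}({element})")
                    continue
                spheres.append(
                    AtomSphere(
                        serial=atom.serial,
                        name=name,
                        element=element,
                        center=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        radius=table[element],
                        residue_key=key,
                    )
                )
            if not spheres:
                continue
            if res.het_flag == "H":
                if include_hetero:
                    hetero.extend(spheres)
                continue
            residues.append(partition_residue(spheres, res.name))

    if unknown:
        raise UnknownElementError(
            "no radius entry for atoms: " + ", ".join(unknown)
        )
    if not residues:
        raise ValueError(f"{path}: no ATOM records (polymer residues) found")
    return Molecule(residues=tuple(residues), hetero_atoms=tuple(hetero))


def assign_radii(molecule: Molecule, table: RadiusTable) -> Molecule:
    """Return a copy of ``molecule`` with every radius looked up in ``table``."""

    def conv(a: AtomSphere) -> AtomSphere:
        return replace(a, radius=table[a.element])

    residues = tuple(
        Residue(
            key=r.key,
            type=r.type,
            main_chain=tuple(conv(a) for a in r.main_chain),
            side_chain=tuple(conv(a) for a in r.side_chain),
            axis=r.axis,
            rotatable=r.rotatable,
        )
        for r in molecule.residues
    )
    hetero = tuple(conv(a) for a in molecule.hetero_atoms)
    return Molecule(residues=residues, hetero_atoms=hetero)


# ---------------------------------------------------------------------------
# tunnel dialect


def read_tunnel(path: str | Path) -> TunnelProfile:
    """Read a tunnel profile.

    Accepted forms: TSV with header ``t x y z r`` (whitespace-separated
    floats, Å), or a JSON array of ``{"t","x","y","z","r"}`` objects.
    ``t`` must be strictly increasing, radii positive, ≥2 samples.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped.startswith("["):
        rows = json.loads(text)
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(
            path, sep=r"\s+", comment="#", float_precision="round_trip"
        )
    missing = [c for c in ("t", "x", "y", "z", "r") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: tunnel file missing columns {missing}")
    if len(df) < 2:
        raise ValueError(f"{path}: tunnel needs at least 2 samples")
    return TunnelProfile(
        t=df["t"].to_numpy(float),
        centers=df[["x", "y", "z"]].to_numpy(float),
        radii=df["r"].to_numpy(float),
    )


def write_tunnel(tunnel: TunnelProfile, path: str | Path) -> None:
    """Write the TSV tunnel dialect with full-precision canonical floats."""
    path = Path(path)
    lines = ["t\tx\ty\tz\tr"]
    for t, c, r in zip(tunnel.t, tunnel.centers, tunnel.radii):
        vals = [t, c[0], c[1], c[2], r]
        lines.append("\t".join(f"{v:.17g}" for v in vals))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# result tables


def write_conformations_tsv(
    path: str | Path, residue_keys: Sequence[ResidueKey], conformations
) -> None:
    """Global conformations as TSV: one residue-keyed column per residue,
    one row of rotamer indices per conformation."""
    header = "\t".join(f"{c}:{n}{i}" for (c, n, i) in residue_keys)
    lines = [header]
    for conf in conformations:
        lines.append("\t".join(str(int(x)) for x in conf))
    Path(path).write_text("\n".join(lines) + "\n")


def write_conformations_json(
    path: str | Path, residue_keys: Sequence[ResidueKey], conformations
) -> None:
    conformations = [list(map(int, conf)) for conf in conformations]
    payload = {
        "residues": [list(k) for k in residue_keys],
        "conformations": conformations,
        "count": len(conformations),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
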