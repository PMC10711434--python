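"""Structure and trajectory ingestion, selection conventions and geometry.

This layer turns PDB/GRO structures and XTC/DCD/multi-model-PDB
trajectories into plain in-memory containers (coordinates in nm), applies
the donor/acceptor selection conventions for minor- and major-groove
binders, and provides the two descriptive geometry observables the
dissociation protocol uses: an approximate minor-groove width profile and
optimal-superposition RMSD.

Selection conventions
---------------------
Minor groove, one acceptor per nucleobase: purines (A, G) contribute N3,
pyrimidines (T, C) contribute O2. Major groove: G -> O6, A -> N7,
T -> O4; cytosine exposes no default acceptor there (its N4 is a donor)
but can be included through an override table.

Groove width dialect
--------------------
The full curvilinear-axis groove definition is not implemented. Instead,
the width at a base-pair step is the minimum cross-strand P-P distance
over a register offset of 1-3 steps, minus 0.58 nm (twice the phosphate
van-der-Waals radius). This preserves relative narrowing/widening trends,
which is what the protocol reads off the profile.
"""

from __future__ import annotations

import difflib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .atoms import AtomId
from .contacts import ContactMapSpec, ContactPair, SwitchingParams
from .errors import StructureError

logger = logging.getLogger(__name__)

ANGSTROM_PER_NM = 10.0

#: Twice the phosphate van-der-Waals radius (nm), subtracted from P-P
#: distances to report groove widths.
PHOSPHATE_VDW_CORRECTION = 0.58

#: Cross-strand register offsets scanned for the narrowest P-P distance.
GROOVE_OFFSETS = (1, 2, 3)

_NUCLEOTIDE_BASE = {
    "DA": "DA", "A": "DA", "ADE": "DA", "RA": "DA",
    "DT": "DT", "T": "DT", "THY": "DT",
    "DG": "DG", "G": "DG", "GUA": "DG", "RG": "DG",
    "DC": "DC", "C": "DC", "CYT": "DC", "RC": "DC",
}

PURINES = {"DA", "DG"}
PYRIMIDINES = {"DT", "DC"}

MINOR_GROOVE_ACCEPTOR = {"DA": "N3", "DG": "N3", "DT": "O2", "DC": "O2"}
MAJOR_GROOVE_ACCEPTOR = {"DG": "O6", "DA": "N7", "DT": "O4"}  # DC: none by default

#: Default H-NS DNA-binding-domain donor preset: backbone and side-chain
#: hydrogen-bond donors of the QGR loop (Q112, G113, R114) plus R93.
HNS_DONOR_PRESET: dict[str, tuple[tuple[int, str], ...]] = {
    "Q112": ((112, "N"), (112, "NE2")),
    "G113": ((113, "N"),),
    "R114": ((114, "N"), (114, "NE"), (114, "NH1"), (114, "NH2")),
    "R93": ((93, "N"), (93, "NE"), (93, "NH1"), (93, "NH2")),
}


def normalize_resname(resname: str) -> str | None:
    """Canonical two-letter deoxynucleotide name, or None if not a nucleotide.

    Tolerates common dialects (DA/ADE/A) and 5'/3' terminal suffixes
    (DA5, DA3).
    """
    name = resname.strip().upper()
    if name in _NUCLEOTIDE_BASE:
        return _NUCLEOTIDE_BASE[name]
    if len(name) >= 2 and name[-1] in "35" and name[:-1] in _NUCLEOTIDE_BASE:
        return _NUCLEOTIDE_BASE[name[:-1]]
    return None


@dataclass
class Structure:
    """Atoms plus one coordinate set (nm) and an optional orthorhombic box."""

    atoms: tuple[AtomId, ...]
    coords: np.ndarray
    box: np.ndarray | None = None
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.atoms = tuple(self.atoms)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise StructureError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,):
                raise StructureError("box must be three lengths (nm)")
        index: dict[tuple[str, int, str], int] = {}
        for i, a in enumerate(self.atoms):
            if a.key in index:
                raise StructureError(
                    f"duplicate atom {a.chain}/{a.resnum}/{a.name}: the "
                    "(chain, residue number, atom name) triplet must be unique"
                )
            index[a.key] = i
        self._index = index

    def __len__(self) -> int:
        return len(self.atoms)

    def index_of(self, atom: AtomId | tuple[str, int, str]) -> int:
        key = atom.key if isinstance(atom, AtomId) else tuple(atom)
        try:
            return self._index[key]
        except KeyError:
            raise StructureError(f"atom {key} not present in structure") from None

    def chains(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return tuple(seen)

    def residues(self, chain: str) -> list[tuple[int, str]]:
        """(resnum, resname) for `chain`, in residue-number order."""
        found: dict[int, str] = {}
        for a in self.atoms:
            if a.chain == chain:
                found.setdefault(a.resnum, a.resname)
        return sorted(found.items())

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(self.atoms, coords, self.box)


@dataclass
class Trajectory:
    """A topology plus an ordered stack of frames (nm) and times (ps)."""

    topology: Structure
    frames: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (
            len(self.topology),
            3,
        ):
            raise StructureError(
                f"frames must have shape (F, {len(self.topology)}, 3), "
                f"got {self.frames.shape}"
            )
        if self.times.shape != (self.frames.shape[0],):
            raise StructureError("one time per frame required")
        if self.frames.shape[0] > 1 and not np.all(np.diff(self.times) > 0):
            raise StructureError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass
class GrooveProfile:
    """Groove widths (nm) per base-pair position; NaN where undefined."""

    positions: np.ndarray
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.positions.shape != self.widths.shape:
            raise StructureError("positions and widths must align")
        defined = self.widths[~np.isnan(self.widths)]
        if np.any(defined < 0):
            raise StructureError("negative groove width")


# ---------------------------------------------------------------------------
# readers / writers (MDAnalysis-backed)
# ---------------------------------------------------------------------------


def _universe_to_structure(u) -> Structure:
    atoms = []
    try:
        chain_ids = u.atoms.chainIDs
    except Exception:
        try:
            chain_ids = u.atoms.segids
        except Exception:
            chain_ids = ["A"] * len(u.atoms)
    for a, cid in zip(u.atoms, chain_ids):
        cid = str(cid).strip() or "A"
        try:
            element = str(a.element).strip() or None
        except Exception:
            element = None
        atoms.append(
            AtomId(
                chain=cid,
                resname=str(a.resname).strip(),
                resnum=int(a.resid),
                name=str(a.name).strip(),
                serial=int(getattr(a, "id", a.index + 1)),
                element=element,
            )
        )
    coords = u.atoms.positions.astype(float) / ANGSTROM_PER_NM
    box = None
    dims = u.dimensions
    if dims is not None and np.all(np.asarray(dims[:3]) > 0):
        box = np.asarray(dims[:3], dtype=float) / ANGSTROM_PER_NM
    return Structure(tuple(atoms), coords, box)


def read_structure(path, fmt: str | None = None) -> Structure:
    """Read a PDB or GRO file into a :class:`Structure` (coordinates in nm)."""
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise StructureError(f"structure file not found: {path}")
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = suffix if suffix else None
    if fmt is not None and fmt.lower() not in {"pdb", "gro"}:
        raise StructureError(f"unknown structure format {fmt!r} (expected PDB or GRO)")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt)
    except StructureError:
        raise
    except Exception as exc:
        raise StructureError(f"failed to parse {path}: {exc}") from exc
    return _universe_to_structure(u)


def read_trajectory(topology_path, trajectory_path=None, fmt: str | None = None) -> Trajectory:
    """Read a trajectory (XTC, DCD or multi-model PDB) into memory.

    `topology_path` provides the atom records; `trajectory_path` the
    coordinates (omit it for a multi-model PDB). Times are taken from the
    file where present (ps); otherwise the frame index is used with a
    warning.
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise StructureError(f"topology file not found: {topology_path}")
    args = [str(topology_path)]
    if trajectory_path is not None:
        trajectory_path = Path(trajectory_path)
        if not trajectory_path.exists():
            raise StructureError(f"trajectory file not found: {trajectory_path}")
        args.append(str(trajectory_path))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(*args, format=fmt) if fmt else mda.Universe(*args)
    except Exception as exc:
        raise StructureError(f"failed to read trajectory: {exc}") from exc
    topology = _universe_to_structure(u)
    frames = []
    times = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            frames.append(u.atoms.positions.astype(float) / ANGSTROM_PER_NM)
            times.append(float(ts.time))
    times = np.asarray(times)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        logger.warning(
            "trajectory carries no usable frame times; using frame index (ps)"
        )
        times = np.arange(len(times), dtype=float)
    return Trajectory(topology, np.asarray(frames), times)


def write_pdb(structure: Structure, path) -> None:
    """Write a structure snapshot as PDB (nm converted back to Angstrom)."""
    import MDAnalysis as mda

    atoms = structure.atoms
    reskeys: list[tuple[str, int]] = []
    resindex = []
    for a in atoms:
        key = (a.chain, a.resnum)
        if key not in reskeys:
            reskeys.append(key)
        resindex.append(reskeys.index(key))
    chains = [k[0] for k in reskeys]
    chain_order: list[str] = []
    for c in chains:
        if c not in chain_order:
            chain_order.append(c)
    segindex = [chain_order.index(c) for c in chains]
    u = mda.Universe.empty(
        n_atoms=len(atoms),
        n_residues=len(reskeys),
        n_segments=len(chain_order),
        atom_resindex=np.asarray(resindex),
        residue_segindex=np.asarray(segindex),
        trajectory=True,
    )
    u.add_TopologyAttr("name", [a.name for a in atoms])
    u.add_TopologyAttr("resname", [atoms[_first_atom(resindex, ri)].resname for ri in range(len(reskeys))])
    u.add_TopologyAttr("resid", [k[1] for k in reskeys])
    u.add_TopologyAttr("segid", list(chain_order))
    u.add_TopologyAttr("chainID", [a.chain for a in atoms])
    u.add_TopologyAttr("element", [a.element or "" for a in atoms])
    u.atoms.positions = structure.coords * ANGSTROM_PER_NM
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def _first_atom(resindex: list[int], ri: int) -> int:
    return resindex.index(ri)


def merge_structures(a: Structure, b: Structure) -> Structure:
    """Concatenate two structures into one (atom keys must stay unique)."""
    return Structure(
        a.atoms + b.atoms, np.vstack([a.coords, b.coords]), a.box
    )


# ---------------------------------------------------------------------------
# selection conventions
# ---------------------------------------------------------------------------


def _resolve_base_atom(
    structure: Structure,
    chain: str,
    resnum: int,
    resname: str,
    atom_name: str,
) -> AtomId:
    key = (chain, resnum, atom_name)
    try:
        idx = structure.index_of(key)
    except StructureError:
        raise StructureError(
            f"base {resname}{resnum} on chain {chain} lacks expected "
            f"acceptor atom {atom_name}"
        ) from None
    return structure.atoms[idx]


def _iter_bases(
    structure: Structure, base_range: Mapping[str, Iterable[int]]
):
    if not base_range:
        raise StructureError("empty base range")
    for chain, resnums in base_range.items():
        residues = dict(structure.residues(chain))
        if not residues:
            raise StructureError(f"no residues on chain {chain!r}")
        for resnum in resnums:
            if resnum not in residues:
                raise StructureError(
                    f"residue {resnum} not found on chain {chain!r}"
                )
            resname = residues[resnum]
            base = normalize_resname(resname)
            if base is None:
                raise StructureError(
                    f"residue {resname}{resnum} on chain {chain!r} is not a "
                    "standard nucleotide"
                )
            yield chain, resnum, resname, base


def select_minor_groove_acceptors(
    structure: Structure, base_range: Mapping[str, Iterable[int]]
) -> list[AtomId]:
    """One minor-groove acceptor per base: purines N3, pyrimidines O2."""
    out = []
    for chain, resnum, resname, base in _iter_bases(structure, base_range):
        out.append(
            _resolve_base_atom(
                structure, chain, resnum, resname, MINOR_GROOVE_ACCEPTOR[base]
            )
        )
    return out


def select_major_groove_acceptors(
    structure: Structure,
    base_range: Mapping[str, Iterable[int]],
    overrides: Mapping[str, str] | None = None,
) -> list[AtomId]:
    """Per-base major-groove acceptor: G O6, A N7, T O4.

    Cytosine exposes no default acceptor in the major groove (N4 is a
    donor) and is skipped unless an override such as {"DC": "N4"} is
    given. Overrides may also replace the default atom of any base.
    """
    table = dict(MAJOR_GROOVE_ACCEPTOR)
    for resname, atom in (overrides or {}).items():
        base = normalize_resname(resname)
        if base is None:
            raise StructureError(f"override names non-nucleotide {resname!r}")
        table[base] = atom
    out = []
    for chain, resnum, resname, base in _iter_bases(structure, base_range):
        atom_name = table.get(base)
        if atom_name is None:
            continue
        out.append(
            _resolve_base_atom(structure, chain, resnum, resname, atom_name)
        )
    return out


def select_protein_donors(
    structure: Structure,
    donor_spec: Mapping[str, Iterable[tuple[int, str]]] = HNS_DONOR_PRESET,
    chain: str | None = None,
) -> dict[str, list[AtomId]]:
    """Resolve donor atoms grouped by residue label.

    `donor_spec` maps a group label (e.g. "Q112") to (residue number,
    atom name) entries. If `chain` is None the unique chain carrying the
    residue is used. Arginine has no NZ atom; a requested NZ on an
    arginine is remapped to NE with a warning (the guanidinium donor it
    almost certainly denotes).
    """
    out: dict[str, list[AtomId]] = {}
    for label, entries in donor_spec.items():
        resolved: list[AtomId] = []
        for resnum, atom_name in entries:
            candidates = [
                a
                for a in structure.atoms
                if a.resnum == resnum and (chain is None or a.chain == chain)
            ]
            if not candidates:
                where = f"chain {chain!r}" if chain else "any chain"
                raise StructureError(
                    f"residue {resnum} ({label}) not found on {where}"
                )
            resname = candidates[0].resname.upper()
            wanted = atom_name
            if wanted == "NZ" and resname in {"ARG", "R"}:
                logger.warning(
                    "%s%d has no NZ atom (arginine); remapping NZ -> NE",
                    resname,
                    resnum,
                )
                wanted = "NE"
            match = [a for a in candidates if a.name == wanted]
            if not match:
                names = sorted({a.name for a in candidates})
                hint = difflib.get_close_matches(wanted, names, n=1)
                suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
                raise StructureError(
                    f"residue {resname}{resnum} has no atom {wanted!r} "
                    f"(available: {', '.join(names)}){suggestion}"
                )
            resolved.append(match[0])
        out[label] = resolved
    return out


def build_contact_map(
    donors: Mapping[str, Sequence[AtomId]],
    acceptors: Sequence[AtomId],
    switching: SwitchingParams,
) -> ContactMapSpec:
    """All donor x acceptor pairs, grouped by donor label."""
    pairs = []
    for label, donor_atoms in donors.items():
        for d in donor_atoms:
            for a in acceptors:
                pairs.append(ContactPair(donor=d, acceptor=a, group=label))
    return ContactMapSpec(pairs=tuple(pairs), switching=switching)


# ---------------------------------------------------------------------------
# geometry observables
# ---------------------------------------------------------------------------


def _phosphorus_lookup(structure: Structure, chain: str) -> dict[int, int]:
    """resnum -> atom index of the backbone phosphorus on `chain`."""
    out = {}
    for i, a in enumerate(structure.atoms):
        if a.chain == chain and a.name == "P":
            out[a.resnum] = i
    return out


def minor_groove_width(
    trajectory: Trajectory,
    strands: tuple[str, str] = ("A", "B"),
    offsets: Sequence[int] = GROOVE_OFFSETS,
    vdw_correction: float = PHOSPHATE_VDW_CORRECTION,
) -> tuple[list[GrooveProfile], GrooveProfile]:
    """Minor-groove width profile per frame, plus the time average.

    Residue i on the first strand is assumed paired with residue N+1-i on
    the second (antiparallel duplex with matching residue numbering). The
    width at position i is the minimum over register offsets k of the
    distance |P1(i) - P2(pair(i)-k)| minus `vdw_correction`, reported as
    NaN where the needed phosphates are absent (5' termini).
    """
    top = trajectory.topology
    s1, s2 = strands
    res1 = [r for r, _ in top.residues(s1)]
    res2 = [r for r, _ in top.residues(s2)]
    if not res1 or not res2 or len(res1) != len(res2):
        raise StructureError(
            f"strands {s1!r} and {s2!r} do not form a duplex "
            f"({len(res1)} vs {len(res2)} residues)"
        )
    n = len(res1)
    p1 = _phosphorus_lookup(top, s1)
    p2 = _phosphorus_lookup(top, s2)
    frames = trajectory.frames
    widths = np.full((len(trajectory), n), np.nan)
    for pos in range(n):
        resnum1 = res1[pos]
        if resnum1 not in p1:
            continue
        pair_pos = n - 1 - pos  # index of the paired residue on strand 2
        candidates = []
        for k in offsets:
            j = pair_pos - k
            if 0 <= j < n and res2[j] in p2:
                candidates.append(p2[res2[j]])
        if not candidates:
            continue
        a = frames[:, p1[resnum1], :]  # (F, 3)
        d = np.linalg.norm(
            frames[:, candidates, :] - a[:, None, :], axis=-1
        )  # (F, n_cand)
        widths[:, pos] = np.clip(d.min(axis=1) - vdw_correction, 0.0, None)
    positions = np.asarray(res1)
    per_frame = [GrooveProfile(positions, widths[f]) for f in range(len(trajectory))]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_width = np.nanmean(widths, axis=0)
    return per_frame, GrooveProfile(positions, mean_width)


def superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Least-squares RMSD (nm) after optimal rotation + translation."""
    from scipy.spatial.transform import Rotation

    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise StructureError("coordinate sets must be matching (N, 3) arrays")
    mob = mob - mob.mean(axis=0)
    ref = ref - ref.mean(axis=0)
    _, rssd = Rotation.align_vectors(ref, mob)
    return float(rssd / np.sqrt(mob.shape[0]))


def rmsd_series(
    trajectory: Trajectory,
    reference: Structure,
    subset: Sequence[AtomId] | None = None,
) -> np.ndarray:
    """Optimal-superposition RMSD (nm) of each frame against `reference`.

    `subset` selects the atoms entering both the fit and the deviation;
    by default every reference atom is used and must exist in the
    trajectory topology.
    """
    top = trajectory.topology
    atoms = list(subset) if subset is not None else list(reference.atoms)
    try:
        ref_idx = [reference.index_of(a) for a in atoms]
        mob_idx = [top.index_of(a) for a in atoms]
    except StructureError as exc:
        raise StructureError(f"atom subset mismatch: {exc}") from None
    ref = reference.coords[ref_idx]
    out = np.empty(len(trajectory))
    for f in range(len(trajectory)):
        out[f] = superpose_rmsd(trajectory.frames[f][mob_idx], ref)
    return out
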