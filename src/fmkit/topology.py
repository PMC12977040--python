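"""GROMACS-dialect topology parsing, modification, and writing.

Supports the sections [defaults], [atomtypes], [bondtypes], [angletypes],
[dihedraltypes], [moleculetype], [atoms], [bonds], [pairs], [angles],
[dihedrals], [exclusions], [system], [molecules]; ``#include`` resolution
against a search path, simple ``#define`` token substitution and
``#ifdef``/``#ifndef``/``#else``/``#endif`` preprocessing.  Unknown sections
are preserved verbatim and re-emitted on writing.

Fittable bonded function types: bonds type 1, angles type 1, proper
dihedrals types 1 and 9, Ryckaert-Bellemans dihedrals type 3, improper
dihedrals type 2.  Other function types parse and round-trip but are not
part of the fittable inventory.

Indexing convention: files are 1-based, internal arrays 0-based; the
:class:`IndexMaps` held by :class:`QMRegion` is the only place conversions
happen.
"""

from __future__ import annotations

import copy
import itertools
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Topology", "MoleculeType", "BondedTerm", "AtomRecord", "QMRegion",
    "parse_topology", "parse_topology_string", "write_topology",
    "select_qm_region", "find_equivalent_atoms", "zero_qm_bonded",
    "update_topology", "read_gro", "write_gro",
]


class TopologyError(ValueError):
    pass


class SelectionError(ValueError):
    pass


# term kinds by GROMACS section + function type
_DIHEDRAL_KINDS = {1: "dihedral_periodic", 9: "dihedral_periodic",
                   3: "dihedral_RB", 2: "improper", 4: "improper_periodic"}
#: parameter slots whose zeroing removes the force (per kind)
FORCE_CONSTANT_SLOTS = {
    ("bond", 1): [1],
    ("angle", 1): [1],
    ("dihedral_periodic", 1): [1],
    ("dihedral_periodic", 9): [1],
    ("dihedral_RB", 3): [0, 1, 2, 3, 4, 5],
    ("improper", 2): [1],
    ("improper_periodic", 4): [1],
}
FITTABLE_KINDS = {("bond", 1), ("angle", 1), ("dihedral_periodic", 1),
                  ("dihedral_periodic", 9), ("dihedral_RB", 3), ("improper", 2)}


@dataclass
class AtomType:
    name: str
    mass: float = 0.0
    charge: float = 0.0
    ptype: str = "A"
    sigma: float = 0.0
    epsilon: float = 0.0


@dataclass
class MolAtom:
    nr: int                 # 1-based within the molecule
    type: str
    resnr: int
    resname: str
    name: str
    cgnr: int
    charge: float
    mass: float


@dataclass
class BondedTerm:
    kind: str                      # bond | angle | dihedral_* | improper*
    atoms: Tuple[int, ...]         # 0-based local indices
    funct: int
    params: List[float] = field(default_factory=list)
    fit_mask: Optional[List[bool]] = None

    @property
    def arity(self) -> int:
        return len(self.atoms)

    def copy(self) -> "BondedTerm":
        return BondedTerm(self.kind, tuple(self.atoms), self.funct,
                          list(self.params),
                          None if self.fit_mask is None else list(self.fit_mask))


@dataclass
class MoleculeType:
    name: str
    nrexcl: int = 3
    atoms: List[MolAtom] = field(default_factory=list)
    bonds: List[BondedTerm] = field(default_factory=list)
    pairs: List[BondedTerm] = field(default_factory=list)
    angles: List[BondedTerm] = field(default_factory=list)
    dihedrals: List[BondedTerm] = field(default_factory=list)
    exclusions: List[Tuple[int, ...]] = field(default_factory=list)  # 0-based
    raw_sections: List[Tuple[str, List[str]]] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def bonded_terms(self) -> List[BondedTerm]:
        return list(self.bonds) + list(self.angles) + list(self.dihedrals)

    def bond_graph(self) -> Dict[int, Set[int]]:
        adj: Dict[int, Set[int]] = {i: set() for i in range(self.n_atoms)}
        for b in self.bonds:
            i, j = b.atoms
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def build_exclusions(self) -> Set[frozenset]:
        """All excluded local pairs: bond graph out to nrexcl, plus explicit."""
        adj = self.bond_graph()
        excl: Set[frozenset] = set()
        for start in range(self.n_atoms):
            seen = {start}
            frontier = {start}
            for _ in range(self.nrexcl):
                frontier = {n for f in frontier for n in adj[f]} - seen
                for n in frontier:
                    excl.add(frozenset((start, n)))
                seen |= frontier
        for ex in self.exclusions:
            a0 = ex[0]
            for other in ex[1:]:
                excl.add(frozenset((a0, other)))
        return excl


@dataclass
class AtomRecord:
    """Global view of one atom after expanding [molecules]."""
    global_index: int     # 1-based
    name: str
    type: str
    resnr: int
    resname: str
    charge: float
    mass: float
    molecule: str         # molecule type name
    mol_instance: int     # 0-based instance counter over the whole system
    local_index: int      # 0-based within the molecule


@dataclass
class Topology:
    defaults: Optional[dict] = None
    atomtypes: Dict[str, AtomType] = field(default_factory=dict)
    bondtypes: Dict[tuple, tuple] = field(default_factory=dict)
    angletypes: Dict[tuple, tuple] = field(default_factory=dict)
    dihedraltypes: Dict[tuple, list] = field(default_factory=dict)
    moleculetypes: Dict[str, MoleculeType] = field(default_factory=dict)
    system: Optional[str] = None
    molecules: List[Tuple[str, int]] = field(default_factory=list)
    raw_sections: List[Tuple[str, List[str]]] = field(default_factory=list)

    # -- defaults ----------------------------------------------------------
    @property
    def comb_rule(self) -> int:
        return int((self.defaults or {}).get("comb_rule", 2))

    @property
    def fudge_lj(self) -> float:
        return float((self.defaults or {}).get("fudge_lj", 0.5))

    @property
    def fudge_qq(self) -> float:
        return float((self.defaults or {}).get("fudge_qq", 0.8333))

    # -- global views ------------------------------------------------------
    def expand_atoms(self) -> List[AtomRecord]:
        records: List[AtomRecord] = []
        gidx = 0
        instance = 0
        for molname, count in self._molecule_list():
            mt = self.moleculetypes[molname]
            for _ in range(count):
                for a in mt.atoms:
                    gidx += 1
                    records.append(AtomRecord(
                        global_index=gidx, name=a.name, type=a.type,
                        resnr=a.resnr, resname=a.resname, charge=a.charge,
                        mass=a.mass, molecule=molname,
                        mol_instance=instance, local_index=a.nr - 1))
                instance += 1
        return records

    def _molecule_list(self) -> List[Tuple[str, int]]:
        if self.molecules:
            return self.molecules
        # itp-style file without [molecules]: treat each type once, in order
        return [(name, 1) for name in self.moleculetypes]

    @property
    def atoms(self) -> List[AtomRecord]:
        return self.expand_atoms()

    @property
    def n_atoms(self) -> int:
        return sum(self.moleculetypes[m].n_atoms * c
                   for m, c in self._molecule_list())

    def lj_parameters(self, type_name: str) -> Tuple[float, float]:
        try:
            at = self.atomtypes[type_name]
        except KeyError:
            raise TopologyError(f"no LJ parameters for atom type {type_name!r}")
        return at.sigma, at.epsilon

    def copy(self) -> "Topology":
        return copy.deepcopy(self)

    def dumps(self) -> str:
        return _dump_topology(self)


# ---------------------------------------------------------------------------
# preprocessing

_INCLUDE_RE = re.compile(r'#include\s+"([^"]+)"')


def _preprocess(lines, src: Path, search_dirs, defines) -> List[str]:
    out: List[str] = []
    skip_stack: List[bool] = []

    def active() -> bool:
        return not any(skip_stack)

    pending = ""
    for raw in lines:
        line = raw.split(";", 1)[0].rstrip("\n")
        if line.endswith("\\"):
            pending += line[:-1] + " "
            continue
        line = pending + line
        pending = ""
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            tokens = stripped.split()
            directive = tokens[0]
            if directive == "#ifdef":
                skip_stack.append(tokens[1] not in defines)
            elif directive == "#ifndef":
                skip_stack.append(tokens[1] in defines)
            elif directive == "#else":
                if not skip_stack:
                    raise TopologyError(f"{src}: #else without #ifdef")
                skip_stack[-1] = not skip_stack[-1]
            elif directive == "#endif":
                if not skip_stack:
                    raise TopologyError(f"{src}: #endif without #ifdef")
                skip_stack.pop()
            elif not active():
                continue
            elif directive == "#define":
                if len(tokens) >= 2:
                    defines[tokens[1]] = tokens[2:]
            elif directive == "#undef":
                defines.pop(tokens[1], None)
            elif directive == "#include":
                m = _INCLUDE_RE.match(stripped)
                if not m:
                    raise TopologyError(f"{src}: malformed include: {stripped}")
                target = _resolve_include(m.group(1), src, search_dirs)
                with open(target) as fh:
                    out.extend(_preprocess(fh, target, search_dirs, defines))
            else:
                raise TopologyError(f"{src}: unknown directive {directive}")
            continue
        if not active():
            continue
        # substitute defined parameter macros token-wise
        if defines:
            tokens = stripped.split()
            expanded: List[str] = []
            for t in tokens:
                if t in defines:
                    expanded.extend(defines[t])
                else:
                    expanded.append(t)
            stripped = " ".join(expanded)
        out.append(stripped)
    return out


def _resolve_include(name: str, src: Path, search_dirs) -> Path:
    candidates = [src.parent / name] + [Path(d) / name for d in search_dirs]
    for c in candidates:
        if c.exists():
            return c
    raise TopologyError(f"{src}: cannot resolve include {name!r} "
                        f"(searched {[str(c) for c in candidates]})")


# ---------------------------------------------------------------------------
# parsing

_SECTION_RE = re.compile(r"\[\s*([^\]\s]+)\s*\]")

_KNOWN_SECTIONS = {
    "defaults", "atomtypes", "bondtypes", "angletypes", "dihedraltypes",
    "moleculetype", "atoms", "bonds", "pairs", "angles", "dihedrals",
    "exclusions", "system", "molecules",
}


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def parse_topology(path, search_dirs: Sequence = (), defines: Optional[dict] = None
                   ) -> Topology:
    """Parse a .top/.itp file, resolving includes depth-first."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        lines = _preprocess(fh, path, list(search_dirs), dict(defines or {}))
    return _parse_lines(lines)


def parse_topology_string(text: str) -> Topology:
    lines = _preprocess(text.splitlines(), Path("<string>"), [], {})
    return _parse_lines(lines)


def _parse_lines(lines: List[str]) -> Topology:
    top = Topology()
    section = None
    current_mol: Optional[MoleculeType] = None
    raw_bucket: Optional[List[str]] = None

    for line in lines:
        m = _SECTION_RE.match(line)
        if m:
            section = m.group(1).lower()
            raw_bucket = None
            if section not in _KNOWN_SECTIONS:
                warnings.warn(f"unknown topology section [{section}]: preserved "
                              "verbatim", stacklevel=2)
                raw_bucket = []
                target = current_mol.raw_sections if current_mol else top.raw_sections
                target.append((section, raw_bucket))
            continue
        if raw_bucket is not None:
            raw_bucket.append(line)
            continue
        if section is None:
            raise TopologyError(f"data line outside any section: {line!r}")
        tok = line.split()
        if section == "defaults":
            top.defaults = _parse_defaults(tok)
        elif section == "atomtypes":
            at = _parse_atomtype(tok)
            top.atomtypes[at.name] = at
        elif section == "bondtypes":
            key = tuple(sorted((tok[0], tok[1])))
            top.bondtypes[key] = (int(tok[2]), [float(x) for x in tok[3:]])
        elif section == "angletypes":
            key = _canon_angle_key((tok[0], tok[1], tok[2]))
            top.angletypes[key] = (int(tok[3]), [float(x) for x in tok[4:]])
        elif section == "dihedraltypes":
            _parse_dihedraltype(top, tok)
        elif section == "moleculetype":
            current_mol = MoleculeType(name=tok[0], nrexcl=int(tok[1]))
            top.moleculetypes[current_mol.name] = current_mol
        elif section == "system":
            top.system = line
        elif section == "molecules":
            top.molecules.append((tok[0], int(tok[1])))
        else:
            if current_mol is None:
                raise TopologyError(f"[{section}] outside a moleculetype")
            _parse_mol_section(current_mol, section, tok, top)

    _resolve_parameters(top)
    return top


def _parse_defaults(tok: List[str]) -> dict:
    d = {"nbfunc": int(tok[0]), "comb_rule": int(tok[1])}
    if len(tok) > 2:
        d["gen_pairs"] = tok[2]
    if len(tok) > 3:
        d["fudge_lj"] = float(tok[3])
    if len(tok) > 4:
        d["fudge_qq"] = float(tok[4])
    return d


def _parse_atomtype(tok: List[str]) -> AtomType:
    # Layouts: name [btype] [at.num] mass charge ptype sigma epsilon
    ptype_idx = next((i for i, t in enumerate(tok)
                      if t in ("A", "S", "V", "D") and i >= 2), None)
    if ptype_idx is None or ptype_idx + 2 >= len(tok) + 0:
        raise TopologyError(f"unparseable atomtype line: {' '.join(tok)}")
    sigma = float(tok[ptype_idx + 1]) if ptype_idx + 1 < len(tok) else 0.0
    epsilon = float(tok[ptype_idx + 2]) if ptype_idx + 2 < len(tok) else 0.0
    return AtomType(name=tok[0], mass=float(tok[ptype_idx - 2]),
                    charge=float(tok[ptype_idx - 1]), ptype=tok[ptype_idx],
                    sigma=sigma, epsilon=epsilon)


def _canon_angle_key(key: Tuple[str, str, str]) -> tuple:
    rev = key[::-1]
    return min(key, rev)


def _canon_dihedral_key(key: Tuple[str, ...]) -> tuple:
    rev = key[::-1]
    return min(key, rev)


def _parse_dihedraltype(top: Topology, tok: List[str]) -> None:
    n_types = 0
    while n_types < len(tok) and not _is_number(tok[n_types]):
        n_types += 1
    if n_types == 2:       # old 2-atom (inner atoms) form
        key = _canon_dihedral_key(("X", tok[0], tok[1], "X"))
        rest = tok[2:]
    elif n_types == 4:
        key = _canon_dihedral_key(tuple(tok[:4]))
        rest = tok[4:]
    else:
        raise TopologyError(f"unparseable dihedraltype line: {' '.join(tok)}")
    entry = (int(rest[0]), [float(x) for x in rest[1:]])
    top.dihedraltypes.setdefault(key, []).append(entry)


def _parse_mol_section(mol: MoleculeType, section: str, tok: List[str],
                       top: Topology) -> None:
    if section == "atoms":
        nr = int(tok[0])
        type_ = tok[1]
        at = top.atomtypes.get(type_)
        charge = float(tok[6]) if len(tok) > 6 else (at.charge if at else 0.0)
        mass = float(tok[7]) if len(tok) > 7 else (at.mass if at else 0.0)
        mol.atoms.append(MolAtom(nr=nr, type=type_, resnr=int(tok[2]),
                                 resname=tok[3], name=tok[4], cgnr=int(tok[5]),
                                 charge=charge, mass=mass))
    elif section in ("bonds", "pairs"):
        i, j = int(tok[0]) - 1, int(tok[1]) - 1
        funct = int(tok[2]) if len(tok) > 2 else 1
        params = [float(x) for x in tok[3:]]
        term = BondedTerm("bond" if section == "bonds" else "pair",
                          (i, j), funct, params)
        getattr(mol, section).append(term)
    elif section == "angles":
        atoms = tuple(int(t) - 1 for t in tok[:3])
        funct = int(tok[3]) if len(tok) > 3 else 1
        mol.angles.append(BondedTerm("angle", atoms, funct,
                                     [float(x) for x in tok[4:]]))
    elif section == "dihedrals":
        atoms = tuple(int(t) - 1 for t in tok[:4])
        funct = int(tok[4]) if len(tok) > 4 else 1
        kind = _DIHEDRAL_KINDS.get(funct, f"dihedral_funct{funct}")
        mol.dihedrals.append(BondedTerm(kind, atoms, funct,
                                        [float(x) for x in tok[5:]]))
    elif section == "exclusions":
        mol.exclusions.append(tuple(int(t) - 1 for t in tok))
    else:  # pragma: no cover
        raise TopologyError(f"unhandled section [{section}]")


def _resolve_parameters(top: Topology) -> None:
    """Fill missing inline bonded parameters from the type tables."""
    for mol in top.moleculetypes.values():
        types = [a.type for a in mol.atoms]
        for b in mol.bonds:
            if not b.params:
                key = tuple(sorted((types[b.atoms[0]], types[b.atoms[1]])))
                hit = top.bondtypes.get(key)
                if hit and hit[0] == b.funct:
                    b.params = list(hit[1])
        for a in mol.angles:
            if not a.params:
                key = _canon_angle_key(tuple(types[i] for i in a.atoms))
                hit = top.angletypes.get(key)
                if hit and hit[0] == a.funct:
                    a.params = list(hit[1])
        expanded: List[BondedTerm] = []
        for d in mol.dihedrals:
            if d.params:
                expanded.append(d)
                continue
            hits = _lookup_dihedraltype(top, [types[i] for i in d.atoms], d.funct)
            if not hits:
                log.warning("molecule %s: no parameters for %s %s",
                            mol.name, d.kind, d.atoms)
                expanded.append(d)
                continue
            for funct, params in hits:
                expanded.append(BondedTerm(d.kind, d.atoms, d.funct, list(params)))
        mol.dihedrals = expanded


def _lookup_dihedraltype(top: Topology, types: List[str], funct: int) -> list:
    t = tuple(types)
    patterns = [t, ("X", t[1], t[2], "X"), (t[0], t[1], t[2], "X"),
                ("X", t[1], t[2], t[3])]
    for pat in patterns:
        hits = top.dihedraltypes.get(_canon_dihedral_key(pat))
        if hits:
            matching = [h for h in hits if h[0] == funct]
            if matching:
                return matching
    return []


# ---------------------------------------------------------------------------
# writing

def _fmt(x: float) -> str:
    return f"{x:.12g}"


def _dump_topology(top: Topology) -> str:
    out: List[str] = []

    def sec(name: str) -> None:
        out.append(f"[ {name} ]")

    if top.defaults is not None:
        sec("defaults")
        d = top.defaults
        line = f"{d['nbfunc']} {d['comb_rule']}"
        if "gen_pairs" in d:
            line += f" {d['gen_pairs']}"
        if "fudge_lj" in d:
            line += f" {_fmt(d['fudge_lj'])}"
        if "fudge_qq" in d:
            line += f" {_fmt(d['fudge_qq'])}"
        out.append(line)
        out.append("")
    if top.atomtypes:
        sec("atomtypes")
        for at in top.atomtypes.values():
            out.append(f"{at.name:<8s} {_fmt(at.mass):>12s} {_fmt(at.charge):>12s} "
                       f"{at.ptype} {_fmt(at.sigma):>14s} {_fmt(at.epsilon):>14s}")
        out.append("")
    if top.bondtypes:
        sec("bondtypes")
        for (t1, t2), (funct, params) in top.bondtypes.items():
            out.append(f"{t1:<6s} {t2:<6s} {funct} "
                       + " ".join(_fmt(p) for p in params))
        out.append("")
    if top.angletypes:
        sec("angletypes")
        for key, (funct, params) in top.angletypes.items():
            out.append(" ".join(f"{t:<6s}" for t in key) + f" {funct} "
                       + " ".join(_fmt(p) for p in params))
        out.append("")
    if top.dihedraltypes:
        sec("dihedraltypes")
        for key, entries in top.dihedraltypes.items():
            for funct, params in entries:
                out.append(" ".join(f"{t:<6s}" for t in key) + f" {funct} "
                           + " ".join(_fmt(p) for p in params))
        out.append("")
    for name, lines in top.raw_sections:
        sec(name)
        out.extend(lines)
        out.append("")
    for mol in top.moleculetypes.values():
        sec("moleculetype")
        out.append(f"{mol.name} {mol.nrexcl}")
        out.append("")
        sec("atoms")
        for a in mol.atoms:
            out.append(f"{a.nr:>6d} {a.type:<8s} {a.resnr:>6d} {a.resname:<6s} "
                       f"{a.name:<6s} {a.cgnr:>6d} {a.charge:>14.10f} "
                       f"{a.mass:>12.6f}")
        out.append("")
        for section, terms in (("bonds", mol.bonds), ("pairs", mol.pairs),
                               ("angles", mol.angles), ("dihedrals", mol.dihedrals)):
            if not terms:
                continue
            sec(section)
            for t in terms:
                idx = " ".join(f"{i + 1:>6d}" for i in t.atoms)
                out.append(f"{idx} {t.funct} " + " ".join(_fmt(p) for p in t.params))
            out.append("")
        if mol.exclusions:
            sec("exclusions")
            for ex in mol.exclusions:
                out.append(" ".join(f"{i + 1:>6d}" for i in ex))
            out.append("")
        for name, lines in mol.raw_sections:
            sec(name)
            out.extend(lines)
            out.append("")
    if top.system is not None:
        sec("system")
        out.append(top.system)
        out.append("")
    if top.molecules:
        sec("molecules")
        for name, count in top.molecules:
            out.append(f"{name:<12s} {count}")
        out.append("")
    return "\n".join(out) + "\n"


def write_topology(topology: Topology, path, prefix: str = "") -> Path:
    """Write a topology file; ``prefix`` is prepended to the file name.

    ``write_topology(top, "topol.itp", prefix="opt_")`` writes
    ``opt_topol.itp`` next to the requested path.  The include graph is
    flattened: all resolved content is emitted into the single output file.
    """
    path = Path(path)
    out = path.parent / (prefix + path.name)
    out.write_text(topology.dumps())
    return out


# ---------------------------------------------------------------------------
# QM region

@dataclass
class IndexMaps:
    """Bijections among file (1-based global), internal slot (0-based, sorted
    ascending by global index) and reference-data orderings."""

    global_ids: np.ndarray                 # slot -> global 1-based

    def __post_init__(self):
        self.global_ids = np.asarray(self.global_ids, int)
        self._g2s = {int(g): s for s, g in enumerate(self.global_ids)}

    @property
    def n(self) -> int:
        return self.global_ids.size

    def slot_of(self, global_id: int) -> int:
        return self._g2s[int(global_id)]

    def global_of(self, slot: int) -> int:
        return int(self.global_ids[slot])

    def dataset_order(self, dataset_qm_ids) -> np.ndarray:
        """Permutation p with p[i] = internal slot of dataset atom i."""
        ids = np.asarray(dataset_qm_ids, int)
        if sorted(ids.tolist()) != sorted(self.global_ids.tolist()):
            raise TopologyError(
                "reference-data QM atom ids do not match the QM region: "
                f"{ids.tolist()} vs {self.global_ids.tolist()}")
        return np.array([self._g2s[int(g)] for g in ids], int)


@dataclass
class FittableTerm:
    """A bonded term fully inside the QM region, addressable for fitting."""
    kind: str
    funct: int
    molecule: str
    section: str            # bonds | angles | dihedrals
    term_index: int         # index into the moleculetype's section list
    global_atoms: Tuple[int, ...]
    slots: Tuple[int, ...]  # internal QM slot per atom
    params: List[float]
    type_signature: Tuple[str, ...]


@dataclass
class QMRegion:
    qm_atom_ids: np.ndarray               # sorted global 1-based indices
    index_maps: IndexMaps
    equivalence_groups: List[List[int]]   # global ids
    boundary_atoms: List[int]             # global ids
    fittable: List[FittableTerm]
    bond_graph: Dict[int, Set[int]]       # intra-QM adjacency on global ids
    atom_records: List[AtomRecord]        # QM atoms, slot order

    @property
    def n_atoms(self) -> int:
        return self.qm_atom_ids.size

    def original_charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atom_records])

    def atom_types(self) -> List[str]:
        return [a.type for a in self.atom_records]

    def group_index(self) -> np.ndarray:
        """Per-slot equivalence-group index."""
        gi = np.full(self.n_atoms, -1, int)
        for g, members in enumerate(self.equivalence_groups):
            for gid in members:
                gi[self.index_maps.slot_of(gid)] = g
        if (gi < 0).any():
            raise TopologyError("equivalence groups do not cover the QM region")
        return gi


# -- selection grammar -----------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _SelParser:
    """resname/resid/name/type/index primitives with and/or/not and ranges."""

    _keywords = ("resname", "resid", "resnr", "name", "type", "index", "all")

    def __init__(self, text: str, atoms: List[AtomRecord]):
        self.tokens = _TOKEN_RE.findall(text)
        self.pos = 0
        self.atoms = atoms

    def parse(self) -> Set[int]:
        if not self.tokens:
            raise SelectionError("empty selection string")
        result = self._expr()
        if self.pos != len(self.tokens):
            raise SelectionError(
                f"unexpected token {self.tokens[self.pos]!r} at position {self.pos}")
        return result

    def _peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> str:
        tok = self._peek()
        if tok is None:
            raise SelectionError("unexpected end of selection")
        self.pos += 1
        return tok

    def _expr(self) -> Set[int]:
        left = self._term()
        while self._peek() == "or":
            self._next()
            left = left | self._term()
        return left

    def _term(self) -> Set[int]:
        left = self._factor()
        while self._peek() == "and":
            self._next()
            left = left & self._factor()
        return left

    def _factor(self) -> Set[int]:
        tok = self._peek()
        if tok == "not":
            self._next()
            universe = {a.global_index for a in self.atoms}
            return universe - self._factor()
        if tok == "(":
            self._next()
            inner = self._expr()
            if self._next() != ")":
                raise SelectionError(f"missing ')' near position {self.pos}")
            return inner
        return self._primitive()

    def _values(self) -> List[str]:
        vals: List[str] = []
        stop = {"and", "or", "not", "(", ")"} | set(self._keywords)
        while True:
            tok = self._peek()
            if tok is None or tok in stop:
                break
            vals.append(self._next())
        if not vals:
            raise SelectionError(f"keyword at position {self.pos} has no values")
        return vals

    def _primitive(self) -> Set[int]:
        kw = self._next()
        if kw == "all":
            return {a.global_index for a in self.atoms}
        if kw not in self._keywords:
            raise SelectionError(
                f"unknown selection keyword {kw!r} at position {self.pos - 1}")
        vals = self._values()
        if kw in ("resid", "resnr", "index"):
            numbers = _expand_ranges(vals)
            if kw == "index":
                return {a.global_index for a in self.atoms
                        if a.global_index in numbers}
            return {a.global_index for a in self.atoms if a.resnr in numbers}
        wanted = set(vals)
        attr = {"resname": "resname", "name": "name", "type": "type"}[kw]
        return {a.global_index for a in self.atoms
                if getattr(a, attr) in wanted}


def _expand_ranges(vals: List[str]) -> Set[int]:
    numbers: Set[int] = set()
    i = 0
    while i < len(vals):
        v = vals[i]
        if i + 2 < len(vals) and vals[i + 1] == "to":
            numbers.update(range(int(v), int(vals[i + 2]) + 1))
            i += 3
        elif "-" in v[1:]:
            lo, hi = v[0] + v[1:].split("-", 1)[0], v[1:].split("-", 1)[1]
            numbers.update(range(int(lo), int(hi) + 1))
            i += 1
        else:
            numbers.add(int(v))
            i += 1
    return numbers


def select_qm_region(topology: Topology, coordinates: Optional[np.ndarray] = None,
                     selection: str = "all") -> QMRegion:
    """Build the QM region from a selection string.

    ``coordinates`` is accepted for interface completeness (the grammar is
    name/index based and does not require positions).
    """
    atoms = topology.expand_atoms()
    try:
        selected = _SelParser(selection, atoms).parse()
    except SelectionError:
        raise
    if not selected:
        raise SelectionError(f"selection {selection!r} matched no atoms")
    qm_ids = np.array(sorted(selected), int)
    by_gid = {a.global_index: a for a in atoms}
    records = [by_gid[int(g)] for g in qm_ids]
    maps = IndexMaps(qm_ids)

    # per-instance global bond graph restricted to molecules containing QM atoms
    bond_graph: Dict[int, Set[int]] = {int(g): set() for g in qm_ids}
    boundary: Set[int] = set()
    fittable: List[FittableTerm] = []
    offset = 0
    for molname, count in topology._molecule_list():
        mt = topology.moleculetypes[molname]
        for _ in range(count):
            base = offset  # global index of local atom 0 is base+1
            local_gids = range(base + 1, base + mt.n_atoms + 1)
            if any(g in selected for g in local_gids):
                _collect_instance_terms(mt, molname, base, selected, maps,
                                        bond_graph, boundary, fittable)
            offset += mt.n_atoms
    for t in fittable:
        t.type_signature = _term_signature(t, by_gid)
    groups = find_equivalent_atoms(topology, qm_ids, bond_graph, by_gid)
    return QMRegion(qm_atom_ids=qm_ids, index_maps=maps,
                    equivalence_groups=groups,
                    boundary_atoms=sorted(boundary), fittable=fittable,
                    bond_graph=bond_graph, atom_records=records)


def _collect_instance_terms(mt: MoleculeType, molname: str, base: int,
                            selected: Set[int], maps: IndexMaps,
                            bond_graph, boundary, fittable) -> None:
    for b in mt.bonds:
        g = tuple(base + i + 1 for i in b.atoms)
        inside = [x in selected for x in g]
        if all(inside):
            bond_graph[g[0]].add(g[1])
            bond_graph[g[1]].add(g[0])
        elif any(inside):
            boundary.add(g[0] if inside[0] else g[1])
    for section, terms in (("bonds", mt.bonds), ("angles", mt.angles),
                           ("dihedrals", mt.dihedrals)):
        for idx, t in enumerate(terms):
            g = tuple(base + i + 1 for i in t.atoms)
            if all(x in selected for x in g) and (t.kind, t.funct) in FITTABLE_KINDS:
                fittable.append(FittableTerm(
                    kind=t.kind, funct=t.funct, molecule=molname,
                    section=section, term_index=idx, global_atoms=g,
                    slots=tuple(maps.slot_of(x) for x in g),
                    params=list(t.params), type_signature=()))


def _term_signature(t: FittableTerm, by_gid) -> Tuple[str, ...]:
    types = tuple(by_gid[g].type for g in t.global_atoms)
    rev = types[::-1]
    sig = min(types, rev)
    return (t.kind, str(t.funct)) + sig


def find_equivalent_atoms(topology: Topology, qm_atom_ids=None,
                          bond_graph: Optional[dict] = None,
                          by_gid: Optional[dict] = None,
                          region: Optional[QMRegion] = None) -> List[List[int]]:
    """Partition QM atoms into chemically equivalent groups.

    Two atoms are equivalent iff they have the same atom type and occupy
    automorphic positions in the intra-QM bond graph, detected by iterative
    neighborhood (color) refinement seeded with the atom types.
    """
    if region is not None:
        qm_atom_ids = region.qm_atom_ids
        bond_graph = region.bond_graph
        by_gid = {a.global_index: a for a in region.atom_records}
    if by_gid is None:
        by_gid = {a.global_index: a for a in topology.expand_atoms()}
    ids = [int(g) for g in qm_atom_ids]
    color = {g: by_gid[g].type for g in ids}
    for _ in range(len(ids)):
        new = {}
        for g in ids:
            neigh = sorted(color[n] for n in bond_graph.get(g, ()) if n in color)
            new[g] = color[g] + "|" + ",".join(neigh)
        # compress labels
        labels = {c: str(i) for i, c in enumerate(sorted(set(new.values())))}
        new = {g: by_gid[g].type + "#" + labels[new[g]] for g in ids}
        if len(set(new.values())) == len(set(color.values())):
            color = new
            break
        color = new
    groups: Dict[str, List[int]] = {}
    for g in ids:
        groups.setdefault(color[g], []).append(g)
    return sorted((sorted(v) for v in groups.values()), key=lambda v: v[0])


# ---------------------------------------------------------------------------
# modification

def _qm_moltypes(topology: Topology, qm_ids: Set[int]):
    """Yield (moltype, base_offset, local QM set); error if a multi-instance
    molecule type is only partially in the QM region."""
    seen: Dict[str, Set[int]] = {}
    counts: Dict[str, int] = {}
    offset = 0
    result = []
    for molname, count in topology._molecule_list():
        mt = topology.moleculetypes[molname]
        counts[molname] = counts.get(molname, 0) + count
        for _ in range(count):
            local = {g - offset - 1 for g in qm_ids
                     if offset < g <= offset + mt.n_atoms}
            if local:
                if molname in seen and seen[molname] != local:
                    raise TopologyError(
                        f"QM region covers instances of molecule type {molname!r} "
                        "differently; split the molecule type first")
                seen[molname] = local
                result.append((molname, offset, local))
            offset += mt.n_atoms
    multi = [m for m, _, _ in result
             if counts[m] > 1]
    if multi:
        raise TopologyError(
            f"QM region touches multi-copy molecule type(s) {sorted(set(multi))}; "
            "modifications at the molecule-type level would affect all copies")
    return result


def zero_qm_bonded(topology: Topology, region: QMRegion) -> Topology:
    """Return a topology whose bonded force constants are zeroed for every
    term touching at least one QM atom; geometry parameters are untouched."""
    new = topology.copy()
    qm = {int(g) for g in region.qm_atom_ids}
    if not qm:
        return new
    for molname, offset, local in _qm_moltypes(new, qm):
        mt = new.moleculetypes[molname]
        for terms in (mt.bonds, mt.angles, mt.dihedrals):
            for t in terms:
                if not any(a in local for a in t.atoms):
                    continue
                slots = FORCE_CONSTANT_SLOTS.get((t.kind, t.funct))
                if slots is None:
                    raise TopologyError(
                        f"cannot zero force constants of unsupported term "
                        f"{t.kind} funct {t.funct} in molecule {molname!r}")
                for s in slots:
                    if s < len(t.params):
                        t.params[s] = 0.0
    return new


def update_topology(topology: Topology, charges=None, params=None) -> Topology:
    """Return a topology with QM charges and/or fitted bonded parameters
    replaced; everything else is unchanged in the semantic model.

    ``charges`` is a ChargeSet (``atom_ids`` + ``q``); ``params`` is a
    BondedParameterSet whose groups reference fittable terms.
    """
    new = topology.copy()
    if charges is not None:
        qm = {int(g) for g in np.asarray(charges.atom_ids, int)}
        target = {}
        for molname, offset, local in _qm_moltypes(new, qm):
            for li in local:
                target[offset + li + 1] = (molname, li)
        for gid, q in zip(np.asarray(charges.atom_ids, int),
                          np.asarray(charges.q, float)):
            if int(gid) not in target:
                raise TopologyError(f"charge update: atom {gid} not resolvable")
            molname, li = target[int(gid)]
            new.moleculetypes[molname].atoms[li].charge = float(q)
    if params is not None:
        for group in params.groups:
            for ft in group.terms:
                mt = new.moleculetypes[ft.molecule]
                term = getattr(mt, ft.section)[ft.term_index]
                vals = group.full_params()
                if len(vals) != len(term.params):
                    raise TopologyError(
                        f"parameter update: slot count mismatch for "
                        f"{ft.kind} term {ft.term_index} in {ft.molecule!r}")
                term.params = [float(v) for v in vals]
    return new


# ---------------------------------------------------------------------------
# minimal .gro coordinate I/O (fixed-column format)

def read_gro(path) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Read positions (n,3) nm and box lengths from a .gro file."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[1])
    pos = np.empty((n, 3))
    for i in range(n):
        ln = lines[2 + i]
        pos[i] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
    box_tokens = lines[2 + n].split()
    box = np.array([float(x) for x in box_tokens[:3]]) if box_tokens else None
    return pos, box


def write_gro(path, positions: np.ndarray, atoms: List[AtomRecord],
              box: Optional[np.ndarray] = None, title: str = "fmkit") -> None:
    positions = np.asarray(positions, float)
    lines = [title, f"{len(atoms):5d}"]
    for a, p in zip(atoms, positions):
        lines.append(f"{a.resnr % 100000:5d}{a.resname:<5.5s}{a.name:>5.5s}"
                     f"{a.global_index % 100000:5d}"
                     f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}")
    b = box if box is not None else np.zeros(3)
    lines.append(f"{b[0]:10.5f}{b[1]:10.5f}{b[2]:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")
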