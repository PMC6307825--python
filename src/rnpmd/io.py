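"""Coordinate-ensemble and tabular I/O.

Conventions used throughout the package:

* lengths are **nanometres** internally; PDB files (Ångström) are converted
  on read and write,
* atom indices are 0-based, residue numbers 1-based (as in the biology),
* an :class:`Ensemble` is an ordered list of frames over one fixed topology,
  matching the multi-model PDB layout of deposited NMR/MD ensembles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "Frame",
    "Ensemble",
    "Selection",
    "ParseError",
    "TopologyMismatchError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select",
    "read_noe_table",
]

ANGSTROM_PER_NM = 10.0


class ParseError(ValueError):
    """A structure or table file could not be parsed."""


class TopologyMismatchError(ValueError):
    """Models of a multi-model file do not share one topology."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology."""

    atom_index: int
    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str


@dataclass
class Frame:
    """Coordinates (nm) of all topology atoms at one time point."""

    coordinates: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Ensemble:
    """Ordered frames over a fixed atom topology."""

    topology: list[AtomRecord]
    frames: list[Frame]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("an Ensemble needs at least one frame")
        n = len(self.topology)
        seen: set[tuple[str, int, str]] = set()
        for rec in self.topology:
            key = (rec.chain_id, rec.residue_index, rec.atom_name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in topology")
            seen.add(key)
        for fr in self.frames:
            if fr.n_atoms != n:
                raise TopologyMismatchError(
                    f"frame {fr.frame_index} has {fr.n_atoms} atoms, topology has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    def coordinate_array(self) -> np.ndarray:
        """Stacked coordinates, shape ``(n_frames, n_atoms, 3)`` in nm."""
        return np.stack([f.coordinates for f in self.frames])

    def atom_index(self, chain_id: str, residue_index: int, atom_name: str) -> int:
        for rec in self.topology:
            if (
                rec.chain_id == chain_id
                and rec.residue_index == residue_index
                and rec.atom_name == atom_name
            ):
                return rec.atom_index
        raise KeyError(f"no atom {chain_id}:{residue_index}:{atom_name} in topology")


@dataclass
class Selection:
    """An ordered, duplicate-free set of 0-based atom indices."""

    atom_indices: list[int]
    expression: str = ""
    empty: bool = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.atom_indices)) != len(self.atom_indices):
            raise ValueError("selection contains duplicate indices")
        self.empty = len(self.atom_indices) == 0

    def __len__(self) -> int:
        return len(self.atom_indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.atom_indices, dtype=int)


# ---------------------------------------------------------------------------
# multi-model PDB


def _check_pdb_lines(path: str) -> int:
    """Light validation pass; returns the number of MODEL records."""
    n_models = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                n_models += 1
            elif rec in ("ATOM", "HETATM"):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except (ValueError, IndexError):
                    raise ParseError(
                        f"{path}:{lineno}: malformed coordinate fields in {rec} record"
                    ) from None
                if line[26].strip():
                    raise ParseError(
                        f"{path}:{lineno}: insertion codes are not supported"
                    )
    return n_models


def read_multimodel_pdb(path: str, label: str = "") -> Ensemble:
    """Read a (multi-)model PDB file into an :class:`Ensemble`.

    Coordinates are converted Å → nm.  The topology is taken from the first
    model; any model with a different atom count is rejected.  Only the first
    altloc is kept; insertion codes raise :class:`ParseError`.
    """
    import biotite.structure.io.pdb as pdb

    n_models = _check_pdb_lines(path)
    pdb_file = pdb.PDBFile.read(path)
    if pdb_file.get_model_count() == 0:
        raise ParseError(f"{path}: file contains no coordinate models")
    try:
        stack = pdb_file.get_structure(model=None, altloc="first")
    except Exception as exc:  # biotite raises on inconsistent models
        if n_models > 1:
            raise TopologyMismatchError(
                f"{path}: models do not share one atom topology ({exc})"
            ) from exc
        raise ParseError(f"{path}: {exc}") from exc

    topology = []
    for i in range(stack.array_length()):
        topology.append(
            AtomRecord(
                atom_index=i,
                atom_name=str(stack.atom_name[i]),
                element=str(stack.element[i]),
                residue_index=int(stack.res_id[i]),
                residue_name=str(stack.res_name[i]),
                chain_id=str(stack.chain_id[i]),
            )
        )
    frames = [
        Frame(coordinates=stack.coord[m] / ANGSTROM_PER_NM, frame_index=m)
        for m in range(stack.stack_depth())
    ]
    return Ensemble(topology=topology, frames=frames, label=label or path)


def write_multimodel_pdb(ens: Ensemble, path: str) -> str:
    """Write an :class:`Ensemble` as a standard multi-model PDB (nm → Å)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = ens.n_atoms
    array = struc.AtomArray(n)
    array.chain_id = np.array([r.chain_id for r in ens.topology])
    array.res_id = np.array([r.residue_index for r in ens.topology])
    array.res_name = np.array([r.residue_name for r in ens.topology])
    array.atom_name = np.array([r.atom_name for r in ens.topology])
    array.element = np.array([r.element for r in ens.topology])
    array.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack(
        [array] * ens.n_frames
        if ens.n_frames > 1
        else [array]
    )
    stack.coord = ens.coordinate_array() * ANGSTROM_PER_NM
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(path)
    return path


# ---------------------------------------------------------------------------
# selection grammar
#
#   expr     := term ("or" term)*
#   term     := factor ("and" factor)*
#   factor   := "not" factor | "(" expr ")" | primitive
#   primitive:= "chain" id[,id...] | "resi" range[,range...]
#             | "name" id[,id...]  | "element" id[,id...] | "all"


def _tokenize(expression: str) -> list[str]:
    out: list[str] = []
    for raw in expression.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _SelParser:
    def __init__(self, tokens: list[str], topology: list[AtomRecord]):
        self.tokens = tokens
        self.pos = 0
        self.top = topology

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise ParseError(f"unexpected token {self.peek()!r} in selection")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise ParseError("unbalanced parentheses in selection")
            return mask
        return self.primitive()

    def primitive(self) -> np.ndarray:
        tok = self.take().lower()
        if tok == "all":
            return np.ones(len(self.top), dtype=bool)
        if tok not in ("chain", "resi", "name", "element"):
            raise ParseError(f"unknown selection keyword {tok!r}")
        values = self.take().split(",")
        if tok == "resi":
            allowed: set[int] = set()
            for v in values:
                if "-" in v[1:]:  # allow negative single numbers
                    lo_s, hi_s = v.rsplit("-", 1)
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError:
                        raise ParseError(f"bad residue range {v!r}") from None
                    allowed.update(range(lo, hi + 1))  # empty when lo > hi
                else:
                    try:
                        allowed.add(int(v))
                    except ValueError:
                        raise ParseError(f"bad residue number {v!r}") from None
            return np.array(
                [r.residue_index in allowed for r in self.top], dtype=bool
            )
        if tok == "chain":
            vals = set(values)
            return np.array([r.chain_id in vals for r in self.top], dtype=bool)
        if tok == "name":
            vals = set(values)
            return np.array([r.atom_name in vals for r in self.top], dtype=bool)
        vals = {v.upper() for v in values}
        return np.array([r.element.upper() in vals for r in self.top], dtype=bool)


def select(ens: Ensemble, expression: str) -> Selection:
    """Evaluate a selection expression against the ensemble topology.

    The grammar supports ``chain``, ``resi`` (single numbers and inclusive
    ranges), ``name``, ``element``, ``all``, combined with ``and``/``or``/
    ``not`` and parentheses.  The result preserves topology order.  An empty
    selection is allowed but emits a warning.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise ParseError("empty selection expression")
    mask = _SelParser(tokens, ens.topology).parse()
    indices = [int(i) for i in np.nonzero(mask)[0]]
    if not indices:
        warnings.warn(
            f"selection {expression!r} matched no atoms", stacklevel=2
        )
    return Selection(atom_indices=indices, expression=expression)


# ---------------------------------------------------------------------------
# NOE restraint table

NOE_CATEGORIES = ("intra_protein", "intra_rna", "intermolecular")


def read_noe_table(path: str):
    """Read a tab-separated NOE upper-bound restraint table.

    Columns: ``group1``, ``group2``, ``upper_bound_nm``, ``category``.  A
    group is one or more ``chain:residue:atom`` specs joined by ``+`` (the
    pseudo-atom convention for equivalent protons).  Order is preserved.
    """
    from .noe import NOERestraint, parse_atom_group

    restraints = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(parts)}"
                )
            g1, g2, bound_s, category = parts
            try:
                bound = float(bound_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad bound {bound_s!r}") from None
            if bound <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive bound {bound}")
            if category not in NOE_CATEGORIES:
                raise ParseError(f"{path}:{lineno}: unknown category {category!r}")
            restraints.append(
                NOERestraint(
                    group1=parse_atom_group(g1),
                    group2=parse_atom_group(g2),
                    r_noe=bound,
                    category=category,
                )
            )
    return restraints


def write_noe_table(restraints, path: str) -> str:
    from .noe import format_atom_group

    with open(path, "w") as fh:
        fh.write("# group1\tgroup2\tupper_bound_nm\tcategory\n")
        for r in restraints:
            fh.write(
                f"{format_atom_group(r.group1)}\t{format_atom_group(r.group2)}"
                f"\t{r.r_noe:.4f}\t{r.category}\n"
            )
    return path
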