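"""PDB structure reading, residue-node extraction and annotated-PDB writing.

A protein contact network (PCN) represents each residue by a single point:
its Cα atom, its Cβ atom (Cα for glycine), or the centroid of its heavy
atoms.  This module parses fixed-column PDB text into a light-weight atom
model, extracts one :class:`ResidueNode` per standard amino-acid residue,
and writes per-node scores back into the B-factor column so any molecular
viewer can colour the 3D structure by them.

Parsing is deliberately line-oriented: every :class:`AtomRecord` keeps its
raw source line so that :func:`write_annotated_pdb` can guarantee that all
columns other than the B-factor field are byte-identical to the input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ParameterError, ParseError, StructureError

# The 20 standard amino acids (3-letter codes).  Non-standard residues,
# including MSE selenomethionine, are excluded from node extraction.
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

_WATER = frozenset({"HOH", "WAT", "DOD"})

REPRESENTATIONS = ("ca", "cb", "centroid")


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record, plus its raw line for byte-exact rewriting."""

    serial: int
    name: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    x: float
    y: float
    z: float
    b_factor: float
    is_hetero: bool
    element: str = ""
    raw: str = ""
    line_no: int = 0

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.i_code)

    @property
    def is_hydrogen(self) -> bool:
        elem = self.element.strip().upper()
        if elem:
            return elem in ("H", "D")
        # Fall back to the atom-name heuristic when the element column is
        # absent: strip leading digits, then test the first letter.
        name = self.name.strip().lstrip("0123456789")
        return name[:1].upper() in ("H", "D")


@dataclass
class StructureModel:
    """Atoms of model 1 of a PDB file, in file order, plus the retained lines."""

    atoms: list[AtomRecord]
    source_label: str = ""
    lines: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ResidueNode:
    """One PCN node: a residue and its representative coordinate."""

    index: int
    chain_id: str
    res_seq: int
    i_code: str
    res_name: str
    coord: tuple[float, float, float]
    representation: str

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.res_seq}{self.i_code.strip()}"


def _parse_atom_line(line: str, line_no: int) -> AtomRecord:
    """Parse one ATOM/HETATM line per wwPDB v3.3 fixed columns."""
    padded = line.rstrip("\n").ljust(80)
    try:
        serial = int(padded[6:11])
    except ValueError:
        serial = 0  # some generators leave serial blank; coordinates matter
    name = padded[12:16]
    alt_loc = padded[16]
    res_name = padded[17:20].strip()
    chain_id = padded[21]
    try:
        res_seq = int(padded[22:26])
    except ValueError as exc:
        raise ParseError(f"line {line_no}: malformed residue number: {padded[22:26]!r}") from exc
    i_code = padded[26]
    try:
        x = float(padded[30:38])
        y = float(padded[38:46])
        z = float(padded[46:54])
    except ValueError as exc:
        raise ParseError(f"line {line_no}: malformed coordinate columns") from exc
    if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
        raise ParseError(f"line {line_no}: non-finite coordinates")
    try:
        b_factor = float(padded[60:66])
    except ValueError:
        b_factor = 0.0
    return AtomRecord(
        serial=serial,
        name=name,
        alt_loc=alt_loc,
        res_name=res_name,
        chain_id=chain_id,
        res_seq=res_seq,
        i_code=i_code,
        x=x,
        y=y,
        z=z,
        b_factor=b_factor,
        is_hetero=line.startswith("HETATM"),
        element=padded[76:78],
        raw=line.rstrip("\n"),
        line_no=line_no,
    )


def parse_structure(pdb_text: str, source_label: str = "") -> StructureModel:
    """Parse PDB text into a :class:`StructureModel`.

    Only model 1 of multi-model (e.g. NMR ensemble) files is retained; lines
    belonging to models >= 2 are dropped entirely.  HETATM records are kept
    but flagged, so downstream node extraction can exclude them.

    Raises :class:`ParseError` on malformed coordinate columns (naming the
    line number) and :class:`StructureError` when no ATOM/HETATM record is
    present.
    """
    atoms: list[AtomRecord] = []
    kept_lines: list[str] = []
    model_no = 0
    in_skipped_model = False
    for line_no, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            model_no += 1
            in_skipped_model = model_no > 1
            if in_skipped_model:
                continue
        elif rec.startswith("ENDMDL"):
            if in_skipped_model:
                in_skipped_model = False
                continue
        if in_skipped_model:
            continue
        kept_lines.append(line)
        if rec in ("ATOM  ", "HETATM"):
            atoms.append(_parse_atom_line(line, line_no))
    if not atoms:
        raise StructureError("empty structure: no ATOM/HETATM records found")
    return StructureModel(atoms=atoms, source_label=source_label, lines=kept_lines)


def _residue_sort_key(key: tuple[str, int, str]) -> tuple[str, int, str]:
    chain, seq, icode = key
    return (chain, seq, icode)


def extract_nodes(
    model: StructureModel,
    mode: str = "ca",
    chains: Optional[Iterable[str]] = None,
) -> list[ResidueNode]:
    """Extract one representative node per standard amino-acid residue.

    mode 'ca' uses the Cα atom; 'cb' uses Cβ, falling back to Cα for glycine
    or when Cβ is missing; 'centroid' uses the unweighted mean of the
    residue's heavy (non-hydrogen) atoms.  When alternate locations exist,
    only alt-loc ' ' and 'A' atoms are used, giving a deterministic
    single-conformer network.  Waters, HETATM residues and residues lacking
    the required atom are skipped.  Nodes are ordered by
    (chain, res_seq, i_code) and indexed 0..N-1.
    """
    if mode not in REPRESENTATIONS:
        raise ParameterError(f"unknown representation mode: {mode!r}")
    chain_set = set(chains) if chains is not None else None

    by_residue: dict[tuple[str, int, str], list[AtomRecord]] = {}
    for atom in model.atoms:
        if atom.is_hetero or atom.res_name in _WATER:
            continue
        if atom.res_name not in STANDARD_AA:
            continue
        if chain_set is not None and atom.chain_id not in chain_set:
            continue
        if atom.alt_loc not in (" ", "A", ""):
            continue
        by_residue.setdefault(atom.residue_key, []).append(atom)

    nodes: list[ResidueNode] = []
    for key in sorted(by_residue, key=_residue_sort_key):
        atoms = by_residue[key]
        coord = _representative_coord(atoms, mode)
        if coord is None:
            continue
        chain_id, res_seq, i_code = key
        nodes.append(
            ResidueNode(
                index=len(nodes),
                chain_id=chain_id,
                res_seq=res_seq,
                i_code=i_code,
                res_name=atoms[0].res_name,
                coord=coord,
                representation=mode,
            )
        )
    if not nodes:
        raise StructureError("no nodes: no eligible residues after filtering")
    return nodes


def _representative_coord(
    atoms: Sequence[AtomRecord], mode: str
) -> Optional[tuple[float, float, float]]:
    named = {a.name.strip(): a for a in atoms}
    if mode == "ca":
        a = named.get("CA")
        return (a.x, a.y, a.z) if a is not None else None
    if mode == "cb":
        a = named.get("CB") or named.get("CA")
        return (a.x, a.y, a.z) if a is not None else None
    heavy = [a for a in atoms if not a.is_hydrogen]
    if not heavy:
        return None
    n = len(heavy)
    return (
        sum(a.x for a in heavy) / n,
        sum(a.y for a in heavy) / n,
        sum(a.z for a in heavy) / n,
    )


def write_annotated_pdb(
    model: StructureModel,
    values: Mapping[int, float],
    nodes: Sequence[ResidueNode],
) -> str:
    """Write per-node values into the B-factor column (columns 61-66).

    Every atom of a node's residue receives that node's value, formatted
    as %6.2f and clamped to [-99.99, 999.99]; atoms of residues without a
    node get 0.00.  All other columns are byte-identical to the input, so
    annotating a model with its own original B-factors reproduces the file
    exactly.
    """
    per_residue: dict[tuple[str, int, str], float] = {}
    for node in nodes:
        if node.index not in values:
            raise ParameterError(f"no value supplied for node {node.index}")
        v = float(values[node.index])
        if not math.isfinite(v):
            raise ParameterError(f"non-finite value for node {node.index}: {v}")
        per_residue[(node.chain_id, node.res_seq, node.i_code)] = v

    atom_by_line = {a.raw: a for a in model.atoms}
    out: list[str] = []
    for line in model.lines:
        if line[:6] in ("ATOM  ", "HETATM") and line in atom_by_line:
            atom = atom_by_line[line]
            v = per_residue.get(atom.residue_key, 0.0)
            v = min(max(v, -99.99), 999.99)
            padded = line.ljust(66)
            out.append(padded[:60] + f"{v:6.2f}" + padded[66:])
        else:
            out.append(line)
    return "\n".join(out) + "\n"


def generate_helix_fixture(n: int) -> str:
    """Generate an ideal poly-alanine α-helix of ``n`` CA-only residues.

    Residue i (0-based) sits at (r·cos(iθ), r·sin(iθ), i·h) with
    r = 2.3 Å, θ = 100° and rise h = 1.5 Å — the canonical α-helix
    geometry (3.6 residues/turn), giving consecutive-CA distances of
    ≈3.83 Å.  Chain 'A', residues numbered 1..n, valid fixed-column PDB.
    """
    if n < 1:
        raise ParameterError("helix fixture requires n >= 1")
    r, theta, h = 2.3, math.radians(100.0), 1.5
    lines = []
    for i in range(n):
        x = r * math.cos(i * theta)
        y = r * math.sin(i * theta)
        z = i * h
        lines.append(
            f"ATOM  {i + 1:5d}  CA  ALA A{i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f" C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
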