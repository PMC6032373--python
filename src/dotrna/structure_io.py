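"""Reading and writing the structural formats the pipeline touches.

PDB structures (ATOM/HETATM with REMARK 465 missing-residue and MODRES
records), DSSP-style per-residue secondary-structure assignments, and
dot-bracket RNA secondary-structure strings.

Coordinate parsing is delegated to :mod:`gemmi`; the REMARK 465 and MODRES
header blocks, which no installed library exposes as structured data, are
parsed here. Residue identity always uses author numbering (chain, number,
insertion code) so that REMARK 465 keys match ATOM keys.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import gemmi
import numpy as np

logger = logging.getLogger("dotrna")

# ---------------------------------------------------------------------------
# residue vocabulary

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AMINO_ACIDS: Tuple[str, ...] = tuple(sorted(AA3_TO_1))          # 3-letter
NUCLEOTIDES: Tuple[str, ...] = ("A", "C", "G", "U")

_ELEMENT_FROM_NAME = re.compile(r"[A-Z]")


class ParseError(ValueError):
    """Raised for malformed structure input, naming the offending line."""


class ResidueKey(NamedTuple):
    """Author-numbering identity of one residue within a structure."""

    chain_id: str
    seq_num: int
    icode: str
    res_name: str

    @property
    def order(self) -> Tuple[str, int, str]:
        """Sort key: chain, author number, insertion code."""
        return (self.chain_id, self.seq_num, self.icode)

    def __str__(self) -> str:  # e.g. A:52A:SER
        num = f"{self.seq_num}{self.icode}".strip()
        return f"{self.chain_id}:{num}:{self.res_name}"


@dataclass(frozen=True)
class AtomRecord:
    key: ResidueKey
    atom_name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Structure:
    """One polymer structure: atom records plus REMARK 465 missing residues.

    ``chain_kinds`` classifies each chain as ``"protein"``, ``"rna"`` or
    ``"other"``; other chains are retained but ignored by the analysis.
    """

    atoms: List[AtomRecord] = field(default_factory=list)
    missing: List[ResidueKey] = field(default_factory=list)
    chain_kinds: Dict[str, str] = field(default_factory=dict)
    name: str = ""

    # -- residue-level views -------------------------------------------------
    def residue_atoms(self) -> "Dict[ResidueKey, List[AtomRecord]]":
        out: Dict[ResidueKey, List[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.key, []).append(a)
        return out

    def residues(self, kind: Optional[str] = None) -> List[ResidueKey]:
        """Atom-bearing residues in file order, optionally one polymer kind."""
        seen: Dict[ResidueKey, None] = {}
        for a in self.atoms:
            if kind is None or self.chain_kinds.get(a.key.chain_id) == kind:
                seen.setdefault(a.key, None)
        return list(seen)

    def chain_residues(self, chain_id: str, include_missing: bool = True) -> List[ResidueKey]:
        """All residues of one chain sorted by author numbering."""
        keys = {k for k in self.residues() if k.chain_id == chain_id}
        if include_missing:
            keys |= {k for k in self.missing if k.chain_id == chain_id}
        return sorted(keys, key=lambda k: k.order)

    def chains(self, kind: Optional[str] = None) -> List[str]:
        ids = [c for c, k in self.chain_kinds.items() if kind is None or k == kind]
        return ids

    def sequence(self, chain_id: str) -> str:
        """One-letter sequence over observed + missing residues, in order."""
        letters = []
        for k in self.chain_residues(chain_id):
            if k.res_name in AA3_TO_1:
                letters.append(AA3_TO_1[k.res_name])
            elif k.res_name in NUCLEOTIDES:
                letters.append(k.res_name.lower())
            else:
                letters.append("X")
        return "".join(letters)

    def coords(self, keys: Optional[Iterable[ResidueKey]] = None,
               heavy_only: bool = True) -> Tuple[np.ndarray, List[AtomRecord]]:
        keyset = None if keys is None else set(keys)
        sel = [a for a in self.atoms
               if (keyset is None or a.key in keyset)
               and not (heavy_only and a.is_hydrogen)]
        if not sel:
            return np.zeros((0, 3)), []
        return np.array([[a.x, a.y, a.z] for a in sel]), sel


@dataclass
class RNASecStruct:
    """Dot-bracket RNA secondary structure with per-position 3-class labels."""

    sequence: str
    annotation: str
    classes: List[str]  # "unpaired" | "basepaired" | "pseudoknot"

    def __post_init__(self) -> None:
        assert len(self.sequence) == len(self.annotation) == len(self.classes)


@dataclass
class ProteinSS:
    """Per-residue protein secondary structure (raw letter + 3-state class)."""

    raw: Dict[ResidueKey, str]
    classes: Dict[ResidueKey, str]  # "helix" | "sheet" | "other"


# ---------------------------------------------------------------------------
# PDB reading

_STANDARD_RES = set(AA3_TO_1) | set(NUCLEOTIDES)

# heavier water/ion names we silently ignore instead of warning about
_SOLVENT = {"HOH", "DOD", "WAT", "NA", "K", "CL", "MG", "ZN", "CA", "MN", "SO4", "PO4"}


def _validate_coordinate_lines(pdb_text: str) -> None:
    for ln, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise ParseError(f"line {ln}: ATOM record too short")
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fieldtxt = line[lo:hi].strip()
                try:
                    val = float(fieldtxt)
                except ValueError:
                    raise ParseError(
                        f"line {ln}: unparsable {what} coordinate {fieldtxt!r}") from None
                if not math.isfinite(val):
                    raise ParseError(f"line {ln}: non-finite {what} coordinate")


def _parse_modres(pdb_text: str) -> Dict[Tuple[str, int, str, str], str]:
    """MODRES records → map (chain, seq, icode, hetname) -> standard name."""
    table: Dict[Tuple[str, int, str, str], str] = {}
    for line in pdb_text.splitlines():
        if not line.startswith("MODRES"):
            continue
        try:
            res_name = line[12:15].strip()
            chain = line[16].strip()
            seq = int(line[18:22])
            icode = line[22].strip() if len(line) > 22 else ""
            std = line[24:27].strip()
        except (ValueError, IndexError):
            continue
        if std:
            table[(chain, seq, icode, res_name)] = std
    return table


_R465_DATA = re.compile(
    r"^REMARK 465\s+(?:\d+\s+)?([A-Z0-9]{1,3})\s+([A-Za-z0-9])\s+(-?\d+)([A-Za-z]?)\s*$")
_R465_HEADER_WORDS = ("MISSING", "SSSEQI", "IDENTIFIER", "EXPERIMENT",
                      "MODELS", "RES C", "THE FOLLOWING")


def parse_missing_residues(pdb_text: str) -> List[ResidueKey]:
    """Extract the REMARK 465 missing-residue list, in file order.

    Returns an empty list when the block is absent. A data line (one that
    follows the ``M RES C SSSEQI`` column header) that cannot be parsed
    raises :class:`ParseError` naming the line.
    """
    keys: List[ResidueKey] = []
    in_data = False
    for ln, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith("REMARK 465"):
            continue
        body = line[10:].strip()
        if not body:
            continue
        if "SSSEQI" in body:
            in_data = True
            continue
        m = _R465_DATA.match(line.rstrip())
        if m:
            res_name, chain, seq, icode = m.groups()
            keys.append(ResidueKey(chain, int(seq), icode, res_name))
        elif in_data:
            raise ParseError(f"line {ln}: unparsable REMARK 465 residue entry: {body!r}")
        # prose lines before the header are ignored
        elif not any(w in body for w in _R465_HEADER_WORDS):
            logger.debug("ignoring REMARK 465 line %d: %s", ln, body)
    return keys


def _classify_chains(per_chain: Dict[str, List[str]]) -> Dict[str, str]:
    kinds: Dict[str, str] = {}
    for chain, names in per_chain.items():
        n = len(names)
        n_aa = sum(1 for r in names if r in AA3_TO_1)
        n_nt = sum(1 for r in names if r in NUCLEOTIDES)
        if n == 0:
            kinds[chain] = "other"
        elif n_nt / n >= 0.8:
            kinds[chain] = "rna"
        elif n_aa / n >= 0.8:
            kinds[chain] = "protein"
        elif n_aa and n_nt:
            raise ParseError(f"chain {chain}: mixed protein/RNA chain")
        else:
            kinds[chain] = "other"
    return kinds


def read_structure(pdb_text: str, name: str = "") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    First model only. Alternate locations are resolved to the highest
    occupancy (ties: first in file). Modified residues are renamed to their
    parent where a MODRES record says so, otherwise skipped with a warning.
    Raises :class:`ParseError` on malformed ATOM lines or when no protein or
    RNA atoms are present.
    """
    _validate_coordinate_lines(pdb_text)
    modres = _parse_modres(pdb_text)
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ParseError("no atoms: structure contains no coordinate records")
    model = st[0]

    atoms: List[AtomRecord] = []
    per_chain: Dict[str, List[str]] = {}
    for chain in model:
        for res in chain:
            icode = res.seqid.icode.strip()
            raw_name = res.name.strip()
            res_name = raw_name
            if res_name not in _STANDARD_RES:
                mapped = modres.get((chain.name, res.seqid.num, icode, raw_name))
                if mapped and mapped in _STANDARD_RES:
                    res_name = mapped
                elif raw_name in _SOLVENT:
                    continue
                else:
                    logger.warning("skipping non-standard residue %s %s%d%s (no MODRES parent)",
                                   raw_name, chain.name, res.seqid.num, icode)
                    continue
            key = ResidueKey(chain.name, res.seqid.num, icode, res_name)
            per_chain.setdefault(chain.name, []).append(res_name)
            # altloc resolution: per atom name keep highest occupancy, first wins ties
            best: Dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom_name, atom in best.items():
                elem = atom.element.name.upper() if atom.element else ""
                if not elem:
                    m = _ELEMENT_FROM_NAME.search(atom_name)
                    elem = m.group(0) if m else "C"
                atoms.append(AtomRecord(key, atom_name, elem,
                                        atom.pos.x, atom.pos.y, atom.pos.z))

    if not atoms:
        raise ParseError("no atoms: structure contains no protein or RNA atoms")

    missing = parse_missing_residues(pdb_text)
    observed = {a.key for a in atoms}
    clean_missing: List[ResidueKey] = []
    for k in missing:
        if k in observed:
            logger.warning("REMARK 465 residue %s also has atoms; treating as observed", k)
            continue
        clean_missing.append(k)
        per_chain.setdefault(k.chain_id, []).append(k.res_name)

    kinds = _classify_chains(per_chain)
    return Structure(atoms=atoms, missing=clean_missing, chain_kinds=kinds, name=name)


# ---------------------------------------------------------------------------
# PDB writing (used by the synthetic generator and the pipeline)

def to_pdb(structure: Structure) -> str:
    """Serialize a :class:`Structure` back to PDB text (coordinates to 3 dp)."""
    lines: List[str] = []
    if structure.missing:
        lines.append("REMARK 465")
        lines.append("REMARK 465 MISSING RESIDUES")
        lines.append("REMARK 465 THE FOLLOWING RESIDUES WERE NOT LOCATED IN THE EXPERIMENT.")
        lines.append("REMARK 465   M RES C SSSEQI")
        for k in structure.missing:
            lines.append(f"REMARK 465     {k.res_name:>3s} {k.chain_id}{k.seq_num:>6d}{k.icode:<1s}".rstrip())
    serial = 0
    last_chain = None
    for a in structure.atoms:
        serial += 1
        if last_chain is not None and a.key.chain_id != last_chain:
            lines.append("TER")
        last_chain = a.key.chain_id
        name = a.atom_name
        # PDB alignment rule: 1-2 char element names start at column 14
        pad = f" {name:<3s}" if len(name) < 4 and len(a.element) == 1 else f"{name:<4s}"
        lines.append(
            f"ATOM  {serial:>5d} {pad} {a.key.res_name:>3s} {a.key.chain_id}"
            f"{a.key.seq_num:>4d}{a.key.icode or ' ':1s}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}")
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# dot-bracket parsing

_OPEN = {"(": ")", "[": "]", "{": "}", "<": ">"}
_CLOSE = {v: k for k, v in _OPEN.items()}
_PSEUDOKNOT = set("[]{}<>")


def parse_dotbracket(sequence: str, annotation: str) -> RNASecStruct:
    """Parse a dot-bracket string into per-position pairing classes.

    ``.`` is unpaired, ``()`` nested base pairs, and ``[] {} <>`` mark
    pseudoknotted pairs. Bracket balance is validated per family.
    """
    if len(sequence) != len(annotation):
        raise ValueError(
            f"sequence length {len(sequence)} != annotation length {len(annotation)}")
    stacks: Dict[str, List[int]] = {k: [] for k in _OPEN}
    classes: List[str] = []
    for i, ch in enumerate(annotation):
        if ch == ".":
            classes.append("unpaired")
        elif ch in _OPEN:
            stacks[ch].append(i)
            classes.append("pseudoknot" if ch in _PSEUDOKNOT else "basepaired")
        elif ch in _CLOSE:
            opener = _CLOSE[ch]
            if not stacks[opener]:
                raise ValueError(f"unbalanced {ch!r} at position {i}")
            stacks[opener].pop()
            classes.append("pseudoknot" if ch in _PSEUDOKNOT else "basepaired")
        else:
            raise ValueError(f"invalid dot-bracket character {ch!r} at position {i}")
    for opener, stack in stacks.items():
        if stack:
            raise ValueError(f"unbalanced {opener!r} at position {stack[-1]}")
    return RNASecStruct(sequence=sequence, annotation=annotation, classes=classes)


# ---------------------------------------------------------------------------
# protein secondary structure

_DSSP_TO_3STATE = {"H": "helix", "G": "helix", "I": "helix",
                   "E": "sheet", "B": "sheet"}


def three_state(letter: str) -> str:
    """DSSP letter → 3-state class (turn/bend/coil/blank/P all map to other)."""
    return _DSSP_TO_3STATE.get(letter.strip().upper() or " ", "other")


def read_protein_ss(dssp_text: str, structure: Optional[Structure] = None) -> ProteinSS:
    """Parse classic DSSP output into per-residue 3-state classes.

    Residues present in ``structure`` but absent from the DSSP output get
    class ``other`` with a warning.
    """
    raw: Dict[ResidueKey, str] = {}
    classes: Dict[ResidueKey, str] = {}
    in_table = False
    res_names: Dict[Tuple[str, int, str], str] = {}
    if structure is not None:
        for k in structure.residues("protein"):
            res_names[(k.chain_id, k.seq_num, k.icode)] = k.res_name
    for line in dssp_text.splitlines():
        if line.lstrip().startswith("#  RESIDUE"):
            in_table = True
            continue
        if not in_table or len(line) < 17:
            continue
        numtxt = line[5:10].strip()
        if not numtxt:  # chain-break row
            continue
        seq = int(numtxt)
        icode = line[10].strip()
        chain = line[11].strip()
        aa1 = line[13].strip().upper()
        letter = line[16]
        res_name = res_names.get((chain, seq, icode)) or AA1_TO_3.get(aa1, "UNK")
        key = ResidueKey(chain, seq, icode, res_name)
        raw[key] = letter.strip()
        classes[key] = three_state(letter)
    if structure is not None:
        for k in structure.residues("protein"):
            if k not in classes:
                logger.warning("residue %s absent from DSSP output; class 'other'", k)
                raw[k] = ""
                classes[k] = "other"
    return ProteinSS(raw=raw, classes=classes)


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle in degrees for four points."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


# phi/psi basins for the fallback assigner; generous boxes around ideal
# helix (-57, -47) and extended strand (-120, +120) geometry
_HELIX_PHI = (-100.0, -30.0)
_HELIX_PSI = (-80.0, -5.0)
_SHEET_PHI = (-180.0, -60.0)
_SHEET_PSI = (90.0, 180.0)


def _in_range(val: Optional[float], lo: float, hi: float) -> bool:
    return val is not None and lo <= val <= hi


def assign_ss_from_geometry(structure: Structure, min_run: int = 4) -> ProteinSS:
    """Backbone-dihedral fallback secondary-structure assigner.

    Classifies each residue by its phi/psi basin (helical or extended) and
    keeps only runs of at least ``min_run`` consecutive residues in the same
    basin; everything else is ``other``. Intended for ideal-geometry
    synthetic structures when no DSSP output is available — it is not a
    hydrogen-bond (Kabsch–Sander) assignment.
    """
    raw: Dict[ResidueKey, str] = {}
    classes: Dict[ResidueKey, str] = {}
    res_atoms = structure.residue_atoms()
    for chain_id in structure.chains("protein"):
        keys = [k for k in structure.chain_residues(chain_id, include_missing=False)
                if k in res_atoms]

        def backbone(k: ResidueKey, name: str) -> Optional[np.ndarray]:
            for a in res_atoms[k]:
                if a.atom_name == name:
                    return a.xyz
            return None

        basins: List[str] = []
        for i, k in enumerate(keys):
            n, ca, c = backbone(k, "N"), backbone(k, "CA"), backbone(k, "C")
            have_bb = all(x is not None for x in (n, ca, c))
            phi = psi = None
            if have_bb and i > 0 and keys[i - 1].seq_num >= k.seq_num - 1:
                prev_c = backbone(keys[i - 1], "C")
                if prev_c is not None:
                    phi = _dihedral(prev_c, n, ca, c)
            if have_bb and i + 1 < len(keys) and keys[i + 1].seq_num <= k.seq_num + 1:
                next_n = backbone(keys[i + 1], "N")
                if next_n is not None:
                    psi = _dihedral(n, ca, c, next_n)
            helix_ok = ((phi is None or _in_range(phi, *_HELIX_PHI))
                        and (psi is None or _in_range(psi, *_HELIX_PSI))
                        and not (phi is None and psi is None))
            sheet_ok = ((phi is None or _in_range(phi, *_SHEET_PHI))
                        and (psi is None or _in_range(psi, *_SHEET_PSI))
                        and not (phi is None and psi is None))
            basins.append("H" if helix_ok else "E" if sheet_ok else "-")

        # keep runs of >= min_run in the same basin
        i = 0
        while i < len(basins):
            j = i
            while j < len(basins) and basins[j] == basins[i]:
                j += 1
            if basins[i] == "-" or (j - i) < min_run:
                for t in range(i, j):
                    basins[t] = "-"
            i = j
        for k, b in zip(keys, basins):
            raw[k] = {"H": "H", "E": "E", "-": ""}[b]
            classes[k] = {"H": "helix", "E": "sheet", "-": "other"}[b]
    return ProteinSS(raw=raw, classes=classes)
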