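"""Core structure records and file I/O for RNA chains.

An RNA chain is reduced to three backbone atoms per nucleotide — the
phosphate P, the ribose C4', and the glycosidic nitrogen (N1 for
pyrimidines, N9 for purines).  The C4' position serves as the node
coordinate everywhere downstream.  Parsing accepts both PDB and mmCIF
text via :mod:`gemmi`; base-pair annotations are consumed from DSSR-style
JSON or a plain whitespace pair-list TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "RNAStructure",
    "BasePairSet",
    "ConformerGroup",
    "ChainNotFoundError",
    "EmptyChainError",
    "PairIndexError",
    "AnnotationParseError",
    "parse_structure",
    "read_basepairs",
    "write_fasta",
    "write_pdb",
]

ALPHABET = "ACGUN"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CU")
ATOM_SLOTS = ("P", "C4'", "N1/N9")

# one-letter codes for the standard and most common modified ribonucleotides
_ONE_LETTER = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "DA": "A", "DC": "C", "DG": "G", "DT": "U", "DU": "U",
}


class ChainNotFoundError(KeyError):
    pass


class EmptyChainError(ValueError):
    pass


class PairIndexError(IndexError):
    pass


class AnnotationParseError(ValueError):
    pass


@dataclass
class RNAStructure:
    """One RNA chain: sequence plus per-nucleotide backbone coordinates.

    ``coords`` has shape (L, 3, 3): axis 1 indexes the atom slots
    (P, C4', N1-or-N9), axis 2 is x/y/z in Angstrom.  Missing atoms hold
    NaN and are flagged False in ``atom_mask`` (shape (L, 3)).
    """

    chain_id: str
    sequence: str
    coords: np.ndarray
    residue_numbers: list[int] = field(default_factory=list)
    atom_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        L = len(self.sequence)
        if self.coords.shape != (L, 3, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match L={L}"
            )
        if not self.residue_numbers:
            self.residue_numbers = list(range(1, L + 1))
        if len(self.residue_numbers) != L:
            raise ValueError("residue_numbers length mismatch")
        if self.atom_mask is None:
            self.atom_mask = ~np.isnan(self.coords).any(axis=2)
        self.atom_mask = np.asarray(self.atom_mask, dtype=bool)
        if self.atom_mask.shape != (L, 3):
            raise ValueError("atom_mask shape mismatch")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(f"illegal sequence letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def c4_coords(self) -> np.ndarray:
        """(L, 3) array of C4' positions (NaN where missing)."""
        return self.coords[:, 1, :]

    @property
    def complete_positions(self) -> np.ndarray:
        """Boolean (L,) — True where all three backbone atoms are present."""
        return self.atom_mask.all(axis=1)


@dataclass
class BasePairSet:
    """Unordered base pairs (0-based, i<j), canonical and non-canonical."""

    pairs: set[tuple[int, int]] = field(default_factory=set)
    class_label: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = set()
        for i, j in self.pairs:
            if i == j:
                raise ValueError(f"self-pair ({i},{j})")
            norm.add((min(i, j), max(i, j)))
        self.pairs = norm

    def __len__(self) -> int:
        return len(self.pairs)

    def validate(self, L: int) -> None:
        for i, j in self.pairs:
            if not (0 <= i < L and 0 <= j < L):
                raise PairIndexError(f"pair ({i},{j}) out of range for L={L}")

    def paired_positions(self) -> set[int]:
        return {k for ij in self.pairs for k in ij}


@dataclass
class ConformerGroup:
    """K structures (with their own pairings) sharing one sequence."""

    sequence: str
    structures: list[tuple[RNAStructure, BasePairSet]]

    def __post_init__(self) -> None:
        if len(self.structures) < 1:
            raise ValueError("ConformerGroup needs K >= 1 structures")
        L = len(self.sequence)
        for st, bp in self.structures:
            if len(st) != L:
                raise ValueError(
                    f"structure {st.chain_id} length {len(st)} != {L}"
                )
            bp.validate(L)

    @property
    def K(self) -> int:
        return len(self.structures)


def _residue_letter(name: str) -> str | None:
    """One-letter code for a nucleotide residue name, N if modified/unknown."""
    name = name.strip().upper()
    if name in _ONE_LETTER:
        return _ONE_LETTER[name]
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_nucleic_acid():
        one = info.one_letter_code.upper()
        # modified nucleotides (non-standard) map to N regardless of parent
        return one if one in "ACGU" and info.is_standard() else "N"
    return None


def _pick_atom(residue: gemmi.Residue, names: tuple[str, ...]) -> gemmi.Atom | None:
    """Highest-occupancy atom among candidate names; first occurrence on ties."""
    best = None
    for atom in residue:
        if atom.name in names:
            if best is None or atom.occ > best.occ + 1e-12:
                best = atom
    return best


def parse_structure(file_text: str, chain_id: str) -> RNAStructure:
    """Parse one RNA chain from PDB or mmCIF text.

    Only the first model is read.  Residues are kept when they carry a
    C4' atom (the ribose marker that ligands, ions and waters lack);
    modified or unknown nucleotides are mapped to the letter N.  For
    alternate locations the highest-occupancy atom wins.
    """
    stripped = file_text.lstrip()
    if stripped.startswith("data_") or "_atom_site." in file_text:
        doc = gemmi.cif.read_string(file_text)
        st = gemmi.make_structure_from_block(doc.sole_block())
    else:
        st = gemmi.read_pdb_string(file_text)
    if len(st) == 0:
        raise EmptyChainError("no models in file")
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = [c.name for c in model]
        raise ChainNotFoundError(
            f"chain {chain_id!r} not found (available: {available})"
        )

    letters: list[str] = []
    coords: list[np.ndarray] = []
    mask: list[list[bool]] = []
    res_nums: list[int] = []
    for residue in chain:
        if residue.find_atom("C4'", "*") is None and _pick_atom(residue, ("C4'",)) is None:
            continue
        letter = _residue_letter(residue.name)
        if letter is None:
            letter = "N"
        if letter in PURINES:
            n_names: tuple[str, ...] = ("N9",)
        elif letter in PYRIMIDINES:
            n_names = ("N1",)
        else:  # unknown: prefer N9, fall back to N1
            n_names = ("N9", "N1")
        row = np.full((3, 3), np.nan)
        row_mask = [False, False, False]
        for slot, names in enumerate((("P",), ("C4'",), n_names)):
            atom = _pick_atom(residue, names)
            if atom is not None:
                row[slot] = [atom.pos.x, atom.pos.y, atom.pos.z]
                row_mask[slot] = True
        letters.append(letter)
        coords.append(row)
        mask.append(row_mask)
        res_nums.append(residue.seqid.num)

    if not letters:
        raise EmptyChainError(f"chain {chain_id!r} contains no ribonucleotides")
    return RNAStructure(
        chain_id=chain_id,
        sequence="".join(letters),
        coords=np.stack(coords),
        residue_numbers=res_nums,
        atom_mask=np.array(mask, dtype=bool),
    )


def _pairs_from_tsv(text: str) -> tuple[set[tuple[int, int]], dict]:
    pairs: set[tuple[int, int]] = set()
    labels: dict[tuple[int, int], str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 2:
            raise AnnotationParseError(f"line {lineno}: expected two indices")
        try:
            i, j = int(fields[0]) - 1, int(fields[1]) - 1
        except ValueError as exc:
            raise AnnotationParseError(f"line {lineno}: {exc}") from exc
        if i == j:
            raise AnnotationParseError(f"line {lineno}: self-pair {i + 1}")
        key = (min(i, j), max(i, j))
        pairs.add(key)
        if len(fields) > 2:
            labels[key] = fields[2]
    return pairs, labels


def _pairs_from_dssr(text: str) -> tuple[set[tuple[int, int]], dict]:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise AnnotationParseError(f"invalid JSON: {exc}") from exc
    entries = doc.get("pairs", doc if isinstance(doc, list) else [])
    pairs: set[tuple[int, int]] = set()
    labels: dict[tuple[int, int], str] = {}
    for k, entry in enumerate(entries):
        try:
            i = int(entry["index_1"]) - 1
            j = int(entry["index_2"]) - 1
        except (KeyError, TypeError, ValueError) as exc:
            raise AnnotationParseError(f"pair record {k}: {exc}") from exc
        key = (min(i, j), max(i, j))
        pairs.add(key)
        lw = entry.get("LW") or entry.get("lw")
        if lw:
            labels[key] = str(lw)
    return pairs, labels


def read_basepairs(annotation_text: str, format: str, L: int) -> BasePairSet:
    """Read base pairs from DSSR JSON (``dssr-json``) or a 1-based TSV
    pair list (``pairs-tsv``).  Duplicates collapse; canonical and
    non-canonical pairs are both retained, with any Leontis-Westhof tag
    kept as metadata."""
    if format == "pairs-tsv":
        pairs, labels = _pairs_from_tsv(annotation_text)
    elif format == "dssr-json":
        pairs, labels = _pairs_from_dssr(annotation_text)
    else:
        raise ValueError(f"unknown base-pair format {format!r}")
    bp = BasePairSet(pairs=pairs, class_label=labels)
    bp.validate(L)
    return bp


def write_fasta(records: list[tuple[str, str]], width: int = 60) -> str:
    """Serialize (name, sequence) records as 60-column-wrapped FASTA."""
    out = []
    for name, seq in records:
        for pos, ch in enumerate(seq):
            if ch not in ALPHABET:
                raise ValueError(
                    f"record {name!r}: illegal character {ch!r} at position {pos}"
                )
        out.append(f">{name}\n")
        for k in range(0, len(seq), width):
            out.append(seq[k : k + width] + "\n")
    return "".join(out)


_SLOT_PDB_NAMES = {"A": ("P", "C4'", "N9"), "G": ("P", "C4'", "N9"),
                   "C": ("P", "C4'", "N1"), "U": ("P", "C4'", "N1"),
                   "N": ("P", "C4'", "N9")}


def write_pdb(structure: RNAStructure) -> str:
    """Minimal PDB text for a backbone-reduced chain (P, C4', N1/N9)."""
    lines = []
    serial = 1
    chain = (structure.chain_id or "A")[0]
    for i, letter in enumerate(structure.sequence):
        names = _SLOT_PDB_NAMES[letter]
        for slot in range(3):
            if not structure.atom_mask[i, slot]:
                continue
            x, y, z = structure.coords[i, slot]
            name = names[slot]
            pad = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {pad} {letter:>3s} {chain}{structure.residue_numbers[i]:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {name[0]:>2s}\n"
            )
            serial += 1
    lines.append("END\n")
    return "".join(lines)
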