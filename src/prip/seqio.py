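"""Sequence, label and structure I/O.

Reads protein chains from FASTA, per-residue interface labels from TSV, and
protein-RNA complexes from PDB files; derives interface labels from complex
coordinates by a distance cutoff (a residue is an interface residue when at
least one of its atoms lies closer than 5 angstroms to any RNA atom).
Also persists trained model bundles as a single JSON document.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: padding / unknown-residue token
PAD = "X"
ALPHABET = STANDARD_AA + PAD

_AA_SET = frozenset(STANDARD_AA)
_ALPHABET_SET = frozenset(ALPHABET)

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
# RNA residue names seen in PDB entries: standard bases plus common
# modified-base codes; anything whose stripped name is a single base letter
# is treated as RNA as well.
_RNA_NAMES = frozenset({
    "A", "C", "G", "U", "I", "N",
    "1MA", "2MG", "5MC", "5MU", "7MG", "H2U", "M2G", "OMC", "OMG", "PSU",
    "4SU", "YG", "MIA", "T6A",
})


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


def sanitize_sequence(seq: str) -> str:
    """Uppercase a sequence and map any non-standard letter to 'X'."""
    seq = seq.upper()
    return "".join(c if c in _AA_SET else PAD for c in seq)


@dataclass
class ProteinChain:
    """A protein chain with optional per-residue interface labels.

    ``labels[i] == 1`` marks residue ``i`` (0-based internally; label files
    use 1-based positions) as an interface residue.
    """

    chain_id: str
    sequence: str
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"chain {self.chain_id!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise ValueError(
                f"chain {self.chain_id!r}: letters outside alphabet: {sorted(bad)}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (len(self.sequence),):
                raise ValueError(
                    f"chain {self.chain_id!r}: {len(self.labels)} labels for "
                    f"{len(self.sequence)} residues"
                )
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError(f"chain {self.chain_id!r}: labels must be 0/1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ComplexStructure:
    """Atom records of a protein-RNA complex.

    Each atom is ``(chain_id, residue_index, residue_name, atom_name, xyz)``
    with 1-based residue indices and coordinates in angstroms.
    """

    protein_atoms: list[tuple[str, int, str, str, np.ndarray]]
    rna_atoms: list[tuple[str, int, str, str, np.ndarray]]

    def __post_init__(self) -> None:
        for cid, idx, rname, aname, xyz in self.protein_atoms + self.rna_atoms:
            xyz = np.asarray(xyz, dtype=float)
            if not np.isfinite(xyz).all():
                raise ValueError(f"non-finite coordinates for {cid}/{idx}/{aname}")
            if idx < 1:
                raise ValueError(f"residue index must be positive, got {idx}")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinChain]:
    """Read protein chains from a FASTA file.

    Letters outside the 20 standard amino acids are mapped to 'X'.  Raises
    :class:`FormatError` on empty files, duplicate record ids, or content
    that is not FASTA (the offending line number is reported).
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(f"{path}:{lineno}: expected '>' header, got {line.strip()[:30]!r}")
            break
        else:
            raise FormatError(f"{path}: empty FASTA file")
    chains: list[ProteinChain] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        chains.append(ProteinChain(rec.id, sanitize_sequence(str(rec.seq))))
    if not chains:
        raise FormatError(f"{path}: no FASTA records")
    return chains


def write_fasta(chains: Iterable[ProteinChain], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for ch in chains:
            fh.write(f">{ch.chain_id}\n")
            for i in range(0, len(ch.sequence), width):
                fh.write(ch.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Labels TSV: chain_id <TAB> position (1-based) <TAB> label

def read_labels(path: str | Path, chain_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Read per-residue labels; unlisted positions default to 0.

    ``chain_lengths`` supplies the length of each chain so dense vectors can
    be built.  Duplicate (chain, position) rows with conflicting labels and
    out-of-range positions are format errors.
    """
    path = Path(path)
    out = {cid: np.zeros(n, dtype=np.int8) for cid, n in chain_lengths.items()}
    seen: dict[tuple[str, int], int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            cid, pos_s, lab_s = parts
            try:
                pos, lab = int(pos_s), int(lab_s)
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
            if lab not in (0, 1):
                raise FormatError(f"{path}:{lineno}: label must be 0 or 1, got {lab}")
            key = (cid, pos)
            if key in seen and seen[key] != lab:
                raise FormatError(f"{path}:{lineno}: conflicting duplicate row for {key}")
            seen[key] = lab
            if cid in out:
                if not 1 <= pos <= len(out[cid]):
                    raise FormatError(
                        f"{path}:{lineno}: position {pos} out of range for chain "
                        f"{cid!r} (length {len(out[cid])})"
                    )
                out[cid][pos - 1] = lab
    return out


def write_labels(chains: Iterable[ProteinChain], path: str | Path) -> None:
    """Write the 1-positions of labeled chains as a labels TSV."""
    with open(path, "w") as fh:
        for ch in chains:
            if ch.labels is None:
                raise ValueError(f"chain {ch.chain_id!r} has no labels")
            for pos in np.flatnonzero(ch.labels):
                fh.write(f"{ch.chain_id}\t{pos + 1}\t1\n")


def load_labeled_chains(fasta_path: str | Path, labels_path: str | Path) -> list[ProteinChain]:
    """Read a FASTA file and attach labels from a labels TSV."""
    chains = read_fasta(fasta_path)
    labels = read_labels(labels_path, {c.chain_id: len(c) for c in chains})
    return [ProteinChain(c.chain_id, c.sequence, labels[c.chain_id]) for c in chains]


# ---------------------------------------------------------------------------
# Structures and the distance rule

def read_pdb_complex(path: str | Path) -> ComplexStructure:
    """Read a PDB file, partitioning atoms into protein and RNA records.

    Residues with a standard amino-acid name become protein atoms; residues
    whose name is a nucleotide base (or a known modified base) become RNA
    atoms.  Water and other heteroatoms are ignored.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("cplx", str(path))
    protein, rna = [], []
    model = next(structure.get_models())
    for chain in model:
        for res in chain:
            rname = res.get_resname().strip()
            idx = res.id[1]
            if rname in _THREE_TO_ONE:
                dest = protein
            elif rname in _RNA_NAMES:
                dest = rna
            else:
                continue
            for atom in res:
                dest.append((chain.id, idx, rname, atom.get_name(), np.asarray(atom.coord, dtype=float)))
    return ComplexStructure(protein, rna)


def label_interfaces(
    structure: ComplexStructure,
    cutoff_angstrom: float = 5.0,
    heavy_only: bool = False,
) -> dict[tuple[str, int], int]:
    """Label each protein residue 1 iff any of its atoms lies strictly closer
    than ``cutoff_angstrom`` to any RNA atom.

    All atoms present participate by default (hydrogens included);
    ``heavy_only`` drops hydrogens from both sides.  An empty RNA atom set
    yields all-zero labels with a warning.
    """
    if cutoff_angstrom <= 0:
        raise ValueError("cutoff must be positive")
    if not structure.protein_atoms:
        raise ValueError("structure has no protein residues")

    def keep(atom_name: str) -> bool:
        return not heavy_only or not atom_name.strip().upper().startswith("H")

    prot = [(cid, idx, xyz) for cid, idx, _, an, xyz in structure.protein_atoms if keep(an)]
    rna_xyz = np.array(
        [xyz for _, _, _, an, xyz in structure.rna_atoms if keep(an)], dtype=float
    ).reshape(-1, 3)

    labels = {(cid, idx): 0 for cid, idx, _ in prot}
    if rna_xyz.shape[0] == 0:
        warnings.warn("no RNA atoms in structure: all residues labeled non-interface")
        return labels
    tree = cKDTree(rna_xyz)
    pxyz = np.array([xyz for _, _, xyz in prot], dtype=float)
    dmin, _ = tree.query(pxyz)
    for (cid, idx, _), d in zip(prot, dmin):
        if d < cutoff_angstrom:
            labels[(cid, idx)] = 1
    return labels


def chains_from_structure(
    structure: ComplexStructure,
    cutoff_angstrom: float = 5.0,
    heavy_only: bool = False,
) -> list[ProteinChain]:
    """Build labeled chains from a complex: observed residues in coordinate
    order, nonstandard residues as 'X', labels from the distance rule."""
    labels = label_interfaces(structure, cutoff_angstrom, heavy_only)
    by_chain: dict[str, dict[int, str]] = {}
    for cid, idx, rname, _, _ in structure.protein_atoms:
        by_chain.setdefault(cid, {})[idx] = _THREE_TO_ONE.get(rname, PAD)
    chains = []
    for cid, residues in by_chain.items():
        indices = sorted(residues)
        seq = "".join(residues[i] for i in indices)
        lab = np.array([labels[(cid, i)] for i in indices], dtype=np.int8)
        chains.append(ProteinChain(cid, seq, lab))
    return chains


# ---------------------------------------------------------------------------
# Model bundle persistence

@dataclass
class ModelBundle:
    """A trained predictor: semantic dictionary + boosted classifier + config."""

    dictionary: "object"  # embed.SemanticDictionary
    classifier: "object"  # gbt.BoostedModel
    window_n: int
    version: str = "1"

    def __post_init__(self) -> None:
        expected = (2 * self.window_n + 1) * self.dictionary.dim
        if self.classifier.feature_dim != expected:
            raise ValueError(
                f"feature dimension mismatch: window gives {expected}, "
                f"classifier expects {self.classifier.feature_dim}"
            )


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    doc = {
        "version": bundle.version,
        "window_n": bundle.window_n,
        "dictionary": bundle.dictionary.to_dict(),
        "classifier": bundle.classifier.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_bundle(path: str | Path) -> ModelBundle:
    from . import embed, gbt

    with open(path) as fh:
        doc = json.load(fh)
    return ModelBundle(
        dictionary=embed.SemanticDictionary.from_dict(doc["dictionary"]),
        classifier=gbt.BoostedModel.from_dict(doc["classifier"]),
        window_n=doc["window_n"],
        version=doc["version"],
    )
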