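"""SMILES-to-graph conversion.

A molecule is represented over its heavy atoms only: hydrogens are
implicit and enter the model through the total-H count feature block.
The adjacency matrix is the symmetric binary heavy-atom bond matrix
(bonds are undirected, so a_ij = a_ji); the diagonal is zero.

Atoms are ordered by the canonical SMILES so that parsing a molecule
written two different ways yields the identical graph, which also makes
canonical-SMILES deduplication and checkpoint reproducibility trivial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from . import constants
from .errors import ParseError

logger = logging.getLogger(__name__)

# RDKit is chatty about kekulization failures etc.; we raise our own errors.
RDLogger.DisableLog("rdApp.error")

_HYB_NAMES = {
    Chem.HybridizationType.SP: "SP",
    Chem.HybridizationType.SP2: "SP2",
    Chem.HybridizationType.SP3: "SP3",
    Chem.HybridizationType.SP3D: "SP3D",
    Chem.HybridizationType.SP3D2: "SP3D2",
}


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom molecular graph with per-atom feature vectors.

    Attributes
    ----------
    n : int
        Number of heavy atoms.
    adjacency : (n, n) ndarray
        Symmetric binary bond matrix, zero diagonal.
    atom_features : (n, d0) ndarray
        One row per atom, the layer-0 node representations.
    smiles_canonical : str
        RDKit canonical SMILES; graph identity for deduplication.
    """

    n: int
    adjacency: np.ndarray = field(repr=False)
    atom_features: np.ndarray = field(repr=False)
    smiles_canonical: str


def _one_hot(value, choices) -> list[float]:
    return [1.0 if value == c else 0.0 for c in choices]


def _atom_feature_vector(atom: Chem.Atom) -> np.ndarray:
    symbol = atom.GetSymbol()
    type_block = _one_hot(symbol, constants.ATOM_TYPES)
    type_block.append(0.0 if symbol in constants.ATOM_TYPES else 1.0)  # "other"
    features = (
        type_block
        + _one_hot(atom.GetDegree(), constants.DEGREES)
        + _one_hot(atom.GetImplicitValence(), constants.IMPLICIT_VALENCES)
        + [float(atom.GetFormalCharge())]
        + [float(atom.GetNumRadicalElectrons())]
        + _one_hot(_HYB_NAMES.get(atom.GetHybridization()), constants.HYBRIDIZATIONS)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + _one_hot(atom.GetTotalNumHs(), constants.NUM_HS)
    )
    return np.asarray(features, dtype=np.float64)


def _featurize_mol(mol: Chem.Mol) -> np.ndarray:
    return np.stack([_atom_feature_vector(a) for a in mol.GetAtoms()])


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    The molecule is canonicalized first and the graph is built in
    canonical atom order. Multi-fragment SMILES (dotted salts/mixtures)
    are accepted as a single disconnected graph with a warning.

    Raises
    ------
    ParseError
        If the string is empty, unparseable, or parses to zero atoms.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise ParseError(f"SMILES parses to an empty molecule: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    # Rebuild from the canonical form so atom order is canonical too.
    mol = Chem.MolFromSmiles(canonical)
    if "." in canonical:
        logger.warning(
            "multi-fragment SMILES %r accepted as a disconnected graph", smiles
        )
    adjacency = np.asarray(Chem.GetAdjacencyMatrix(mol), dtype=np.float64)
    return MolecularGraph(
        n=mol.GetNumAtoms(),
        adjacency=adjacency,
        atom_features=_featurize_mol(mol),
        smiles_canonical=canonical,
    )


def featurize_atoms(graph: MolecularGraph) -> np.ndarray:
    """Recompute the (n, d0) atom feature matrix of a parsed graph.

    Deterministic: re-deriving features from the stored canonical SMILES
    reproduces ``graph.atom_features`` exactly.
    """
    mol = Chem.MolFromSmiles(graph.smiles_canonical)
    if mol is None:  # cannot happen for graphs built by parse_smiles
        raise ParseError(f"invalid canonical SMILES: {graph.smiles_canonical!r}")
    return _featurize_mol(mol)


def canonicalize(smiles: str) -> str:
    """Canonical SMILES of ``smiles``; raises ParseError if unparseable."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)
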