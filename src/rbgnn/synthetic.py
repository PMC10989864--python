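"""Deterministic synthetic benchmark for end-to-end testing.

Generates small valid molecules from a fixed grammar — alkyl chains of
one to six carbons, optionally attached to a benzene core, decorated
with hydroxyl / amine / carboxyl groups and zero to three chlorine
substituents — and labels them with a rule the classifier must learn:

* ``halogenated`` (default): NRB iff the molecule carries at least one
  chlorine, else RB. Halogenation is a classic driver of environmental
  persistence, and the rule is linearly separable in the atom-type
  features, so a correctly implemented model has no excuse not to
  learn it.
* ``halogenated_aromatic`` (harder, for nonlinearity regression tests):
  NRB iff at least two chlorines AND an aromatic ring.

Splits are assigned 60/20/20 train/test/external, stratified by label.
Generation is a pure function of the spec (n_molecules, seed, rule,
class balance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .dataio import DatasetRecord
from .errors import ConfigError

RULES = ("halogenated", "halogenated_aromatic")
_DECORATIONS = ["O", "N", "C(=O)O"]
_MAX_ATTEMPTS_PER_MOLECULE = 200


@dataclass(frozen=True)
class SyntheticSpec:
    n_molecules: int = 400
    seed: int = 0
    rule: str = "halogenated"
    class_balance: float = 0.5   # target RB fraction


def _label_of(mol: Chem.Mol, rule: str) -> str:
    n_cl = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "Cl")
    if rule == "halogenated":
        return "NRB" if n_cl >= 1 else "RB"
    aromatic = any(a.GetIsAromatic() for a in mol.GetAtoms())
    return "NRB" if (n_cl >= 2 and aromatic) else "RB"


def _sample_smiles(rng: np.random.Generator, n_cl: int) -> str | None:
    """Assemble one grammar molecule with exactly ``n_cl`` chlorines."""
    use_ring = rng.random() < 0.35
    chain_len = int(rng.integers(1, 7))
    chain_subs: list[list[str]] = [[] for _ in range(chain_len)]
    ring_subs: list[str | None] = [None] * 6 if use_ring else []

    # chain capacity: 2 free slots interior, 3 terminal (minus ring bond)
    def capacity(i: int) -> int:
        cap = 3 if i in (0, chain_len - 1) and chain_len > 1 else 2
        if chain_len == 1:
            cap = 4
        if use_ring and i == 0:
            cap -= 1
        return cap - len(chain_subs[i])

    for dec in _DECORATIONS:
        if rng.random() < {"O": 0.30, "N": 0.20, "C(=O)O": 0.15}[dec]:
            spots = [i for i in range(chain_len) if capacity(i) > 0]
            if spots:
                chain_subs[int(rng.choice(spots))].append(dec)
    for _ in range(n_cl):
        if use_ring and rng.random() < 0.5:
            free = [i for i in range(1, 6) if ring_subs[i] is None]
            if free:
                ring_subs[int(rng.choice(free))] = "Cl"
                continue
        spots = [i for i in range(chain_len) if capacity(i) > 0]
        if not spots:
            return None
        chain_subs[int(rng.choice(spots))].append("Cl")

    chain = "".join(
        "C" + "".join(f"({s})" for s in subs) for subs in chain_subs)
    if not use_ring:
        smiles = chain
    else:
        ring = "c1" + "".join(
            "c" + (f"({ring_subs[i]})" if ring_subs[i] else "")
            for i in range(1, 6)) + "1"
        smiles = f"{chain[:1]}(-{ring}){chain[1:]}" if chain else ring
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def generate(spec: SyntheticSpec) -> list[DatasetRecord]:
    """Produce the synthetic labelled dataset described by ``spec``."""
    if spec.n_molecules < 4:
        raise ConfigError("n_molecules must be >= 4")
    if spec.rule not in RULES:
        raise ConfigError(f"unknown rule {spec.rule!r}")
    if not 0.0 < spec.class_balance < 1.0:
        raise ConfigError("class_balance must be in (0, 1)")
    rng = np.random.default_rng(spec.seed)
    n_rb = int(round(spec.n_molecules * spec.class_balance))
    quotas = {"RB": n_rb, "NRB": spec.n_molecules - n_rb}
    got: dict[str, list[str]] = {"RB": [], "NRB": []}
    attempts = 0
    budget = spec.n_molecules * _MAX_ATTEMPTS_PER_MOLECULE
    while (len(got["RB"]) < quotas["RB"] or len(got["NRB"]) < quotas["NRB"]):
        attempts += 1
        if attempts > budget:
            raise ConfigError(
                f"class balance {spec.class_balance} unreachable under the "
                f"grammar with rule {spec.rule!r}")
        n_cl = int(rng.choice([0, 0, 1, 2, 3]))
        smiles = _sample_smiles(rng, n_cl)
        if smiles is None:
            continue
        label = _label_of(Chem.MolFromSmiles(smiles), spec.rule)
        if len(got[label]) < quotas[label]:
            got[label].append(smiles)

    # stratified 60/20/20 split per class
    records: list[DatasetRecord] = []
    for label in ("RB", "NRB"):
        smileses = got[label]
        order = rng.permutation(len(smileses))
        n = len(smileses)
        n_train, n_test = int(round(n * 0.6)), int(round(n * 0.2))
        for rank, idx in enumerate(order):
            split = ("train" if rank < n_train
                     else "test" if rank < n_train + n_test
                     else "external")
            records.append(DatasetRecord(
                id=f"SYN{len(records):05d}", smiles=smileses[idx],
                smiles_canonical=smileses[idx], label=label, split=split))
    return records
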