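"""Imino-to-sugar proton proximity screen over an NMR structure ensemble.

A water-selective inversion pulse also partially inverts sugar protons
(H3', H4') whose chemical shifts sit near the water resonance; an NOE
from such a proton to a nearby imino proton would mimic exchange-driven
magnetization transfer.  This screen walks a deposited multi-model NMR
ensemble and reports every (imino proton, sugar proton) pair closer than
a cutoff in at least a minimum number of models — the control used to
argue such artifacts are negligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "StructureModels",
    "Contact",
    "load_models",
    "imino_sugar_contacts",
    "DEFAULT_DONOR_ATOMS",
    "DEFAULT_TARGET_ATOMS",
]

#: imino proton per base type: guanine H1, thymine/uracil H3
DEFAULT_DONOR_ATOMS = {"G": ("H1",), "T": ("H3",), "U": ("H3",)}
DEFAULT_TARGET_ATOMS = ("H3'", "H4'")

_BASE_ALIASES = {
    "G": "G", "DG": "G", "GUA": "G", "RG": "G",
    "T": "T", "DT": "T", "THY": "T",
    "U": "U", "RU": "U", "URA": "U",
    "A": "A", "DA": "A", "ADE": "A", "RA": "A",
    "C": "C", "DC": "C", "CYT": "C", "RC": "C",
}


def normalize_atom_name(name: str) -> str:
    """Collapse PDB atom-name dialects: H4' == H4′ == H4*."""
    return name.strip().replace("′", "'").replace("*", "'")


def base_letter(residue_name: str) -> str | None:
    return _BASE_ALIASES.get(residue_name.strip().upper())


@dataclass(frozen=True)
class Atom:
    residue_name: str
    residue_number: int
    chain: str
    name: str  # normalized
    xyz: tuple[float, float, float]

    @property
    def residue_label(self) -> str:
        base = base_letter(self.residue_name) or self.residue_name
        return f"{base}{self.residue_number}"

    @property
    def roster_key(self) -> tuple:
        return (self.chain, self.residue_number, self.residue_name, self.name)


@dataclass(frozen=True)
class StructureModels:
    """A multi-model coordinate ensemble with a common atom roster."""

    models: tuple[tuple[Atom, ...], ...]

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("no models")
        roster = [a.roster_key for a in self.models[0]]
        for i, m in enumerate(self.models[1:], start=2):
            if [a.roster_key for a in m] != roster:
                raise ValueError(f"model {i} has a different atom roster than model 1")
        for m in self.models:
            for a in m:
                if not all(np.isfinite(a.xyz)):
                    raise ValueError(f"non-finite coordinates for {a.roster_key}")

    @property
    def n_models(self) -> int:
        return len(self.models)

    def coordinates(self) -> np.ndarray:
        """(n_models, n_atoms, 3) coordinate array in model order."""
        return np.array([[a.xyz for a in m] for m in self.models])


@dataclass(frozen=True)
class Contact:
    donor_residue: str
    donor_atom: str
    target_residue: str
    target_atom: str
    n_models_satisfying: int
    min_distance: float


def load_models(path: str | Path) -> StructureModels:
    """Load a multi-model PDB/mmCIF file, one coordinate set per MODEL.

    Hydrogen atoms are required (the screen is about protons); atom
    names are normalized on load and all models must share one roster.
    """
    st = gemmi.read_structure(str(path))
    models = []
    for model in st:
        atoms = []
        for chain in model:
            for res in chain:
                for atom in res:
                    atoms.append(
                        Atom(
                            residue_name=res.name,
                            residue_number=res.seqid.num,
                            chain=chain.name,
                            name=normalize_atom_name(atom.name),
                            xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                        )
                    )
        models.append(tuple(atoms))
    sm = StructureModels(models=tuple(models))
    if not any(a.name.startswith("H") for a in sm.models[0]):
        raise ValueError(
            f"{path}: no hydrogen atoms found; the proximity screen needs protons"
        )
    return sm


def imino_sugar_contacts(
    models: StructureModels,
    donor_atoms: dict[str, tuple[str, ...]] | None = None,
    target_atoms: tuple[str, ...] = DEFAULT_TARGET_ATOMS,
    cutoff: float = 5.0,
    min_models: int = 7,
    strict: bool = True,
) -> list[Contact]:
    """Report (imino proton, sugar proton) pairs consistently close.

    A pair is reported iff its Euclidean distance is below ``cutoff``
    (strictly, unless ``strict=False``) in at least ``min_models`` of
    the ensemble's models.  The default thresholds (5 A in >= 7 of 12
    models) implement "closer than 5 A in more than six of twelve
    structures".
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if not (1 <= min_models <= models.n_models):
        raise ValueError("min_models must be in [1, n_models]")
    donor_atoms = DEFAULT_DONOR_ATOMS if donor_atoms is None else donor_atoms

    roster = models.models[0]
    donors = [
        i
        for i, a in enumerate(roster)
        if base_letter(a.residue_name) in donor_atoms
        and a.name in donor_atoms[base_letter(a.residue_name)]
    ]
    targets = [i for i, a in enumerate(roster) if a.name in target_atoms]
    if not donors or not targets:
        raise ValueError("empty donor or target atom selection")

    coords = models.coordinates()  # (M, N, 3)
    dvec = coords[:, donors, None, :] - coords[:, None, targets, :]
    dist = np.linalg.norm(dvec, axis=-1)  # (M, n_donors, n_targets)
    close = dist < cutoff if strict else dist <= cutoff
    counts = close.sum(axis=0)  # (n_donors, n_targets)

    contacts = []
    for di, ti in zip(*np.nonzero(counts >= min_models)):
        d, t = roster[donors[di]], roster[targets[ti]]
        if donors[di] == targets[ti]:
            continue
        contacts.append(
            Contact(
                donor_residue=d.residue_label,
                donor_atom=d.name,
                target_residue=t.residue_label,
                target_atom=t.name,
                n_models_satisfying=int(counts[di, ti]),
                min_distance=float(dist[:, di, ti].min()),
            )
        )
    contacts.sort(key=lambda c: (c.donor_residue, c.target_residue, c.target_atom))
    return contacts
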