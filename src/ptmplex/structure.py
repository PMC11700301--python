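"""Mapping PTM sites onto predicted structures: CA distances and confidence.

Predicted single-chain models (AlphaFold2 convention) store the per-residue
confidence (pLDDT, 0-100) in the B-factor column, and author residue
numbering equals UniProt numbering.  Distances between modified residues
are Euclidean distances between alpha carbons, in Angstroms.  Sites that
fall in low-confidence (often intrinsically disordered) regions are flagged
so the distances are interpreted cautiously.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .errors import MappingError, ValidationError

import warnings

#: pLDDT below this is the conventional "low confidence" boundary
DEFAULT_PLDDT_THRESHOLD = 70.0

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
_AA1TO3 = {v: k for k, v in _AA3TO1.items()}


@dataclass
class StructureModel:
    """Per-residue CA coordinates and confidence for one protein chain."""

    accession: str
    residues: pd.DataFrame  # index: 1-based position; columns: letter, x, y, z, plddt

    def __post_init__(self) -> None:
        df = self.residues
        if df.index.has_duplicates:
            raise ValidationError("duplicate residue positions in structure")
        if not df.index.is_monotonic_increasing:
            self.residues = df.sort_index()
        coords = self.residues[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise ValidationError("non-finite CA coordinates")
        plddt = self.residues["plddt"].to_numpy(dtype=float)
        if ((plddt < 0) | (plddt > 100)).any():
            raise ValidationError("pLDDT values must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> pd.Series:
        try:
            return self.residues.loc[position]
        except KeyError:
            raise MappingError(
                f"{self.accession}: no residue with CA at position {position}"
            ) from None


@dataclass
class DistanceMatrix:
    """Symmetric CA-CA distance matrix (A) over labeled sites."""

    labels: list[str]  # e.g. ["K26", "C42", "S1407"]
    distances: pd.DataFrame
    plddt: pd.Series
    low_confidence: pd.Series  # bool per label

    def annotate(self) -> pd.DataFrame:
        """Distances as strings, marking cells touching low-confidence sites."""
        out = self.distances.round(1).astype(str)
        for a in self.labels:
            for b in self.labels:
                if self.low_confidence[a] or self.low_confidence[b]:
                    out.loc[a, b] += "*"
        return out


def read_structure(path, accession: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF model into a :class:`StructureModel`.

    Expects a single chain; residues lacking a CA atom are skipped with a
    warning.  pLDDT is taken from the CA B-factor.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValidationError(f"{path}: no models in structure file")
    model = st[0]
    chains = [ch for ch in model if len(ch) > 0]
    if len(chains) > 1:
        raise ValidationError(
            f"{path}: {len(chains)} chains present; single-chain models expected "
            f"— extract the chain of interest first"
        )
    if not chains:
        raise ValidationError(f"{path}: no chains in structure file")
    chain = chains[0]
    rows = {}
    skipped = []
    for residue in chain:
        ca = residue.find_atom("CA", "*")
        if ca is None:
            skipped.append(residue.seqid.num)
            continue
        letter = _AA3TO1.get(residue.name.upper(), "X")
        rows[residue.seqid.num] = {
            "letter": letter,
            "x": ca.pos.x,
            "y": ca.pos.y,
            "z": ca.pos.z,
            "plddt": ca.b_iso,
        }
    if skipped:
        warnings.warn(f"{path}: residue(s) without CA skipped: {skipped}")
    if not rows:
        raise ValidationError(f"{path}: no residues with CA atoms")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "position"
    return StructureModel(accession or st.name or "unknown", df)


def build_structure(
    accession: str,
    residues: list[tuple[str, int]],
    coordinates: np.ndarray,
    plddt,
) -> gemmi.Structure:
    """Assemble a minimal single-chain gemmi structure with CA-only residues."""
    coordinates = np.asarray(coordinates, dtype=float)
    if not np.isfinite(coordinates).all():
        raise ValidationError("coordinates must be finite")
    positions = [p for _, p in residues]
    if len(set(positions)) != len(positions):
        raise ValidationError("duplicate residue positions")
    st = gemmi.Structure()
    st.name = accession
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for (letter, pos), xyz, conf in zip(residues, coordinates, np.asarray(plddt, float)):
        res = gemmi.Residue()
        res.name = _AA1TO3.get(letter.upper(), "GLY")
        res.seqid = gemmi.SeqId(int(pos), " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.b_iso = float(conf)
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def site_distance_matrix(
    model: StructureModel,
    residues: list[tuple[str, int]],
    plddt_threshold: float = DEFAULT_PLDDT_THRESHOLD,
) -> DistanceMatrix:
    """Pairwise CA-CA Euclidean distances among the requested residues.

    Each requested (letter, position) is validated against the model; a
    letter mismatch (e.g. requesting C42 where position 42 is alanine)
    raises :class:`ValidationError`.
    """
    labels = []
    coords = []
    confidences = []
    for letter, pos in residues:
        row = model.residue(int(pos))
        if row["letter"] != letter.upper():
            raise ValidationError(
                f"{model.accession}: position {pos} is {row['letter']}, not {letter}"
            )
        labels.append(f"{letter.upper()}{pos}")
        coords.append([row["x"], row["y"], row["z"]])
        confidences.append(float(row["plddt"]))
    coords = np.asarray(coords, dtype=float)
    if len(coords) == 1:
        dist = np.zeros((1, 1))
    else:
        dist = squareform(pdist(coords))
    distances = pd.DataFrame(dist, index=labels, columns=labels)
    plddt = pd.Series(confidences, index=labels, name="plddt")
    return DistanceMatrix(
        labels=labels,
        distances=distances,
        plddt=plddt,
        low_confidence=plddt < plddt_threshold,
    )


def flag_low_confidence(
    model: StructureModel,
    residues: list[tuple[str, int]],
    threshold: float = DEFAULT_PLDDT_THRESHOLD,
) -> pd.Series:
    """Boolean flags (per site label) for pLDDT below ``threshold``."""
    flags = {}
    for letter, pos in residues:
        row = model.residue(int(pos))
        flags[f"{letter.upper()}{pos}"] = bool(row["plddt"] < threshold)
    return pd.Series(flags, name="low_confidence")
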