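"""Common/specific ligand-skeleton partitioning and feature filtering.

Inhibitor series for one target usually share a scaffold - the *common
skeleton* - that anchors the conserved interactions with key binding-site
residues, while the substituent groups (*specific skeletons*) explore
subsites and drive potency differences.  For lead optimisation the
informative interaction features are the ones made by the substituents, so
features arising purely from common-skeleton atoms can be discarded.

"Shared scaffold" is realised here as the maximum common substructure (MCS)
of the compound set: ring-aware (ring bonds only match ring bonds, partial
rings disallowed), element-matched, with a wall-clock timeout.  Each
compound's atoms are then labelled common (inside its MCS match) or specific
(outside); compounds that fail to match the MCS are all-specific and lower
the coverage.  A common skeleton is only accepted when at least half the
compounds match it.

Ligand atoms are addressed as ``a<index>`` where the index is the RDKit atom
index of the parsed structure (SMILES order / SDF atom-block order).
Interaction records must use the same addressing for attribution to work.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFMCS

#: minimum MCS size (atoms) considered a real skeleton
MIN_MCS_ATOMS = 3
#: minimum fraction of compounds that must match the MCS
MIN_COVERAGE = 0.5
#: MCS search timeout, seconds
MCS_TIMEOUT_S = 60

FEATURE_CLASSES = ("common", "specific", "mixed")


def ligand_atom_id(index: int) -> str:
    return f"a{index}"


@dataclass
class SkeletonPartition:
    mcs_pattern: str  # SMARTS; empty when no skeleton accepted
    atom_labels: dict  # compound_id -> {ligand_atom_id: "common"|"specific"}
    coverage: float  # fraction of compounds matching the MCS

    def common_atoms(self, compound_id: str) -> set:
        return {
            a for a, lab in self.atom_labels[compound_id].items() if lab == "common"
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SkeletonPartition":
        with open(path) as fh:
            return cls(**json.load(fh))


def _as_mol(compound_id: str, structure) -> Chem.Mol:
    if isinstance(structure, Chem.Mol):
        return structure
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(
            f"unparsable structure for compound {compound_id!r}: {structure!r}"
        )
    return mol


def find_common_skeleton(
    structures: Sequence[tuple],
    timeout: int = MCS_TIMEOUT_S,
    min_coverage: float = MIN_COVERAGE,
) -> SkeletonPartition:
    """Label every ligand atom of every compound common/specific via MCS.

    ``structures`` is a list of (compound_id, SMILES-or-Mol).  When the MCS
    has fewer than 3 atoms, or matches fewer than ``min_coverage`` of the
    compounds, no skeleton is accepted and every atom is specific.
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures to find a common skeleton")
    mols = {cid: _as_mol(cid, s) for cid, s in structures}

    def all_specific(pattern: str = "") -> SkeletonPartition:
        labels = {
            cid: {ligand_atom_id(a.GetIdx()): "specific" for a in mol.GetAtoms()}
            for cid, mol in mols.items()
        }
        return SkeletonPartition(mcs_pattern=pattern, atom_labels=labels, coverage=0.0)

    def search(subset):
        return rdFMCS.FindMCS(
            subset,
            ringMatchesRingOnly=True,
            completeRingsOnly=True,
            atomCompare=rdFMCS.AtomCompare.CompareElements,
            bondCompare=rdFMCS.BondCompare.CompareOrder,
            timeout=timeout,
        )

    mcs = search(list(mols.values()))
    if mcs.canceled:
        warnings.warn("MCS search timed out; using best substructure found so far")
    if mcs.numAtoms < MIN_MCS_ATOMS and len(mols) > 2:
        # no skeleton spans every compound (outlier present); fall back to the
        # largest skeleton found after leaving out one compound at a time -
        # the left-out outlier simply ends up all-specific below
        warnings.warn(
            "no common substructure spans all compounds; searching for a "
            "skeleton shared by the remaining compounds"
        )
        mol_list = list(mols.values())
        trials = [
            search(mol_list[:i] + mol_list[i + 1 :]) for i in range(len(mol_list))
        ]
        mcs = max(trials, key=lambda m: m.numAtoms)
    if mcs.numAtoms < MIN_MCS_ATOMS:
        warnings.warn(
            f"no common substructure of >= {MIN_MCS_ATOMS} atoms; "
            "all atoms labelled specific"
        )
        return all_specific()

    query = Chem.MolFromSmarts(mcs.smartsString)
    labels: dict = {}
    matched = 0
    unmatched: list = []
    for cid, mol in mols.items():
        match = mol.GetSubstructMatch(query)
        in_mcs = set(match)
        if in_mcs:
            matched += 1
        else:
            unmatched.append(cid)
        labels[cid] = {
            ligand_atom_id(a.GetIdx()): ("common" if a.GetIdx() in in_mcs else "specific")
            for a in mol.GetAtoms()
        }
    coverage = matched / len(mols)
    if coverage < min_coverage:
        warnings.warn(
            f"common skeleton matched only {coverage:.0%} of compounds "
            f"(< {min_coverage:.0%}); rejected, all atoms labelled specific"
        )
        return all_specific()
    if unmatched:
        warnings.warn(
            f"compounds not matching the common skeleton (all-specific): {unmatched}"
        )
    return SkeletonPartition(
        mcs_pattern=mcs.smartsString, atom_labels=labels, coverage=coverage
    )


def attribute_features(
    records: Sequence,
    partition: SkeletonPartition,
    matrix,
) -> dict:
    """Classify each matrix feature by the skeleton class of the ligand atoms
    behind it.

    The ligand-atom identity is only present in the raw contact records (the
    aggregated matrix erases it), so attribution pools, per feature, the
    labels of every contributing record's ligand atom across all compounds:
    all common -> "common", all specific -> "specific", otherwise "mixed".
    Features with no contributing record touch no common-skeleton atom and
    are classed "specific".
    """
    feature_ids = set(matrix.feature_ids)
    if matrix.feature_kind == "residue":
        key = lambda r: f"{r.residue_id}:{r.chain_part}:{r.interaction_type}"
    else:
        key = lambda r: f"{r.protein_atom_id}:{r.interaction_type}"
    seen: dict = {}
    for r in records:
        fid = key(r)
        if fid not in feature_ids:
            raise ValueError(f"record maps to feature {fid!r} absent from matrix")
        comp_labels = partition.atom_labels.get(r.compound_id)
        if comp_labels is None:
            raise ValueError(f"compound {r.compound_id!r} has no skeleton labels")
        label = comp_labels.get(r.ligand_atom_id)
        if label is None:
            raise ValueError(
                f"ligand atom {r.ligand_atom_id!r} of compound "
                f"{r.compound_id!r} is unlabelled"
            )
        seen.setdefault(fid, set()).add(label)
    out: dict = {}
    for fid in matrix.feature_ids:
        labels = seen.get(fid)
        if not labels:
            out[fid] = "specific"
        elif labels == {"common"}:
            out[fid] = "common"
        elif labels == {"specific"}:
            out[fid] = "specific"
        else:
            out[fid] = "mixed"
    return out


def filter_specific(matrix, attribution: dict, keep_mixed: bool = False):
    """Drop common-skeleton features (and, by default, mixed ones)."""
    missing = [f for f in matrix.feature_ids if f not in attribution]
    if missing:
        raise ValueError(f"attribution missing features: {missing[:5]}")
    keep_classes = {"specific", "mixed"} if keep_mixed else {"specific"}
    keep = [f for f in matrix.feature_ids if attribution[f] in keep_classes]
    if not keep:
        raise ValueError(
            "no features survive the skeleton filter; retry with keep_mixed=True"
        )
    return matrix.subset_features(keep)


def write_attribution_tsv(attribution: dict, path) -> None:
    pd.DataFrame(
        sorted(attribution.items()), columns=["feature_id", "class"]
    ).to_csv(path, sep="\t", index=False)


def read_structures_smi(path) -> list:
    """Read `SMILES<whitespace>id` lines (blank lines and # comments skipped)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"CPD{len(out) + 1:03d}"
            out.append((cid, smiles))
    return out
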