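"""Interaction-profile feature construction.

A docked protein-ligand pose decomposes into per-contact interaction records:
one protein atom (belonging to a residue, on the main chain or a side chain)
touching one ligand atom through an electrostatic (E), hydrogen-bond (H) or
van der Waals (V) interaction, with a signed docking energy (negative =
favourable).  This module aggregates such records into dense compound x
feature matrices at two resolutions:

* residue-based - one feature per (residue, chain part, interaction type),
  id ``"TRP86:S:V"``; 6 features per residue;
* atom-based - one feature per (protein atom, interaction type),
  id ``"atomA:H"``; 3 features per protein atom.

A cell holds the *sum* of contact energies mapping to that feature for that
compound (docking pairwise-potential totals are additive over contacts);
absent contacts are exactly 0.0, so profiles are dense with sparse nonzeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

CHAIN_PARTS = ("M", "S")
INTERACTION_TYPES = ("E", "H", "V")

#: significant digits used when writing energies to TSV; chosen so a
#: write/read round-trip reproduces IEEE doubles bit-exactly.
TSV_SIG_DIGITS = 17

RECORD_COLUMNS = [
    "compound_id",
    "protein_atom_id",
    "residue_id",
    "chain_part",
    "ligand_atom_id",
    "interaction_type",
    "energy",
]


@dataclass
class InteractionRecord:
    """One docked protein-ligand contact with a typed energy."""

    compound_id: str
    protein_atom_id: str
    residue_id: str
    chain_part: str
    ligand_atom_id: str
    interaction_type: str
    energy: float

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if self.chain_part not in CHAIN_PARTS:
            raise ValueError(
                f"chain_part must be one of {CHAIN_PARTS}, got {self.chain_part!r}"
            )
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(
                f"interaction_type must be one of {INTERACTION_TYPES}, "
                f"got {self.interaction_type!r}"
            )
        self.energy = float(self.energy)
        if not math.isfinite(self.energy):
            raise ValueError("energy must be finite")


@dataclass
class FeatureMatrix:
    """Compounds x interaction-features matrix with a fixed column schema.

    ``values`` is dense; an absent contact is 0.0, never NaN.  Feature ids are
    unique and ordered; the ordering is part of the schema so that models
    trained on one matrix can be applied to another with the same schema.
    """

    compound_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    feature_kind: str  # "atom" or "residue"

    def __post_init__(self) -> None:
        self.compound_ids = list(self.compound_ids)
        self.feature_ids = list(self.feature_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.feature_kind not in ("atom", "residue"):
            raise ValueError("feature_kind must be 'atom' or 'residue'")
        if self.values.shape != (len(self.compound_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.compound_ids)} compounds x {len(self.feature_ids)} features"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")
        if np.isnan(self.values).any():
            raise ValueError("FeatureMatrix must not contain missing values")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def zero_variance_mask(self) -> np.ndarray:
        """Boolean mask over columns that are constant across compounds."""
        return np.ptp(self.values, axis=0) == 0.0

    def feature_index(self, feature_id: str) -> int:
        return self.feature_ids.index(feature_id)

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        """Return a copy restricted to ``feature_ids``, preserving this
        matrix's column order (not the order of the argument)."""
        wanted = set(feature_ids)
        missing = wanted - set(self.feature_ids)
        if missing:
            raise KeyError(f"unknown feature ids: {sorted(missing)}")
        keep = [i for i, f in enumerate(self.feature_ids) if f in wanted]
        return FeatureMatrix(
            compound_ids=list(self.compound_ids),
            feature_ids=[self.feature_ids[i] for i in keep],
            values=self.values[:, keep].copy(),
            feature_kind=self.feature_kind,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.compound_ids, name="compound_id"),
            columns=self.feature_ids,
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(
            path, sep="\t", float_format=f"%.{TSV_SIG_DIGITS}g"
        )

    @classmethod
    def read_tsv(cls, path, feature_kind: str = "residue") -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        return cls(
            compound_ids=[str(c) for c in df.index],
            feature_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            feature_kind=feature_kind,
        )


@dataclass
class ActivityTable:
    """Per-compound activity: IC50 in nM and/or a modelling response.

    The modelling response ``activity`` is pIC50 = -log10(IC50 [M]) unless the
    table was loaded pre-transformed.
    """

    compound_ids: list[str]
    ic50_nM: np.ndarray | None = None
    activity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.compound_ids = list(self.compound_ids)
        n = len(self.compound_ids)
        if len(set(self.compound_ids)) != n:
            raise ValueError("duplicate compound ids in activity table")
        if self.ic50_nM is not None:
            self.ic50_nM = np.asarray(self.ic50_nM, dtype=float)
            if self.ic50_nM.shape != (n,):
                raise ValueError("ic50_nM length mismatch")
            if not (self.ic50_nM > 0).all():
                bad = [c for c, v in zip(self.compound_ids, self.ic50_nM) if v <= 0]
                raise ValueError(f"non-positive IC50 for compounds: {bad}")
        if self.activity is not None:
            self.activity = np.asarray(self.activity, dtype=float)
            if self.activity.shape != (n,):
                raise ValueError("activity length mismatch")
            if not np.isfinite(self.activity).all():
                raise ValueError("activity values must be finite")
        if self.ic50_nM is None and self.activity is None:
            raise ValueError("activity table needs ic50_nM or activity")

    @classmethod
    def read_csv(cls, path) -> "ActivityTable":
        df = pd.read_csv(path)
        if "compound_id" not in df.columns:
            raise ValueError("activity CSV must have a compound_id column")
        ids = [str(c) for c in df["compound_id"]]
        ic50 = df["ic50_nM"].to_numpy(float) if "ic50_nM" in df.columns else None
        act = df["activity"].to_numpy(float) if "activity" in df.columns else None
        return cls(compound_ids=ids, ic50_nM=ic50, activity=act)

    def write_csv(self, path) -> None:
        cols: dict = {"compound_id": self.compound_ids}
        if self.ic50_nM is not None:
            cols["ic50_nM"] = self.ic50_nM
        if self.activity is not None:
            cols["activity"] = self.activity
        pd.DataFrame(cols).to_csv(path, index=False)


def pic50_from_nM(ic50_nM: np.ndarray) -> np.ndarray:
    """pIC50 = -log10(IC50 in molar) for IC50 given in nanomolar."""
    return -np.log10(np.asarray(ic50_nM, dtype=float) * 1e-9)


# ---------------------------------------------------------------------------
# record I/O
# ---------------------------------------------------------------------------

def read_records_csv(path) -> list[InteractionRecord]:
    df = pd.read_csv(path, dtype={c: str for c in RECORD_COLUMNS[:-1]})
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing columns: {sorted(missing)}")
    return [
        InteractionRecord(
            compound_id=row.compound_id,
            protein_atom_id=row.protein_atom_id,
            residue_id=row.residue_id,
            chain_part=row.chain_part,
            ligand_atom_id=row.ligand_atom_id,
            interaction_type=row.interaction_type,
            energy=float(row.energy),
        )
        for row in df.itertuples(index=False)
    ]


def write_records_csv(records: Iterable[InteractionRecord], path) -> None:
    rows = [
        [r.compound_id, r.protein_atom_id, r.residue_id, r.chain_part,
         r.ligand_atom_id, r.interaction_type, r.energy]
        for r in records
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(
        path, index=False, float_format=f"%.{TSV_SIG_DIGITS}g"
    )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def residue_feature_ids(residue_ids: Sequence[str]) -> list[str]:
    """Canonical residue-feature schema: residue x {M,S} x {E,H,V}."""
    return [
        f"{res}:{part}:{typ}"
        for res in residue_ids
        for part in CHAIN_PARTS
        for typ in INTERACTION_TYPES
    ]


def atom_feature_ids(protein_atom_ids: Sequence[str]) -> list[str]:
    """Canonical atom-feature schema: protein atom x {E,H,V}."""
    return [
        f"{atom}:{typ}" for atom in protein_atom_ids for typ in INTERACTION_TYPES
    ]


def _compound_order(
    records: Sequence[InteractionRecord], compound_ids: Sequence[str] | None
) -> list[str]:
    if compound_ids is not None:
        return list(compound_ids)
    seen: dict[str, None] = {}
    for r in records:
        seen.setdefault(r.compound_id, None)
    return list(seen)


def _aggregate(
    records: Sequence[InteractionRecord],
    feature_ids: list[str],
    key_fn: Callable[[InteractionRecord], str],
    compound_ids: Sequence[str] | None,
    feature_kind: str,
) -> FeatureMatrix:
    compounds = _compound_order(records, compound_ids)
    crow = {c: i for i, c in enumerate(compounds)}
    fcol = {f: j for j, f in enumerate(feature_ids)}
    values = np.zeros((len(compounds), len(feature_ids)))
    for r in records:
        if r.compound_id not in crow:
            raise ValueError(f"record for unknown compound {r.compound_id!r}")
        values[crow[r.compound_id], fcol[key_fn(r)]] += r.energy
    return FeatureMatrix(
        compound_ids=compounds, feature_ids=feature_ids,
        values=values, feature_kind=feature_kind,
    )


def aggregate_residue_profile(
    records: Sequence[InteractionRecord],
    residue_ids: Sequence[str],
    compound_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Sum contact energies into the residue-based schema.

    The schema is fixed by ``residue_ids`` alone: 6 columns per residue
    (main/side chain x E/H/V), all zero when no record maps to them.  Records
    naming a residue outside ``residue_ids`` are rejected.
    """
    known = set(residue_ids)
    for r in records:
        if r.residue_id not in known:
            raise ValueError(f"record references unknown residue {r.residue_id!r}")
    fids = residue_feature_ids(residue_ids)
    return _aggregate(
        records, fids,
        lambda r: f"{r.residue_id}:{r.chain_part}:{r.interaction_type}",
        compound_ids, "residue",
    )


def aggregate_atom_profile(
    records: Sequence[InteractionRecord],
    protein_atom_ids: Sequence[str],
    compound_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Sum contact energies into the atom-based schema (3 columns per atom)."""
    known = set(protein_atom_ids)
    for r in records:
        if r.protein_atom_id not in known:
            raise ValueError(
                f"record references unknown protein atom {r.protein_atom_id!r}"
            )
    fids = atom_feature_ids(protein_atom_ids)
    return _aggregate(
        records, fids,
        lambda r: f"{r.protein_atom_id}:{r.interaction_type}",
        compound_ids, "atom",
    )


def attach_activities(
    matrix: FeatureMatrix,
    table: ActivityTable,
    transform: str | Callable[[np.ndarray], np.ndarray] = "pic50",
) -> tuple[FeatureMatrix, np.ndarray]:
    """Align a response vector to the matrix's compound order.

    ``transform`` applies to IC50 (nM): ``"pic50"`` (default) maps 1 nM to
    9.0; ``"raw"`` uses IC50 values as-is; a callable receives the nM vector.
    When the table carries a pre-transformed ``activity`` column it is used
    directly and ``transform`` is ignored.
    """
    idx = {c: i for i, c in enumerate(table.compound_ids)}
    missing = [c for c in matrix.compound_ids if c not in idx]
    if missing:
        raise KeyError(f"compounds missing from activity table: {missing}")
    order = [idx[c] for c in matrix.compound_ids]
    if table.activity is not None:
        y = table.activity[order]
    else:
        ic50 = table.ic50_nM[order]
        if transform == "pic50":
            y = pic50_from_nM(ic50)
        elif transform == "raw":
            y = ic50.copy()
        elif callable(transform):
            y = np.asarray(transform(ic50), dtype=float)
        else:
            raise ValueError(f"unknown transform {transform!r}")
    return matrix, y
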