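"""Coordinate handling for refinement assessment.

Reads and writes single-chain PDB coordinate files, parses the residue-range
notation used in refinement target definitions ("43-95, 106-181"), pairs model
and target residues by author residue number (the refinement convention: model
and target share numbering, so no alignment search is needed), and summarises
target-definition tables.

The B-factor column is dual-use in this category: when a predictor declares
error estimates, it holds the predicted coordinate error of each atom in
Angstroms; otherwise it is ignored.  Submissions carrying a constant column of
0 or 1 are flagged as having no usable error estimates.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "Residue",
    "StructureModel",
    "ResidueRangeSpec",
    "AlignmentMap",
    "TargetRecord",
    "read_pdb",
    "write_pdb",
    "parse_residue_ranges",
    "count_residues",
    "pair_by_residue_number",
    "has_usable_error_estimates",
    "read_target_table",
    "casp13_target_table",
    "target_table_stats",
]

# Hyphen dialects accepted in residue-range text: ASCII, U+2010, U+2011,
# U+2012, U+2013, U+2212.
_HYPHENS = "‐‑‒–−"

VALID_CATEGORIES = ("TBM-easy", "TBM-hard", "TBM/FM", "FM")


@dataclass
class AtomRecord:
    """One atom: label, element, position (A), B-column value, occupancy."""

    name: str
    element: str
    coords: np.ndarray
    bcol: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if self.bcol < 0:
            raise ValueError(f"atom {self.name}: B-column value must be non-negative")


@dataclass
class Residue:
    """A residue keyed by author number + insertion code, holding its atoms."""

    number: int
    name: str
    insertion_code: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)

    def atom(self, label: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == label:
                return a
        return None

    @property
    def ca(self) -> AtomRecord | None:
        return self.atom("CA")

    def atom_labels(self) -> list[str]:
        return [a.name for a in self.atoms]


@dataclass
class StructureModel:
    """Parsed coordinates of one model or target (single chain)."""

    model_id: str
    residues: list[Residue]
    chain_id: str = "A"

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue (number, insertion_code) pairs")
        self._index = {r.key: r for r in self.residues}

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, key: tuple[int, str]) -> Residue:
        return self._index[key]

    def __contains__(self, key: tuple[int, str]) -> bool:
        return key in self._index

    def keys(self) -> list[tuple[int, str]]:
        return [r.key for r in self.residues]

    def copy(self) -> "StructureModel":
        residues = [
            Residue(
                r.number,
                r.name,
                r.insertion_code,
                [AtomRecord(a.name, a.element, a.coords.copy(), a.bcol, a.occupancy) for a in r.atoms],
            )
            for r in self.residues
        ]
        return StructureModel(self.model_id, residues, self.chain_id)


@dataclass(frozen=True)
class ResidueRangeSpec:
    """Sorted, non-overlapping inclusive residue intervals (1-based)."""

    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_hi = None
        for lo, hi in self.intervals:
            if lo > hi:
                raise ValueError(f"inverted interval {lo}-{hi}")
            if prev_hi is not None and lo <= prev_hi:
                raise ValueError("overlapping or unsorted intervals")
            prev_hi = hi

    def __contains__(self, number: int) -> bool:
        return any(lo <= number <= hi for lo, hi in self.intervals)


@dataclass
class AlignmentMap:
    """One-to-one residue pairing between a model and a target."""

    pairs: list[tuple[tuple[int, str], tuple[int, str]]]

    @property
    def coverage(self) -> int:
        return len(self.pairs)


@dataclass
class TargetRecord:
    """One refinement target: ranges, size, category, start-model quality."""

    target_id: str
    range_spec: ResidueRangeSpec
    nres: int
    category: str
    start_model_id: str
    start_gdt_ha: float

    def __post_init__(self) -> None:
        if self.category not in VALID_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.nres != count_residues(self.range_spec):
            raise ValueError(
                f"{self.target_id}: nres {self.nres} inconsistent with ranges "
                f"({count_residues(self.range_spec)})"
            )


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi)
# ---------------------------------------------------------------------------

def _element_of(atom: gemmi.Atom) -> str:
    name = atom.element.name
    if name and name != "X":
        return name
    label = atom.name.strip("0123456789")
    return label[:1] if label else "C"


def read_pdb(path: str | Path, model_id: str | None = None) -> StructureModel:
    """Parse the first model / first chain of a PDB file.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties: first encountered).  The B-factor column is stored in ``bcol``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0 or len(st[0]) == 0:
        raise ValueError(f"{path}: no ATOM records")
    chain = st[0][0]
    residues: list[Residue] = []
    for gres in chain:
        if gres.het_flag != "A":  # polymer ATOM records only
            continue
        # resolve altlocs: keep the highest-occupancy atom per label
        chosen: dict[str, gemmi.Atom] = {}
        for atom in gres:
            prev = chosen.get(atom.name)
            if prev is None or atom.occ > prev.occ:
                chosen[atom.name] = atom
        atoms = [
            AtomRecord(
                name=a.name,
                element=_element_of(a),
                coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                bcol=max(a.b_iso, 0.0),
                occupancy=a.occ,
            )
            for a in chosen.values()
        ]
        icode = gres.seqid.icode.strip()
        residues.append(Residue(gres.seqid.num, gres.name, icode, atoms))
    if not residues:
        raise ValueError(f"{path}: no ATOM records")
    residues.sort(key=lambda r: (r.number, r.insertion_code))
    return StructureModel(model_id or path.stem, residues, chain.name or "A")


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as standard ATOM records."""
    st = gemmi.Structure()
    st.name = structure.model_id
    model = gemmi.Model(1)
    chain = gemmi.Chain(structure.chain_id or "A")
    for res in structure.residues:
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
        gres.het_flag = "A"
        for a in res.atoms:
            atom = gemmi.Atom()
            atom.name = a.name
            atom.pos = gemmi.Position(*a.coords)
            atom.occ = a.occupancy
            atom.b_iso = a.bcol
            atom.element = gemmi.Element(a.element)
            gres.add_atom(atom)
        chain.add_residue(gres)
    model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


def has_usable_error_estimates(structure: StructureModel) -> bool:
    """Whether the B-column plausibly carries per-atom error estimates.

    Constant columns of 0 or 1 mark submissions that did not provide
    estimates; they are excluded from ASE scoring rather than zero-filled.
    """
    values = np.array([a.bcol for r in structure.residues for a in r.atoms])
    if values.size == 0:
        return False
    if np.allclose(values, values[0]) and (
        np.isclose(values[0], 0.0) or np.isclose(values[0], 1.0)
    ):
        return False
    return True


# ---------------------------------------------------------------------------
# Residue ranges
# ---------------------------------------------------------------------------

def parse_residue_ranges(text: str) -> ResidueRangeSpec:
    """Parse "43-95, 106-181"-style range text (any common hyphen dialect)."""
    for h in _HYPHENS:
        text = text.replace(h, "-")
    intervals: list[tuple[int, int]] = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        # split on the dash separating two bounds, allowing negative numbers
        parts = token.split("-")
        parts = [p.strip() for p in parts if p.strip()]
        try:
            if len(parts) == 1:
                lo = hi = int(parts[0])
            elif len(parts) == 2:
                lo, hi = int(parts[0]), int(parts[1])
            else:
                raise ValueError
        except ValueError:
            raise ValueError(f"unparseable range token {token!r}") from None
        if lo > hi:
            raise ValueError(f"inverted interval {lo}-{hi}")
        intervals.append((lo, hi))
    if not intervals:
        raise ValueError(f"no intervals in {text!r}")
    intervals.sort()
    return ResidueRangeSpec(tuple(intervals))


def count_residues(spec: ResidueRangeSpec) -> int:
    """Total residues covered by the spec (inclusive intervals)."""
    return sum(hi - lo + 1 for lo, hi in spec.intervals)


# ---------------------------------------------------------------------------
# Residue pairing
# ---------------------------------------------------------------------------

def pair_by_residue_number(
    model: StructureModel,
    target: StructureModel,
    spec: ResidueRangeSpec | None = None,
) -> AlignmentMap:
    """Pair residues sharing (number, insertion code), optionally restricted
    to a residue-range spec.  This is sequence-dependent pairing: no search
    over alignments is performed."""
    pairs = []
    for res in model.residues:
        if spec is not None and res.number not in spec:
            continue
        if res.key in target:
            pairs.append((res.key, res.key))
    if not pairs:
        raise ValueError("zero paired residues between model and target")
    return AlignmentMap(pairs)


# ---------------------------------------------------------------------------
# Target table
# ---------------------------------------------------------------------------

_TABLE_PATH = Path(__file__).parent / "data" / "casp13_refinement_targets.tsv"


def _normalise_category(cat: str) -> str:
    for h in _HYPHENS:
        cat = cat.replace(h, "-")
    return cat.strip()


def read_target_table(path: str | Path) -> list[TargetRecord]:
    """Read a tab- or comma-delimited target-definition table.

    Expected columns: target_id, residues_included, nres, category,
    start_model, start_gdt_ha.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"target_id", "residues_included", "nres", "category", "start_model", "start_gdt_ha"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"target table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            TargetRecord(
                target_id=str(row.target_id),
                range_spec=parse_residue_ranges(str(row.residues_included)),
                nres=int(row.nres),
                category=_normalise_category(str(row.category)),
                start_model_id=str(row.start_model),
                start_gdt_ha=float(row.start_gdt_ha),
            )
        )
    return records


def casp13_target_table() -> list[TargetRecord]:
    """The packaged CASP13 refinement target-definition table (29 targets)."""
    return read_target_table(_TABLE_PATH)


def target_table_stats(records: Sequence[TargetRecord]) -> dict:
    """Descriptive statistics of a target table.

    Start-model GDT_HA mean and SD are reported to one decimal; the SD uses
    the sample (n-1) convention.
    """
    if len(records) < 2:
        raise ValueError("need at least two target records")
    gdt = [r.start_gdt_ha for r in records]
    nres = [r.nres for r in records]
    return {
        "n": len(records),
        "start_gdt_ha_min": min(gdt),
        "start_gdt_ha_max": max(gdt),
        "start_gdt_ha_mean": round(statistics.fmean(gdt), 1),
        "start_gdt_ha_median": statistics.median(gdt),
        "start_gdt_ha_sd": round(statistics.stdev(gdt), 1),
        "nres_min": min(nres),
        "nres_max": max(nres),
        "category_counts": dict(Counter(r.category for r in records)),
    }
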