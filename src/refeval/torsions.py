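"""Torsion-space model scoring.

Extracts backbone (phi/psi/omega) and side-chain (chi1..chi4) torsion angles
from parsed structures, measures circular deviations between conformations,
classifies residues into "good" regions (where the starting model already
agrees with the target, defined by a mean backbone torsion difference below
30 degrees) and the remainder, and aggregates a composite torsion score from
weighted backbone and side-chain deviation terms.

Two-fold-symmetric terminal torsions (Phe/Tyr chi2, Asp chi2, Glu chi3) are
compared under a 180-degree periodicity so that chemically indistinguishable
labelings never register as deviations.  Omega is excluded from the backbone
deviation by default — the good/bad region threshold applies to phi/psi —
and can be enabled via the config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import StructureModel
from .superpose import kabsch

__all__ = [
    "CHI_ATOMS",
    "SYMMETRIC_CHI",
    "TorsionConfig",
    "ResidueTorsions",
    "TorsionProfile",
    "TorsionScore",
    "RegionStats",
    "RegionSummary",
    "dihedral",
    "circular_diff",
    "chi_deviation",
    "extract_torsions",
    "residue_backbone_error",
    "classify_regions",
    "s_torsion",
    "region_summaries",
    "profile_frame",
]

# Standard chi-angle atom quadruples.  chi_k is the torsion about the k-th
# side-chain bond; the fourth atom of chi_k is the moving atom placed by it.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# (residue name, chi index 1-based) pairs with two-fold terminal symmetry.
SYMMETRIC_CHI: frozenset[tuple[str, int]] = frozenset(
    {("PHE", 2), ("TYR", 2), ("ASP", 2), ("GLU", 3)}
)

CHAIN_BREAK_CN = 2.5  # A; C(i-1)-N(i) beyond this is a chain break


@dataclass
class TorsionConfig:
    region_threshold: float = 30.0  # degrees
    backbone_weight: float = 0.5
    sidechain_weight: float = 0.5
    include_omega: bool = False

    def __post_init__(self) -> None:
        if self.backbone_weight < 0 or self.sidechain_weight < 0:
            raise ValueError("weights must be non-negative")
        if not math.isclose(self.backbone_weight + self.sidechain_weight, 1.0):
            raise ValueError("weights must sum to 1")


@dataclass
class ResidueTorsions:
    name: str
    phi: float | None = None
    psi: float | None = None
    omega: float | None = None
    chis: list[float | None] = field(default_factory=list)


@dataclass
class TorsionProfile:
    """Per-residue torsions of one structure, keyed by (number, icode)."""

    residues: dict[tuple[int, str], ResidueTorsions]

    def keys(self):
        return self.residues.keys()

    def __getitem__(self, key) -> ResidueTorsions:
        return self.residues[key]

    def __contains__(self, key) -> bool:
        return key in self.residues


@dataclass
class TorsionScore:
    score: float  # -(wb*backbone + ws*sidechain); 0 = identical conformation
    backbone_term: float | None
    sidechain_term: float | None
    n_backbone: int
    n_sidechain: int


@dataclass
class RegionStats:
    n: int
    backbone: float | None  # mean backbone torsion deviation, degrees
    sidechain: float | None  # mean side-chain torsion deviation, degrees
    ca_rmsd: float | None  # A, after all-Calpha alignment


@dataclass
class RegionSummary:
    good: RegionStats
    bad: RegionStats


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle about the p2-p3 axis, degrees in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9 or b2n < 1e-9:
        raise ValueError("collinear points: torsion undefined")
    x = n1 @ n2
    y = np.cross(n1, n2) @ b2 / b2n
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 + 1e-12 else ang


def circular_diff(a: float, b: float) -> float:
    """Shortest angular distance, degrees in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def chi_deviation(resname: str, chi_index: int, a: float, b: float) -> float:
    """Circular chi difference; two-fold-symmetric angles folded to [0, 90]."""
    d = circular_diff(a, b)
    if (resname, chi_index) in SYMMETRIC_CHI:
        d = min(d, 180.0 - d)
    return d


def _coords(res, label):
    atom = res.atom(label)
    return None if atom is None else atom.coords


def extract_torsions(structure: StructureModel) -> TorsionProfile:
    """Backbone and side-chain torsions; missing atoms or chain breaks yield
    nulls rather than errors."""
    residues = structure.residues
    out: dict[tuple[int, str], ResidueTorsions] = {}

    def connected(prev, curr) -> bool:
        c = _coords(prev, "C")
        n = _coords(curr, "N")
        return c is not None and n is not None and np.linalg.norm(c - n) <= CHAIN_BREAK_CN

    for i, res in enumerate(residues):
        rt = ResidueTorsions(name=res.name)
        n, ca, c = (_coords(res, lab) for lab in ("N", "CA", "C"))
        prev = residues[i - 1] if i > 0 else None
        nxt = residues[i + 1] if i + 1 < len(residues) else None
        if prev is not None and connected(prev, res):
            pc, pca = _coords(prev, "C"), _coords(prev, "CA")
            if all(v is not None for v in (pc, n, ca, c)):
                rt.phi = dihedral(pc, n, ca, c)
            if all(v is not None for v in (pca, pc, n, ca)):
                rt.omega = dihedral(pca, pc, n, ca)
        if nxt is not None and connected(res, nxt):
            nn = _coords(nxt, "N")
            if all(v is not None for v in (n, ca, c, nn)):
                rt.psi = dihedral(n, ca, c, nn)
        for quad in CHI_ATOMS.get(res.name, []):
            pts = [_coords(res, lab) for lab in quad]
            rt.chis.append(dihedral(*pts) if all(p is not None for p in pts) else None)
        out[res.key] = rt
    return TorsionProfile(out)


def residue_backbone_error(
    profile_a: TorsionProfile,
    profile_b: TorsionProfile,
    key: tuple[int, str],
    config: TorsionConfig | None = None,
) -> float | None:
    """Mean circular difference over the backbone angles defined in both
    profiles for this residue (phi/psi; omega only if configured)."""
    config = config or TorsionConfig()
    ra, rb = profile_a[key], profile_b[key]
    diffs = []
    pairs = [(ra.phi, rb.phi), (ra.psi, rb.psi)]
    if config.include_omega:
        pairs.append((ra.omega, rb.omega))
    for a, b in pairs:
        if a is not None and b is not None:
            diffs.append(circular_diff(a, b))
    return float(np.mean(diffs)) if diffs else None


def _residue_sidechain_error(
    profile_a: TorsionProfile, profile_b: TorsionProfile, key: tuple[int, str]
) -> float | None:
    ra, rb = profile_a[key], profile_b[key]
    diffs = [
        chi_deviation(ra.name, k + 1, a, b)
        for k, (a, b) in enumerate(zip(ra.chis, rb.chis))
        if a is not None and b is not None
    ]
    return float(np.mean(diffs)) if diffs else None


def classify_regions(
    start_profile: TorsionProfile,
    target_profile: TorsionProfile,
    config: TorsionConfig | None = None,
) -> dict[tuple[int, str], bool | None]:
    """True = "good" (mean backbone torsion difference below the threshold),
    False = "bad", None = unclassifiable (no backbone angle in common)."""
    config = config or TorsionConfig()
    mask: dict[tuple[int, str], bool | None] = {}
    for key in start_profile.keys():
        if key not in target_profile:
            continue
        err = residue_backbone_error(start_profile, target_profile, key, config)
        mask[key] = None if err is None else err < config.region_threshold
    return mask


def s_torsion(
    model_profile: TorsionProfile,
    target_profile: TorsionProfile,
    config: TorsionConfig | None = None,
) -> TorsionScore:
    """Composite torsion score (0 for identical conformations, negative
    otherwise).

    backbone term: mean residue backbone error over shared residues.
    side-chain term: mean symmetry-corrected chi deviation over residues with
    at least one shared chi.  If a structure has no side-chain torsions at
    all the score falls back to the backbone term alone (weights are
    renormalised over the available terms), and vice versa.
    """
    config = config or TorsionConfig()
    shared = [k for k in model_profile.keys() if k in target_profile]
    if not shared:
        raise ValueError("no shared residues between torsion profiles")
    bb = [e for k in shared
          if (e := residue_backbone_error(model_profile, target_profile, k, config)) is not None]
    sc = [e for k in shared
          if (e := _residue_sidechain_error(model_profile, target_profile, k)) is not None]
    if not bb and not sc:
        raise ValueError("no shared torsions between profiles")
    bb_term = float(np.mean(bb)) if bb else None
    sc_term = float(np.mean(sc)) if sc else None
    w_bb = config.backbone_weight if bb else 0.0
    w_sc = config.sidechain_weight if sc else 0.0
    total_w = w_bb + w_sc
    if total_w == 0:  # all weight on a missing term: fall back to the other
        w_bb, w_sc = (1.0, 0.0) if bb else (0.0, 1.0)
        total_w = 1.0
    score = -(w_bb * (bb_term or 0.0) + w_sc * (sc_term or 0.0)) / total_w
    return TorsionScore(
        score=score,
        backbone_term=bb_term,
        sidechain_term=sc_term,
        n_backbone=len(bb),
        n_sidechain=len(sc),
    )


def _region_ca_rmsd(
    model: StructureModel, reference: StructureModel, region_keys: set
) -> float | None:
    """Calpha RMSD over the region after aligning on ALL shared Calphas."""
    mc, rc, keys = [], [], []
    for res in model.residues:
        if res.key not in reference:
            continue
        ma, ra = res.ca, reference.residue(res.key).ca
        if ma is None or ra is None:
            continue
        mc.append(ma.coords)
        rc.append(ra.coords)
        keys.append(res.key)
    if len(mc) < 3:
        return None
    fit = kabsch(np.array(mc), np.array(rc))
    dev = np.linalg.norm(fit.apply(np.array(mc)) - np.array(rc), axis=1)
    sel = [i for i, k in enumerate(keys) if k in region_keys]
    if not sel:
        return None
    return float(np.sqrt(np.mean(dev[sel] ** 2)))


def _summarise(
    model: StructureModel,
    reference: StructureModel,
    pm: TorsionProfile,
    pr: TorsionProfile,
    mask: dict,
    config: TorsionConfig,
) -> RegionSummary:
    stats = {}
    for good in (True, False):
        keys = {k for k, v in mask.items() if v is good and k in pm and k in pr}
        bb = [e for k in keys
              if (e := residue_backbone_error(pm, pr, k, config)) is not None]
        sc = [e for k in keys if (e := _residue_sidechain_error(pm, pr, k)) is not None]
        stats[good] = RegionStats(
            n=len(keys),
            backbone=float(np.mean(bb)) if bb else None,
            sidechain=float(np.mean(sc)) if sc else None,
            ca_rmsd=_region_ca_rmsd(model, reference, keys) if keys else None,
        )
    return RegionSummary(good=stats[True], bad=stats[False])


def region_summaries(
    start: StructureModel,
    model: StructureModel,
    target: StructureModel,
    config: TorsionConfig | None = None,
) -> tuple[RegionSummary, RegionSummary]:
    """Change-from-start and residual-vs-target summaries split by the
    good/bad regions of the starting model.

    Returns (change, residual): for each region, the mean backbone torsion
    deviation, mean side-chain torsion deviation, and Calpha RMSD of the
    model against the start (change) and against the target (residual),
    with Calpha RMSDs computed after alignment on all shared Calphas.
    """
    config = config or TorsionConfig()
    ps = extract_torsions(start)
    pm = extract_torsions(model)
    pt = extract_torsions(target)
    mask = classify_regions(ps, pt, config)
    change = _summarise(model, start, pm, ps, mask, config)
    residual = _summarise(model, target, pm, pt, mask, config)
    return change, residual


def profile_frame(
    profile: TorsionProfile,
    regions: dict | None = None,
    backbone_errors: dict | None = None,
) -> pd.DataFrame:
    """Per-residue torsion table (exportable as CSV)."""
    rows = []
    for key, rt in profile.residues.items():
        row = {
            "residue": key[0],
            "insertion_code": key[1],
            "name": rt.name,
            "phi": rt.phi,
            "psi": rt.psi,
            "omega": rt.omega,
        }
        for k in range(4):
            row[f"chi{k + 1}"] = rt.chis[k] if k < len(rt.chis) else None
        if regions is not None:
            flag = regions.get(key)
            row["region"] = None if flag is None else ("good" if flag else "bad")
        if backbone_errors is not None:
            row["backbone_error"] = backbone_errors.get(key)
        rows.append(row)
    return pd.DataFrame(rows)
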