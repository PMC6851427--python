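"""Superposition-free and locality-based model quality metrics.

* lDDT — the local Distance Difference Test: the fraction of target
  inter-atomic distances (within an inclusion radius, between different
  residues) reproduced by the model within a set of thresholds, averaged
  over thresholds.  Computed stereochemistry-unaware and symmetry-naive:
  ambiguous terminal atoms (OD1/OD2 and the like) are matched by label.
* SphereGrinder — per-residue local environment score: all-atom RMSD of the
  target atoms within a sphere around each residue's Calpha after local
  superposition, summarised as the percentage of residues under RMSD
  cutoffs.
* ASE — accuracy of self-estimates of coordinate error: agreement between
  the predicted per-residue error and the actual Calpha deviation, both
  mapped through the sigmoid S(d) = 1 / (1 + (d/d0)^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .structures import AlignmentMap, StructureModel
from .superpose import kabsch

__all__ = [
    "LddtConfig",
    "SphereGrinderConfig",
    "AseConfig",
    "lddt",
    "sphere_grinder",
    "sphere_rmsds",
    "aggregate_sphere_scores",
    "ase",
    "ase_sigmoid",
]


@dataclass
class LddtConfig:
    inclusion_radius: float = 15.0
    thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    min_sequence_separation: int = 1  # 1 = exclude intra-residue pairs

    def __post_init__(self) -> None:
        if self.inclusion_radius <= max(self.thresholds):
            raise ValueError("inclusion radius must exceed the largest threshold")


@dataclass
class SphereGrinderConfig:
    sphere_radius: float = 6.0
    rmsd_cutoffs: tuple[float, ...] = (2.0, 4.0)

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0:
            raise ValueError("sphere radius must be positive")
        if list(self.rmsd_cutoffs) != sorted(self.rmsd_cutoffs):
            raise ValueError("cutoffs must be ascending")


@dataclass
class AseConfig:
    d0: float = 5.0

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")


def _common_atoms(
    model: StructureModel, target: StructureModel, amap: AlignmentMap
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Coordinates of atoms present in both partners of each paired residue.

    Returns model coords, target coords, a residue index per atom, and the
    list of residue keys (target side).
    """
    mc, tc, res_idx, res_keys = [], [], [], []
    for i, (mkey, tkey) in enumerate(amap.pairs):
        mres = model.residue(mkey)
        tres = target.residue(tkey)
        for ta in tres.atoms:
            ma = mres.atom(ta.name)
            if ma is None:
                continue
            mc.append(ma.coords)
            tc.append(ta.coords)
            res_idx.append(i)
        res_keys.append(tkey)
    return np.array(mc), np.array(tc), np.array(res_idx), res_keys


def lddt(
    model: StructureModel,
    target: StructureModel,
    amap: AlignmentMap,
    config: LddtConfig | None = None,
) -> float:
    """lDDT score in [0, 1] over all shared atoms of the paired residues."""
    config = config or LddtConfig()
    mc, tc, res_idx, _ = _common_atoms(model, target, amap)
    if len(tc) < 2:
        raise ValueError("no qualifying atom pairs for lDDT")
    dt = pdist(tc)
    dm = pdist(mc)
    n = len(tc)
    iu = np.triu_indices(n, k=1)
    sep = np.abs(res_idx[iu[0]] - res_idx[iu[1]])
    mask = (dt <= config.inclusion_radius) & (sep >= config.min_sequence_separation)
    if not mask.any():
        raise ValueError("no qualifying atom pairs for lDDT")
    delta = np.abs(dm[mask] - dt[mask])
    fractions = [(delta < t).mean() for t in config.thresholds]
    return float(np.mean(fractions))


def sphere_rmsds(
    model: StructureModel,
    target: StructureModel,
    amap: AlignmentMap,
    config: SphereGrinderConfig | None = None,
) -> dict:
    """Per-residue local-environment RMSD (A) after sphere superposition.

    For each paired residue, the target atoms within ``sphere_radius`` of its
    Calpha plus the residue's own atoms define the sphere; the corresponding
    model atoms are superposed onto them and the all-atom RMSD recorded.
    Spheres with fewer than 3 shared atoms are skipped with a warning.
    """
    config = config or SphereGrinderConfig()
    mc, tc, res_idx, res_keys = _common_atoms(model, target, amap)
    if len(tc) == 0:
        raise ValueError("no shared atoms for SphereGrinder")
    out: dict = {}
    for i, (mkey, tkey) in enumerate(amap.pairs):
        tres = target.residue(tkey)
        ca = tres.ca
        if ca is None:
            continue
        dist = np.linalg.norm(tc - ca.coords, axis=1)
        sel = (dist <= config.sphere_radius) | (res_idx == i)
        if sel.sum() < 3:
            warnings.warn(f"residue {tkey}: sphere has fewer than 3 shared atoms; skipped",
                          stacklevel=2)
            continue
        out[tkey] = kabsch(mc[sel], tc[sel]).rmsd
    if not out:
        raise ValueError("no residue spheres with enough shared atoms")
    return out


def aggregate_sphere_scores(
    rmsds: "list[float] | np.ndarray", config: SphereGrinderConfig | None = None
) -> float:
    """Percentage-under-cutoff summary of per-residue sphere RMSDs."""
    config = config or SphereGrinderConfig()
    r = np.asarray(list(rmsds), dtype=float)
    if r.size == 0:
        raise ValueError("no sphere RMSDs to aggregate")
    return float(np.mean([100.0 * (r < c).mean() for c in config.rmsd_cutoffs]))


def sphere_grinder(
    model: StructureModel,
    target: StructureModel,
    amap: AlignmentMap,
    config: SphereGrinderConfig | None = None,
) -> float:
    """SphereGrinder score in [0, 100]."""
    config = config or SphereGrinderConfig()
    return aggregate_sphere_scores(sphere_rmsds(model, target, amap, config).values(), config)


def ase_sigmoid(d: "float | np.ndarray", d0: float = 5.0) -> "float | np.ndarray":
    """S(d) = 1 / (1 + (d/d0)^2) — maps a distance to a (0, 1] similarity."""
    d = np.asarray(d, dtype=float)
    out = 1.0 / (1.0 + (d / d0) ** 2)
    return float(out) if out.ndim == 0 else out


def ase(
    predicted_errors: "np.ndarray | list[float]",
    actual_deviations: "np.ndarray | list[float]",
    config: AseConfig | None = None,
) -> float:
    """Accuracy self-estimate score in [0, 100].

    ASE = 100 * (1 - mean_i |S(e_i) - S(d_i)|) over paired residues, where
    e_i is the predicted coordinate error and d_i the actual Calpha deviation
    under the RMS_CA superposition.  Submissions without usable estimates are
    flagged upstream and excluded from the z-score pool rather than scored.
    """
    config = config or AseConfig()
    e = np.asarray(predicted_errors, dtype=float)
    d = np.asarray(actual_deviations, dtype=float)
    if e.shape != d.shape or e.ndim != 1 or e.size == 0:
        raise ValueError("predicted and actual vectors must be equal-length, non-empty")
    if np.any(e < 0) or np.any(d < 0):
        raise ValueError("errors and deviations must be non-negative")
    s_e = ase_sigmoid(e, config.d0)
    s_d = ase_sigmoid(d, config.d0)
    return float(100.0 * (1.0 - np.mean(np.abs(s_e - s_d))))
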