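"""Synthetic structures, perturbations, and prediction-set scenarios.

Everything here exists so that every metric and ranking operation can be
exercised with known ground truth and no external structure data.  Chains are
built from ideal backbone geometry with requested phi/psi torsions; side
chains are linear idealized chains following the standard chi-angle atom
definitions (no rotamer library, no branch atoms beyond the chi chain) —
non-physical, but exactly what the torsion and distance metrics measure.

Perturbation kinds mirror the error modes seen in refinement targets:

* ``coordinate_noise`` — i.i.d. Gaussian displacement of every atom,
* ``rigid_shift_element`` — a secondary-structure element translated away
  from its true position (the classic shifted-helix failure),
* ``register_shift`` — a segment renumbered by a residue offset, emulating a
  sequence-register error,
* ``sidechain_scramble`` — chi angles redrawn at fixed backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .local_scores import ase, sphere_grinder, lddt
from .ranking import MetricTable
from .structures import AlignmentMap, AtomRecord, Residue, StructureModel, pair_by_residue_number
from .superpose import gdt, per_residue_ca_deviations, rms_ca
from .torsions import CHI_ATOMS, extract_torsions, s_torsion

__all__ = [
    "PerturbationSpec",
    "ScenarioSpec",
    "ScenarioResult",
    "make_ideal_chain",
    "apply_perturbation",
    "compute_metrics",
    "generate_scenario",
]

# Ideal backbone internal coordinates (A, degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
BOND_SIDECHAIN = 1.52
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_SIDECHAIN = 114.0
OMEGA_TRANS = 180.0

AA_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

_ELEMENT = {"N": "N", "O": "O", "S": "S"}


def _element_for(name: str) -> str:
    return _ELEMENT.get(name.strip("0123456789")[:1], "C")


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension-reference-frame placement: position a new atom at
    the given bond length from ``c``, bond angle at ``c``, and torsion about
    the b-c axis (degrees)."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _sidechain_chain(resname: str) -> list[str]:
    """Atom names placed successively by chi1, chi2, ... (after CB)."""
    return [quad[3] for quad in CHI_ATOMS.get(resname, [])]


_DEFAULT_CHIS = (-60.0, 180.0, -60.0, 180.0)


def make_ideal_chain(
    n_residues: int,
    phi: "float | list[float]" = -57.0,
    psi: "float | list[float]" = -47.0,
    sequence: str | None = None,
    chis: "dict[int, list[float]] | None" = None,
    start_number: int = 1,
    model_id: str = "ideal",
    chain_id: str = "A",
) -> StructureModel:
    """Build a chain with ideal bond geometry and the requested torsions.

    ``phi``/``psi`` may be scalars or per-residue lists; ``sequence`` is a
    1-letter string (default poly-alanine); ``chis`` maps residue index
    (0-based) to chi values, defaulting to a fixed rotamer.  Deterministic:
    two calls with the same arguments give bit-identical coordinates.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    phis = [phi] * n_residues if np.isscalar(phi) else list(phi)
    psis = [psi] * n_residues if np.isscalar(psi) else list(psi)
    if len(phis) != n_residues or len(psis) != n_residues:
        raise ValueError("phi/psi lists must match n_residues")
    seq = sequence or "A" * n_residues
    if len(seq) != n_residues:
        raise ValueError("sequence length must match n_residues")

    # first residue: N at origin, CA on x, C in the xy-plane
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_residues):
        prev = coords[i - 1]
        n = place_atom(prev["N"], prev["CA"], prev["C"],
                       BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        ca = place_atom(prev["CA"], prev["C"], n,
                        BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        c = place_atom(prev["C"], n, ca, BOND_CA_C, ANGLE_N_CA_C, phis[i])
        coords.append({"N": n, "CA": ca, "C": c})

    residues: list[Residue] = []
    for i, atom_map in enumerate(coords):
        resname = AA_THREE[seq[i]]
        n, ca, c = atom_map["N"], atom_map["CA"], atom_map["C"]
        # carbonyl O: anti to the next N (torsion psi + 180 about CA-C)
        atom_map["O"] = place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psis[i] + 180.0)
        if resname != "GLY":
            # CB off the backbone plane (L-configuration improper)
            atom_map["CB"] = place_atom(c, n, ca, BOND_CA_CB, 110.5, -122.6)
            chain = _sidechain_chain(resname)
            chi_vals = (chis or {}).get(i, list(_DEFAULT_CHIS[: len(chain)]))
            prev3 = [n, ca, atom_map["CB"]]
            for k, label in enumerate(chain):
                chi = chi_vals[k] if k < len(chi_vals) else _DEFAULT_CHIS[k % 4]
                pos = place_atom(prev3[-3], prev3[-2], prev3[-1],
                                 BOND_SIDECHAIN, ANGLE_SIDECHAIN, chi)
                atom_map[label] = pos
                prev3.append(pos)
        atoms = [
            AtomRecord(label, _element_for(label), xyz)
            for label, xyz in atom_map.items()
        ]
        residues.append(Residue(start_number + i, resname, "", atoms))
    return StructureModel(model_id, residues, chain_id)


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

@dataclass
class PerturbationSpec:
    """Exactly one perturbation kind with its parameters."""

    kind: str  # coordinate_noise | rigid_shift_element | register_shift | sidechain_scramble
    sigma: float | None = None  # A, for coordinate_noise
    translation: "np.ndarray | None" = None  # A, for rigid_shift_element
    interval: tuple[int, int] | None = None  # residue numbers, inclusive
    offset: int | None = None  # residues, for register_shift
    seed: int | None = None  # mandatory for stochastic kinds

    KINDS = ("coordinate_noise", "rigid_shift_element", "register_shift", "sidechain_scramble")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind in ("coordinate_noise", "sidechain_scramble") and self.seed is None:
            raise ValueError(f"{self.kind} requires a seed")
        if self.kind == "coordinate_noise" and self.sigma is None:
            raise ValueError("coordinate_noise requires sigma")
        if self.kind == "rigid_shift_element" and (
            self.translation is None or self.interval is None
        ):
            raise ValueError("rigid_shift_element requires translation and interval")
        if self.kind == "register_shift" and (self.offset is None or self.interval is None):
            raise ValueError("register_shift requires offset and interval")


def _check_interval(structure: StructureModel, interval: tuple[int, int]) -> None:
    numbers = {r.number for r in structure.residues}
    lo, hi = interval
    if not any(lo <= n <= hi for n in numbers):
        raise ValueError(f"interval {interval} outside structure")


def apply_perturbation(structure: StructureModel, spec: PerturbationSpec) -> StructureModel:
    """Return a perturbed copy; the input is never modified."""
    out = structure.copy()
    if spec.kind == "coordinate_noise":
        rng = np.random.default_rng(spec.seed)
        for res in out.residues:
            for atom in res.atoms:
                atom.coords = atom.coords + rng.normal(0.0, spec.sigma, size=3)
    elif spec.kind == "rigid_shift_element":
        _check_interval(out, spec.interval)
        lo, hi = spec.interval
        t = np.asarray(spec.translation, dtype=float)
        for res in out.residues:
            if lo <= res.number <= hi:
                for atom in res.atoms:
                    atom.coords = atom.coords + t
    elif spec.kind == "register_shift":
        _check_interval(out, spec.interval)
        lo, hi = spec.interval
        original = {r.number for r in out.residues}
        kept: list[Residue] = []
        taken: set[int] = set()
        # residues outside the segment keep their numbers
        for res in out.residues:
            if not (lo <= res.number <= hi):
                kept.append(res)
                taken.add(res.number)
        for res in out.residues:
            if lo <= res.number <= hi:
                new_number = res.number + spec.offset
                if new_number in taken or new_number not in original:
                    continue  # pushed onto an occupied number or outside the range
                res.number = new_number
                kept.append(res)
                taken.add(new_number)
        kept.sort(key=lambda r: (r.number, r.insertion_code))
        out = StructureModel(out.model_id, kept, out.chain_id)
    elif spec.kind == "sidechain_scramble":
        rng = np.random.default_rng(spec.seed)
        for res in out.residues:
            chain = _sidechain_chain(res.name)
            if not chain:
                continue
            n, ca, cb = res.atom("N"), res.atom("CA"), res.atom("CB")
            if n is None or ca is None or cb is None:
                continue
            prev3 = [n.coords, ca.coords, cb.coords]
            for label in chain:
                atom = res.atom(label)
                if atom is None:
                    break
                chi = rng.uniform(-180.0, 180.0)
                atom.coords = place_atom(prev3[-3], prev3[-2], prev3[-1],
                                         BOND_SIDECHAIN, ANGLE_SIDECHAIN, chi)
                prev3.append(atom.coords)
    return out


# ---------------------------------------------------------------------------
# full scenarios
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSpec:
    """A synthetic prediction set: targets, start models, group submissions."""

    seed: int
    n_targets: int = 4
    n_groups: int = 6
    n_residues: int = 48
    start_sigma: float = 1.2  # A of coordinate noise separating start from target
    # per-group probability of improving (moving toward the target) rather
    # than degrading the start; length n_groups or a scalar applied to all
    improvement_bias: "float | list[float]" = 0.5
    # mean/sd of the degradation noise magnitude (A) and of the improvement
    # fraction (how far toward the target an improving model moves)
    quality_spread: tuple[float, float] = (1.0, 0.3)
    improve_fraction: tuple[float, float] = (0.7, 0.15)

    def __post_init__(self) -> None:
        biases = self.biases()
        if any(not 0.0 <= b <= 1.0 for b in biases):
            raise ValueError("improvement biases must be in [0, 1]")

    def biases(self) -> list[float]:
        if np.isscalar(self.improvement_bias):
            return [float(self.improvement_bias)] * self.n_groups
        return [float(b) for b in self.improvement_bias]


@dataclass
class ScenarioResult:
    targets: dict[str, StructureModel]
    starts: dict[str, StructureModel]
    submissions: dict[tuple[str, str], StructureModel]
    metric_table: MetricTable
    start_rows: pd.DataFrame  # one row per target with the start-model metrics
    manifest: dict


_SCENARIO_SEQ = "AVLSKDEFRTMQNY"  # mixed sequence, repeated to chain length


def compute_metrics(
    model: StructureModel,
    target: StructureModel,
    predicted_errors: "np.ndarray | None" = None,
) -> dict:
    """All native metrics of one model against one target."""
    amap = pair_by_residue_number(model, target)
    g = gdt(model, target, amap)
    row = {
        "rms_ca": rms_ca(model, target, amap),
        "gdt_ts": g.gdt_ts,
        "gdt_ha": g.gdt_ha,
        "sg": sphere_grinder(model, target, amap),
        "lddt": lddt(model, target, amap),
        "s_torsion": s_torsion(extract_torsions(model), extract_torsions(target)).score,
    }
    if predicted_errors is not None:
        dev = per_residue_ca_deviations(model, target, amap)
        d = np.array([dev[k] for k, _ in amap.pairs if k in dev])
        row["ase"] = ase(predicted_errors[: len(d)], d)
    else:
        row["ase"] = np.nan
    return row


def generate_scenario(spec: ScenarioSpec) -> ScenarioResult:
    """Emit targets, start models, and per-group submissions with known
    ground truth, plus the computed metric table.

    Improving submissions interpolate the start coordinates toward the
    target; degrading ones add extra coordinate noise.  Groups with bias at
    least 0.5 provide per-residue error estimates (the actual deviation with
    mild noise); the rest submit a constant zero column, flagged as
    estimate-free, so their ASE is null.
    """
    rng = np.random.default_rng(spec.seed)
    biases = spec.biases()
    targets: dict[str, StructureModel] = {}
    starts: dict[str, StructureModel] = {}
    submissions: dict[tuple[str, str], StructureModel] = {}
    rows: list[dict] = []
    start_rows: list[dict] = []
    truth: dict = {}

    seq = (_SCENARIO_SEQ * (spec.n_residues // len(_SCENARIO_SEQ) + 1))[: spec.n_residues]
    group_ids = [f"G{g:02d}" for g in range(spec.n_groups)]

    for t in range(spec.n_targets):
        tid = f"T{t:02d}"
        # alternate helix-like and strand-like backbones across targets
        phi, psi = (-57.0, -47.0) if t % 2 == 0 else (-120.0, 130.0)
        target = make_ideal_chain(spec.n_residues, phi, psi, seq, model_id=tid)
        start = apply_perturbation(
            target,
            PerturbationSpec("coordinate_noise", sigma=spec.start_sigma,
                             seed=int(rng.integers(2**31))),
        )
        start.model_id = f"{tid}-start"
        targets[tid] = target
        starts[tid] = start
        start_rows.append({"target_id": tid, **compute_metrics(start, target)})

        t_coords = {
            (res.key, a.name): a.coords for res in target.residues for a in res.atoms
        }
        for gid, bias in zip(group_ids, biases):
            improves = bool(rng.random() < bias)
            model = start.copy()
            if improves:
                f = float(np.clip(rng.normal(*spec.improve_fraction), 0.05, 0.98))
                for res in model.residues:
                    for atom in res.atoms:
                        tgt = t_coords[(res.key, atom.name)]
                        atom.coords = atom.coords + f * (tgt - atom.coords)
                magnitude = -f
            else:
                extra = float(max(rng.normal(*spec.quality_spread), 0.05))
                model = apply_perturbation(
                    model,
                    PerturbationSpec("coordinate_noise", sigma=extra,
                                     seed=int(rng.integers(2**31))),
                )
                magnitude = extra
            model.model_id = f"{tid}-{gid}"
            submissions[(tid, gid)] = model
            truth[f"{tid}/{gid}"] = {"improves": improves, "magnitude": magnitude}

            provides_estimates = bias >= 0.5
            errors = None
            if provides_estimates:
                amap = pair_by_residue_number(model, target)
                dev = per_residue_ca_deviations(model, target, amap)
                d = np.array([dev[k] for k, _ in amap.pairs if k in dev])
                errors = np.clip(d + rng.normal(0.0, 0.25, size=len(d)), 0.0, None)
            rows.append(
                {
                    "target_id": tid,
                    "group_id": gid,
                    "model_index": 1,
                    **compute_metrics(model, target, errors),
                }
            )

    table = MetricTable(pd.DataFrame(rows))
    manifest = {
        "seed": spec.seed,
        "n_targets": spec.n_targets,
        "n_groups": spec.n_groups,
        "n_residues": spec.n_residues,
        "start_sigma": spec.start_sigma,
        "improvement_bias": biases,
        "ground_truth": truth,
    }
    return ScenarioResult(
        targets=targets,
        starts=starts,
        submissions=submissions,
        metric_table=table,
        start_rows=pd.DataFrame(start_rows),
        manifest=manifest,
    )
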