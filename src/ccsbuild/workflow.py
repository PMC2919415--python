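"""Decision tree and end-to-end pipeline.

Routing: a structure missing no mass is used as-is ("complete"); one
missing < 5% of its mass has its computed CCS scaled linearly
("linear_scaled"); larger gaps go through homology modelling when a
template with > 30% sequence identity and < 95% structural completeness
exists, and through coarse-grained sphere modelling otherwise.  The
pipeline then builds archetype trend lines, mines crystal symmetry for
compact candidate packings, selects a nested series against the
experimental CCS table, and emits a ranked, reproducible report.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ccs as ccs_mod
from . import coarse_grain, geometry, structio, symmetry
from .models import AtomicStructure, SphereModel
from .synthetic import read_ccs_table

__all__ = [
    "PathDecision",
    "RankingReport",
    "decide_path",
    "run_pipeline",
    "compare_conformers",
]

log = logging.getLogger("ccsbuild")

SEQ_IDENTITY_MIN = 30.0  # %, homology-template gate
COMPLETENESS_MAX = 95.0  # %, structural-completeness gate


@dataclass(frozen=True)
class PathDecision:
    """Which modelling path a building unit takes, and why."""

    path: str  # complete | linear_scaled | homology | coarse_grained
    f_missing: float
    seq_identity: float | None = None
    structure_completeness: float | None = None
    rationale: str = ""


def decide_path(
    account,
    homolog: tuple | None = None,
    complete_tol: float = 1e-6,
) -> PathDecision:
    """Route a building unit through the modelling decision tree.

    ``homolog`` is an optional (sequence identity %, structural
    completeness %) pair describing the best available template.
    """
    f = account.f_missing
    si, sc = (homolog if homolog is not None else (None, None))
    if f <= complete_tol:
        return PathDecision("complete", f, si, sc, "structure is complete")
    if f < ccs_mod.MISSING_MASS_THRESHOLD:
        return PathDecision(
            "linear_scaled", f, si, sc,
            f"missing {f:.1%} < 5%: scale the computed CCS linearly",
        )
    if si is not None and si > SEQ_IDENTITY_MIN:
        if sc is not None and sc < COMPLETENESS_MAX:
            return PathDecision(
                "homology", f, si, sc,
                f"template with S.I. {si:.0f}% > 30% and S.C. {sc:.0f}% < 95%",
            )
        return PathDecision(
            "coarse_grained", f, si, sc,
            "template is already nearly complete (S.C. >= 95%); falling back "
            "to coarse-grained representation of the missing mass",
        )
    return PathDecision(
        "coarse_grained", f, si, sc,
        "no usable homology template (S.I. <= 30% or none): represent the "
        "missing mass with a coarse-grained sphere",
    )


@dataclass
class RankingReport:
    """Ranked candidates and the selected nested series of a pipeline run."""

    path_decision: PathDecision
    block_ccs: float
    ccs_postscale: float
    candidates: list = field(default_factory=list)  # per-n dict rows
    selected: list = field(default_factory=list)  # selected series rows
    consistent: bool = False
    messages: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "path": {
                "path": self.path_decision.path,
                "f_missing": round(self.path_decision.f_missing, 6),
                "seq_identity": self.path_decision.seq_identity,
                "structure_completeness": self.path_decision.structure_completeness,
                "rationale": self.path_decision.rationale,
            },
            "block_ccs_A2": round(self.block_ccs, 2),
            "ccs_postscale": round(self.ccs_postscale, 6),
            "candidates": self.candidates,
            "selected_series": self.selected,
            "consistent": self.consistent,
            "messages": self.messages,
            "config": self.config,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


_DEFAULTS = {
    "shell": 1,
    "tolerance": 0.10,
    "subunits_per_block": 1,
    "topologies": ["linear", "ring", "collapsed", "edge_to_edge"],
    "overlap": 0.10,
    "scale": 1.0,
    "seed": 0,
    "n_rotations": 120,
    "n_points": 2500,
    "search_n_rotations": 80,
    "search_n_points": 1500,
}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    cfg = dict(_DEFAULTS)
    cfg.update(config)
    if "structure" not in cfg or "ccs_table" not in cfg:
        raise ValueError("config must name 'structure' and 'ccs_table'")
    return cfg


def _experimental_by_blocks(table, subunits_per_block: int) -> dict:
    exp = {}
    for _, row in table.iterrows():
        n_sub = int(row["n_subunits"])
        if n_sub % subunits_per_block:
            continue
        n_blocks = n_sub // subunits_per_block
        rel = float(row["rel_error"]) if "rel_error" in row else None
        exp[n_blocks] = (float(row["ccs_A2"]), rel)
    return exp


def run_pipeline(config, outdir=None) -> RankingReport:
    """Run the full decision-tree pipeline from a config dict or YAML path.

    Stages: read inputs -> mass accounting -> path decision -> building
    block completion -> archetype trend lines -> symmetry mining with
    stepwise nested selection -> ranked report.  Fully reproducible from
    the config's seed; artifacts are written to ``outdir`` when given.
    """
    cfg = _load_config(config)
    seed = int(cfg["seed"])
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    structure = structio.read_structure(cfg["structure"])
    full_seq = None
    if cfg.get("sequence_fasta"):
        full_seq = structio.read_fasta_sequences(cfg["sequence_fasta"])
    account = structio.mass_account(structure, full_sequence=full_seq)

    homolog_info = None
    hom_cfg = cfg.get("homolog")
    if hom_cfg:
        homolog_info = (
            float(hom_cfg["seq_identity"]),
            float(hom_cfg["completeness"]),
        )
    decision = decide_path(account, homolog_info)
    log.info("path decision: %s (%s)", decision.path, decision.rationale)

    table = read_ccs_table(cfg["ccs_table"])
    spb = int(cfg["subunits_per_block"])
    experimental = _experimental_by_blocks(table, spb)
    radii = None
    if cfg.get("radii"):
        radii = ccs_mod.CollisionRadii.from_yaml(cfg["radii"])

    ccs_postscale = 1.0
    block = structure
    messages = []
    if decision.path == "homology":
        block = structio.read_structure(hom_cfg["model"])
    elif decision.path == "linear_scaled":
        ccs_postscale = account.m_full / account.m_present
        messages.append(
            f"CCS values scaled by m_full/m_present = {ccs_postscale:.4f} "
            "for the missing mass"
        )
    elif decision.path == "coarse_grained":
        decomp = coarse_grain.decompose_domains(structure)
        model = coarse_grain.build_sphere_model(
            structure, decomp, radii=radii, seed=seeds[0]
        )
        model = coarse_grain.calibrate_radii(
            structure, model, radii=radii, seed=seeds[1]
        )
        missing_mass = account.m_full - account.m_present
        r_missing = coarse_grain.missing_sphere_radius(model, missing_mass)
        mono_exp = experimental.get(1)
        if mono_exp is not None:
            anchor = max(model.spheres, key=lambda s: s.radius).label
            model, scan = coarse_grain.place_missing_sphere(
                model, anchor, r_missing, mono_exp[0], missing_mass,
                rel_error=mono_exp[1], seed=seeds[2],
            )
            messages.append(
                f"missing-mass sphere (r={r_missing:.1f} Å) placed at overlap "
                f"{scan.best_overlap:.2f}, theta {scan.best_theta:.2f} rad"
            )
            if outdir is not None:
                scan.to_dataframe().to_csv(outdir / "placement_scan.csv", index=False)
        else:
            messages.append(
                "no monomer experimental CCS: missing-mass sphere left at the "
                "most compact placement"
            )
            anchor = max(model.spheres, key=lambda s: s.radius).label
            a = [s for s in model.spheres if s.label == anchor][0]
            model = model.with_sphere(
                coarse_grain.Sphere(
                    label="missing",
                    center=tuple(np.asarray(a.center) + np.array([a.radius, 0, 0])),
                    radius=r_missing,
                    mass=missing_mass,
                    kind="missing",
                )
            )
        block = model
        if outdir is not None:
            structio.write_sphere_pdb(model, outdir / "building_block_cg.pdb")

    block_est = (
        ccs_mod.pa_ccs_spheres(
            block, n_rotations=cfg["n_rotations"], n_points=cfg["n_points"],
            seed=seeds[3], scale=cfg["scale"],
        )
        if isinstance(block, SphereModel)
        else ccs_mod.pa_ccs_atoms(
            block, radii=radii, scale=cfg["scale"],
            n_rotations=cfg["n_rotations"], n_points=cfg["n_points"], seed=seeds[3],
        )
    )
    block_ccs = block_est.value * ccs_postscale

    n_values = sorted(experimental)
    trend = geometry.trend_lines(
        block,
        topologies=cfg["topologies"],
        n_values=n_values,
        experimental=experimental,
        overlap=cfg["overlap"],
        radii=radii,
        n_rotations=cfg["search_n_rotations"],
        n_points=cfg["search_n_points"],
        seed=seeds[4],
        scale=cfg["scale"],
    )
    if outdir is not None:
        trend.to_csv(outdir / "trend_lines.csv")

    candidates = []
    for topo, pts in trend.series.items():
        for n, value, stderr in pts:
            value = value * ccs_postscale
            row = {"topology": topo, "n_blocks": n, "ccs_A2": round(value, 2)}
            if n in experimental:
                dev = ccs_mod.deviation(
                    value, experimental[n][0], rel_error=experimental[n][1],
                    tolerance=cfg["tolerance"],
                )
                row["deviation"] = round(dev.value, 4)
                row["within_error"] = dev.within_error
            candidates.append(row)

    selected = []
    consistent = False
    ops = getattr(structure, "sym_ops", None)
    if ops:
        if isinstance(block, SphereModel):
            # carry the crystal frame of the parent structure with the CG block
            sym_block = symmetry.expand_symmetry(
                _CellCarrier(block, structure.cell), operators=ops,
                shell=cfg["shell"],
            )
        else:
            sym_block = symmetry.expand_symmetry(block, operators=ops,
                                                 shell=cfg["shell"])
        n_max = max(n_values) if n_values else 1
        result = symmetry.stepwise_series(
            sym_block, n_max, experimental,
            tolerance=cfg["tolerance"], radii=radii,
            n_rotations=cfg["search_n_rotations"],
            n_points=cfg["search_n_points"], seed=seeds[5],
            scale=cfg["scale"] * ccs_postscale,
        )
        messages.extend(result.messages)
        for cand in result.series:
            row = {
                "topology": "symmetry_mined",
                "n_blocks": cand.n,
                "members": list(cand.members),
                "compactness_A": round(cand.compactness, 2),
                "symmetry": list(cand.symmetry),
            }
            if cand.ccs is not None:
                row["ccs_A2"] = round(cand.ccs.value, 2)
                row["deviation"] = round(cand.deviation, 4)
                tol = experimental.get(cand.n, (None, None))[1] or cfg["tolerance"]
                row["within_error"] = abs(cand.deviation) <= tol
            selected.append(row)
        if outdir is not None and result.series:
            final = result.series[-1]
            structio.write_sphere_pdb(
                symmetry.assembly_to_sphere_model(sym_block, final.members,
                                                  radii=radii),
                outdir / f"selected_assembly_n{final.n}.pdb",
            )
        consistent = result.complete and all(
            row.get("within_error", True) for row in selected
        )
    else:
        messages.append("no symmetry operators: symmetry mining skipped")

    if not consistent:
        messages.append("no consistent model across all oligomer orders")

    report = RankingReport(
        path_decision=decision,
        block_ccs=block_ccs,
        ccs_postscale=ccs_postscale,
        candidates=candidates,
        selected=selected,
        consistent=consistent,
        messages=messages,
        config={k: v for k, v in cfg.items() if not isinstance(v, (dict, list))}
        | {"topologies": list(cfg["topologies"])},
    )
    if outdir is not None:
        report.to_json(outdir / "report.json")
    return report


class _CellCarrier:
    """Wrap a SphereModel with the parent structure's unit cell for mining."""

    def __init__(self, model: SphereModel, cell):
        self._model = model
        self.cell = cell
        self.sym_ops = None

    @property
    def centers(self):
        return self._model.centers

    @property
    def radii(self):
        return self._model.radii

    @property
    def masses(self):
        return self._model.masses

    def __getattr__(self, name):
        return getattr(self._model, name)


def compare_conformers(
    model_a,
    model_b,
    exp_ccs: float,
    rel_error: float | None = None,
    radii: ccs_mod.CollisionRadii | None = None,
    n_rotations: int = ccs_mod.DEFAULT_N_ROTATIONS,
    n_points: int = ccs_mod.DEFAULT_N_POINTS,
    seed: int = 0,
) -> dict:
    """Pick the conformer whose CCS is closer to a measurement.

    Both models must have the same composition (same total mass within
    0.1% for sphere models, same atom count for atomic models).  Returns
    {"choice": "a"|"b"|"tie", "deviation_a": ..., "deviation_b": ...}.
    """
    def _composition(m):
        if isinstance(m, SphereModel):
            return ("spheres", len(m), round(m.total_mass, 1))
        return ("atoms", m.n_atoms)

    ca, cb = _composition(model_a), _composition(model_b)
    if ca[0] != cb[0] or ca[1] != cb[1]:
        raise ValueError(f"composition mismatch: {ca} vs {cb}")
    if ca[0] == "spheres" and abs(ca[2] - cb[2]) > 1e-3 * max(ca[2], cb[2]):
        raise ValueError(f"composition mismatch: masses {ca[2]} vs {cb[2]}")

    def _ccs(m):
        if isinstance(m, SphereModel):
            return ccs_mod.pa_ccs_spheres(
                m, n_rotations=n_rotations, n_points=n_points, seed=seed
            )
        return ccs_mod.pa_ccs_atoms(
            m, radii=radii, n_rotations=n_rotations, n_points=n_points, seed=seed
        )

    da = ccs_mod.deviation(_ccs(model_a), exp_ccs, rel_error=rel_error)
    db = ccs_mod.deviation(_ccs(model_b), exp_ccs, rel_error=rel_error)
    if abs(abs(da.value) - abs(db.value)) < 1e-9:
        choice = "tie"
    else:
        choice = "a" if abs(da.value) < abs(db.value) else "b"
    return {"choice": choice, "deviation_a": da.value, "deviation_b": db.value}
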