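"""End-to-end orchestration: common lines -> voting -> two embeddings ->
orientation assembly, with optional simulation, reconstruction and
evaluation, persisting every intermediate and a JSON run report.

`estimate_orientations` is the library entry point used by tests and the
acceptance harness; `run_pipeline` adds file I/O around it for the CLI.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .alignment import AlignmentResult, assemble_orientations, build_xaxis_targets
from .commonlines import CommonLineSet, build_common_line_set
from .embedding import EmbeddingProblem, SphereConfig, embed
from .evaluation import compare_orientations, fsc
from .geometry import OrientationSet
from .mrcio import read_stack, write_mrc, write_stack
from .reconstruct import ReconstructionSettings, backproject
from .simulate import ImageStack, NoiseSpec, make_phantom, simulate_dataset
from .stario import write_star
from .voting import build_dihedral_estimates, compute_weights

__all__ = ["PipelineConfig", "OrientationOutcome", "estimate_orientations",
           "run_pipeline", "write_angles_tsv", "read_angles_tsv"]


@dataclass
class PipelineConfig:
    """All tunables of the six-stage pipeline (angles in files are degrees)."""

    # input: either a stack on disk or simulator settings
    input_stack: str | None = None
    simulate_n: int = 30
    simulate_size: int = 64
    simulate_snr: float | None = None  # None = noiseless
    phantom_blobs: int = 8
    # common lines
    L: int = 360
    r_min: float = 3.0
    r_max: float | None = None
    pad: int = 3
    mask_radius: float | None = 0.25
    weighting: str | None = "wiener"
    # voting
    T: int = 180
    weight_percentile: float = 10.0
    # embeddings
    restarts: int = 5
    tol: float = 1e-9
    max_iter: int = 2000
    # misc
    seed: int = 0
    out_dir: str = "cryoembed_run"
    reconstruct: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class OrientationOutcome:
    orientations: OrientationSet
    alignment: AlignmentResult
    common_lines: CommonLineSet
    normals_config: SphereConfig
    xaxes_config: SphereConfig
    stress_normals: float
    stress_xaxes: float


def _stage_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    return {name: int(rng.integers(0, 2**31 - 1))
            for name in ("simulate", "embed_normals", "embed_xaxes")}


def estimate_orientations(stack_data: np.ndarray, L: int = 360,
                          r_min: float = 3.0, r_max: float | None = None,
                          pad: int = 3, mask_radius: float | None = 0.25,
                          weighting: str | None = "wiener",
                          T: int = 180, weight_percentile: float = 10.0,
                          restarts: int = 5, tol: float = 1e-9,
                          max_iter: int = 2000, seed: int = 0) -> OrientationOutcome:
    """Run the six estimation stages on an in-memory image stack."""
    seeds = _stage_seeds(seed)
    cl = build_common_line_set(stack_data, L=L, r_min=r_min, r_max=r_max,
                               pad=pad, mask_radius=mask_radius,
                               weighting=weighting)
    est = build_dihedral_estimates(cl, T=T)
    w = compute_weights(est, percentile=weight_percentile)
    target = est.theta.copy()
    target[w.omega == 0] = np.nan
    prob1 = EmbeddingProblem(target, _zeroed(w, target))
    normals_cfg = embed(prob1, restarts=restarts, tol=tol, max_iter=max_iter,
                        seed=seeds["embed_normals"])
    xt = build_xaxis_targets(cl, normals_cfg, w)
    prob2 = EmbeddingProblem(xt.phi, xt.weights)
    xaxes_cfg = embed(prob2, restarts=restarts, tol=tol, max_iter=max_iter,
                      seed=seeds["embed_xaxes"])
    orientations, alignment = assemble_orientations(normals_cfg, xaxes_cfg, cl)
    return OrientationOutcome(orientations, alignment, cl, normals_cfg,
                              xaxes_cfg, normals_cfg.stress, xaxes_cfg.stress)


def _zeroed(w, target):
    from .voting import WeightMatrix
    omega = w.omega.copy()
    omega[np.isnan(target)] = 0.0
    return WeightMatrix(omega, w.H)


def write_angles_tsv(path, orientations: OrientationSet,
                     deltas: np.ndarray | None = None) -> None:
    deg = np.degrees(orientations.angles)
    with open(path, "w") as fh:
        if deltas is None:
            fh.write("index\talpha_deg\tbeta_deg\tgamma_deg\n")
            for i, (a, b, g) in enumerate(deg):
                fh.write(f"{i}\t{a:.6f}\t{b:.6f}\t{g:.6f}\n")
        else:
            fh.write("index\talpha_deg\tbeta_deg\tgamma_deg\tdelta\n")
            for i, (a, b, g) in enumerate(deg):
                fh.write(f"{i}\t{a:.6f}\t{b:.6f}\t{g:.6f}\t{deltas[i]:.6e}\n")


def read_angles_tsv(path) -> OrientationSet:
    rows = np.loadtxt(path, skiprows=1)
    rows = np.atleast_2d(rows)
    return OrientationSet(np.radians(rows[:, 1:4]))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute simulate (optional) -> estimate -> reconstruct -> evaluate,
    persisting every intermediate under ``cfg.out_dir``; returns the report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": asdict(cfg), "stages": {}}
    seeds = _stage_seeds(cfg.seed)
    t0 = time.time()
    stage = "input"
    try:
        if cfg.input_stack is not None:
            data, pixel = read_stack(cfg.input_stack)
            stack = ImageStack(data, pixel)
        else:
            stage = "simulate"
            vol = make_phantom(cfg.simulate_size, cfg.phantom_blobs,
                               seed=seeds["simulate"])
            spec = None if cfg.simulate_snr is None else NoiseSpec(cfg.simulate_snr)
            stack = simulate_dataset(vol, cfg.simulate_n, spec,
                                     seed=seeds["simulate"])
            write_mrc(out / "phantom.mrc", vol.data, vol.voxel_size)
            write_stack(out / "stack.mrcs", stack.data, stack.pixel_size)
            write_angles_tsv(out / "reference_angles.tsv", stack.reference_angles)
            write_star(out / "reference_angles.star", stack.reference_angles)
        report["stages"][stage] = {"n": stack.n, "D": stack.image_size,
                                   "t": time.time() - t0}

        stage = "estimate"
        t1 = time.time()
        outcome = estimate_orientations(
            stack.data, L=cfg.L, r_min=cfg.r_min, r_max=cfg.r_max,
            pad=cfg.pad, mask_radius=cfg.mask_radius, weighting=cfg.weighting,
            T=cfg.T,
            weight_percentile=cfg.weight_percentile, restarts=cfg.restarts,
            tol=cfg.tol, max_iter=cfg.max_iter, seed=cfg.seed)
        outcome.common_lines.to_tsv(out / "common_lines.tsv")
        outcome.normals_config.to_tsv(out / "embedding_normals.tsv")
        outcome.xaxes_config.to_tsv(out / "embedding_xaxes.tsv")
        write_angles_tsv(out / "orientations.tsv", outcome.orientations,
                         outcome.alignment.deltas)
        write_star(out / "orientations.star", outcome.orientations)
        report["stages"][stage] = {
            "stress_normals": outcome.stress_normals,
            "stress_xaxes": outcome.stress_xaxes,
            "consistency": outcome.alignment.consistency,
            "mirror_choice": list(outcome.alignment.mirror_choice),
            "orthogonality_residual": outcome.alignment.residual,
            "t": time.time() - t1,
        }

        if cfg.reconstruct:
            stage = "reconstruct"
            t2 = time.time()
            vol_rec = backproject(stack, outcome.orientations,
                                  ReconstructionSettings())
            write_mrc(out / "reconstruction.mrc", vol_rec.data, vol_rec.voxel_size)
            report["stages"][stage] = {"t": time.time() - t2}

        if stack.reference_angles is not None:
            stage = "evaluate"
            cmp_ = compare_orientations(outcome.orientations, stack.reference_angles)
            report["stages"][stage] = {
                "rmse_alpha_deg": cmp_.rmse_alpha,
                "rmse_beta_deg": cmp_.rmse_beta,
                "rmse_gamma_deg": cmp_.rmse_gamma,
                "median_geodesic_deg": cmp_.median_geodesic_deg,
                "mirror_applied": bool(cmp_.mirror_applied),
                "max_dihedral_error_deg": float(np.degrees(
                    np.max(np.abs(cmp_.per_pair_dihedral_errors[:, 0]
                                  - cmp_.per_pair_dihedral_errors[:, 1])))),
            }
            np.savetxt(out / "dihedral_scatter.tsv",
                       np.degrees(cmp_.per_pair_dihedral_errors),
                       header="actual_deg\testimated_deg", comments="",
                       delimiter="\t", fmt="%.4f")
        report["ok"] = True
    except Exception as err:  # persist partial state with the failing stage
        report["ok"] = False
        report["failed_stage"] = stage
        report["error"] = str(err)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        raise
    report["total_t"] = time.time() - t0
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
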