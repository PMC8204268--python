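"""Experiment-design enumeration and seeded end-to-end pipelines.

Two analyses are orchestrated over a digital phantom:

* the *reconstruction-parameter* design — bootstrap datasets per
  (frame x correction mode), reconstructed at one to three OSEM
  iterations — and the *count-level* design — bootstrap datasets per
  (frame x count level), reconstructed with AC at two voxel sizes.  The
  enumerators count datasets, images and the extra mu-map-alignment
  reconstructions by explicitly listing the cells.
* the end-to-end uncertainty pipeline: bootstrap -> reconstruct ->
  (perturb the MR position ->) register -> propagate the parcellation ->
  Dice against the gold-standard (full-count) registration, and the
  propagation of the resulting registration jitter into SUVr with and
  without partial volume correction.

Every cell derives its own seed from the root seed and the cell identity,
so runs are deterministic, order-independent and resumable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import VoxelGrid, upsample_split
from .metrics import DiceDistribution, UncertaintyMatrix, cov, sd_matrix, suvr, yang_pvc
from .phantom import FRAME_SPECS, FrameSpec, make_activity, make_phantom
from .recon import ReconConfig, osem, estimate_scatter
from .register import (
    NMIEngine,
    PerturbationSpec,
    RigidTransform,
    draw_perturbation,
    perturb_grid,
    propagate_labels,
)
from .simulate import (
    Sinogram,
    attenuation_factors,
    bin_events,
    bootstrap_listmode,
    default_system,
    simulate_prompts,
)

__all__ = [
    "ExperimentDesign",
    "RunRecord",
    "paper_design",
    "desk_design",
    "derive_seed",
    "enumerate_recon_param_design",
    "enumerate_count_level_design",
    "run_uncertainty_analysis",
    "run_suvr_propagation",
]


def derive_seed(root_seed: int, *parts) -> int:
    """Deterministic per-cell seed from the root seed and a cell identity."""
    payload = repr((int(root_seed),) + tuple(parts)).encode()
    h = hashlib.blake2b(payload, digest_size=4)
    return int.from_bytes(h.digest(), "little") % (2**31)


@dataclass(frozen=True)
class ExperimentDesign:
    """The full design grid plus phantom/simulation conditions."""

    frames: tuple[str, ...] = ("early_neg", "late_neg", "early_pos", "late_pos")
    modes: tuple[str, ...] = ("NAC", "AC", "QNT")
    iteration_grid: tuple[int, ...] = (1, 2, 3)
    subsets: int = 14
    count_levels: tuple[float, ...] = (0.05, 0.15, 0.30, 0.60)
    n_bootstrap: int = 50
    engines: tuple[str, ...] = ("nmi-powell",)
    voxel_sizes: tuple[float, ...] = (2.0, 1.0)
    perturb: bool = True
    mumap_align_recons: bool = True
    # phantom / simulation conditions
    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size_mm: float = 2.0
    scatter_fraction: float = 0.15
    randoms_fraction: float = 0.15
    recon_param_count_level: float = 0.30

    def __post_init__(self) -> None:
        if len(self.engines) < 1:
            raise ValueError("at least one engine required")
        for seq, name in [
            (self.frames, "frames"),
            (self.modes, "modes"),
            (self.iteration_grid, "iteration_grid"),
            (self.count_levels, "count_levels"),
            (self.voxel_sizes, "voxel_sizes"),
        ]:
            if len(set(seq)) != len(seq):
                raise ValueError(f"duplicate entries in {name}")

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentDesign":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        for k, v in raw.items():
            if isinstance(v, list):
                raw[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        if isinstance(raw.get("grid_shape"), tuple):
            raw["grid_shape"] = tuple(int(x) for x in raw["grid_shape"])
        return cls(**raw)


def paper_design() -> ExperimentDesign:
    """The full-scale design grid (expensive; for cluster-free bookkeeping)."""
    return ExperimentDesign()


def desk_design() -> ExperimentDesign:
    """Reduced profile that runs end-to-end on one CPU in minutes."""
    return ExperimentDesign(
        frames=("late_neg",),
        modes=("AC",),
        iteration_grid=(2,),
        count_levels=(0.15, 0.60),
        n_bootstrap=3,
        voxel_sizes=(2.0,),
        grid_shape=(48, 48, 36),
    )


# ----------------------------------------------------------------------
# design enumeration (explicit listing, not closed-form products)
# ----------------------------------------------------------------------
def enumerate_recon_param_design(d: ExperimentDesign) -> tuple[int, int, int, int]:
    """Counts for the reconstruction-parameter analysis.

    Returns (bootstrap datasets, uncertainty images, mu-map-alignment
    reconstructions, total images).  One independent bootstrap dataset per
    (frame x mode x replicate); each is reconstructed at every iteration
    number in the grid; AC and QNT images each require one extra
    reconstruction for mu-map alignment.
    """
    datasets = [
        (f, m, b)
        for f in d.frames
        for m in d.modes
        for b in range(d.n_bootstrap)
    ]
    images = [
        (f, m, it, b)
        for f in d.frames
        for m in d.modes
        for it in d.iteration_grid
        for b in range(d.n_bootstrap)
    ]
    mumap = [
        img for img in images if d.mumap_align_recons and img[1] in ("AC", "QNT")
    ]
    return len(datasets), len(images), len(mumap), len(images) + len(mumap)


def enumerate_count_level_design(d: ExperimentDesign) -> tuple[int, int]:
    """Counts for the count-level analysis.

    One bootstrap dataset per (frame x count level x replicate), each
    reconstructed with AC at every voxel size, plus one mu-map-alignment
    reconstruction per dataset.  Returns (datasets, total images).
    """
    datasets = [
        (f, lvl, b)
        for f in d.frames
        for lvl in d.count_levels
        for b in range(d.n_bootstrap)
    ]
    images = [(ds, v) for ds in datasets for v in d.voxel_sizes]
    mumap = list(datasets) if d.mumap_align_recons else []
    return len(datasets), len(images) + len(mumap)


# ----------------------------------------------------------------------
# pipeline records
# ----------------------------------------------------------------------
@dataclass
class RunRecord:
    """One bootstrap replicate of the registration pipeline."""

    frame: str
    mode: str
    iterations: int
    count_level: float
    engine: str
    voxel_mm: float
    bootstrap_index: int
    seed: int
    perturbation: list | None
    transform: list
    center_mm: list
    converged: bool
    n_evaluations: int
    final_similarity: float
    dice: dict

    def to_json_dict(self) -> dict:
        return asdict(self)


_CORTEX_ROI = "CORTEX"


def _roi_masks(label_vals: np.ndarray, regions) -> dict[str, np.ndarray]:
    """Analysis masks: the nine named ROIs plus the whole cerebral cortex."""
    masks = {}
    for name in regions.analysis_roi_names():
        masks[name] = label_vals == regions.id_of(name)
    cortex = np.zeros_like(label_vals, dtype=bool)
    for lid in regions.cortical_gm_ids():
        cortex |= label_vals == lid
    masks[_CORTEX_ROI] = cortex
    return masks


@dataclass
class _FrameContext:
    """Per-frame reference data shared by all bootstrap cells."""

    frame_id: str
    listmode: object
    scatter: Sinogram
    randoms: Sinogram
    reference_pet: VoxelGrid
    reference_transform: RigidTransform
    reference_converged: bool


class UncertaintyPipeline:
    """End-to-end seeded pipeline over one phantom.

    Builds the phantom once, simulates one full-count list-mode stream per
    frame, establishes the gold-standard (full-count, unperturbed)
    registration per frame and engine, then evaluates every bootstrap
    design cell against it.
    """

    def __init__(self, design: ExperimentDesign, root_seed: int, workdir: str | Path | None = None):
        self.design = design
        self.root_seed = int(root_seed)
        self.workdir = Path(workdir) if workdir is not None else None
        if self.workdir is not None:
            self.workdir.mkdir(parents=True, exist_ok=True)

        d = design
        vox = (d.voxel_size_mm,) * 3
        self.labels, self.regions, self.mu_map, self.t1w = make_phantom(
            derive_seed(self.root_seed, "phantom"), d.grid_shape, vox
        )
        self.labels_mr = upsample_split(self.labels)  # parcellation in MR space
        self.sys = default_system(self.labels)
        self.af = attenuation_factors(self.mu_map, self.sys)
        self.engine = NMIEngine()
        self._frames: dict[str, _FrameContext] = {}

    # ------------------------------------------------------------------
    def frame_context(self, frame_id: str) -> _FrameContext:
        if frame_id in self._frames:
            return self._frames[frame_id]
        d = self.design
        spec: FrameSpec = FRAME_SPECS[frame_id]
        act = make_activity(self.labels, self.regions, spec, self.sys)
        lm, scatter, randoms = simulate_prompts(
            act,
            self.mu_map,
            self.sys,
            d.scatter_fraction,
            d.randoms_fraction,
            seed=derive_seed(self.root_seed, "listmode", frame_id),
            frame_id=frame_id,
        )
        prompts = bin_events(lm, self.sys)
        ref_cfg = ReconConfig(mode="AC", iterations=2, subsets=d.subsets)
        ref_pet = osem(prompts, self.sys, ref_cfg, af=self.af, randoms_est=randoms)
        ref_res = self.engine.register(ref_pet, self.t1w, init=None)
        ctx = _FrameContext(
            frame_id, lm, scatter, randoms, ref_pet, ref_res.transform, ref_res.converged
        )
        self._frames[frame_id] = ctx
        return ctx

    # ------------------------------------------------------------------
    def _recon_bootstrap(
        self, ctx: _FrameContext, mode: str, iterations: int, level: float, voxel_mm: float, seed: int
    ) -> VoxelGrid:
        d = self.design
        blm = bootstrap_listmode(ctx.listmode, level, seed)
        prompts = bin_events(blm, self.sys)
        randoms_est = Sinogram(ctx.randoms.values * level, "randoms")
        cfg = ReconConfig(
            mode=mode,
            iterations=iterations,
            subsets=d.subsets,
            out_voxel_mm=voxel_mm,
            native_voxel_mm=d.voxel_size_mm,
        )
        scatter_est = None
        if mode == "QNT":
            scatter_est = estimate_scatter(prompts, self.af, randoms_est=randoms_est)
        return osem(
            prompts,
            self.sys,
            cfg,
            af=self.af if mode in ("AC", "QNT") else None,
            scatter_est=scatter_est,
            randoms_est=randoms_est,
        )

    def run_cell(
        self, frame_id: str, mode: str, iterations: int, level: float, voxel_mm: float, b: int
    ) -> RunRecord:
        """One bootstrap replicate: resample, reconstruct, register, Dice."""
        d = self.design
        ctx = self.frame_context(frame_id)
        cell = (frame_id, mode, iterations, float(level), float(voxel_mm), b)
        seed = derive_seed(self.root_seed, "cell", *cell)

        img = self._recon_bootstrap(ctx, mode, iterations, level, voxel_mm, seed)

        if d.perturb:
            q = draw_perturbation(
                PerturbationSpec(seed=derive_seed(self.root_seed, "perturb", *cell))
            )
            t1_moving = perturb_grid(self.t1w, q)
            labels_moving = perturb_grid(self.labels_mr, q)
            pert = q.parameters.tolist()
        else:
            t1_moving, labels_moving, pert = self.t1w, self.labels_mr, None

        res = self.engine.register(img, t1_moving, init=None)

        dice_vals: dict[str, float] = {}
        if res.converged:
            ref_lab = propagate_labels(self.labels_mr, ctx.reference_transform, img)
            boot_lab = propagate_labels(labels_moving, res.transform, img)
            ref_masks = _roi_masks(ref_lab.values, self.regions)
            boot_masks = _roi_masks(boot_lab.values, self.regions)
            from .metrics import dice as _dice

            for name, rmask in ref_masks.items():
                dice_vals[name] = _dice(rmask, boot_masks[name])

        return RunRecord(
            frame=frame_id,
            mode=mode,
            iterations=iterations,
            count_level=float(level),
            engine=self.engine.name,
            voxel_mm=float(voxel_mm),
            bootstrap_index=b,
            seed=seed,
            perturbation=pert,
            transform=res.transform.parameters.tolist(),
            center_mm=res.transform.center_mm.tolist(),
            converged=bool(res.converged),
            n_evaluations=int(res.n_evaluations),
            final_similarity=float(res.final_similarity),
            dice=dice_vals,
        )

    # ------------------------------------------------------------------
    def _cell_path(self, key: tuple) -> Path | None:
        if self.workdir is None:
            return None
        tag = "_".join(str(k) for k in key).replace(" ", "")
        return self.workdir / f"cell_{tag}.json"

    def run_group(
        self, frame_id: str, mode: str, iterations: int, level: float, voxel_mm: float
    ) -> list[RunRecord]:
        """All bootstrap replicates of one design cell, resumable on disk."""
        key = (frame_id, mode, iterations, level, voxel_mm)
        path = self._cell_path(key)
        if path is not None and path.exists():
            raw = json.loads(path.read_text())
            return [RunRecord(**r) for r in raw]
        records = [
            self.run_cell(frame_id, mode, iterations, level, voxel_mm, b)
            for b in range(self.design.n_bootstrap)
        ]
        if path is not None:
            path.write_text(json.dumps([r.to_json_dict() for r in records], indent=1))
        return records


def _records_to_distributions(records: list[RunRecord], roi_names: list[str]):
    by_cell: dict[tuple, list[RunRecord]] = {}
    for r in records:
        key = (r.frame, r.mode, r.iterations, r.count_level, r.engine, r.voxel_mm)
        by_cell.setdefault(key, []).append(r)
    dists = []
    for key in sorted(by_cell):
        recs = by_cell[key]
        n_failed = sum(not r.converged for r in recs)
        for roi in roi_names:
            samples = [r.dice[roi] for r in recs if r.converged]
            dists.append(
                DiceDistribution(
                    roi_name=roi,
                    frame=key[0],
                    mode=key[1],
                    iterations=key[2],
                    count_level=key[3],
                    engine=key[4],
                    voxel_mm=key[5],
                    samples=np.array(samples),
                    n_failed=n_failed,
                )
            )
    return dists


def run_uncertainty_analysis(
    design: ExperimentDesign,
    root_seed: int,
    workdir: str | Path | None = None,
) -> tuple[UncertaintyMatrix, list[RunRecord]]:
    """Run the registration-uncertainty analysis over the design grid.

    Every (frame x mode x iterations x count level x voxel size) cell is
    bootstrapped ``n_bootstrap`` times; each replicate is reconstructed,
    registered (after a random MR-position perturbation when enabled) and
    compared via Dice to the gold-standard full-count registration.
    Deterministic for a fixed root seed; cells already on disk in
    ``workdir`` are loaded instead of recomputed.
    """
    pipe = UncertaintyPipeline(design, root_seed, workdir)
    d = design
    records: list[RunRecord] = []
    for frame in d.frames:
        for mode in d.modes:
            for it in d.iteration_grid:
                for level in d.count_levels:
                    for vox in d.voxel_sizes:
                        records.extend(pipe.run_group(frame, mode, it, level, vox))
    roi_names = pipe.regions.analysis_roi_names() + [_CORTEX_ROI]
    dists = _records_to_distributions(records, roi_names)
    matrix = sd_matrix(dists)
    if workdir is not None:
        matrix.to_csv(Path(workdir) / "dice_sd_per_roi.csv", Path(workdir) / "dice_sd_averages.csv")
    return matrix, records


def run_suvr_propagation(
    design: ExperimentDesign,
    root_seed: int,
    records: list[RunRecord] | None = None,
    workdir: str | Path | None = None,
    pvc_fwhm_mm: float = 4.5,
) -> pd.DataFrame:
    """Propagate registration jitter into SUVr precision (CoV).

    A single fixed quantitative PET per frame (a 30%-count AC
    reconstruction, the typical clinical count level) is sampled with each
    replicate's propagated parcellation; SUVr is computed with and without
    iterative-Yang PVC and summarised as CoV per (frame x count level).
    The observed variability therefore comes from registration imprecision
    only, not from noise in the quantitative PET itself.
    """
    pipe = UncertaintyPipeline(design, root_seed, None)
    d = design
    if records is None:
        _, records = run_uncertainty_analysis(design, root_seed, workdir)

    tid = pipe.regions.target.label_id
    rid = pipe.regions.reference.label_id
    rows = []
    for frame in d.frames:
        ctx = pipe.frame_context(frame)
        qlm = bootstrap_listmode(
            ctx.listmode, 0.30, derive_seed(root_seed, "quantpet", frame)
        )
        prompts = bin_events(qlm, pipe.sys)
        # quantification uses the fully corrected reconstruction, run to more
        # iterations than the registration images, with the scanner-side
        # scatter/randoms expectations scaled to the count level
        qcfg = ReconConfig(mode="QNT", iterations=4, subsets=d.subsets)
        qpet = osem(
            prompts,
            pipe.sys,
            qcfg,
            af=pipe.af,
            scatter_est=Sinogram(ctx.scatter.values * 0.30, "scatter"),
            randoms_est=Sinogram(ctx.randoms.values * 0.30, "randoms"),
        )
        frame_recs = [r for r in records if r.frame == frame and r.converged]
        by_cell: dict[tuple, list[RunRecord]] = {}
        for r in frame_recs:
            by_cell.setdefault((r.count_level, r.mode, r.iterations, r.voxel_mm), []).append(r)
        for (level, mode, it, vox), recs in sorted(by_cell.items()):
            suvr_plain, suvr_pvc = [], []
            for r in recs:
                if r.perturbation is not None:
                    q = RigidTransform(r.perturbation[:3], r.perturbation[3:])
                    lab_moving = perturb_grid(pipe.labels_mr, q)
                else:
                    lab_moving = pipe.labels_mr
                t = RigidTransform(r.transform[:3], r.transform[3:], r.center_mm)
                prop = propagate_labels(lab_moving, t, qpet)
                try:
                    plain = suvr(qpet, prop, tid, rid).suvr
                    pvc_img = yang_pvc(qpet, prop, psf_fwhm_mm=pvc_fwhm_mm)
                    corrected = suvr(pvc_img, prop, tid, rid, pvc_applied=True).suvr
                except ValueError:
                    # ROI propagated off the grid: a failed replicate is
                    # excluded from the distribution, not an error
                    continue
                suvr_plain.append(plain)
                suvr_pvc.append(corrected)
            for pvc_flag, vals in ((False, suvr_plain), (True, suvr_pvc)):
                if len(vals) >= 2:
                    c = cov(vals)
                elif len(vals) == 1:
                    c = 0.0
                else:
                    c = float("nan")
                rows.append(
                    dict(
                        frame=frame,
                        mode=mode,
                        iterations=it,
                        count_level=level,
                        voxel_mm=vox,
                        pvc=pvc_flag,
                        n=len(vals),
                        mean_suvr=float(np.mean(vals)) if vals else float("nan"),
                        cov=c,
                    )
                )
    table = pd.DataFrame(rows)
    if workdir is not None:
        table.to_csv(Path(workdir) / "suvr_cov.csv", index=False)
    return table
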