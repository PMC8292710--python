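"""End-to-end study pipeline on the synthetic phantom.

Chains phantom generation, (optional) deformable registration, ventilation
imaging, eligibility screening, structure derivation, robust standard and
functional plan optimization, interplay simulation, and the metric/NTCP
report. Every stage is also reachable individually through its module API;
this wrapper exists so the CLI and reproducibility scripts share one code
path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ventavoid import interplay as ip
from ventavoid import metrics_stats as ms
from ventavoid import phantom4d as p4
from ventavoid import planner as pl
from ventavoid import ventilation as vent
from ventavoid.core import ImageGrid
from ventavoid.dose_engine import Beam, MachineModel, compute_dose_volume, default_machine_model
from ventavoid.registration import RegistrationParams, register_deformable
from ventavoid.structures import StructureSet, build_structure_set

#: DVH metric rows reported per plan (structure, spec, label)
REPORT_METRICS: tuple[tuple[str, str, str], ...] = (
    ("ctv", "max", "CTV max (Gy)"),
    ("ctv", "D95", "CTV D95 (Gy)"),
    ("lungs", "mean", "Total MLD (Gy)"),
    ("lungs", "V20", "Total lung V20 (%)"),
    ("lungs", "V5", "Total lung V5 (%)"),
    ("esophagus", "mean", "Esophagus mean (Gy)"),
    ("heart", "mean", "Heart mean (Gy)"),
    ("cord", "max", "Cord max (Gy)"),
    ("functional_lung", "mean", "Total fMLD (Gy)"),
    ("functional_lung", "V5", "Total lung fV5 (%)"),
    ("functional_lung", "V10", "Total lung fV10 (%)"),
    ("functional_lung", "V20", "Total lung fV20 (%)"),
    ("functional_lung", "V30", "Total lung fV30 (%)"),
    ("functional_ipsi", "mean", "Ipsilateral fMLD (Gy)"),
    ("functional_contra", "mean", "Contralateral fMLD (Gy)"),
)


@dataclass
class StudyConfig:
    seed: int = 1
    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    amplitude_mm: float = 6.0
    defect_factor: float = 0.05
    rx_gy: float = 60.0
    gantry_angles: tuple[float, ...] = (0.0, 90.0)
    use_registration: bool = False
    modes: tuple[str, ...] = ("standard", "functional")
    run_interplay: bool = True
    interplay_mode: str = "functional"
    max_rounds: int = 3
    optimizer_iterations: int = 150
    boundary_erosion_voxels: int = 2
    noise_hu: float = 0.0


@dataclass
class StudyResult:
    config: StudyConfig
    anatomy: p4.PhantomAnatomy
    fourdct: p4.FourDCT
    ventilation: vent.VentilationMap
    profile: vent.RegionalProfile
    eligibility: vent.EligibilityResult
    structures: StructureSet
    machine: MachineModel
    plans: dict[str, pl.PlanResult]
    doses: dict[str, ImageGrid]
    metrics: pd.DataFrame
    ntcp: dict[str, ms.NTCPReduction] | None
    interplay: pd.DataFrame | None
    registration_info: dict | None = None


def plan_metrics(dose: ImageGrid, structures: StructureSet, rx_gy: float,
                 plan_name: str) -> pd.DataFrame:
    rows = []
    for struct, spec, label in REPORT_METRICS:
        if struct not in structures:
            continue
        rows.append({"plan": plan_name, "structure": struct, "metric": label,
                     "value": ms.dvh_metric(dose, spec, mask=structures[struct])})
    rows.append({"plan": plan_name, "structure": "ctv", "metric": "Conformity index",
                 "value": ms.conformity_index(dose, structures["ctv"], rx_gy,
                                              structures["body"])})
    rows.append({"plan": plan_name, "structure": "ctv", "metric": "Homogeneity index",
                 "value": ms.homogeneity_index(dose, structures["ctv"])})
    return pd.DataFrame(rows)


def functional_metric_values(dose: ImageGrid, structures: StructureSet
                             ) -> dict[str, float]:
    f = structures["functional_lung"]
    return {
        "fV20": ms.dvh_metric(dose, "V20", mask=f),
        "fV30": ms.dvh_metric(dose, "V30", mask=f),
        "fMLD": ms.dvh_metric(dose, "mean", mask=f),
    }


def run_study(config: StudyConfig | None = None) -> StudyResult:
    config = config or StudyConfig()
    rng_seed = config.seed

    # ---- phantom ----------------------------------------------------------
    pcfg = p4.PhantomConfig(shape=config.shape, spacing=config.spacing,
                            noise_hu=config.noise_hu)
    anatomy = p4.build_reference_anatomy(pcfg, seed=rng_seed)
    dvf_true = p4.synthesize_dvf(anatomy, amplitude_mm=config.amplitude_mm,
                                 defect_factor=config.defect_factor, seed=rng_seed)
    breathing = p4.BreathingConfig(tumor_amplitude_mm=config.amplitude_mm)
    fourdct = p4.make_4dct(anatomy, dvf_true, breathing, seed=rng_seed)
    exhale = fourdct.phases[fourdct.exhale_index]
    inhale = fourdct.phases[fourdct.inhale_index]

    # ---- correspondence ---------------------------------------------------
    registration_info = None
    if config.use_registration:
        reg = register_deformable(exhale, inhale, RegistrationParams(),
                                  body_mask=anatomy.body_mask)
        dvf_used = reg.dvf
        registration_info = {"converged": reg.converged,
                             "iterations": reg.iterations,
                             "final_objective": reg.final_objective}
    else:
        dvf_used = dvf_true

    # ---- ventilation + eligibility ----------------------------------------
    igtv_union = np.zeros(anatomy.grid.shape, dtype=bool)
    for m in fourdct.tumor_masks:
        igtv_union |= m
    lung_masks = vent.segment_lungs(exhale, exclusions=[igtv_union, anatomy.airway_mask])
    lung_total = lung_masks["left"] | lung_masks["right"]
    vmask = vent.parenchyma_mask(exhale, lung_total,
                                 erosion_voxels=config.boundary_erosion_voxels)
    vmap = vent.compute_ventilation(exhale, inhale, dvf_used, vmask)
    vmap = vent.normalize_to_max(vmap)
    profile = vent.regional_profile(vmap, lung_masks)
    eligibility = vent.screen_eligibility(profile)

    # ---- structures --------------------------------------------------------
    structures = build_structure_set(
        {"body": anatomy.body_mask,
         "lung_left": lung_masks["left"], "lung_right": lung_masks["right"],
         "gtv": anatomy.tumor_mask, **anatomy.oar_masks},
        fourdct.tumor_masks, vmap, anatomy.spacing,
    )

    # ---- planning ----------------------------------------------------------
    machine = default_machine_model()
    beams = [Beam(g) for g in config.gantry_angles]
    geometry = pl.place_spots(anatomy.grid, structures["ctv"], machine, beams,
                              rx_gy=config.rx_gy)
    scenarios = pl.robust_scenarios()

    objective_sets = {}
    for mode in config.modes:
        if mode == "standard":
            objective_sets[mode] = pl.standard_objectives(config.rx_gy)
        elif mode == "functional":
            objective_sets[mode] = pl.functional_objectives(config.rx_gy)
        else:
            raise ValueError(f"unknown planning mode {mode!r}")

    all_terms = tuple(t for o in objective_sets.values() for t in o.terms)
    problem = pl.PlannerProblem.build(
        anatomy.grid, geometry, machine, structures.masks,
        pl.ObjectiveSet(terms=all_terms), scenarios,
    )

    plans: dict[str, pl.PlanResult] = {}
    doses: dict[str, ImageGrid] = {}
    tables = []
    for mode, objectives in objective_sets.items():
        result = pl.reweight_until_robust(problem, objectives,
                                          max_rounds=config.max_rounds,
                                          max_iterations=config.optimizer_iterations)
        dose = compute_dose_volume(anatomy.grid, result.plan, machine)
        plan, dose, _ = pl.normalize_plan(result.plan, dose, structures["ctv"],
                                          config.rx_gy)
        result.plan = plan
        plans[mode] = result
        doses[mode] = dose
        tables.append(plan_metrics(dose, structures, config.rx_gy, mode))
    metrics = pd.concat(tables, ignore_index=True)

    # ---- NTCP --------------------------------------------------------------
    ntcp = None
    if {"standard", "functional"} <= set(plans):
        std = {k: np.array([v]) for k, v in
               functional_metric_values(doses["standard"], structures).items()}
        fun = {k: np.array([v]) for k, v in
               functional_metric_values(doses["functional"], structures).items()}
        ntcp = ms.ntcp_reduction(std, fun)

    # ---- interplay ---------------------------------------------------------
    interplay_table = None
    if config.run_interplay and config.interplay_mode in plans:
        plan = plans[config.interplay_mode].plan
        painted = ip.repaint_layers(plan, machine.max_mu_per_spot)
        timed = ip.delivery_timeline(painted, machine)
        rows = []
        for trace in ip.enumerate_scenarios(template=breathing):
            dyn = ip.simulate_dynamic_dose(timed, trace, fourdct, painted, machine)
            rep = ip.interplay_report(doses[config.interplay_mode], dyn,
                                      structures, config.rx_gy)
            rep["start_phase"] = trace.start_phase
            rep["period_s"] = trace.period_s
            rows.append(rep)
        interplay_table = pd.concat(rows, ignore_index=True)

    return StudyResult(
        config=config, anatomy=anatomy, fourdct=fourdct, ventilation=vmap,
        profile=profile, eligibility=eligibility, structures=structures,
        machine=machine, plans=plans, doses=doses, metrics=metrics, ntcp=ntcp,
        interplay=interplay_table, registration_info=registration_info,
    )
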