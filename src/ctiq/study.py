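"""End-to-end synthetic replica of a two-dose-level, three-reconstruction
chest-CT image-quality study.

The default configuration mirrors a 25-patient paired design: every patient
is "scanned" with a full-dose and an ultra-low-dose (ULD) protocol and each
acquisition is "reconstructed" three ways —

* ``asirv``   — sharp-kernel hybrid IR surrogate: band-pass noise spectrum,
  high noise magnitude, no extra smoothing (best spatial resolution);
* ``dlir``    — deep-learning reconstruction surrogate: low-pass noise
  spectrum, low noise magnitude;
* ``dlir_e2`` — ``dlir`` followed by an unsharp-mask edge filter, which
  raises high-frequency power and noise slightly.

The ULD protocol scales noise by dose_factor^(-1/2) with dose_factor 0.133
(noise-index ratio 85/31 between the protocols); its dose records are set so
the mean effective dose is 0.05 mSv vs 2.5 mSv at full dose (2%).

For each protocol two paired observer studies are simulated: ``dlir`` vs
``asirv`` (reference) and ``dlir_e2`` vs ``dlir`` (reference), with latent
quality shifts that favour the deep-learning arms more strongly at ULD and
give no systematic difference between ``dlir`` and ``dlir_e2``.

All randomness derives from one global seed; per-stage seeds are obtained by
hashing stage names, so adding a stage never perturbs existing streams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ctio
from .dose import DoseRecord, effective_dose, protocol_summary
from .noise import NoiseModel, apply_edge_enhancement, apply_noise, apply_resolution_blur
from .phantom import PhantomConfig, default_chest_phantom, generate_phantom_stack
from .ps import cohort_ps, examination_ps, radial_average
from .ratings import LatentRatingModel, RatingDesign, default_rating_design, generate_ratings
from .roi import ROISpec, cnr, cnr_difference_analysis, line_profile, roi_stats
from .vgc import bootstrap_vgc, proportion_table

__all__ = ["ProtocolArm", "ReconArm", "StudyConfig", "StudyReport", "run_study",
           "stage_seed"]

log = logging.getLogger("ctiq.study")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stage seed (< 2^31) from the global seed by stable hashing."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class ProtocolArm:
    dose_factor: float          # scales noise SD as dose_factor^(-1/2)
    dlp_mean: float             # mGy*cm
    dlp_sd: float               # between-patient spread, mGy*cm
    ctdi_mean: float            # mGy


@dataclass
class ReconArm:
    radial_shape: str
    sigma_ref: float            # noise SD (HU) at dose_factor 1
    resolution_sigma: float = 0.0   # kernel MTF surrogate: anatomy blur, mm
    edge_gain: float = 0.0
    edge_radius: float = 1.5    # mm


@dataclass
class StudyConfig:
    phantom: PhantomConfig = field(default_factory=lambda: default_chest_phantom(n_slices=20))
    n_patients: int = 25
    protocols: dict = field(default_factory=lambda: {
        # full dose: effective dose 2.5 mSv (DLP 166.7 mGy*cm at k = 0.015)
        "full_dose": ProtocolArm(dose_factor=1.0, dlp_mean=166.7, dlp_sd=25.0,
                                 ctdi_mean=4.5),
        # ULD: 2% of the full-dose effective dose; noise x (1/0.133)^0.5 ~ 2.74
        "uld": ProtocolArm(dose_factor=0.133, dlp_mean=3.33, dlp_sd=0.5,
                           ctdi_mean=0.08),
    })
    recons: dict = field(default_factory=lambda: {
        "asirv": ReconArm(radial_shape="sharp_kernel", sigma_ref=40.0,
                          resolution_sigma=0.4),
        "dlir": ReconArm(radial_shape="smooth_kernel", sigma_ref=15.0,
                         resolution_sigma=0.8),
        "dlir_e2": ReconArm(radial_shape="smooth_kernel", sigma_ref=15.0,
                            resolution_sigma=0.8, edge_gain=1.0, edge_radius=1.5),
    })
    # observer studies: (test, reference) -> latent shift per protocol
    comparisons: dict = field(default_factory=lambda: {
        ("dlir", "asirv"): {"full_dose": 0.6, "uld": 1.2},
        ("dlir_e2", "dlir"): {"full_dose": 0.0, "uld": 0.0},
    })
    rating_design: RatingDesign = None     # filled per comparison
    rating_model: LatentRatingModel = field(default_factory=LatentRatingModel)
    # analysis settings
    roi1: ROISpec = field(default_factory=lambda: ROISpec(center=(0.0, 10.0), diameter=15.0))
    roi2: ROISpec = field(default_factory=lambda: ROISpec(center=(0.0, -30.0), diameter=15.0))
    profile_endpoints: tuple = ((-76.0, -40.0), (-64.0, -40.0))  # across a 2 mm vessel
    n_boot: int = 2000
    cnr_pairs: tuple = (("dlir", "asirv"), ("dlir_e2", "asirv"), ("dlir", "dlir_e2"))


@dataclass
class StudyReport:
    ps_curves: dict             # (protocol, recon) -> cohort PSCurve1D
    cnr_table: pd.DataFrame     # per (protocol, recon, patient) CNR
    cnr_comparisons: dict       # (protocol, (recon_a, recon_b)) -> CNRComparison
    profiles: dict              # (protocol, recon) -> LineProfile (first patient)
    vgc_table: pd.DataFrame     # per (protocol, comparison, question, mode)
    proportions: dict           # (protocol, comparison) -> DataFrame
    dose_records: list
    dose_summary: dict
    seed: int


def _patient_stack(anatomy_stack, recon: ReconArm, protocol: ProtocolArm, seed: int):
    """One simulated reconstruction: kernel-blurred anatomy + shaped noise,
    then any post-processing edge enhancement (which also amplifies noise)."""
    noise = NoiseModel(radial_shape=recon.radial_shape, sigma_ref=recon.sigma_ref,
                       dose_factor=protocol.dose_factor)
    noisy = apply_noise(anatomy_stack, noise, seed=seed)
    if recon.edge_gain > 0:
        noisy = apply_edge_enhancement(noisy, recon.edge_gain, recon.edge_radius)
    return noisy


def run_study(config: StudyConfig, seed: int, out_dir=None) -> StudyReport:
    """Run the full synthetic pipeline and optionally write a report bundle."""
    phantom_stack = generate_phantom_stack(config.phantom)
    sp = config.phantom.pixel_spacing
    # anatomy as seen through each kernel's resolution (shared by patients)
    anatomy = {name: apply_resolution_blur(phantom_stack, r.resolution_sigma)
               for name, r in config.recons.items()}

    # ---- image-domain analysis: PS, CNR, line profiles -------------------
    ps_curves, profiles = {}, {}
    cnr_rows = []
    for proto_name, proto in config.protocols.items():
        for recon_name, recon in config.recons.items():
            log.info("imaging arm %s/%s: %d patients", proto_name, recon_name,
                     config.n_patients)
            curves = []
            for p in range(config.n_patients):
                s = stage_seed(seed, f"noise/{proto_name}/{recon_name}/patient{p}")
                stack = _patient_stack(anatomy[recon_name], recon, proto, s)
                curves.append(radial_average(examination_ps(stack)))
                img = stack.voxels[0]
                stats1 = roi_stats(img, config.roi1, sp)
                stats2 = roi_stats(img, config.roi2, sp)
                cnr_rows.append({"protocol": proto_name, "recon": recon_name,
                                 "patient": p, "cnr": cnr(stats1, stats2),
                                 "roi1_mean": stats1.mean_hu, "roi1_sd": stats1.sd_hu,
                                 "roi2_mean": stats2.mean_hu, "roi2_sd": stats2.sd_hu})
                if p == 0:
                    profiles[(proto_name, recon_name)] = line_profile(
                        img, *config.profile_endpoints, sample_step=sp / 2.0,
                        pixel_spacing=sp)
            ps_curves[(proto_name, recon_name)] = cohort_ps(curves)
    cnr_table = pd.DataFrame(cnr_rows)

    cnr_comparisons = {}
    for proto_name in config.protocols:
        sub = cnr_table[cnr_table["protocol"] == proto_name]
        by_recon = {r: g.sort_values("patient")["cnr"].to_numpy()
                    for r, g in sub.groupby("recon")}
        for a, b in config.cnr_pairs:
            cnr_comparisons[(proto_name, (a, b))] = \
                cnr_difference_analysis(by_recon[a], by_recon[b])

    # ---- observer studies: ratings + VGC ---------------------------------
    vgc_rows = []
    proportions = {}
    for (test, ref), deltas in config.comparisons.items():
        for proto_name in config.protocols:
            design = config.rating_design or default_rating_design(conditions=(ref, test))
            if design.conditions != (ref, test):
                design = RatingDesign(n_cases=design.n_cases, n_readers=design.n_readers,
                                      questions=design.questions, conditions=(ref, test))
            # thresholds re-derive from each comparison's delta (delta/2
            # centring); config.rating_model contributes the effect SDs
            model = LatentRatingModel(
                delta=deltas[proto_name],
                sigma_case=config.rating_model.sigma_case,
                sigma_reader=config.rating_model.sigma_reader,
                sigma_noise=config.rating_model.sigma_noise,
            )
            rs = generate_ratings(design, model,
                                  seed=stage_seed(seed, f"ratings/{proto_name}/{test}-vs-{ref}"))
            proportions[(proto_name, f"{test}_vs_{ref}")] = proportion_table(rs)
            for q in design.questions:
                for mode in ("fixed_reader", "random_reader"):
                    res = bootstrap_vgc(
                        rs, q.id, mode=mode, n_boot=config.n_boot,
                        seed=stage_seed(seed, f"boot/{proto_name}/{test}-vs-{ref}/{q.id}/{mode}"))
                    vgc_rows.append({"protocol": proto_name,
                                     "comparison": f"{test}_vs_{ref}",
                                     "question": q.id, "mode": mode,
                                     "estimator": res.estimator, "auc": res.auc,
                                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                                     "significant": res.significant})
    vgc_table = pd.DataFrame(vgc_rows)

    # ---- dose records -----------------------------------------------------
    dose_rng = np.random.default_rng(stage_seed(seed, "dose"))
    dose_records = []
    for proto_name, proto in config.protocols.items():
        dlps = np.maximum(proto.dlp_mean + proto.dlp_sd * dose_rng.standard_normal(config.n_patients), 0.0)
        # recentre so the cohort mean matches the protocol's nominal DLP
        dlps += proto.dlp_mean - dlps.mean()
        for p, dlp in enumerate(dlps):
            dose_records.append(DoseRecord(
                patient_id=f"patient{p + 1:03d}", protocol=proto_name,
                ctdi_vol=proto.ctdi_mean * dlp / proto.dlp_mean, dlp=float(dlp)))
    dose_summary = protocol_summary(dose_records)

    report = StudyReport(ps_curves=ps_curves, cnr_table=cnr_table,
                         cnr_comparisons=cnr_comparisons, profiles=profiles,
                         vgc_table=vgc_table, proportions=proportions,
                         dose_records=dose_records, dose_summary=dose_summary,
                         seed=seed)
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: StudyReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for (proto, recon), curve in report.ps_curves.items():
        ctio.write_curve(curve, out_dir / f"ps_{proto}_{recon}.csv")
    report.cnr_table.to_csv(out_dir / "cnr_per_patient.csv", index=False)
    comp_rows = []
    for (proto, (a, b)), comp in report.cnr_comparisons.items():
        comp_rows.append({"protocol": proto, "recon_a": a, "recon_b": b,
                          "mean_diff": comp.mean_diff, "sem": comp.sem,
                          "t": comp.t_statistic, "p_value": comp.p_value})
    pd.DataFrame(comp_rows).to_csv(out_dir / "cnr_comparisons.csv", index=False)
    for (proto, recon), prof in report.profiles.items():
        pd.DataFrame({"position_mm": prof.positions, "hu": prof.values}) \
            .to_csv(out_dir / f"profile_{proto}_{recon}.csv", index=False)
    report.vgc_table.to_csv(out_dir / "vgc_results.csv", index=False)
    for (proto, comp), props in report.proportions.items():
        props.to_csv(out_dir / f"proportions_{proto}_{comp}.csv")
    ctio.write_dose_records(report.dose_records, out_dir / "dose_records.csv")
    (out_dir / "dose_summary.json").write_text(json.dumps(report.dose_summary, indent=2))
    (out_dir / "summary.json").write_text(json.dumps({
        "seed": report.seed,
        "n_arms": len(report.ps_curves),
        "n_vgc_results": len(report.vgc_table),
        "n_dose_records": len(report.dose_records),
    }, indent=2))
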