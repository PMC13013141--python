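"""Virtual-trial data generation emulating a staged dermatomyositis study.

Produces tidy long-format datasets with the statistical structure the joint
model assumes: two disease subtypes with stage-dependent endpoint panels
(skin scores in all stages, the TIS core set and MMT-8 only in the
muscle-predominant stage), Q4W intravenous dosing with optional 12-week
crossover sequences, correlated individual baselines, and additive residual
noise (enzyme observations denormalized by each subject's ULN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .exposure import Regimen
from .model_core import enzyme_observation
from .params import ENDPOINT_ORDER, ParameterSet
from .population import draw_subjects

DEFAULT_VISITS = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
SPDM_PANEL = ("cdasi_d", "cdasi_a", "sf36_pfd", "sf36_mcs", "phga", "ptga",
              "haq")
FULL_PANEL = tuple(ENDPOINT_ORDER)

__all__ = ["Arm", "TrialDesign", "TidyColumns", "generate_trial",
           "truth_record", "study_stage_designs", "cts_design",
           "DEFAULT_VISITS", "SPDM_PANEL", "FULL_PANEL"]


@dataclass
class Arm:
    """One randomized arm: label, dose level, size, crossover sequence.

    sequence None = same assignment throughout; "AP" = active then placebo
    after the crossover week; "PA" = placebo then active.
    """

    label: str
    dose_mg: float
    n: int
    sequence: str | None = None

    def __post_init__(self):
        if self.dose_mg < 0 or self.n <= 0:
            raise ValueError("invalid arm")
        if self.sequence not in (None, "AP", "PA"):
            raise ValueError(f"unknown sequence {self.sequence!r}")


@dataclass
class TrialDesign:
    """Stage-level design: subtype, arms, schedule and endpoint panel."""

    name: str
    dm_type: str                     # "SPDM" | "MPDM" | "MIX80"
    arms: list
    visits: tuple = DEFAULT_VISITS
    panel: tuple = FULL_PANEL
    crossover_week: float | None = None
    doses_per_period: int = 3
    dosing_interval: float = 4.0
    mpdm_fraction: float = 0.8       # used only for dm_type == "MIX80"

    def __post_init__(self):
        if self.crossover_week is not None and \
                self.crossover_week not in self.visits:
            raise ValueError("crossover must occur at a scheduled visit")
        unknown = set(self.panel) - set(ENDPOINT_ORDER)
        if unknown:
            raise ValueError(f"panel/model mismatch: {sorted(unknown)}")
        if any(a.sequence for a in self.arms) and self.crossover_week is None:
            raise ValueError("sequences require a crossover week")

    def regimen_for(self, arm: Arm, infusion_duration_hr: float) -> Regimen:
        """Drug dose events for one arm (placebo periods contribute none)."""
        iv = self.dosing_interval
        if arm.dose_mg == 0:
            return Regimen([], [], infusion_duration_hr)
        if arm.sequence is None:
            times = [iv * k for k in range(self.doses_per_period)]
        elif arm.sequence == "AP":
            times = [iv * k for k in range(self.doses_per_period)]
        else:  # "PA": active only after the crossover
            times = [self.crossover_week + iv * k
                     for k in range(self.doses_per_period)]
        times = [t for t in times if t <= max(self.visits)]
        return Regimen([arm.dose_mg] * len(times), times, infusion_duration_hr)

    def dm_labels(self, n: int, rng) -> list:
        if self.dm_type in ("SPDM", "MPDM"):
            return [self.dm_type] * n
        n_mpdm = int(round(self.mpdm_fraction * n))
        labels = ["MPDM"] * n_mpdm + ["SPDM"] * (n - n_mpdm)
        rng.shuffle(labels)
        return labels


class TidyColumns:
    """Column dictionary of the tidy dataset.

    subject : integer id, unique within the dataset
    stage   : design name
    arm     : arm label; sequence : crossover sequence or ""
    dm_type : SPDM/MPDM
    time    : weeks from first dose
    record  : "dose" or "obs"
    endpoint: endpoint id (obs rows)
    value   : observed score / concentration (obs) ; NaN for dose rows
    amount  : dose in mg (dose rows)
    uln     : enzyme upper limit of normal, U/L (enzyme obs rows)
    """

    names = ["subject", "stage", "arm", "sequence", "dm_type", "time",
             "record", "endpoint", "value", "amount", "uln"]


def generate_trial(design: TrialDesign, params: ParameterSet, seed,
                   include_ruv: bool = True,
                   mmt8_spdm_adjust: bool = False,
                   return_truth: bool = False):
    """Simulate one complete virtual trial as a tidy dataset.

    Subjects are realized from the population model, exposure follows each
    arm's regimen (honoring crossover sequences), panel endpoints are
    integrated with the exact piecewise engine, additive residual noise is
    applied on the modeled scale, and enzyme rows are denormalized by ULN.
    Identical seeds give identical datasets.
    """
    rng = np.random.default_rng(seed)
    panel = [e for e in ENDPOINT_ORDER if e in design.panel]
    visits = np.asarray(design.visits, dtype=float)
    breaks = []
    for arm in design.arms:
        breaks += list(design.regimen_for(arm,
                                          params.infusion_duration_hr).dose_times)
    grid, vidx = engine.time_grid(visits, dt=1.0, extra_breaks=breaks)

    # subtype allocation stratified by arm (fixed counts per arm)
    dm_all = sum((design.dm_labels(a.n, rng) for a in design.arms), [])
    subjects = draw_subjects(params, dm_all, seed=int(rng.integers(2**31 - 1)),
                             mmt8_spdm_adjust=mmt8_spdm_adjust)

    emax = np.array([params.endpoints[e].emax for e in panel])
    ruv = np.array([params.endpoints[e].ruv_sd for e in panel])
    is_enz = np.array([params.endpoints[e].is_enzyme for e in panel])

    rows, latent_rows = [], []
    pos = 0
    for arm in design.arms:
        subs = subjects[pos:pos + arm.n]
        pos += arm.n
        regimen = design.regimen_for(arm, params.infusion_duration_hr)
        p_seg = engine.segment_punbound(params.pk, regimen, grid)
        p_seg = np.broadcast_to(p_seg, (arm.n, len(p_seg)))
        baselines = np.array([[s.baselines[e] for e in panel] for s in subs])
        en = np.array([s.emax_norm for s in subs])
        ep = np.array([s.e_plac for s in subs])
        latent = engine.latent_trajectories(
            p_seg, grid, baselines, emax, en, ep, params.shared.k_out,
            visit_index=vidx)                     # (n, n_vis, n_end)
        eps = rng.standard_normal(latent.shape) if include_ruv else \
            np.zeros(latent.shape)
        obs = latent + ruv[None, None, :] * eps
        for i, s in enumerate(subs):
            for td, amt in zip(regimen.dose_times, regimen.dose_amounts):
                rows.append((s.subject_id, design.name, arm.label,
                             arm.sequence or "", s.dm_type, td, "dose",
                             "", np.nan, amt, np.nan))
            for j, t in enumerate(visits):
                for k, e in enumerate(panel):
                    val = obs[i, j, k]
                    uln = np.nan
                    if is_enz[k]:
                        uln = s.uln
                        val = enzyme_observation(latent[i, j, k],
                                                 eps[i, j, k], ruv[k], uln)
                    rows.append((s.subject_id, design.name, arm.label,
                                 arm.sequence or "", s.dm_type, t, "obs",
                                 e, val, np.nan, uln))
                    if return_truth:
                        latent_rows.append((s.subject_id, t, e,
                                            latent[i, j, k]))
    data = pd.DataFrame(rows, columns=TidyColumns.names)
    if not return_truth:
        return data
    truth = _truth_frames(subjects, latent_rows)
    return data, truth


def _truth_frames(subjects, latent_rows):
    subj = pd.DataFrame([
        {"subject": s.subject_id, "dm_type": s.dm_type,
         "emax_norm": s.emax_norm, "e_plac": s.e_plac, "uln": s.uln,
         **{f"base_{k}": v for k, v in s.baselines.items()},
         **{f"eta_{k}": v for k, v in s.etas.items()}}
        for s in subjects])
    latent = pd.DataFrame(latent_rows,
                          columns=["subject", "time", "endpoint", "latent"])
    return {"subjects": subj, "latent": latent}


def truth_record(design: TrialDesign, params: ParameterSet, seed):
    """Latent truth (etas, baselines, noiseless trajectories) for a trial.

    Deterministically reproduces the latent state behind
    ``generate_trial(design, params, seed)``.
    """
    _, truth = generate_trial(design, params, seed, return_truth=True)
    return truth


def load_design(path) -> TrialDesign:
    """Read a trial design from a YAML file.

    Schema: name, dm_type, arms (label, dose_mg, n, optional sequence),
    optional visits, panel, crossover_week, doses_per_period, mpdm_fraction.
    """
    import yaml
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    arms = [Arm(a["label"], float(a["dose_mg"]), int(a["n"]),
                a.get("sequence")) for a in doc["arms"]]
    return TrialDesign(
        name=doc["name"], dm_type=doc["dm_type"], arms=arms,
        visits=tuple(doc.get("visits", DEFAULT_VISITS)),
        panel=tuple(doc.get("panel", FULL_PANEL)),
        crossover_week=doc.get("crossover_week"),
        doses_per_period=int(doc.get("doses_per_period", 3)),
        dosing_interval=float(doc.get("dosing_interval", 4.0)),
        mpdm_fraction=float(doc.get("mpdm_fraction", 0.8)))


def study_stage_designs() -> dict:
    """Designs structurally mirroring the staged study.

    Stage 1: SPDM, 600 mg vs placebo; Stage 2 adds 150 mg; Stage 2A runs the
    dose levels as 12-week crossover sequences; Stage 3: MPDM 600 mg
    crossover with the full TIS panel.  Sizes mirror the reported stage
    totals (32/25/18).
    """
    return {
        "stage1": TrialDesign(
            "stage1", "SPDM",
            [Arm("placebo", 0.0, 16), Arm("600mg", 600.0, 16)],
            visits=(0.0, 4.0, 8.0, 12.0), panel=SPDM_PANEL),
        "stage2": TrialDesign(
            "stage2", "SPDM",
            [Arm("placebo", 0.0, 4), Arm("150mg", 150.0, 4),
             Arm("600mg", 600.0, 4)],
            visits=(0.0, 4.0, 8.0, 12.0), panel=SPDM_PANEL),
        "stage2a": TrialDesign(
            "stage2a", "SPDM",
            [Arm("150mg AP", 150.0, 3, "AP"), Arm("150mg PA", 150.0, 3, "PA"),
             Arm("600mg AP", 600.0, 4, "AP"), Arm("600mg PA", 600.0, 3, "PA")],
            visits=DEFAULT_VISITS, panel=SPDM_PANEL, crossover_week=12.0),
        "stage3": TrialDesign(
            "stage3", "MPDM",
            [Arm("600mg AP", 600.0, 9, "AP"), Arm("600mg PA", 600.0, 9, "PA")],
            visits=DEFAULT_VISITS, panel=FULL_PANEL, crossover_week=12.0),
    }


def cts_design(n_per_arm: int = 120, dose_mg: float = 600.0,
               mpdm_fraction: float = 0.8,
               visits=DEFAULT_VISITS) -> TrialDesign:
    """Six-month continued-dosing design for clinical trial simulation:
    placebo vs dose Q4W, mixed 80% MPDM / 20% SPDM, full panel."""
    n_doses = int(max(visits) // 4) + 1
    return TrialDesign(
        "cts", "MIX80",
        [Arm("placebo", 0.0, n_per_arm), Arm(f"{dose_mg:g}mg", dose_mg,
                                             n_per_arm)],
        visits=visits, panel=FULL_PANEL, doses_per_period=n_doses,
        mpdm_fraction=mpdm_fraction)
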