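"""Synthetic-experiment generator for the 4-group ischemia-reperfusion design.

Emulates the structure of a rat lung ischemia-reperfusion (IR) ventilation
study so every pipeline stage runs end-to-end without animal data:

* 24 ventilated animals in 4 groups (Sham/IR crossed with VCV/VV, 6 per
  group) plus 12 non-ventilated (NV) reference animals (6 NV-Sham,
  6 NV-IR) whose lungs calibrate the expression analysis;
* four mechanics time points per ventilated animal (Baseline 1, Baseline 2
  after clamp release, Initial after 5 min of the assigned strategy, Final
  after the 2-h ventilation period), each represented by a short recording
  window with scheduled ground-truth mechanics;
* triplicate Ct tables for 7 target genes plus the 36B4 reference gene,
  with group- and side-dependent log2-fold-change shifts;
* point-count morphometry fields and two-observer electron-microscopy
  grades per lung side.

Effect magnitudes are configuration knobs chosen to reproduce the
*directions* reported for this kind of injury — IR raises elastance mainly
through its volume-dependent component E2; prolonged VCV raises E1 and E2
further while VV does not; VCV after IR up-regulates IL-6 and ICAM-1 in the
injured lung while VV up-regulates SP-D; collapse fractions order
IR-VCV > Sham-VCV > IR-VV > Sham-VV — not any particular in-vivo value.
Ground truth is retained alongside every output for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import breath_mech, gene_expr, histo_score
from .errors import InvalidArgumentError
from .histo_score import FieldCount, em_grade_from_fraction
from .lung_sim import MechParams, Recording, VentSettings, simulate_run
from .vt_pattern import generate_vt_sequence

__all__ = [
    "GROUPS",
    "NV_GROUPS",
    "TIMEPOINTS",
    "GENES",
    "StudyDesign",
    "EffectConfig",
    "StudyBundle",
    "generate_study",
    "end_to_end",
]

GROUPS = ("Sham-VCV", "Sham-VV", "IR-VCV", "IR-VV")
NV_GROUPS = ("NV-Sham", "NV-IR")
TIMEPOINTS = ("Baseline1", "Baseline2", "Initial", "Final")
GENES = ("IL6", "NRF2", "SPD", "ANG1", "ANG2", "TIE", "ICAM1")
SIDES = ("left", "right")

_SEED_MOD = 2**31 - 1


def _default_log2_fold() -> dict:
    # (gene, group, side) -> log2 fold change vs the pooled NV calibrator.
    # VCV after IR drives inflammation/adhesion in the injured (left) lung;
    # VV drives SP-D (type II epithelial protection) in both strategies' arms.
    return {
        ("IL6", "IR-VCV", "left"): 2.0,
        ("ICAM1", "IR-VCV", "left"): 1.5,
        ("SPD", "Sham-VV", "left"): 1.2,
        ("SPD", "IR-VV", "left"): 1.2,
        ("SPD", "Sham-VV", "right"): 0.8,
        ("SPD", "IR-VV", "right"): 0.8,
        ("IL6", "NV-IR", "left"): 1.0,
        ("NRF2", "NV-IR", "left"): 0.8,
        ("ANG2", "NV-IR", "left"): -0.8,
        ("ANG2", "NV-IR", "right"): -0.8,
    }


def _default_collapse_p() -> dict:
    return {
        ("Sham-VCV", "left"): 0.15,
        ("Sham-VV", "left"): 0.05,
        ("IR-VCV", "left"): 0.25,
        ("IR-VV", "left"): 0.08,
        ("Sham-VCV", "right"): 0.10,
        ("Sham-VV", "right"): 0.05,
        ("IR-VCV", "right"): 0.15,
        ("IR-VV", "right"): 0.06,
    }


def _default_em_fraction_mean() -> dict:
    # mean percent of tissue with ultrastructural changes per group x side
    return {
        ("Sham-VCV", "left"): 20.0,
        ("Sham-VV", "left"): 12.0,
        ("IR-VCV", "left"): 55.0,
        ("IR-VV", "left"): 25.0,
        ("Sham-VCV", "right"): 12.0,
        ("Sham-VV", "right"): 10.0,
        ("IR-VCV", "right"): 25.0,
        ("IR-VV", "right"): 15.0,
    }


@dataclass(frozen=True)
class StudyDesign:
    """Group sizes, body-weight distribution and time points."""

    n_per_group: int = 6
    nv_per_group: int = 6
    body_weight_mean: float = 0.526   # kg
    body_weight_sd: float = 0.117     # kg
    timepoints: tuple = TIMEPOINTS
    breaths_per_window: int = 20      # recording window per time point
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.nv_per_group < 1:
            raise InvalidArgumentError("group sizes must be >= 1")


@dataclass(frozen=True)
class EffectConfig:
    """Ground-truth mechanics schedule, expression shifts, histology rates."""

    # baseline single-compartment mechanics (population means)
    baseline_r: float = 0.15          # cmH2O.s/mL
    baseline_e1: float = 2.0          # cmH2O/mL
    baseline_e2: float = 0.15         # cmH2O/mL^2
    baseline_p0: float = 2.0          # cmH2O (PEEP level)
    between_animal_cv: float = 15.0   # percent, lognormal on r/e1/e2

    # IR effect applied at Baseline 2 (clamp release): elastance rises
    # mainly through its volume-dependent component
    ir_e1_mult: float = 1.15
    ir_e2_mult: float = 2.0
    # ventilation-time effect applied at Final, per strategy
    vcv_final_e1_mult: float = 1.2
    vcv_final_e2_mult: float = 2.0
    vv_final_e1_mult: float = 0.95
    vv_final_e2_mult: float = 0.8

    # waveform noise and VV pattern
    noise_sd: float = 0.2             # cmH2O, additive on Paw
    delivery_cv: float = 1.5          # percent, multiplicative on V_T
    vv_cv: float = 30.0
    vv_n: int = 1200

    # expression model
    log2_fold: dict = field(default_factory=_default_log2_fold)
    ct_ref_mean: float = 18.0
    ct_ref_sd: float = 0.5
    ct_base_dct: float = 5.0          # baseline dCt for every target gene
    ct_animal_sd: float = 0.3         # biological spread of dCt
    ct_replicate_sd: float = 0.15     # technical replicate noise

    # histology model
    collapse_p: dict = field(default_factory=_default_collapse_p)
    other_point_p: float = 0.10       # non-parenchymal grid points
    n_fields: int = 10
    n_points: int = 100
    em_fraction_mean: dict = field(default_factory=_default_em_fraction_mean)
    em_fraction_sd: float = 12.0      # percent
    em_images_per_side: int = 20
    observer_confusion: float = 0.10  # probability of a +/-1 grade slip (kappa ~ 0.7, "good")

    def __post_init__(self) -> None:
        for mult in (self.ir_e1_mult, self.ir_e2_mult, self.vcv_final_e1_mult,
                     self.vcv_final_e2_mult, self.vv_final_e1_mult, self.vv_final_e2_mult):
            if mult <= 0:
                raise InvalidArgumentError("effect multipliers must be positive")
        for p in self.collapse_p.values():
            if not (0 <= p <= 1):
                raise InvalidArgumentError("collapse probabilities must lie in [0, 1]")
        if not (0 <= self.observer_confusion <= 1):
            raise InvalidArgumentError("observer_confusion must lie in [0, 1]")


@dataclass
class StudyBundle:
    """Everything one synthetic experiment produced, plus ground truth."""

    animals: pd.DataFrame                      # animal_id, group, body_weight_kg, ...
    recordings: dict                           # (animal_id, timepoint) -> Recording
    truth_mechanics: pd.DataFrame              # scheduled params per animal x timepoint
    ct_table: pd.DataFrame                     # long triplicate Ct table
    field_counts: pd.DataFrame                 # point counts per animal x side x field
    em_grades: pd.DataFrame                    # two observers' grades per image
    em_truth: pd.DataFrame                     # true fraction-changed per image
    design: StudyDesign = None
    effects: EffectConfig = None
    seed: int = 0


def _strategy(group: str) -> str:
    return "VV" if group.endswith("VV") else "VCV"


def _scheduled_params(base: MechParams, group: str, timepoint: str,
                      effects: EffectConfig) -> MechParams:
    e1, e2 = base.e1_rs, base.e2_rs
    if group.startswith("IR") and timepoint in ("Baseline2", "Initial", "Final"):
        e1 *= effects.ir_e1_mult
        e2 *= effects.ir_e2_mult
    if timepoint == "Final":
        if _strategy(group) == "VCV":
            e1 *= effects.vcv_final_e1_mult
            e2 *= effects.vcv_final_e2_mult
        else:
            e1 *= effects.vv_final_e1_mult
            e2 *= effects.vv_final_e2_mult
    return MechParams(r_rs=base.r_rs, e1_rs=e1, e2_rs=e2, p0=base.p0)


def generate_study(design: StudyDesign = None, effects: EffectConfig = None,
                   seed: int | None = None) -> StudyBundle:
    """Generate one fully reproducible synthetic experiment.

    Every output is directly consumable by the estimation modules
    (breath_mech, gene_expr, histo_score); scheduled ground truth travels
    with the bundle so recovery can be tested. All randomness flows from a
    single seed.
    """
    design = design or StudyDesign()
    effects = effects or EffectConfig()
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)

    # --- animals and randomized group assignment -------------------------
    n_vent = 4 * design.n_per_group
    n_nv = 2 * design.nv_per_group
    ids = [f"A{i + 1:03d}" for i in range(n_vent + n_nv)]
    order = rng.permutation(len(ids))
    labels = (
        [g for g in GROUPS for _ in range(design.n_per_group)]
        + [g for g in NV_GROUPS for _ in range(design.nv_per_group)]
    )
    assignment = {ids[order[k]]: labels[k] for k in range(len(ids))}

    weights = rng.normal(design.body_weight_mean, design.body_weight_sd, size=len(ids))
    while (weights <= 0.2).any():  # keep weights physiological
        bad = weights <= 0.2
        weights[bad] = rng.normal(design.body_weight_mean, design.body_weight_sd,
                                  size=int(bad.sum()))
    animals = pd.DataFrame(
        {
            "animal_id": ids,
            "group": [assignment[a] for a in ids],
            "body_weight_kg": weights,
            # passthrough observational columns, non-mechanistic by design
            "pao2_fio2": rng.normal(350.0, 50.0, size=len(ids)),
            "paco2_mmhg": rng.normal(36.0, 4.0, size=len(ids)),
            "pha": rng.normal(7.38, 0.04, size=len(ids)),
            "map_mmhg": rng.normal(95.0, 12.0, size=len(ids)),
        }
    ).sort_values("animal_id", ignore_index=True)

    vent = animals[animals["group"].isin(GROUPS)]

    # --- mechanics recordings at the four time points --------------------
    sigma = np.sqrt(np.log(1.0 + (effects.between_animal_cv / 100.0) ** 2))
    recordings: dict = {}
    truth_rows = []
    for _, row in vent.iterrows():
        aid, group, bw = row["animal_id"], row["group"], row["body_weight_kg"]
        base = MechParams(
            r_rs=effects.baseline_r * rng.lognormal(-sigma**2 / 2, sigma),
            e1_rs=effects.baseline_e1 * rng.lognormal(-sigma**2 / 2, sigma),
            e2_rs=effects.baseline_e2 * rng.lognormal(-sigma**2 / 2, sigma),
            p0=effects.baseline_p0,
        )
        settings = VentSettings(body_weight=bw)
        vv_seq = None
        for tp in design.timepoints:
            params = _scheduled_params(base, group, tp, effects)
            # VV is applied only after randomization to strategy (post surgery)
            use_vv = _strategy(group) == "VV" and tp in ("Initial", "Final")
            if use_vv and vv_seq is None:
                vv_seq = generate_vt_sequence(
                    settings.vt_nominal, effects.vv_cv, effects.vv_n,
                    seed=int(rng.integers(_SEED_MOD)),
                )
            vt_source = vv_seq if use_vv else settings.vt_nominal
            rec = simulate_run(
                params, settings, vt_source, design.breaths_per_window,
                noise_sd=effects.noise_sd, delivery_cv=effects.delivery_cv,
                seed=int(rng.integers(_SEED_MOD)),
            )
            recordings[(aid, tp)] = rec
            truth_rows.append(
                {
                    "animal_id": aid, "group": group, "timepoint": tp,
                    "strategy": "VV" if use_vv else "VCV",
                    "r_rs": params.r_rs, "e1_rs": params.e1_rs,
                    "e2_rs": params.e2_rs, "p0": params.p0,
                    "body_weight_kg": bw,
                }
            )
    truth_mechanics = pd.DataFrame(truth_rows)

    # --- triplicate Ct table (all animals, both sides) -------------------
    ct_rows = []
    for _, row in animals.iterrows():
        aid, group = row["animal_id"], row["group"]
        for side in SIDES:
            ct_ref = rng.normal(effects.ct_ref_mean, effects.ct_ref_sd)
            for rep in (1, 2, 3):
                ct_rows.append(
                    {
                        "animal_id": aid, "group": group, "lung_side": side,
                        "gene": gene_expr.REFERENCE_GENE, "replicate": rep,
                        "ct": ct_ref + rng.normal(0.0, effects.ct_replicate_sd),
                    }
                )
            for gene in GENES:
                lfc = effects.log2_fold.get((gene, group, side), 0.0)
                dct = effects.ct_base_dct - lfc + rng.normal(0.0, effects.ct_animal_sd)
                for rep in (1, 2, 3):
                    ct_rows.append(
                        {
                            "animal_id": aid, "group": group, "lung_side": side,
                            "gene": gene, "replicate": rep,
                            "ct": ct_ref + dct + rng.normal(0.0, effects.ct_replicate_sd),
                        }
                    )
    ct_table = pd.DataFrame(ct_rows)

    # --- point-count morphometry (ventilated animals) --------------------
    fc_rows = []
    for _, row in vent.iterrows():
        aid, group = row["animal_id"], row["group"]
        for side in SIDES:
            p = effects.collapse_p[(group, side)]
            for k in range(effects.n_fields):
                n_other = rng.binomial(effects.n_points, effects.other_point_p)
                n_collapsed = rng.binomial(effects.n_points - n_other, p)
                fc_rows.append(
                    {
                        "animal_id": aid, "group": group, "lung_side": side,
                        "field_id": f"F{k + 1:02d}",
                        "n_points": effects.n_points,
                        "n_collapsed": int(n_collapsed),
                        "n_normal": int(effects.n_points - n_other - n_collapsed),
                        "n_other": int(n_other),
                    }
                )
    field_counts = pd.DataFrame(fc_rows)

    # --- electron microscopy: shared truth, two noisy observers ----------
    em_rows, em_truth_rows = [], []
    for _, row in vent.iterrows():
        aid, group = row["animal_id"], row["group"]
        for side in SIDES:
            mu = effects.em_fraction_mean[(group, side)]
            for k in range(effects.em_images_per_side):
                frac = float(np.clip(rng.normal(mu, effects.em_fraction_sd), 0.0, 100.0))
                image_id = f"{aid}-{side}-I{k + 1:02d}"
                em_truth_rows.append(
                    {"animal_id": aid, "group": group, "lung_side": side,
                     "image_id": image_id, "fraction_changed": frac}
                )
                true_grade = em_grade_from_fraction(frac)
                for obs in ("obs1", "obs2"):
                    grade = true_grade
                    if rng.random() < effects.observer_confusion:
                        grade = int(np.clip(true_grade + rng.choice([-1, 1]), 0, 4))
                    em_rows.append(
                        {"animal_id": aid, "group": group, "lung_side": side,
                         "image_id": image_id, "observer_id": obs, "grade": grade}
                    )
    em_grades = pd.DataFrame(em_rows)
    em_truth = pd.DataFrame(em_truth_rows)

    return StudyBundle(
        animals=animals,
        recordings=recordings,
        truth_mechanics=truth_mechanics,
        ct_table=ct_table,
        field_counts=field_counts,
        em_grades=em_grades,
        em_truth=em_truth,
        design=design,
        effects=effects,
        seed=int(seed),
    )


@dataclass
class StudyReport:
    """Per-stage analysis tables computed from one synthetic experiment."""

    mechanics_per_animal: pd.DataFrame
    mechanics_summary: pd.DataFrame
    histology_summary: pd.DataFrame
    em_summary: pd.DataFrame
    em_kappa: float
    fold_changes: pd.DataFrame
    expression_summary: pd.DataFrame
    truth_mechanics: pd.DataFrame


def _analyze_mechanics(bundle: StudyBundle) -> pd.DataFrame:
    rows = []
    for (aid, tp), rec in bundle.recordings.items():
        cycles = breath_mech.segment_breaths(rec)
        fits = []
        for i, c in enumerate(cycles):
            fits.append(breath_mech.fit_volume_dependent_eom(c, breath_index=i))
        summ = breath_mech.summarize_window(
            fits, label=tp, window_last_s=30.0,
            breath_duration_s=rec.settings.cycle_duration,
        )
        vt = np.array([f.vt_measured for f in fits]) / rec.settings.body_weight
        group = bundle.animals.set_index("animal_id").loc[aid, "group"]
        row = {"animal_id": aid, "group": group, "timepoint": tp,
               "n_breaths": summ.n_breaths,
               "vt_ml_kg": float(vt.mean()),
               "vt_cv_pct": float(100.0 * vt.std(ddof=1) / vt.mean()) if len(vt) > 1 else 0.0,
               "negative_e2_flag": summ.flagged}
        for name in ("r_rs", "e1_rs", "e2_rs", "p0", "pct_e2"):
            row[name] = summ.params[name][0]
        rows.append(row)
    return pd.DataFrame(rows)


def end_to_end(design: StudyDesign = None, effects: EffectConfig = None,
               seed: int | None = None, bundle: StudyBundle | None = None) -> StudyReport:
    """Run the full pipeline on one synthetic experiment.

    Produces the analysis shape of such a study: a mechanics block
    (group x time point, mean +/- SD across animals), histology and
    electron-microscopy summaries (median [IQR]), the inter-observer kappa,
    and the expression fold-change block, each with ground truth attached.
    """
    if bundle is None:
        bundle = generate_study(design, effects, seed)

    per_animal = _analyze_mechanics(bundle)
    mech_rows = []
    for (group, tp), sub in per_animal.groupby(["group", "timepoint"], sort=True):
        for var in ("r_rs", "e1_rs", "e2_rs", "pct_e2", "vt_ml_kg", "vt_cv_pct"):
            v = sub[var].to_numpy()
            mech_rows.append(
                {"group": group, "timepoint": tp, "parameter": var,
                 "mean": float(v.mean()),
                 "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                 "n": len(v)}
            )
    mechanics_summary = pd.DataFrame(mech_rows)

    histo_rows = []
    for (group, side, aid), sub in bundle.field_counts.groupby(
        ["group", "lung_side", "animal_id"], sort=True
    ):
        fields = [
            FieldCount(
                field_id=r.field_id, n_collapsed=r.n_collapsed,
                n_normal=r.n_normal, n_other=r.n_other, n_points=r.n_points,
            )
            for r in sub.itertuples()
        ]
        cs = histo_score.collapse_fraction(fields)
        histo_rows.append(
            {"group": group, "lung_side": side, "animal_id": aid,
             "collapse_median_pct": cs.median, "collapse_mean_pct": cs.mean}
        )
    per_animal_histo = pd.DataFrame(histo_rows)
    histology_summary = (
        per_animal_histo.groupby(["group", "lung_side"], sort=True)["collapse_median_pct"]
        .agg(
            median="median",
            q1=lambda s: float(np.percentile(s, 25)),
            q3=lambda s: float(np.percentile(s, 75)),
            n="count",
        )
        .reset_index()
    )

    em_wide = bundle.em_grades.pivot_table(
        index=["animal_id", "group", "lung_side", "image_id"],
        columns="observer_id", values="grade",
    ).reset_index()
    kappa = histo_score.cohens_kappa(em_wide["obs1"], em_wide["obs2"])
    per_animal_em = (
        em_wide.groupby(["group", "lung_side", "animal_id"], sort=True)["obs1"]
        .median()
        .rename("grade_median")
        .reset_index()
    )
    em_summary = (
        per_animal_em.groupby(["group", "lung_side"], sort=True)["grade_median"]
        .agg(
            median="median",
            q1=lambda s: float(np.percentile(s, 25)),
            q3=lambda s: float(np.percentile(s, 75)),
            n="count",
        )
        .reset_index()
    )

    mean_ct = gene_expr.collapse_replicates(bundle.ct_table)
    folds = gene_expr.fold_change_ddct(mean_ct)
    expression_summary = gene_expr.summarize_folds(folds)

    return StudyReport(
        mechanics_per_animal=per_animal,
        mechanics_summary=mechanics_summary,
        histology_summary=histology_summary,
        em_summary=em_summary,
        em_kappa=float(kappa),
        fold_changes=folds,
        expression_summary=expression_summary,
        truth_mechanics=bundle.truth_mechanics,
    )


def write_bundle(bundle: StudyBundle, out_dir) -> list:
    """Serialize a bundle as the CSV dialects the other modules read."""
    import os

    from .lung_sim import write_recording_csv

    os.makedirs(out_dir, exist_ok=True)
    written = []

    def _save(df: pd.DataFrame, name: str):
        path = os.path.join(out_dir, name)
        df.to_csv(path, index=False)
        written.append(path)

    _save(bundle.animals, "animals.csv")
    _save(bundle.truth_mechanics, "truth_mechanics.csv")
    _save(bundle.ct_table, "ct_table.csv")
    _save(bundle.field_counts, "field_counts.csv")
    _save(bundle.em_grades, "em_grades.csv")
    _save(bundle.em_truth, "em_truth.csv")
    rec_dir = os.path.join(out_dir, "recordings")
    os.makedirs(rec_dir, exist_ok=True)
    for (aid, tp), rec in bundle.recordings.items():
        path = os.path.join(rec_dir, f"{aid}_{tp}.csv")
        write_recording_csv(rec, path)
        written.append(path)
    return written
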