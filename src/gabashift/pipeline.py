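"""End-to-end pipeline: simulate → fit input → fit 2TC → compose → Lassen → stats.

All randomness flows from one top-level seed through per-stage derived
seeds, so a rerun with the same configuration reproduces every output file
(checksummed in the run manifest).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import input_function as ifn
from . import kinetics as kin
from . import synthetic_data as synth
from .group_stats import paired_comparison, pearson_with_normality, rm_anova
from .lassen import LASSEN_ROIS, group_shift_summary, lassen_fit
from .regions import DEFAULT_COMPOSITES, DEFAULT_VOLUMES_MM3, composite_value, load_region_config
from .schedule import make_frame_schedule

__all__ = ["RunConfig", "run_pipeline", "fit_cohort", "input_fit_to_dict", "input_fit_from_dict"]

# pons kinetics for the reference region: no specific binding (k3 = 0)
_PONS_K1 = 0.15


@dataclass
class RunConfig:
    """Configuration for an end-to-end synthetic-cohort run.

    ``dose_group`` picks the affinity-shift regime: 'I' (low dose, no
    shift, s = 1.0) or 'II' (high dose, s = 1.27); ``shift`` overrides it
    when set.  ``shift_sd`` is the between-subject SD of the true shift.
    """

    out_dir: str = "gabashift_run"
    n_subjects: int = 9
    dose_group: str = "II"
    shift: float | None = None
    shift_sd: float = 0.1
    vnd_true: float = 1.0
    noise_scale: float = 0.05
    blood_volume_fraction: float = 0.05
    seed: int = 0
    regions_config: str | None = None
    run_eeg: bool = True

    def __post_init__(self):
        if not 0 <= self.blood_volume_fraction <= 0.2:
            raise ValueError("blood volume fraction must lie in [0, 0.2]")
        if self.dose_group not in ("I", "II"):
            raise ValueError("dose_group must be 'I' or 'II'")

    @property
    def group_shift(self) -> float:
        if self.shift is not None:
            return self.shift
        return 1.0 if self.dose_group == "I" else 1.27


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def input_fit_to_dict(fit: ifn.InputFunctionFit) -> dict:
    return {
        "peak_time": fit.peak_time,
        "pre_times": fit.pre_times.tolist(),
        "pre_values": fit.pre_values.tolist(),
        "amplitudes": fit.amplitudes.tolist(),
        "rates": fit.rates.tolist(),
        "auc": fit.auc,
        "residual_norm": fit.residual_norm,
    }


def input_fit_from_dict(d: dict) -> ifn.InputFunctionFit:
    return ifn.InputFunctionFit(
        peak_time=d["peak_time"],
        pre_times=np.asarray(d["pre_times"]),
        pre_values=np.asarray(d["pre_values"]),
        amplitudes=np.asarray(d["amplitudes"]),
        rates=np.asarray(d["rates"]),
        auc=d["auc"],
        residual_norm=d.get("residual_norm", 0.0),
    )


def _subject_truth(config: RunConfig, subject_seed: int, rng: np.random.Generator) -> synth.GroundTruth:
    s = max(rng.normal(config.group_shift, config.shift_sd), 0.05)
    return synth.default_ground_truth(
        affinity_shift=s,
        vnd_true=config.vnd_true,
        noise_scale=config.noise_scale,
        seed=subject_seed,
        blood_volume_fraction=config.blood_volume_fraction,
    )


def fit_cohort(
    pairs: dict,
    input_fit: ifn.InputFunctionFit,
    parent_fraction: ifn.ParentFractionFit | None = None,
    blood_volume_fraction: float = 0.05,
) -> pd.DataFrame:
    """Blood-correct and 2TC-fit every TAC of every subject/condition/region.

    Returns the tidy fit table (one row per subject × condition × region)
    with kinetic parameters, VT and, where a PON fit exists, BP_P/BP_ND.
    """
    schedule = next(iter(pairs.values())).tacs_baseline[
        next(iter(next(iter(pairs.values())).tacs_baseline))
    ].schedule
    plasma_frames = synth.total_plasma_at_frames(input_fit, schedule, parent_fraction)
    rows = []
    for subject, pair in pairs.items():
        for condition, tacs in (("baseline", pair.tacs_baseline), ("post", pair.tacs_post)):
            for region, tac in tacs.items():
                corrected = kin.blood_correct(tac, plasma_frames, blood_volume_fraction)
                fit = kin.fit_2tc(corrected, input_fit)
                rows.append(
                    {
                        "subject": subject,
                        "condition": condition,
                        "region": region,
                        "K1": fit.params.K1,
                        "k2": fit.params.k2,
                        "k3": fit.params.k3,
                        "k4": fit.params.k4,
                        "VT": fit.vt,
                        "converged": fit.converged,
                        "residual": fit.weighted_residual_norm,
                    }
                )
    df = pd.DataFrame(rows)
    # attach binding potentials relative to the pons VT of the same scan
    bp_p, bp_nd = [], []
    pons = df[df.region == "PON"].set_index(["subject", "condition"]).VT
    for _, r in df.iterrows():
        if (r.subject, r.condition) in pons.index and r.region != "PON":
            out = kin.outcomes(r.VT, pons.loc[(r.subject, r.condition)])
            bp_p.append(out.bp_p)
            bp_nd.append(out.bp_nd)
        else:
            bp_p.append(np.nan)
            bp_nd.append(np.nan)
    df["BP_P"] = bp_p
    df["BP_ND"] = bp_nd
    return df


def region_tables(fits: pd.DataFrame, composites=None, volumes=None) -> pd.DataFrame:
    """Per-subject composite rows (volume-weighted) appended to component rows."""
    composites = composites or DEFAULT_COMPOSITES
    volumes = volumes or DEFAULT_VOLUMES_MM3
    out = [fits.assign(is_composite=False)]
    for name, members in composites.items():
        sub = fits[fits.region.isin(members)]
        if sub.empty:
            continue
        vols = [volumes[m] for m in members]
        grouped = sub.groupby(["subject", "condition"])
        rows = []
        for (subject, condition), g in grouped:
            g = g.set_index("region").loc[members]
            row = {"subject": subject, "condition": condition, "region": name, "is_composite": True}
            for col in ("K1", "VT", "BP_P", "BP_ND"):
                row[col] = composite_value(g[col].to_numpy(), vols)
            rows.append(row)
        out.append(pd.DataFrame(rows))
    return pd.concat(out, ignore_index=True)


def stats_tables(region_fits: pd.DataFrame, measure: str = "VT") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired baseline/post comparison per region plus the split-plot RM ANOVA.

    Returns (comparison table, ANOVA table); the ANOVA uses the ten
    component ROIs only, matching the study design.
    """
    wide = region_fits.pivot_table(index=["subject", "region"], columns="condition", values=measure)
    rows = []
    for region, g in wide.groupby(level="region"):
        cmp_ = paired_comparison(g["baseline"].to_numpy(), g["post"].to_numpy())
        row = {"region": region, **asdict(cmp_)}
        rows.append(row)
    comparisons = pd.DataFrame(rows)
    long = region_fits[region_fits.region.isin(LASSEN_ROIS)][
        ["subject", "region", "condition", measure]
    ].rename(columns={measure: "value"})
    anova = rm_anova(long)
    return comparisons, anova


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic-cohort analysis and write a manifest.

    Stages: plasma simulation and input fitting; per-subject scan-pair
    simulation; blood correction and 2TC fits; composite tables; Lassen
    fits and group shift summary; paired t / RM ANOVA tables; optional
    EEG simulation with the frontal gamma summary and its correlation with
    the orbitofrontal VT change.  Every output file is checksummed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seed_plasma, seed_subjects, seed_eeg = [int(s) for s in ss.generate_state(3)]
    results: dict = {"config": asdict(config)}
    files: list[Path] = []

    # --- stage 1: plasma + input function -------------------------------
    plasma, mets, true_input, true_pf = synth.simulate_plasma(seed=seed_plasma % 2**31)
    plasma.to_csv(out / "plasma.csv", index=False)
    mets.to_csv(out / "metabolites.csv", index=False)
    pf_fit = ifn.fit_parent_fraction(mets.time_min, mets.parent_fraction)
    parent = ifn.compute_input(plasma.time_min, plasma.total_activity_kbq_ml, pf_fit)
    input_fit = ifn.fit_input_function(plasma.time_min, parent)
    (out / "input_fit.json").write_text(
        json.dumps(
            {
                **input_fit_to_dict(input_fit),
                "parent_fraction": {"a": pf_fit.a, "b": pf_fit.b, "c_const": pf_fit.c_const},
            },
            indent=1,
        )
    )
    files += [out / "plasma.csv", out / "metabolites.csv", out / "input_fit.json"]

    # --- stage 2: subject scan pairs ------------------------------------
    rng = np.random.default_rng(seed_subjects % 2**31)
    schedule = make_frame_schedule()
    pairs = {}
    truths = {}
    for i in range(config.n_subjects):
        sid = f"S{i + 1:02d}"
        truth = _subject_truth(config, int(rng.integers(2**31)), rng)
        pons = kin.KineticParams(K1=_PONS_K1, k2=_PONS_K1 / config.vnd_true, k3=0.0, k4=0.0)
        truth = synth.GroundTruth(
            params_baseline={**truth.params_baseline, "PON": pons},
            affinity_shift=truth.affinity_shift,
            vnd_true=truth.vnd_true,
            blood_volume_fraction=truth.blood_volume_fraction,
            noise_scale=truth.noise_scale,
            seed=truth.seed,
        )
        pairs[sid] = synth.simulate_subject_pair(
            truth,
            regions=tuple(LASSEN_ROIS) + ("PON",),
            input_fit=true_input,
            schedule=schedule,
            parent_fraction=true_pf,
        )
        truths[sid] = truth
    tac_table = synth.tacs_to_frame(pairs, schedule)
    tac_table.to_csv(out / "tacs.csv", index=False)
    (out / "ground_truth.json").write_text(
        json.dumps(
            {
                sid: {
                    "affinity_shift": t.affinity_shift,
                    "vnd_true": t.vnd_true,
                    "noise_scale": t.noise_scale,
                    "seed": t.seed,
                }
                for sid, t in truths.items()
            },
            indent=1,
        )
    )
    files += [out / "tacs.csv", out / "ground_truth.json"]

    # --- stage 3: kinetic fits ------------------------------------------
    fits = fit_cohort(pairs, input_fit, true_pf, config.blood_volume_fraction)
    fits.to_csv(out / "fits.csv", index=False)
    files.append(out / "fits.csv")

    # --- stage 4: composites --------------------------------------------
    composites, volumes = (
        load_region_config(config.regions_config)
        if config.regions_config
        else (DEFAULT_COMPOSITES, DEFAULT_VOLUMES_MM3)
    )
    region_fits = region_tables(fits, composites, volumes)
    region_fits.to_csv(out / "region_fits.csv", index=False)
    files.append(out / "region_fits.csv")

    # --- stage 5: Lassen -------------------------------------------------
    wide = fits[fits.region.isin(LASSEN_ROIS)].pivot_table(
        index=["subject", "region"], columns="condition", values="VT"
    )
    lassen_rows = []
    lassen_fits = []
    for subject, g in wide.groupby(level="subject"):
        fit = lassen_fit(g["baseline"].to_numpy(), g["post"].to_numpy())
        lassen_fits.append(fit)
        lassen_rows.append({"subject": subject, **asdict(fit)})
    lassen_table = pd.DataFrame(lassen_rows)
    lassen_table.to_csv(out / "lassen.csv", index=False)
    shift_summary = group_shift_summary(lassen_fits)
    (out / "lassen_summary.json").write_text(json.dumps(shift_summary, indent=1))
    files += [out / "lassen.csv", out / "lassen_summary.json"]
    results["lassen_summary"] = shift_summary

    # --- stage 6: group statistics ---------------------------------------
    comparisons, anova = stats_tables(region_fits, measure="VT")
    comparisons.to_csv(out / "stats_vt.csv", index=False)
    anova.to_csv(out / "anova_vt.csv", index=False)
    files += [out / "stats_vt.csv", out / "anova_vt.csv"]
    results["anova_vt"] = anova.to_dict(orient="records")

    # --- stage 7: EEG (optional) ------------------------------------------
    if config.run_eeg:
        from .eeg import frontal_gamma_summary, morlet_power, reject_artifacts

        eeg_ss = np.random.SeedSequence(seed_eeg % 2**31)
        eeg_seeds = eeg_ss.generate_state(config.n_subjects)
        eeg_rows = []
        for i, (sid, truth) in enumerate(truths.items()):
            # couple the high-control burst amplitude to the subject's true
            # GABA response so a PET-EEG correlation exists by construction
            high_amp = 1.0 + max(truth.affinity_shift - 1.0, 0.0) * 2.0
            epochs = synth.simulate_eeg(
                n_trials=100,
                gamma_amplitude_by_condition={"low": 1.0, "high": high_amp},
                seed=int(eeg_seeds[i]),
            )
            kept = reject_artifacts(epochs)
            epochs.data = epochs.data[kept]
            epochs.labels = epochs.labels[kept]
            tf = morlet_power(epochs)
            summary = frontal_gamma_summary(tf)
            eeg_rows.append({"subject": sid, **summary})
        eeg_table = pd.DataFrame(eeg_rows)
        eeg_table.to_csv(out / "eeg_gamma.csv", index=False)
        files.append(out / "eeg_gamma.csv")
        # correlate OFC VT percent change with the frontal gamma contrast
        ofc = wide.xs("OFC", level="region")
        pct = 100.0 * (ofc["post"] - ofc["baseline"]) / ofc["baseline"]
        merged = eeg_table.set_index("subject").join(pct.rename("ofc_dvt_pct"))
        if merged.shape[0] >= 3:
            r, p, ks = pearson_with_normality(merged["ofc_dvt_pct"], merged["contrast"])
            results["eeg_pet_correlation"] = {"r": r, "p": p, "ks_pass": ks}
            (out / "eeg_pet_correlation.json").write_text(
                json.dumps(results["eeg_pet_correlation"], indent=1)
            )
            files.append(out / "eeg_pet_correlation.json")

    manifest = {
        "seed": config.seed,
        "stage_seeds": {"plasma": seed_plasma, "subjects": seed_subjects, "eeg": seed_eeg},
        "files": {f.name: _sha256(f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results
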