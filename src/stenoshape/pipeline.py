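"""End-to-end workflow orchestration.

Runs the full chain: cohort generation -> shape-model fit and projection ->
reference flow campaign -> loss-coefficient fitting -> geometry-wise
train/test split -> GP regressor training -> pressure-drop and FFR
prediction on the held-out geometries -> evaluation.  Every stage writes a
CSV artifact into the run directory and the whole run is summarised in a
machine-readable ``summary.json``; all randomness is driven by the seeds
recorded there, so every artifact is regenerable bit-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import FluidConstants, StateError, pa_to_mmhg
from .element import HeinenGeometry, heinen_dp
from .geometry import generate_cohort, save_cohort
from .lossfit import build_training_table, fit_campaign, h_terms
from .metrics import (ffr_agreement, r2_identity, rmse_and_calibration,
                      roc_auc_delong)
from .oracle import OracleConfig, run_campaign
from .regression import gpr_predict, train_target
from .shape import (displacement_field, explained_variance, fit_shape_model,
                    project_cohort, save_model, straight_template)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (YAML-serializable)."""

    n_geometries: int = 1024
    cohort_seed: int = 42
    oracle_seed: int = 7
    split_seed: int = 0
    search_seed: int = 0
    severity_lo: float = 0.3
    severity_hi: float = 0.8
    n_modes: int | str = 5
    var_threshold: float = 0.90
    noise_sd: float = 0.0
    mismatch_gain: float = 0.0
    fail_prob: float = 0.0
    train_fraction: float = 0.9
    n_trials: int = 20
    folds: int = 5
    sampler: str = "tpe"
    out_root: str = "runs"

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def split_geometries(manifest: pd.DataFrame, train_fraction: float,
                     seed: int) -> tuple[list[str], list[str]]:
    """Seeded geometry-wise train/test split, stratified by severity decile.

    The training count is floor(train_fraction * n); the test geometries
    are spread across severity deciles so small test sets still cover the
    severity range.
    """
    n = len(manifest)
    n_train = math.floor(train_fraction * n)
    n_test = n - n_train
    order = manifest.sort_values("s_sev", kind="mergesort")["id"].tolist()
    deciles: list[list[str]] = [[] for _ in range(10)]
    for rank, gid in enumerate(order):
        deciles[min(rank * 10 // max(n, 1), 9)].append(gid)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51137]))
    for d in deciles:
        rng.shuffle(d)
    interleaved: list[str] = []
    while any(deciles):
        for d in deciles:
            if d:
                interleaved.append(d.pop())
    test = sorted(interleaved[:n_test])
    train = sorted(set(manifest["id"]) - set(test))
    return train, test


def run_full_pipeline(cfg: PipelineConfig,
                      consts: FluidConstants | None = None,
                      write_meshes: bool = False) -> Path:
    """Execute the full workflow; returns the run directory."""
    consts = consts or FluidConstants()
    run_dir = Path(cfg.out_root) / (
        f"run_n{cfg.n_geometries}_s{cfg.cohort_seed}")
    for sub in ("cohort", "ssm", "campaign", "models", "eval"):
        (run_dir / sub).mkdir(parents=True, exist_ok=True)

    # --- cohort ---------------------------------------------------------
    profiles, meshes, manifest = generate_cohort(
        cfg.n_geometries, cfg.cohort_seed, consts,
        lo=cfg.severity_lo, hi=cfg.severity_hi)
    if write_meshes:
        save_cohort(run_dir / "cohort", profiles, meshes, manifest)
    else:
        manifest.to_csv(run_dir / "cohort" / "manifest.csv", index=False)

    # --- statistical shape model ---------------------------------------
    template = straight_template(consts, ntheta=meshes[0].ntheta)
    disps = [displacement_field(template, m) for m in meshes]
    model = fit_shape_model(disps, n_modes=cfg.n_modes,
                            var_threshold=cfg.var_threshold,
                            template=template)
    save_model(model, run_dir / "ssm" / "model.ssm.npz")
    frac, cum = explained_variance(model)
    pd.DataFrame({"mode": np.arange(1, frac.size + 1),
                  "variance_fraction": frac,
                  "cumulative_fraction": cum}).to_csv(
        run_dir / "ssm" / "explained_variance.csv", index=False)
    alphas = project_cohort(model, meshes)
    alphas.to_csv(run_dir / "ssm" / "alphas.csv", index=False)

    # --- reference campaign and loss-coefficient fits -------------------
    oracle_cfg = OracleConfig(noise_sd=cfg.noise_sd,
                              mismatch_gain=cfg.mismatch_gain,
                              fail_prob=cfg.fail_prob, seed=cfg.oracle_seed)
    campaign = run_campaign(profiles, oracle_cfg, consts,
                            geometry_ids=manifest["id"].tolist())
    campaign.to_csv(run_dir / "campaign" / "campaign.csv", index=False)
    loss = fit_campaign(campaign, consts)
    table = build_training_table(loss, alphas)
    table.to_csv(run_dir / "campaign" / "training_table.csv", index=False)

    # --- split and train -------------------------------------------------
    train_ids, test_ids = split_geometries(manifest, cfg.train_fraction,
                                           cfg.split_seed)
    train_tbl = table[table["id"].isin(train_ids)]
    test_tbl = table[table["id"].isin(test_ids)].reset_index(drop=True)
    models = {}
    for target in ("kv", "kt"):
        m, trials = train_target(train_tbl, target, n_trials=cfg.n_trials,
                                 k=cfg.folds, seed=cfg.search_seed,
                                 sampler=cfg.sampler)
        models[target] = m
        if len(trials):
            trials.to_csv(run_dir / "models" / f"{target}_trials.csv",
                          index=False)

    # --- predict and evaluate -------------------------------------------
    alpha_cols = [c for c in table.columns if c.startswith("alpha_")]
    X_test = test_tbl[alpha_cols].to_numpy(float)
    kv_hat, kv_sd = gpr_predict(models["kv"], X_test)
    kt_hat, kt_sd = gpr_predict(models["kt"], X_test)
    coeff_pred = test_tbl[["id", "kv", "kt"]].assign(
        kv_pred=kv_hat, kv_sigma=kv_sd, kt_pred=kt_hat, kt_sigma=kt_sd)
    coeff_pred.to_csv(run_dir / "eval" / "coefficients.csv", index=False)

    usable = campaign[campaign["converged"] & ~campaign["excluded"]]
    test_samples = usable[usable["geometry_id"].isin(test_ids)].merge(
        coeff_pred, left_on="geometry_id", right_on="id")
    h1, h2 = h_terms(test_samples["q_m3s"].to_numpy(), consts)
    dp_pred = test_samples["kv_pred"].to_numpy() * h1 \
        + test_samples["kt_pred"].to_numpy() * h2
    dp_sigma = np.hypot(h1 * test_samples["kv_sigma"].to_numpy(),
                        h2 * test_samples["kt_sigma"].to_numpy())
    dp_ref = test_samples["dp_sten_pa"].to_numpy()
    # parameter-free geometry-based comparator: unit loss coefficients with
    # the lesion's Borda-Carnot area factor
    a_s = (1.0 - test_samples["geometry_id"].map(
        manifest.set_index("id")["s_sev"]).to_numpy()) * consts.a0
    dp_heinen = np.array([
        heinen_dp(HeinenGeometry(a0=consts.a0, a_s=s, ls=consts.ls,
                                 kv=1.0, kt=1.0), q, consts)
        for s, q in zip(a_s, test_samples["q_m3s"].to_numpy())])

    ffr_ref = 1.0 - dp_ref / consts.p_aorta
    ffr_pred = 1.0 - dp_pred / consts.p_aorta
    ffr_hein = 1.0 - dp_heinen / consts.p_aorta
    preds = pd.DataFrame({
        "id": test_samples["geometry_id"], "re": test_samples["re"],
        "dp_ref_pa": dp_ref, "dp_pred_pa": dp_pred, "dp_sigma_pa": dp_sigma,
        "dp_heinen_pa": dp_heinen, "ffr_ref": ffr_ref,
        "ffr_pred": ffr_pred, "ffr_heinen": ffr_hein})
    preds.to_csv(run_dir / "eval" / "predictions.csv", index=False)

    def metric_block(y, yhat, sig):
        r = rmse_and_calibration(y, yhat, sig)
        return {"r2_identity": r2_identity(y, yhat), "rmse": r.rmse,
                "mean_predictive_sigma": r.mean_predictive_sigma,
                "rmse_sigma_ratio": r.rmse_sigma_ratio, "n": int(r.n)}

    agree = ffr_agreement(ffr_ref, ffr_pred)
    agree_h = ffr_agreement(ffr_ref, ffr_hein)
    ischemic = ffr_ref <= 0.80
    roc = None
    if ischemic.any() and (~ischemic).any():
        auc_dd, auc_h, delta, p = roc_auc_delong(ischemic, dp_pred, dp_heinen)
        roc = {"auc_data_driven": auc_dd, "auc_heinen": auc_h,
               "delta_auc": delta, "delong_p": p}

    summary = {
        "config": {k: v for k, v in asdict(cfg).items()
                   if k != "out_root"},
        "counts": {
            "geometries": int(cfg.n_geometries),
            "train": len(train_ids), "test": len(test_ids),
            "campaign_rows": int(len(campaign)),
            "non_converged": int((~campaign["converged"]).sum()),
            "excluded": int(campaign["excluded"].sum()),
        },
        "shape_model": {
            "n_modes_kept": int(model.n_modes_kept),
            "cumulative_variance_kept": float(cum[model.n_modes_kept - 1]),
            "cumulative_variance_5": float(cum[min(4, cum.size - 1)]),
        },
        "metrics": {
            "kv": metric_block(coeff_pred["kv"].to_numpy(), kv_hat, kv_sd),
            "kt": metric_block(coeff_pred["kt"].to_numpy(), kt_hat, kt_sd),
            "dp": metric_block(dp_ref, dp_pred, dp_sigma),
        },
        "ffr": {
            "data_driven": asdict(agree),
            "heinen": asdict(agree_h),
            "roc": roc,
        },
    }
    with open(run_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return run_dir


def export_report(run_dir) -> str:
    """Render a human-readable report from a completed run directory."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise StateError(f"no summary.json in {run_dir}; run the pipeline "
                         "first")
    with open(summary_path) as fh:
        s = json.load(fh)
    lines = ["stenoshape pipeline report", "=" * 26, ""]
    c = s["counts"]
    lines.append(f"cohort: {c['geometries']} geometries "
                 f"({c['train']} train / {c['test']} test); "
                 f"campaign rows: {c['campaign_rows']} "
                 f"({c['excluded']} excluded > 60 mmHg, "
                 f"{c['non_converged']} non-converged)")
    sm = s["shape_model"]
    lines.append(f"shape model: {sm['n_modes_kept']} modes kept, "
                 f"cumulative variance "
                 f"{100 * sm['cumulative_variance_kept']:.1f}% "
                 f"(first five: {100 * sm['cumulative_variance_5']:.1f}%)")
    lines.append("")
    lines.append(f"{'model':<6} {'R2_y=x':>8} {'RMSE':>10} "
                 f"{'mean sigma':>11} {'RMSE/sigma':>11}")
    for name in ("kv", "kt", "dp"):
        m = s["metrics"][name]
        lines.append(f"{name:<6} {m['r2_identity']:>8.3f} "
                     f"{m['rmse']:>10.3f} {m['mean_predictive_sigma']:>11.3f} "
                     f"{m['rmse_sigma_ratio']:>11.2f}")
    lines.append("")
    for name, block in (("data-driven", s["ffr"]["data_driven"]),
                        ("Heinen", s["ffr"]["heinen"])):
        lines.append(
            f"FFR {name}: within 0.02 of reference in "
            f"{100 * block['within_tol_fraction']:.1f}% of samples; "
            f"bias {block['bias']:+.3f} "
            f"[{block['loa_low']:+.3f}, {block['loa_high']:+.3f}]; "
            f"accuracy at 0.80: {100 * block['accuracy']:.1f}%")
    roc = s["ffr"]["roc"]
    if roc:
        lines.append(f"ROC: AUC data-driven {roc['auc_data_driven']:.3f} "
                     f"vs Heinen {roc['auc_heinen']:.3f} "
                     f"(delta {roc['delta_auc']:+.3f}, "
                     f"DeLong p = {roc['delong_p']:.3f})")
    report = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(report)
    return report
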