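"""Validation report: compare manual and automatic landmark batches.

Reproduces the standard accuracy/reliability battery for an automatic
landmarking method against a manual gold standard: per-landmark Euclidean
distances and per-axis RMSE, Bland–Altman limits of agreement, ICC on
centroid size, sequential-SS ANOVA of centroid size and Procrustes ANOVA of
shape (individual, observer, method, individual × observer), intra-/inter-
observer error SDs, Levene's test on error distributions, and a paired t
comparing manual vs manual–automatic inter-observer errors.

Batch tables use the long CSV layout ``face_id, landmark, method, observer,
iteration, x, y, z`` (method/observer/iteration optional where they do not
apply).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import (
    AnovaTable,
    ShapeSample,
    anova_univariate,
    bland_altman,
    centroid_size,
    euclidean_error,
    gpa_align,
    icc_agreement,
    levene_test,
    observer_error_sd,
    paired_t,
    procrustes_anova,
    rmse_per_axis,
)

__all__ = ["validation_report"]

_COORDS = ["x", "y", "z"]


def _mean_per_face_landmark(df: pd.DataFrame) -> pd.DataFrame:
    return df.groupby(["face_id", "landmark"], as_index=False)[_COORDS].mean()


def _configs_from_table(df: pd.DataFrame, landmark_order: list[str]) -> tuple[np.ndarray, list]:
    """Stack per-face configurations (faces sorted) in a fixed landmark order."""
    faces = sorted(df["face_id"].unique())
    out = np.empty((len(faces), len(landmark_order), 3))
    piv = df.set_index(["face_id", "landmark"])
    for i, f in enumerate(faces):
        for j, lm in enumerate(landmark_order):
            out[i, j] = piv.loc[(f, lm), _COORDS].to_numpy(dtype=np.float64)
    return out, faces


def validation_report(
    manual: pd.DataFrame,
    auto: pd.DataFrame,
    seed: int = 0,
    n_permutations: int = 999,
) -> dict:
    """Full accuracy + reliability comparison of two landmark batches.

    ``manual`` may contain repeated indications (observer/iteration
    columns); ``auto`` one indication per face/landmark, optionally per
    training observer.  Returns a dict of DataFrames/scalars; the CLI
    writes each entry as a CSV.
    """
    for df, nm in ((manual, "manual"), (auto, "auto")):
        missing = {"face_id", "landmark", "x", "y", "z"} - set(df.columns)
        if missing:
            raise ValueError(f"{nm} batch missing columns {sorted(missing)}")
    landmark_order = sorted(manual["landmark"].unique())
    if set(auto["landmark"].unique()) != set(landmark_order):
        raise ValueError("manual and automatic batches cover different landmarks")

    report: dict = {}
    c_ml = _mean_per_face_landmark(manual)
    c_auto = _mean_per_face_landmark(auto)

    per_lm, grand = euclidean_error(c_ml, c_auto)
    report["euclidean_per_landmark"] = per_lm.rename("mean_distance_mm").to_frame()
    report["euclidean_grand_mean"] = grand
    report["rmse_per_axis"] = rmse_per_axis(c_ml, c_auto)

    merged = c_ml.merge(c_auto, on=["face_id", "landmark"], suffixes=("_ml", "_auto"))
    ba_rows = []
    for ax in _COORDS:
        m, (lo, hi) = bland_altman(merged[f"{ax}_ml"], merged[f"{ax}_auto"])
        ba_rows.append({"axis": ax, "mean_diff": m, "loa_low": lo, "loa_high": hi})
    report["bland_altman"] = pd.DataFrame(ba_rows)

    # --- centroid size and shape models -----------------------------------
    has_observers = (
        "observer" in manual.columns
        and "observer" in auto.columns
        and manual["observer"].nunique() > 1
        and set(auto["observer"].unique()) == set(manual["observer"].unique())
    )
    rows, configs, labels = [], [], []
    if has_observers:
        for obs in sorted(manual["observer"].unique()):
            for method, df in (("manual", manual), ("auto", auto)):
                sub = _mean_per_face_landmark(df[df["observer"] == obs])
                cfg, faces = _configs_from_table(sub, landmark_order)
                for f, c in zip(faces, cfg):
                    configs.append(c)
                    labels.append({"individual": f, "observer": obs, "method": method})
        terms = ["individual", "observer", "method", "individual:observer"]
    else:
        for method, df in (("manual", c_ml), ("auto", c_auto)):
            cfg, faces = _configs_from_table(df, landmark_order)
            for f, c in zip(faces, cfg):
                configs.append(c)
                labels.append({"individual": f, "method": method})
        terms = ["individual", "method"]
    configs = np.asarray(configs)
    labels = pd.DataFrame(labels)

    cs = np.array([centroid_size(c) for c in configs])
    cs_anova: AnovaTable = anova_univariate(cs, labels, terms, n_permutations, seed)
    report["centroid_size_anova"] = cs_anova

    sample = ShapeSample(configs, labels, landmark_order)
    aligned, _ = gpa_align(sample, scale=True)
    report["shape_anova"] = procrustes_anova(aligned, terms, n_permutations, seed)

    # ICC of centroid size between methods, per observer pairing
    icc_rows = []
    if has_observers:
        for obs in sorted(manual["observer"].unique()):
            mask = labels["observer"] == obs
            tab = pd.DataFrame({"cs": cs[mask], "individual": labels.loc[mask, "individual"],
                                "method": labels.loc[mask, "method"]})
            wide = tab.pivot(index="individual", columns="method", values="cs")
            icc_rows.append({"pairing": obs, "icc_a1": icc_agreement(wide.to_numpy())})
    tab = pd.DataFrame({"cs": cs, "individual": labels["individual"], "method": labels["method"]})
    wide = tab.groupby(["individual", "method"])["cs"].mean().unstack()
    icc_rows.append({"pairing": "combined", "icc_a1": icc_agreement(wide.to_numpy())})
    report["icc_centroid_size"] = pd.DataFrame(icc_rows)

    # --- reliability -------------------------------------------------------
    if has_observers and "iteration" in manual.columns:
        observers = sorted(manual["observer"].unique())
        intra = []
        for obs in observers:
            _, g = observer_error_sd(manual[manual["observer"] == obs])
            intra.append({"observer": obs, "mean_sd_mm": g})
        report["intra_observer_error"] = pd.DataFrame(intra)

        def obs_mean(df, obs):
            sub = _mean_per_face_landmark(df[df["observer"] == obs])
            return sub

        def inter_sd(batch_a, batch_b):
            both = pd.concat([batch_a, batch_b], ignore_index=True)
            return observer_error_sd(both)

        pairs = {}
        if len(observers) == 2:
            a, b = observers
            pairs["A_ML_vs_B_ML"] = (obs_mean(manual, a), obs_mean(manual, b))
            pairs["A_ML_vs_B_Auto"] = (obs_mean(manual, a), obs_mean(auto, b))
            pairs["A_Auto_vs_B_ML"] = (obs_mean(auto, a), obs_mean(manual, b))
            pairs["A_Auto_vs_B_Auto"] = (obs_mean(auto, a), obs_mean(auto, b))
        inter_rows, per_lm_sd = [], {}
        for name, (ba_, bb_) in pairs.items():
            tab_sd, g = inter_sd(ba_, bb_)
            inter_rows.append({"comparison": name, "mean_sd_mm": g})
            per_lm_sd[name] = tab_sd.mean(axis=1)  # per-landmark mean over axes
        report["inter_observer_error"] = pd.DataFrame(inter_rows)

        if len(observers) == 2:
            # per-face error magnitudes feed Levene; per-landmark means feed paired t
            def per_face_sd(batch_a, batch_b):
                both = pd.concat([batch_a, batch_b], ignore_index=True)
                cell = both.groupby(["face_id", "landmark"])[_COORDS].std(ddof=1)
                return cell.mean(axis=1)

            sd_manual = per_face_sd(*pairs["A_ML_vs_B_ML"])
            sd_auto = per_face_sd(*pairs["A_Auto_vs_B_Auto"])
            lev_rows = []
            for lm in landmark_order:
                g1 = sd_manual.xs(lm, level="landmark").to_numpy()
                g2 = sd_auto.xs(lm, level="landmark").to_numpy()
                f, p = levene_test([g1, g2], center="median")
                lev_rows.append({"landmark": lm, "F": f, "p": p})
            report["levene_manual_vs_auto"] = pd.DataFrame(lev_rows)

            t_rows = []
            base = per_lm_sd["A_ML_vs_B_ML"].reindex(landmark_order)
            for name in ("A_ML_vs_B_Auto", "A_Auto_vs_B_ML", "A_Auto_vs_B_Auto"):
                other = per_lm_sd[name].reindex(landmark_order)
                t, p = paired_t(base.to_numpy(), other.to_numpy())
                t_rows.append({"comparison": f"A_ML_vs_B_ML minus {name}", "t": t, "p": p})
            report["paired_t_inter_observer"] = pd.DataFrame(t_rows)

    return report


def write_report(report: dict, out_dir) -> None:
    """Write every report entry as CSV plus a human-readable summary."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = [f"grand mean Euclidean error: {report['euclidean_grand_mean']:.4f} mm"]
    for key, val in report.items():
        if isinstance(val, AnovaTable):
            tab = val.table.copy()
            tab.loc[len(tab)] = ["Residuals", val.residual["Df"], val.residual["SS"],
                                 val.residual["MS"],
                                 val.residual["SS"] / val.total_ss if val.total_ss else 0.0,
                                 np.nan, np.nan]
            tab.to_csv(out / f"{key}.csv", index=False)
            lines.append(f"\n{key}:\n{val}")
        elif isinstance(val, pd.DataFrame):
            val.to_csv(out / f"{key}.csv")
            lines.append(f"\n{key}:\n{val.to_string()}")
        else:
            lines.append(f"{key}: {val}")
    (out / "summary.txt").write_text("\n".join(str(x) for x in lines) + "\n")
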