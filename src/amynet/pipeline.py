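"""End-to-end orchestration: cohort -> network selection -> per-subject
metrics -> searchlight -> cohort statistics -> report.

The mid-level helpers (:func:`cohort_metrics`, :func:`residualize_metrics`,
:func:`cohort_inference`) are the workhorses; :func:`run_pipeline` wires
them into a configurable, logged, reproducible run whose JSON report is
byte-identical for identical config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as mx
from . import network_select as ns
from . import searchlight as sl
from . import stats as st
from . import synthetic as syn
from .volumes import VolumeMap, sphere_offsets

log = logging.getLogger("amynet")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything one run depends on; echoed verbatim into the report."""

    design: syn.CohortDesign | None = None
    manifest: str | None = None
    z_threshold: float = 1.0
    log_transform: bool = True
    radius_mm: float = 6.0
    min_neighbors: int = 25
    covariate_scope: str = "per_group"
    welch: bool = False
    network_family: int | None = None  # default: number of networks
    alpha: float = 0.05
    n_subsample_draws: int = 100
    seed: int = 0
    outdir: str = "amynet_run"
    write_maps: bool = False

    def validate(self) -> None:
        if (self.design is None) == (self.manifest is None):
            raise ConfigError("provide exactly one of design / manifest")
        if self.radius_mm <= 0:
            raise ConfigError("searchlight radius must be positive")
        if self.min_neighbors < 1:
            raise ConfigError("min_neighbors must be >= 1")
        if self.z_threshold <= 0:
            raise ConfigError("z threshold must be positive")
        if self.covariate_scope not in ("pooled", "per_group"):
            raise ConfigError(f"unknown covariate scope {self.covariate_scope!r}")


# --------------------------------------------------------------------------
# per-subject metric table
# --------------------------------------------------------------------------

def cohort_metrics(subjects: list[syn.SubjectRecord], z_threshold: float = 1.0,
                   log_transform: bool = True, radius_mm: float = 6.0,
                   min_neighbors: int = 25, compute_rlocal: bool = True,
                   keep_maps: bool = False):
    """One row per subject x network with every scalar metric.

    Columns: subject_id, group, network, age, gender, neocortical_suvr,
    pib_status, n_voxels, gm_median, median_pib, conn_score, r_global,
    fisher_z and (if requested) median_rlocal plus searchlight skip tallies.
    Returns ``(DataFrame, searchlight_maps)`` where the second item maps
    ``(subject_id, network)`` to the averaged SearchlightMap when
    ``keep_maps`` is set (else it is empty).
    """
    rows = []
    maps = {}
    offsets = None
    for s in subjects:
        for name in s.network_names:
            nvs = mx.select_network_voxels(s, name, z_threshold)
            gm_median = float(np.median(s.gm_map.values[tuple(nvs.voxel_indices.T)]))
            glob = mx.r_global(nvs, log_transform=log_transform)
            row = {
                "subject_id": s.subject_id, "group": s.group, "network": name,
                "age": s.age, "gender": s.gender,
                "neocortical_suvr": s.neocortical_suvr,
                "pib_status": mx.classify_pib_status(s.neocortical_suvr),
                "n_voxels": len(nvs), "gm_median": gm_median,
                "median_pib": mx.median_network_pib(nvs),
                "conn_score": mx.network_connectivity_score(nvs),
                "r_global": glob.r_global, "fisher_z": glob.fisher_z,
            }
            if compute_rlocal:
                if offsets is None:
                    offsets = sphere_offsets(radius_mm, nvs.voxel_size_mm)
                slmap = sl.symmetric_rlocal(nvs, offsets, min_neighbors, log_transform)
                row["median_rlocal"] = sl.median_rlocal(slmap)
                row["n_rlocal_voxels"] = int(slmap.valid_mask.values.sum())
                row["n_skipped_few_neighbors"] = slmap.n_skipped_few_neighbors
                row["n_skipped_zero_variance"] = slmap.n_skipped_zero_variance
                if keep_maps:
                    maps[(s.subject_id, name)] = slmap
            rows.append(row)
    return pd.DataFrame(rows), maps


RESIDUALIZED_METRICS = ("median_pib", "fisher_z", "median_rlocal")


def residualize_metrics(df: pd.DataFrame, scope: str = "per_group",
                        metric_names=RESIDUALIZED_METRICS) -> pd.DataFrame:
    """Add ``<metric>_resid`` columns, residualizing each metric against
    gm_median / age / gender separately within each network."""
    df = df.copy()
    for name in metric_names:
        if name not in df.columns:
            continue
        out = np.full(len(df), np.nan)
        for net, sub in df.groupby("network", sort=False):
            resid, _ = mx.residualize(
                sub[name].to_numpy(float),
                sub[["gm_median", "age", "gender", "group"]],
                scope=scope, network_name=net)
            out[sub.index.to_numpy()] = resid
        df[f"{name}_resid"] = out
    return df


# --------------------------------------------------------------------------
# cohort-level statistics
# --------------------------------------------------------------------------

def _wide(df: pd.DataFrame, col: str) -> tuple[pd.DataFrame, pd.Series]:
    wide = df.pivot(index="subject_id", columns="network", values=col)
    wide = wide[list(dict.fromkeys(df["network"]))]  # keep network order
    groups = df.drop_duplicates("subject_id").set_index("subject_id")["group"]
    return wide, groups.reindex(wide.index)


def cohort_inference(df: pd.DataFrame, alpha: float = 0.05,
                     network_family: int | None = None,
                     welch: bool = False) -> dict:
    """Mixed ANOVA + per-network post-hoc tests for each residualized
    metric, one-sample tests on patient median r_LOCAL, and the
    across-subject PiB vs r_GLOBAL correlation."""
    networks = list(dict.fromkeys(df["network"]))
    fam = network_family or len(networks)
    out: dict = {"networks": networks, "alpha": alpha}

    for col in [f"{m}_resid" for m in RESIDUALIZED_METRICS]:
        if col not in df.columns:
            continue
        wide, groups = _wide(df, col)
        res = st.mixed_anova(wide, groups)
        out[f"anova_{col}"] = {
            "F_group": res.F_group, "df_group": res.df_group, "p_group": res.p_group,
            "F_network": res.F_network, "df_network": res.df_network,
            "p_network": res.p_network, "F_interaction": res.F_interaction,
            "df_interaction": res.df_interaction, "p_interaction": res.p_interaction,
        }
        per_net = {}
        for net in networks:
            sub = df[df["network"] == net]
            t = st.two_sample_t(sub.loc[sub["group"] == "patient", col],
                                sub.loc[sub["group"] == "control", col],
                                family_size=fam, welch=welch)
            per_net[net] = {"t": t.statistic, "df": t.df, "p_raw": t.p_raw,
                            "p_corrected": t.p_corrected}
        out[f"group_tests_{col}"] = per_net

    if "median_rlocal" in df.columns:
        one = {}
        for net in networks:
            sub = df[(df["network"] == net) & (df["group"] == "patient")]
            t = st.one_sample_t(sub["median_rlocal"], 0.0, family_size=fam)
            one[net] = {"t": t.statistic, "df": t.df, "p_raw": t.p_raw,
                        "p_corrected": t.p_corrected}
        out["patient_rlocal_vs_zero"] = one

    # across-subject coupling of plaque load and global correlation
    pib_r = {}
    for grp in ("patient", "control"):
        sub = df[df["group"] == grp]
        r, t = st.pib_vs_rglobal_correlation(sub["median_pib"], sub["r_global"])
        pib_r[grp] = {"pooled_r": r, "p": t.p_raw}
        per_net = {}
        for net in networks:
            s2 = sub[sub["network"] == net]
            r2, t2 = st.pib_vs_rglobal_correlation(s2["median_pib"], s2["r_global"])
            per_net[net] = {"r": r2, "p": t2.p_raw}
        pib_r[grp]["per_network"] = per_net
    out["pib_vs_rglobal"] = pib_r
    return out


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None  # strict-JSON-safe encoding of NaN/inf
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _match_networks(subjects, design) -> list[dict]:
    """Template-match the cohort-mean connectivity maps against the design's
    binarized templates (a self-check that selection recovers identity)."""
    templates = syn.make_network_templates(design)
    names = list(templates)
    mean_maps = []
    for name in names:
        stack = np.mean([s.connectivity_maps[name].values for s in subjects], axis=0)
        mean_maps.append(VolumeMap(stack, design.voxel_size_mm))
    masks = {n: VolumeMap((templates[n].values > 1.0).astype(float), design.voxel_size_mm)
             for n in names}
    matches = ns.match_components(mean_maps, masks)
    return [{"template": m.template_name, "component": names[m.component_index],
             "beta": m.beta, "rank": m.rank} for m in matches]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write tables plus a deterministic JSON report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    try:
        stage = "load-cohort"
        if config.design is not None:
            design = config.design
            if design.seed != config.seed:
                from dataclasses import replace
                design = replace(design, seed=config.seed)
            subjects = syn.generate_cohort(design)
        else:
            design = None
            subjects = syn.load_cohort(config.manifest)
        log.info("stage=%s n_subjects=%d elapsed=%.1fs", stage, len(subjects), time.time() - t0)

        selection = None
        if design is not None:
            stage = "network-selection"
            selection = _match_networks(subjects, design)
            log.info("stage=%s matches=%s", stage, selection)

        stage = "metrics+searchlight"
        df, _ = cohort_metrics(subjects, config.z_threshold, config.log_transform,
                               config.radius_mm, config.min_neighbors)
        log.info("stage=%s rows=%d skipped_few=%d skipped_flat=%d elapsed=%.1fs",
                 stage, len(df), df["n_skipped_few_neighbors"].sum(),
                 df["n_skipped_zero_variance"].sum(), time.time() - t0)

        stage = "residualize"
        df = residualize_metrics(df, scope=config.covariate_scope)

        stage = "inference"
        report_stats = cohort_inference(df, alpha=config.alpha,
                                        network_family=config.network_family,
                                        welch=config.welch)

        stage = "subsample-control"
        subsample = {}
        n_pat = df.drop_duplicates("subject_id").groupby("group").size().get("patient", 0)
        n_con = df.drop_duplicates("subject_id").groupby("group").size().get("control", 0)
        if n_pat > n_con:
            for col in [f"{m}_resid" for m in RESIDUALIZED_METRICS if f"{m}_resid" in df]:
                per_net = {}
                for net in report_stats["networks"]:
                    sub = df[df["network"] == net].rename(columns={col: "value"})
                    s = st.subsample_control(sub[["value", "group"]],
                                             n_draws=config.n_subsample_draws,
                                             seed=config.seed)
                    per_net[net] = s.fraction_significant
                subsample[col] = per_net

        stage = "write-outputs"
        metrics_path = outdir / "metrics.csv"
        df.to_csv(metrics_path, index=False, float_format="%.10g")
        # outdir is where the report lives, not part of what it computed:
        # excluding it keeps identical runs byte-identical across locations
        cfg_echo = {k: v for k, v in asdict(config).items()
                    if k not in ("design", "outdir")}
        cfg_echo["design"] = _jsonable(asdict(config.design)) if config.design else None
        report = {
            "config": _jsonable(cfg_echo),
            "n_subjects": len(subjects),
            "network_selection": selection,
            "statistics": _jsonable(report_stats),
            "subsample_control": _jsonable(subsample),
            "significant_group_effects": {
                k.removeprefix("anova_"): report_stats[k]["p_group"] < config.alpha
                for k in report_stats if k.startswith("anova_")
            },
            "outputs": {"metrics.csv": _sha256(metrics_path)},
        }
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        log.info("stage=done elapsed=%.1fs report=%s", time.time() - t0, report_path)
        return report
    except Exception as exc:
        log.exception("pipeline aborted at stage=%s", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
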