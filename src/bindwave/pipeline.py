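"""Config-driven orchestration of the full sensor-to-source analysis.

Stages: simulate -> preprocess -> behavior -> tfr -> dics -> cluster ->
lcmv -> xcorr.  Every tunable (regularization, bin width, top fraction,
DBSCAN epsilon factor, significance levels, band definitions, TOIs, seeds)
lives in the config; defaults are the analysis constants of the underlying
protocol (Morlet width 5; theta 4-7, alpha 8-12, beta 13-30 Hz; TOIs
post-S1 [-2500,-1500), pre-S2 [-1000,0), post-S2 [0,1000) ms; top fraction
0.01; DBSCAN minPts 2, eps 1.5x grid spacing).  A run is deterministic
given its seed and writes TSV tables, a metrics JSON and a provenance log
into its output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import behavior as bh
from . import experiments
from .cluster import dbscan_clusters, select_top_voxels
from .epochs import CONDITIONS, EpochSet, bandpass_notch, reject_epochs
from .headmodel import build_grid, fibonacci_sensors, octant_labels, spherical_leadfield
from .source_dics import (
    SourcePowerMap,
    csd,
    dics_filters,
    neural_activity_index,
    power_ratio,
    source_power,
)
from .source_lcmv import (
    cluster_timeseries,
    covariance,
    interaction_course,
    lcmv_filters,
    stack_participants,
)
from .synthdata import BehaviorSimParams, EEGSimParams, SourceSpec, generate_behavior, generate_eeg
from .tfr import band_power, fr_vs_fa_ttests, morlet_tfr, _binned
from .xcorr import fdr_threshold, timewise_correlation

logger = logging.getLogger("bindwave")

STAGES = ("simulate", "preprocess", "behavior", "tfr", "dics", "cluster", "lcmv", "xcorr")

FR_CONDITIONS = {"RR": "RRFR", "RA": "RAFR"}
FA_CONDITIONS = {"RR": "RRFA", "RA": "RAFA"}


class StageDependencyError(RuntimeError):
    """A stage was asked to run before its inputs exist."""


def _from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class BehaviorConfig:
    n_hc: int = 62
    n_gts: int = 54
    trials_per_condition: int = 24
    base_rt_ms: float = 480.0
    binding_cost_ms: float = 35.0
    rt_sd_ms: float = 100.0
    error_base: float = 0.05
    error_binding_cost: float = 0.09
    s1_accuracy: float = 0.95


@dataclass(frozen=True)
class EEGConfig:
    n_hc: int = 12
    n_gts: int = 12
    n_channels: int = 60
    sensor_radius_m: float = 0.09
    grid_radius_m: float = 0.07
    grid_spacing_m: float = 0.005
    conductivity: float = 0.33
    trials_per_condition: int = 24
    noise_sd_uv: float = 1.0
    coupling_rho: float = 0.6
    amp_cv_participant: float = 0.25
    amp_cv_trial: float = 0.1
    sfreq: float = 256.0
    epoch_window_ms: tuple = (-7000.0, 2000.0)
    sources: tuple = (
        {
            "position": [0.02, 0.02, 0.03],
            "band": "theta",
            "amplitudes": {
                "post_s1": {"all": 30.0},
                "pre_s2": {"all": 30.0},
                "post_s2": {"RAFR": 45.0, "all": 30.0},
            },
        },
    )


@dataclass(frozen=True)
class TFRConfig:
    width: float = 5.0
    bands: dict = field(
        default_factory=lambda: {"theta": (4.0, 7.0), "alpha": (8.0, 12.0), "beta": (13.0, 30.0)}
    )
    freq_step_hz: float = 1.0
    bin_ms: float = 50.0
    window_ms: tuple = (0.0, 1000.0)
    alpha: float = 0.05
    decim: int = 4


@dataclass(frozen=True)
class SourceConfig:
    lam: float = 0.05
    tois_ms: dict = field(
        default_factory=lambda: {
            "post_s1": (-2500.0, -1500.0),
            "pre_s2": (-1000.0, 0.0),
            "post_s2": (0.0, 1000.0),
        }
    )


@dataclass(frozen=True)
class ClusterConfig:
    fraction: float = 0.01
    min_points: int = 2
    eps_factor: float = 1.5
    exclude_labels: tuple = ("inferior-posterior",)


@dataclass(frozen=True)
class XCorrConfig:
    alpha: float = 0.01
    alpha_secondary: float = 0.05


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    stages: tuple = STAGES
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    eeg: EEGConfig = field(default_factory=EEGConfig)
    tfr: TFRConfig = field(default_factory=TFRConfig)
    source: SourceConfig = field(default_factory=SourceConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    xcorr: XCorrConfig = field(default_factory=XCorrConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sub = {
            "behavior": BehaviorConfig,
            "eeg": EEGConfig,
            "tfr": TFRConfig,
            "source": SourceConfig,
            "cluster": ClusterConfig,
            "xcorr": XCorrConfig,
        }
        kwargs = {}
        for key, klass in sub.items():
            if key in data:
                kwargs[key] = _from_dict(klass, data.pop(key))
        for key in ("seed", "stages"):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise ValueError(f"unknown config keys: {sorted(data)}")
        bad = set(kwargs.get("stages", ())) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


class PipelineRun:
    """Stateful execution of the configured stages into a run directory."""

    def __init__(self, config: PipelineConfig, out_dir):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.metrics: dict = {}
        self._forward = None

    # ---------------- infrastructure ----------------

    def _require(self, stage: str, *paths):
        for p in paths:
            if not (self.out / p).exists():
                raise StageDependencyError(
                    f"stage '{stage}' needs missing input '{p}'; run its upstream stage first"
                )

    def _participants(self):
        cfg = self.config.eeg
        return [(f"HC{i + 1:03d}", "HC") for i in range(cfg.n_hc)] + [
            (f"GTS{i + 1:03d}", "GTS") for i in range(cfg.n_gts)
        ]

    def forward_model(self):
        """Sensors, grid (with octant labels) and lead field from the config."""
        if self._forward is None:
            cfg = self.config.eeg
            sensors = fibonacci_sensors(cfg.n_channels, radius=cfg.sensor_radius_m)
            grid = octant_labels(build_grid(cfg.grid_radius_m, cfg.grid_spacing_m))
            lf = spherical_leadfield(grid, sensors, conductivity=cfg.conductivity)
            self._forward = (sensors, grid, lf)
        return self._forward

    def _source_specs(self, grid):
        specs = []
        for raw in self.config.eeg.sources:
            raw = dict(raw)
            if "position" in raw:
                pos = np.asarray(raw.pop("position"), dtype=float)
                raw["voxel"] = int(
                    np.argmin(np.linalg.norm(grid.positions - pos[None, :], axis=1))
                )
            raw["amplitudes"] = {
                per: dict(amp) for per, amp in raw.get("amplitudes", {}).items()
            }
            specs.append(SourceSpec(**raw))
        return tuple(specs)

    def _epoch_path(self, pid: str) -> Path:
        return self.out / "epochs" / f"{pid}.h5"

    def _load_epochs(self, pid: str) -> EpochSet:
        return EpochSet.load(self._epoch_path(pid))

    # ---------------- stages ----------------

    def simulate(self):
        cfg = self.config
        logger.info("simulate: behavioral tables")
        tables = []
        for group, n in (("HC", cfg.behavior.n_hc), ("GTS", cfg.behavior.n_gts)):
            params = BehaviorSimParams(
                n_participants=n,
                trials_per_condition=cfg.behavior.trials_per_condition,
                base_rt_ms=cfg.behavior.base_rt_ms,
                binding_cost_ms=cfg.behavior.binding_cost_ms,
                rt_sd_ms=cfg.behavior.rt_sd_ms,
                error_base=cfg.behavior.error_base,
                error_binding_cost=cfg.behavior.error_binding_cost,
                s1_accuracy=cfg.behavior.s1_accuracy,
                seed=cfg.seed + (0 if group == "HC" else 1),
            )
            tables.append(generate_behavior(params, group=group))
        behavior_table = pd.concat(tables, ignore_index=True)
        behavior_table.to_csv(self.out / "behavior.tsv", sep="\t", index=False)

        logger.info("simulate: forward-modelled EEG")
        _, grid, lf = self.forward_model()
        specs = self._source_specs(grid)
        (self.out / "epochs").mkdir(exist_ok=True)
        truths = []
        for k, (pid, group) in enumerate(self._participants()):
            params = EEGSimParams(
                sources=specs,
                trials_per_condition=cfg.eeg.trials_per_condition,
                coupling_rho=cfg.eeg.coupling_rho,
                amp_cv_participant=cfg.eeg.amp_cv_participant,
                amp_cv_trial=cfg.eeg.amp_cv_trial,
                noise_sd_uv=cfg.eeg.noise_sd_uv,
                sfreq=cfg.eeg.sfreq,
                epoch_window_ms=tuple(cfg.eeg.epoch_window_ms),
                seed=cfg.seed * 100003 + 7 * k + 13,
            )
            epochs, truth = generate_eeg(params, lf, participant=pid, group=group)
            epochs.save(self._epoch_path(pid))
            truth.insert(0, "participant", pid)
            truths.append(truth)
        pd.concat(truths, ignore_index=True).to_csv(
            self.out / "simulation_truth.tsv", sep="\t", index=False
        )
        grid_df = pd.DataFrame(grid.positions, columns=["x", "y", "z"])
        grid_df["region"] = grid.region_labels
        grid_df.to_csv(self.out / "source_grid.tsv", sep="\t", index=False)
        self.metrics["simulate"] = {
            "n_participants": len(self._participants()),
            "n_voxels": grid.n_voxels,
            "source_voxels": [int(s.voxel) for s in specs],
        }

    def preprocess(self, apply_filter: bool = False):
        self._require("preprocess", "epochs")
        reports = []
        for pid, _ in self._participants():
            ep = self._load_epochs(pid)
            if apply_filter:
                ep = bandpass_notch(ep)
            ep, report = reject_epochs(ep)
            ep.save(self._epoch_path(pid))
            report.insert(0, "participant", pid)
            reports.append(report)
        report = pd.concat(reports, ignore_index=True)
        report.to_csv(self.out / "rejection_report.tsv", sep="\t", index=False)
        self.metrics["preprocess"] = {
            "n_trials_kept": int(report["kept"].sum()),
            "n_trials_rejected": int((~report["kept"]).sum()),
        }

    def behavior(self):
        self._require("behavior", "behavior.tsv")
        table = pd.read_csv(self.out / "behavior.tsv", sep="\t")
        filtered, filter_report = bh.filter_trials(table)
        filter_report.to_csv(self.out / "trial_filter_report.tsv", sep="\t", index=False)
        binding = bh.participant_binding(filtered)
        binding.to_csv(self.out / "binding_scores.tsv", sep="\t", index=False)

        stats: dict = {}
        for measure in ("rt", "err"):
            col = f"{measure}_binding"
            per_group = {}
            for group, sub in binding.groupby("group"):
                x = sub[col].dropna()
                t, df, dz, p = bh.one_sample_t_data(x)
                per_group[group] = {
                    "mean": float(x.mean()),
                    "sd": float(x.std(ddof=1)),
                    "n": int(x.size),
                    "t": t,
                    "df": df,
                    "dz": dz,
                    "p": p,
                }
            g1, g2 = sorted(per_group)
            a, b = per_group[g1], per_group[g2]
            wt, wdf, wp = bh.welch_t(a["mean"], a["sd"], a["n"], b["mean"], b["sd"], b["n"])
            anova_in = binding.rename(
                columns={f"{measure}_{c}": c for c in CONDITIONS}
            )[["participant", "group", *CONDITIONS]]
            anova = bh.mixed_anova_2x2x2(anova_in)
            anova.to_csv(self.out / f"anova_{measure}.tsv", sep="\t", index=False)
            stats[measure] = {
                "one_sample": per_group,
                "welch": {"t": wt, "df": wdf, "p": wp, "groups": [g1, g2]},
                "anova": anova.set_index("effect")[["F", "p", "ges"]].to_dict("index"),
            }
        _write_json(self.out / "behavior_stats.json", stats)
        self.metrics["behavior"] = {
            m: {g: {"t": v["t"], "dz": v["dz"]} for g, v in stats[m]["one_sample"].items()}
            for m in stats
        }

    def _band_freqs(self, band_name: str) -> np.ndarray:
        lo, hi = self.config.tfr.bands[band_name]
        return np.arange(lo, hi + 1e-9, self.config.tfr.freq_step_hz)

    def tfr(self):
        self._require("tfr", "epochs")
        cfg = self.config.tfr
        groups: dict = {}
        for pid, group in self._participants():
            ep = self._load_epochs(pid)
            for band_name in cfg.bands:
                tfr = morlet_tfr(ep, self._band_freqs(band_name), width=cfg.width, decim=cfg.decim)
                lo, hi = self.config.tfr.bands[band_name]
                fmask = (tfr.freqs >= lo) & (tfr.freqs <= hi)
                for resp in ("RR", "RA"):
                    entry = {}
                    for tag, cond in (("FR", FR_CONDITIONS[resp]), ("FA", FA_CONDITIONS[resp])):
                        sel = ep.conditions == cond
                        if not sel.any():
                            continue
                        p = tfr.power[sel][:, :, fmask].mean(axis=(0, 2))  # (ch, times)
                        binned, starts = _binned(p, tfr.times, cfg.window_ms, cfg.bin_ms)
                        entry[tag] = binned
                    if len(entry) == 2:
                        key = (group, band_name, resp)
                        groups.setdefault(key, {"FR": [], "FA": []})
                        groups[key]["FR"].append(entry["FR"])
                        groups[key]["FA"].append(entry["FA"])
                        bin_starts = starts
        ch_names = self._load_epochs(self._participants()[0][0]).ch_names
        frames = []
        n_sig = {}
        for (group, band_name, resp), acc in sorted(groups.items()):
            res = fr_vs_fa_ttests(
                np.stack(acc["FR"]), np.stack(acc["FA"]), ch_names, bin_starts, alpha=cfg.alpha
            )
            res.insert(0, "group", group)
            res.insert(1, "band", band_name)
            res.insert(2, "response", resp)
            frames.append(res)
            n_sig[f"{group}_{band_name}_{resp}"] = int(res["significant"].sum())
        contrast = pd.concat(frames, ignore_index=True)
        contrast.to_csv(self.out / "sensor_contrast.tsv", sep="\t", index=False)
        self.metrics["tfr"] = {"n_significant_cells": n_sig}

    def dics(self):
        self._require("dics", "epochs")
        scfg = self.config.source
        _, grid, lf = self.forward_model()
        bands = self.config.tfr.bands
        maps_acc: dict = {}

        def acc(key, values):
            maps_acc.setdefault(key, []).append(values)

        for pid, group in self._participants():
            ep = self._load_epochs(pid)
            for band_name, band in bands.items():
                for toi_name in ("post_s1", "pre_s2"):
                    c = csd(ep, band, scfg.tois_ms[toi_name])
                    filt = dics_filters(c, lf, lam=scfg.lam)
                    acc((band_name, toi_name, "nai"), neural_activity_index(filt, c).values)
                c_common = csd(ep, band, scfg.tois_ms["post_s2"])
                filt = dics_filters(c_common, lf, lam=scfg.lam)
                for resp in ("RR", "RA"):
                    ep_fr = ep.select(FR_CONDITIONS[resp])
                    ep_fa = ep.select(FA_CONDITIONS[resp])
                    if not (ep_fr.n_trials and ep_fa.n_trials):
                        continue
                    p_fr = source_power(filt, csd(ep_fr, band, scfg.tois_ms["post_s2"]))
                    p_fa = source_power(filt, csd(ep_fa, band, scfg.tois_ms["post_s2"]))
                    acc((band_name, "post_s2", resp), power_ratio(p_fr, p_fa).values)

        (self.out / "dics").mkdir(exist_ok=True)
        for (band_name, toi_name, tag), values in sorted(maps_acc.items()):
            mean_map = np.mean(values, axis=0)
            df = pd.DataFrame(grid.positions, columns=["x", "y", "z"])
            df.insert(0, "voxel", np.arange(grid.n_voxels))
            df["value"] = mean_map
            df.to_csv(self.out / "dics" / f"{band_name}_{toi_name}_{tag}.tsv", sep="\t", index=False)
        self.metrics["dics"] = {"n_maps": len(maps_acc), "lam": scfg.lam}

    def cluster(self):
        self._require("cluster", "dics", "source_grid.tsv")
        ccfg = self.config.cluster
        _, grid, _ = self.forward_model()
        summaries = []
        memberships = []
        for path in sorted((self.out / "dics").glob("*.tsv")):
            df = pd.read_csv(path, sep="\t")
            values = df["value"].to_numpy()
            kind = "nai" if path.stem.endswith("_nai") else "ratio"
            smap = SourcePowerMap(values, df["voxel"].to_numpy(), None, None, kind)
            mode = "two_sided" if kind == "ratio" else "signed"
            sel = select_top_voxels(
                smap, grid.region_labels, ccfg.fraction, ccfg.exclude_labels, mode=mode
            )
            cs = dbscan_clusters(
                sel, grid, eps_factor=ccfg.eps_factor, min_points=ccfg.min_points
            )
            summary = cs.summary(values[cs.voxel_indices])
            summary.insert(0, "map", path.stem)
            summaries.append(summary)
            for cid in cs.cluster_ids:
                for vox in cs.members(cid):
                    memberships.append({"map": path.stem, "cluster": int(cid), "voxel": int(vox)})
        if summaries:
            pd.concat(summaries, ignore_index=True).to_csv(
                self.out / "clusters_summary.tsv", sep="\t", index=False
            )
        pd.DataFrame(memberships, columns=["map", "cluster", "voxel"]).to_csv(
            self.out / "clusters_members.tsv", sep="\t", index=False
        )
        self.metrics["cluster"] = {
            "n_clusters_per_map": pd.DataFrame(memberships).groupby("map")["cluster"]
            .nunique()
            .to_dict()
            if memberships
            else {}
        }

    def lcmv(self):
        self._require("lcmv", "clusters_members.tsv", "epochs")
        members = pd.read_csv(self.out / "clusters_members.tsv", sep="\t")
        if members.empty:
            raise StageDependencyError("stage 'lcmv': no clusters found upstream")
        scfg = self.config.source
        _, grid, lf = self.forward_model()
        (self.out / "lcmv").mkdir(exist_ok=True)
        self._courses: dict = {}
        for map_name, msub in members.groupby("map"):
            band_name, toi_name = map_name.split("_")[0], "_".join(map_name.split("_")[1:3])
            toi = scfg.tois_ms[toi_name]
            band = self.config.tfr.bands[band_name]
            resp = map_name.split("_")[-1] if map_name.split("_")[-1] in ("RR", "RA") else None
            for cid, csub in msub.groupby("cluster"):
                voxels = csub["voxel"].to_numpy()
                per_part: dict = {}
                for pid, group in self._participants():
                    ep = self._load_epochs(pid)
                    cov = covariance(ep, toi)
                    filt = lcmv_filters(cov, lf, lam=scfg.lam, voxels=voxels)
                    if resp is None:
                        cts = cluster_timeseries(
                            filt, ep, voxels, band, toi, width=self.config.tfr.width,
                            decim=self.config.tfr.decim,
                        )
                    else:
                        parts = {}
                        for tag, cond in (
                            ("FR", FR_CONDITIONS[resp]),
                            ("FA", FA_CONDITIONS[resp]),
                        ):
                            parts[tag] = cluster_timeseries(
                                filt, ep.select(cond), voxels, band, toi,
                                width=self.config.tfr.width, decim=self.config.tfr.decim,
                            )
                        cts = interaction_course(parts["FR"], parts["FA"])
                    per_part.setdefault(group, []).append(cts)
                for group, courses in per_part.items():
                    key = (map_name, int(cid), group)
                    stacked = stack_participants(courses)
                    self._courses[key] = stacked
                    out = pd.DataFrame(stacked.power, columns=[f"t{t:.1f}" for t in stacked.times])
                    out.insert(0, "participant", list(stacked.participants))
                    out.to_csv(
                        self.out / "lcmv" / f"{map_name}_c{cid}_{group}.tsv",
                        sep="\t",
                        index=False,
                    )
        self.metrics["lcmv"] = {"n_courses": len(self._courses)}

    def xcorr(self):
        self._require("xcorr", "lcmv")
        xcfg = self.config.xcorr
        courses = getattr(self, "_courses", None)
        if courses is None:
            courses = self._load_courses()
        pre_keys = [k for k in courses if "_post_s1_" in k[0] or "_pre_s2_" in k[0]]
        post_keys = [k for k in courses if "_post_s2_" in k[0]]
        if not pre_keys or not post_keys:
            raise StageDependencyError("stage 'xcorr': need both pre- and post-trial clusters")
        (self.out / "xcorr").mkdir(exist_ok=True)
        summary = []
        for pre_k in sorted(pre_keys):
            for post_k in sorted(post_keys):
                if pre_k[2] != post_k[2]:  # same group only
                    continue
                pre, post = courses[pre_k], courses[post_k]
                if pre.power.shape[0] != post.power.shape[0] or pre.power.shape[0] < 4:
                    continue
                pair = f"{pre_k[0]}_c{pre_k[1]}__{post_k[0]}_c{post_k[1]}__{pre_k[2]}"
                corr = timewise_correlation(pre, post, pair=pair)
                mask = fdr_threshold(corr, xcfg.alpha)
                mask2 = fdr_threshold(corr, xcfg.alpha_secondary)
                pd.DataFrame(corr.r).to_csv(self.out / "xcorr" / f"{pair}_r.tsv", sep="\t", index=False)
                pd.DataFrame(corr.q).to_csv(self.out / "xcorr" / f"{pair}_q.tsv", sep="\t", index=False)
                summary.append(
                    {
                        "pair": pair,
                        "group": pre_k[2],
                        "n": corr.n,
                        "r_max": float(np.nanmax(corr.r)),
                        "r_min": float(np.nanmin(corr.r)),
                        "n_significant_q01": int(mask.sum()),
                        "n_significant_q05": int(mask2.sum()),
                        "n_cells": int(np.isfinite(corr.r).sum()),
                    }
                )
        summary_df = pd.DataFrame(summary)
        summary_df.to_csv(self.out / "xcorr_summary.tsv", sep="\t", index=False)
        self.metrics["xcorr"] = {
            "n_pairs": len(summary),
            "n_pairs_with_q01_block": int((summary_df["n_significant_q01"] > 0).sum())
            if len(summary)
            else 0,
        }

    def _load_courses(self) -> dict:
        courses = {}
        from .source_lcmv import ClusterTimeSeries

        for path in sorted((self.out / "lcmv").glob("*.tsv")):
            df = pd.read_csv(path, sep="\t")
            stem = path.stem
            map_name, rest = stem.rsplit("_c", 1)
            cid, group = rest.split("_", 1)
            times = np.array([float(c[1:]) for c in df.columns[1:]])
            toi_name = "post_s2" if "_post_s2" in map_name else (
                "post_s1" if "_post_s1" in map_name else "pre_s2"
            )
            band_name = map_name.split("_")[0]
            courses[(map_name, int(cid), group)] = ClusterTimeSeries(
                df.iloc[:, 1:].to_numpy(float),
                times,
                tuple(self.config.tfr.bands[band_name]),
                tuple(self.config.source.tois_ms[toi_name]),
                participants=tuple(df["participant"]),
            )
        return courses

    # ---------------- driver ----------------

    def run(self) -> Path:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO)
        log_path = self.out / "provenance.json"
        for stage in STAGES:
            if stage not in self.config.stages:
                continue
            logger.info("running stage %s", stage)
            try:
                getattr(self, stage)()
            except StageDependencyError:
                raise
            except Exception as err:
                _write_json(self.out / "metrics.json", self.metrics)
                raise RuntimeError(f"stage '{stage}' failed: {err}") from err
        _write_json(self.out / "metrics.json", self.metrics)
        _write_json(
            log_path,
            {
                "config": self.config.to_dict(),
                "config_hash": _config_hash(self.config),
                "package_version": __version__,
                "numpy_version": np.__version__,
                "stages_run": [s for s in STAGES if s in self.config.stages],
            },
        )
        return self.out


def run(config: PipelineConfig, out_dir) -> Path:
    """Execute the configured stages; returns the run directory."""
    return PipelineRun(config, out_dir).run()


# Reference cohort summary statistics bundled for verification: group sizes,
# binding-score means/SDs, and demographic 2x2 counts with the test values
# they imply.
REFERENCE_COHORT = {
    "one_sample": {
        "rt_hc": {"mean": 58.14, "sd": 92.31, "n": 62, "t": 4.96, "dz": 0.63},
        "rt_gts": {"mean": 70.93, "sd": 85.56, "n": 54, "t": 6.09, "dz": 0.83},
        "err_hc": {"mean": 18.06, "sd": 17.36, "n": 62, "t": 8.19, "dz": 1.04},
        "err_gts": {"mean": 21.48, "sd": 17.16, "n": 54, "t": 9.20, "dz": 1.25},
    },
    "chi2": {
        "sex": {"table": (35, 19, 37, 25), "chi2": 0.14},
        "handedness": {"table": (46, 7, 56, 6), "chi2": 0.09},
        "comorbidity": {"table": (15, 38, 2, 60), "chi2": 12.34},
    },
}


def verify(seed: int = 0, fast: bool = True) -> pd.DataFrame:
    """Recompute the bundled reference statistics and run reduced property
    suites; returns a pass/fail table.

    ``fast`` shrinks the stochastic suites (fewer seeds/replicates) for an
    interactive check; the full-size versions live in the acceptance script.
    """
    rows = []

    def add(name, value, target, ok):
        rows.append({"check": name, "value": value, "target": target, "passed": bool(ok)})

    for key, ref in REFERENCE_COHORT["one_sample"].items():
        t, _, dz = bh.one_sample_t(ref["mean"], ref["sd"], ref["n"])
        add(f"one_sample_t_{key}", round(t, 2), ref["t"], round(t, 2) == ref["t"])
        add(f"dz_{key}", round(dz, 2), ref["dz"], round(dz, 2) == ref["dz"])
    for key, ref in REFERENCE_COHORT["chi2"].items():
        chi2, _ = bh.chi2_2x2(*ref["table"], continuity=True)
        add(f"chi2_{key}", round(chi2, 2), ref["chi2"], round(chi2, 2) == ref["chi2"])

    n_loc = 20 if fast else 100
    loc = experiments.dics_localization(n_seeds=n_loc, seed=seed)
    add("dics_localization_rate", loc["success_rate"], ">=0.95", loc["success_rate"] >= 0.95)
    rec = experiments.xcorr_recovery(seed=seed)
    add("xcorr_recovered_rho", rec["mean_r"], f"[{rec['ci_low']:.3f}, {rec['ci_high']:.3f}]", rec["in_ci"])
    bhres = experiments.bh_oracle_check(n_vectors=200 if fast else 1000, seed=seed)
    add("bh_oracle_max_diff", bhres["max_abs_diff"], "<=1e-12", bhres["max_abs_diff"] <= 1e-12)
    db = experiments.dbscan_oracle_check(n_sets=10 if fast else 50, seed=seed)
    add("dbscan_oracle_agreement", db["agreement_rate"], "==1.0", db["agreement_rate"] == 1.0)
    an = experiments.anova_oracle_check(seed=seed)
    add("anova_ss_max_diff", an["max_abs_ss_diff"], "<=1e-8", an["max_abs_ss_diff"] <= 1e-8)
    cal = experiments.null_calibration(n_replicates=50 if fast else 200, seed=seed)
    add(
        "null_raw_false_positive_rate",
        cal["raw_false_positive_rate"],
        "~0.05",
        abs(cal["raw_false_positive_rate"] - 0.05) < 0.02,
    )
    return pd.DataFrame(rows)
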