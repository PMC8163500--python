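"""End-to-end orchestration of the synthetic dichotic-listening experiment.

``run_experiment`` drives the full chain — stimulus generation, neural
simulation, tag-aligned segmentation, ITPC spectra and FOI statistics,
condition and ROI permutation tests, TRF estimation with cross-validated
hyperparameters, predictive-power null, TRF cluster comparison, and
behavioral statistics — and writes a directory of TSV tables plus one
plain-text summary.  A single master seed deterministically derives every
stage seed, so a run is bit-reproducible from its configuration alone.
"""

from __future__ import annotations

import contextlib
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, neurosim, permstats, spectral, trf
from .neurosim import NONSTRUCTURED, STRUCTURED, SimConfig

__all__ = ["RunConfig", "RunReport", "run_experiment", "make_fixtures",
           "default_roi_map", "PipelineStageError"]


def default_roi_map(n_channels: int, channels_per_roi: int = 2) -> dict:
    """Label channel groups as left/right-hemisphere ROIs.

    The first half of the channels is 'left', the second 'right'; each ROI
    is a contiguous group.  Stands in for the anatomical parcellation used
    with real source-level data.
    """
    half = n_channels // 2
    rois = {}
    for hemi, start in (("L", 0), ("R", half)):
        for k in range(half // channels_per_roi):
            lo = start + k * channels_per_roi
            rois[f"{hemi}{k}"] = list(range(lo, lo + channels_per_roi))
    return rois


@dataclass
class RunConfig:
    """Everything needed to reproduce one full run."""

    sim: SimConfig = field(default_factory=SimConfig)
    n_perm: int = 1000
    trf_lags: tuple = (-0.050, 0.400)
    cv_grid_tolerance: tuple = (1.0, 0.95)
    cv_grid_sparseness: tuple = (0.0,)
    run_cv: bool = True
    run_power_null: bool = True
    power_null_n_perm: int = 200
    channels_per_roi: int = 2
    behavior_accuracy_mean: float = 0.715
    behavior_accuracy_sd: float = 0.15
    master_seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        h = np.frombuffer(stage.encode(), dtype=np.uint8).astype(np.int64)
        mix = int((np.sum(h * np.arange(1, h.size + 1)) * 2654435761) % (2**31))
        return int(np.random.default_rng([self.master_seed, mix]).integers(2**31))

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["sim"].pop("trf_kernel_true")
        d["sim"].pop("trf_lags")
        for key in ("phrase_channels", "trf_gain_channels", "trf_gain_window"):
            d["sim"][key] = list(d["sim"][key])
        for key in ("trf_lags", "cv_grid_tolerance", "cv_grid_sparseness"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in d.pop("sim").items()})
        return cls(sim=sim, **{k: tuple(v) if isinstance(v, list) else v
                               for k, v in d.items()})


@dataclass
class RunReport:
    config: RunConfig
    spectra: pd.DataFrame  # participant, condition, channel_set, freq_hz, z
    foi_tests: pd.DataFrame
    condition_tests: pd.DataFrame
    roi_results: dict  # hemisphere -> RoiPermutationResult
    roi_table: pd.DataFrame
    trf_cluster: permstats.ClusterResult
    roi_trf_cluster: permstats.ClusterResult
    cv_table: pd.DataFrame | None
    selected_hp: trf.TRFHyperParams
    power_null: permstats.PermutationResult | None
    behavior_table: pd.DataFrame
    behavior_stats: dict
    seeds: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "run_config.yaml")
        self.spectra.to_csv(out / "itpc_spectra.tsv", sep="\t", index=False)
        self.foi_tests.to_csv(out / "foi_tests.tsv", sep="\t", index=False)
        self.condition_tests.to_csv(out / "condition_tests.tsv", sep="\t",
                                    index=False)
        self.roi_table.to_csv(out / "roi_tests.tsv", sep="\t", index=False)
        if self.cv_table is not None:
            self.cv_table.to_csv(out / "trf_cv.tsv", sep="\t", index=False)
        rows = [{"cluster": i, "mass": c["mass"], "corrected_p": c["corrected_p"],
                 "n_points": len(c["members"])}
                for i, c in enumerate(self.trf_cluster.clusters)]
        pd.DataFrame(rows, columns=["cluster", "mass", "corrected_p",
                                    "n_points"]).to_csv(
            out / "trf_clusters.tsv", sep="\t", index=False)
        self.behavior_table.to_csv(out / "behavior_accuracy.tsv", sep="\t")
        (out / "summary.txt").write_text(self.summary())

    def summary(self) -> str:
        lines = [f"master_seed\t{self.config.master_seed}"]
        for _, row in self.foi_tests.iterrows():
            lines.append(f"foi\t{row.condition}\t{row.foi}Hz\t"
                         f"t={row.t_stat:.3f}\tp={row.p:.4g}\td={row.cohen_d:.3f}")
        for _, row in self.condition_tests.iterrows():
            lines.append(f"condition_test\t{row.foi}Hz\tt={row.observed_t:.3f}"
                         f"\tp={row.p:.4g}")
        for hemi, res in self.roi_results.items():
            lines.append(f"roi_global\t{hemi}\tstat={res.global_stat:.3f}"
                         f"\tp={res.global_p:.4g}")
        sig = self.trf_cluster.significant()
        lines.append(f"trf_clusters_significant\t{len(sig)}")
        if self.power_null is not None:
            lines.append(f"predictive_power\tr={self.power_null.observed_stat:.4f}"
                         f"\tp={self.power_null.p:.4g}")
        b = self.behavior_stats
        lines.append(f"behavior_vs_chance\tt({b['df']})={b['t_vs_chance']:.2f}"
                     f"\tp={b['p_vs_chance']:.3g}")
        lines.append(f"behavior_between_conditions\tt={b['t_between']:.2f}"
                     f"\tp={b['p_between']:.3g}")
        lines.append(f"median_split\tp={b['median_split_p']:.3g}")
        return "\n".join(lines) + "\n"


def _stage(name, seeds, cfg):
    seeds[name] = cfg.stage_seed(name)
    return seeds[name]


class PipelineStageError(RuntimeError):
    """Raised when one pipeline stage fails; names the stage."""


@contextlib.contextmanager
def _guard(stage: str):
    try:
        yield
    except PipelineStageError:
        raise
    except Exception as err:
        raise PipelineStageError(f"pipeline stage {stage!r} failed: {err}") from err


def run_experiment(cfg: RunConfig, out_dir=None) -> RunReport:
    """Run the full synthetic experiment; optionally write the report.

    Any stage failure raises :class:`PipelineStageError` naming the stage;
    results computed before the failure are preserved on the exception's
    ``__cause__`` context.
    """
    seeds: dict = {}

    with _guard("simulate"):
        sim_cfg = dataclasses.replace(cfg.sim,
                                      seed=_stage("simulate", seeds, cfg))
        recordings, truth = neurosim.simulate_experiment(sim_cfg)

    # --- ITPC spectra per participant x condition, several channel sets
    with _guard("spectral"):
        phrase_ch = list(sim_cfg.phrase_channels)
        other_ch = [c for c in range(sim_cfg.n_channels) if c not in phrase_ch]
        roi_map = default_roi_map(sim_cfg.n_channels, cfg.channels_per_roi)
        spect_rows = []
        z_all = {}  # condition -> channel_set -> (n_participants, n_freqs)
        z_sets = {"all": None, "phrase": phrase_ch, "other": other_ch}
        roi_1hz = {}  # condition -> (n_participants, n_rois), sorted-ROI order
        freqs = None
        roi_names = sorted(roi_map)
        for condition in (STRUCTURED, NONSTRUCTURED):
            per_set = {k: [] for k in z_sets}
            per_roi = []
            for pid in range(sim_cfg.n_participants):
                recs = [r for r in recordings
                        if r.participant_id == pid and r.condition == condition]
                segs = spectral.segment_trials(recs)
                spec = spectral.compute_itpc(segs)
                freqs = spec.freqs
                for set_name, chans in z_sets.items():
                    zvec = spectral.channel_average(spec, chans)
                    per_set[set_name].append(zvec)
                    for f, zz in zip(freqs, zvec):
                        spect_rows.append({"participant": pid,
                                           "condition": condition,
                                           "channel_set": set_name,
                                           "freq_hz": f, "z": zz})
                i1 = int(np.argmin(np.abs(freqs - 1.0)))
                per_roi.append([spec.z[roi_map[name], i1].mean()
                                for name in roi_names])
            z_all[condition] = {k: np.asarray(v) for k, v in per_set.items()}
            roi_1hz[condition] = np.asarray(per_roi)

    # --- FOI peak tests within condition (channel-averaged spectra)
    with _guard("foi_tests"):
        foi_rows = []
        for condition in (STRUCTURED, NONSTRUCTURED):
            for foi in spectral.FOIS:
                res = spectral.foi_peak_test(z_all[condition]["all"], freqs, foi)
                foi_rows.append({"condition": condition, "foi": foi,
                                 "t_stat": res.t_stat, "p": res.p,
                                 "cohen_d": res.cohen_d})
        foi_tests = pd.DataFrame(foi_rows)

    # --- between-condition permutation tests at each FOI (one-sided)
    with _guard("condition_tests"):
        cond_rows = []
        perm_seed = _stage("condition_perm", seeds, cfg)
        for k, foi in enumerate(spectral.FOIS):
            i = int(np.argmin(np.abs(freqs - foi)))
            res = permstats.condition_permutation_test(
                z_all[STRUCTURED]["all"][:, i],
                z_all[NONSTRUCTURED]["all"][:, i],
                n_perm=cfg.n_perm, tail="one_sided_greater", seed=perm_seed + k)
            cond_rows.append({"foi": foi, "observed_t": res.observed_stat,
                              "p": res.p, "n_perm": res.n_perm, "seed": res.seed})
        condition_tests = pd.DataFrame(cond_rows)

    # --- ROI global statistic per hemisphere at 1 Hz
    with _guard("roi_tests"):
        roi_seed = _stage("roi_perm", seeds, cfg)
        roi_results, roi_rows = {}, []
        for h, hemi in enumerate(("L", "R")):
            cols = [i for i, name in enumerate(roi_names)
                    if name.startswith(hemi)]
            res = permstats.roi_global_permutation(
                roi_1hz[STRUCTURED][:, cols], roi_1hz[NONSTRUCTURED][:, cols],
                n_perm=cfg.n_perm, seed=roi_seed + h, hemisphere=hemi)
            roi_results[hemi] = res
            for j, col in enumerate(cols):
                roi_rows.append({"hemisphere": hemi, "roi": roi_names[col],
                                 "t": res.roi_t[j],
                                 "p_uncorrected": res.roi_p[j],
                                 "suprathreshold": bool(res.suprathreshold[j]),
                                 "global_p": res.global_p})
        roi_table = pd.DataFrame(roi_rows)

    # --- TRF hyperparameters (condition-pooled), then per-participant TRFs
    with _guard("trf"):
        by_key: dict = {}
        for r in recordings:
            by_key.setdefault((r.participant_id, r.condition), []).append(r)
        cv_table, selected_hp = None, trf.TRFHyperParams()
        pooled = by_key[(0, STRUCTURED)] + by_key[(0, NONSTRUCTURED)]
        if cfg.run_cv:
            grid = [trf.TRFHyperParams(tolerance=t, sparseness=s)
                    for t in cfg.cv_grid_tolerance
                    for s in cfg.cv_grid_sparseness]
            selected_hp, cv_table = trf.jackknife_cv(
                [r.attended_envelope for r in pooled],
                [r.data for r in pooled],
                lags=cfg.trf_lags, sample_rate=sim_cfg.sample_rate, grid=grid)

        models = {}
        for condition in (STRUCTURED, NONSTRUCTURED):
            models[condition] = []
            for pid in range(sim_cfg.n_participants):
                recs = by_key[(pid, condition)]
                models[condition].append(trf.estimate_trf(
                    [r.attended_envelope for r in recs], [r.data for r in recs],
                    lags=cfg.trf_lags, sample_rate=sim_cfg.sample_rate,
                    hp=selected_hp, compute_power=False))

        power_null = None
        if cfg.run_power_null:
            power_null = trf.predictive_power_null(
                [r.attended_envelope for r in pooled],
                [r.data for r in pooled],
                hp=selected_hp, lags=cfg.trf_lags,
                sample_rate=sim_cfg.sample_rate,
                n_perm=cfg.power_null_n_perm,
                seed=_stage("power_null", seeds, cfg))

        # condition comparison: scalp clusters and ROI x window variant
        side = int(round(np.sqrt(sim_cfg.n_channels)))
        adjacency = permstats.grid_adjacency(side, sim_cfg.n_channels // side)
        trf_cluster = trf.compare_trf_conditions(
            models[STRUCTURED], models[NONSTRUCTURED], adjacency,
            n_perm=cfg.n_perm, seed=_stage("trf_cluster", seeds, cfg))
        kernels = {c: np.stack([m.kernel for m in models[c]]) for c in models}
        roi_kernels = {c: trf.roi_average_kernels(kernels[c], roi_map)
                       for c in kernels}
        roi_adj = np.ones((len(roi_names), len(roi_names)), dtype=bool)
        lags_axis = models[STRUCTURED][0].lags
        roi_trf_cluster = permstats.windowed_roi_trf_test(
            roi_kernels[STRUCTURED], roi_kernels[NONSTRUCTURED], lags_axis,
            roi_adj, n_perm=cfg.n_perm,
            seed=_stage("roi_trf_cluster", seeds, cfg))

    # --- behavior
    with _guard("behavior"):
        answers = neurosim.simulate_behavior(
            sim_cfg, cfg.behavior_accuracy_mean, cfg.behavior_accuracy_sd,
            seed=_stage("behavior", seeds, cfg))
        acc = behavior.score_accuracy(answers)
        t_c, df_c, p_c = behavior.test_vs_chance(acc[STRUCTURED])
        t_b, _, p_b = behavior.paired_condition_test(acc[STRUCTURED],
                                                     acc[NONSTRUCTURED])
        i1 = int(np.argmin(np.abs(freqs - 1.0)))
        itpc_1hz = pd.Series(z_all[STRUCTURED]["all"][:, i1], index=acc.index)
        split = behavior.median_split_by_neural(acc, itpc_1hz)
        behavior_stats = {"t_vs_chance": t_c, "df": df_c, "p_vs_chance": p_c,
                          "t_between": t_b, "p_between": p_b,
                          "median_split_p": split.p,
                          "median_split_p_diff": split.p_diff}

    report = RunReport(config=cfg, spectra=pd.DataFrame(spect_rows),
                       foi_tests=foi_tests, condition_tests=condition_tests,
                       roi_results=roi_results, roi_table=roi_table,
                       trf_cluster=trf_cluster, roi_trf_cluster=roi_trf_cluster,
                       cv_table=cv_table, selected_hp=selected_hp,
                       power_null=power_null, behavior_table=acc,
                       behavior_stats=behavior_stats, seeds=seeds)
    if out_dir is not None:
        report.write(out_dir)
    return report


def make_fixtures(size: str = "tiny") -> RunConfig:
    """Preset run configurations.

    ``tiny``: 6 participants, 4 trials/condition, 16-channel grid,
    200 permutations — a full pipeline exercise in well under five
    minutes.  ``default``: published-study scale (29 participants,
    15 trials per condition).
    """
    if size == "tiny":
        return RunConfig(
            sim=SimConfig(n_participants=6, n_trials_per_condition=4,
                          n_channels=16),
            n_perm=200, power_null_n_perm=50)
    if size == "default":
        return RunConfig(
            sim=SimConfig(n_participants=29, n_trials_per_condition=15,
                          n_channels=16),
            n_perm=1000, power_null_n_perm=200)
    raise ValueError(f"unknown fixture size {size!r}")
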