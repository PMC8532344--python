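"""End-to-end synthetic pipelines and their configuration.

``run_pipeline`` chains the stages into the two experiment arms:

* in vivo  — simulate two genotype groups of spontaneous PC recordings and a
  SEP session per genotype; compute per-neuron firing statistics, detect SEP
  components, and report estimation statistics (mean difference with BCa CI)
  per metric.
* ex vivo  — simulate patch-clamp cell populations and morphology
  populations; recover rheobase, f-I slope, passive properties, apical
  length and spine density, with group comparisons.

Everything derives from one master seed (split per stage); re-running with
an identical config reproduces the summary byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import conditions as cond
from . import evoked, intrinsic, morphology, recovery, spiketrain
from . import stats as _stats
from . import synthgen

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips losslessly through YAML.

    Defaults follow the study conditions in :mod:`pcsense.conditions`;
    values marked free there are free here too.
    """

    seed: int = 0
    out_dir: str = "pcsense_out"
    arm: str = "all"                      # in_vivo | ex_vivo | all
    # spontaneous activity
    n_wt: int = cond.N_NEURONS_WT
    n_ko: int = cond.N_NEURONS_KO
    duration_s: float = cond.RECORDING_DURATION_S
    wt_ss_rate: float = cond.WT_SS_RATE_HZ
    ko_ss_rate: float = cond.ko_ss_rate_hz()
    wt_ss_cv: float = cond.WT_SS_CV
    ko_ss_cv: float = cond.ko_ss_cv()
    wt_cs_rate: float = cond.WT_CS_RATE_HZ
    ko_cs_rate: float = cond.ko_cs_rate_hz()
    cs_pause_s: float = 0.015
    rate_bin_hz: float = 2.0
    # SEP
    sep_trials: int = 30
    sep_noise_uv: float = synthgen.DEFAULT_SEP_NOISE_UV
    # patch clamp
    n_wt_cells: int = cond.N_CELLS_WT
    n_ko_cells: int = cond.N_CELLS_KO
    wt_rheobase_pa: float = cond.WT_RHEOBASE_PA
    ko_rheobase_pa: float = cond.ko_rheobase_pa()
    rheobase_sd_pa: float = cond.RHEOBASE_SD_PA
    # morphology
    n_wt_trees: int = cond.N_TREES_WT
    n_ko_trees: int = cond.N_TREES_KO
    wt_apical_um: float = cond.WT_APICAL_UM
    ko_apical_um: float = cond.ko_apical_um()
    apical_sd_um: float = cond.APICAL_SD_UM
    # statistics
    n_boot: int = 5000
    alpha: float = 0.05
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _comparison(a, b, rng, n_boot, label) -> dict:
    gc = _stats.bootstrap_md_ci(a, b, n_boot=n_boot, seed=rng)
    return {
        "metric": label,
        "mean_wt": float(np.mean(a)),
        "mean_ko": float(np.mean(b)),
        "md_ko_minus_wt": gc.md,
        "ci95_lo": gc.ci95[0],
        "ci95_hi": gc.ci95[1],
        "t": gc.t,
        "p": gc.p,
        "n_wt": gc.n_a,
        "n_ko": gc.n_b,
    }


def _in_vivo(config: RunConfig, rng_pool: list, out: Path, n_boot_rng) -> dict:
    rng_wt, rng_ko, rng_sep_wt, rng_sep_ko = rng_pool
    rows = []
    for genotype, n, rates, rng in (
            ("WT", config.n_wt,
             (config.wt_ss_rate, config.wt_ss_cv, config.wt_cs_rate), rng_wt),
            ("KO", config.n_ko,
             (config.ko_ss_rate, config.ko_ss_cv, config.ko_cs_rate), rng_ko)):
        ss_rate, ss_cv, cs_rate = rates
        for i in range(n):
            params = synthgen.PCParams(ss_rate=ss_rate, ss_cv=ss_cv,
                                       cs_rate=cs_rate,
                                       cs_pause=config.cs_pause_s,
                                       duration=config.duration_s)
            rec = synthgen.gen_pc_recording(params, rng)
            if not spiketrain.qc_min_duration(rec.ss):
                log.warning("unit %s-%d rejected by the duration rule", genotype, i)
                continue
            st = spiketrain.train_stats(rec.ss, rate_bin=config.rate_bin_hz)
            rows.append({
                "genotype": genotype, "neuron": i,
                "ss_rate_hz": st.rate, "ss_predominant_hz": st.predominant_rate,
                "ss_cv": st.cv, "ss_cv2": st.cv2,
                "cs_rate_hz": rec.cs.rate,
            })
    units = pd.DataFrame(rows)
    units.to_csv(out / "unit_stats.csv", index=False)

    comparisons = []
    for col, label in [("cs_rate_hz", "cs_rate_hz"), ("ss_rate_hz", "ss_rate_hz"),
                       ("ss_predominant_hz", "ss_predominant_hz"),
                       ("ss_cv", "ss_cv"), ("ss_cv2", "ss_cv2")]:
        a = units.loc[units.genotype == "WT", col].to_numpy()
        b = units.loc[units.genotype == "KO", col].to_numpy()
        comparisons.append(_comparison(a, b, n_boot_rng, config.n_boot, label))

    seps = {}
    for genotype, template, rng in (
            ("WT", synthgen.wt_sep_template(n_trials=config.sep_trials,
                                            noise_sd=config.sep_noise_uv), rng_sep_wt),
            ("KO", synthgen.ko_sep_template(n_trials=config.sep_trials,
                                            noise_sd=config.sep_noise_uv), rng_sep_ko)):
        trace, stim = synthgen.gen_sep_session(template, rng)
        epochs = evoked.baseline_correct(evoked.segment(trace, stim))
        mean, _sem = evoked.average_sep(epochs)
        noise_floor = float(epochs.data[:, epochs.pre_mask].std())
        comps = evoked.detect_components(mean, epochs.times_ms, noise_floor)
        seps[genotype] = [
            {"latency_ms": c.latency_ms, "amplitude_uv": c.amplitude}
            for c in comps
        ]
    return {"group_comparisons": comparisons, "sep_components": seps}


def _ex_vivo(config: RunConfig, rng_pool: list, out: Path, n_boot_rng) -> dict:
    rng_patch_wt, rng_patch_ko, rng_tree_wt, rng_tree_ko = rng_pool
    # wide-range protocol: covers the lognormal rheobase tail of both groups
    protocol = recovery.population_protocol(fs=10_000.0)
    rows = []
    for genotype, n, rheo_mean, rng in (
            ("WT", config.n_wt_cells, config.wt_rheobase_pa, rng_patch_wt),
            ("KO", config.n_ko_cells, config.ko_rheobase_pa, rng_patch_ko)):
        cells = synthgen.gen_cell_population(n, rheo_mean, config.rheobase_sd_pa, rng)
        for i, cell in enumerate(cells):
            sweeps = synthgen.gen_patch_sweeps(cell, protocol)
            res = intrinsic.analyze_cell(sweeps)
            hyper = next(sw for sw in sweeps if sw.step_pA < 0)
            passive = intrinsic.passive_props(hyper)
            rows.append({
                "genotype": genotype, "cell": i,
                "rheobase_pA": res.rheobase_pA,
                "fi_slope_hz_per_pa": res.fi_slope,
                "ap_threshold_mV": res.ap_threshold_mV,
                "v_rest_mV": passive.v_rest, "r_in_MOhm": passive.r_in,
                "c_m_pF": passive.c_m,
            })
    cells_df = pd.DataFrame(rows)
    cells_df.to_csv(out / "cell_stats.csv", index=False)

    comparisons = []
    for col in ["rheobase_pA", "fi_slope_hz_per_pa", "ap_threshold_mV",
                "v_rest_mV", "r_in_MOhm", "c_m_pF"]:
        a = cells_df.loc[cells_df.genotype == "WT", col].to_numpy()
        b = cells_df.loc[cells_df.genotype == "KO", col].to_numpy()
        comparisons.append(_comparison(a, b, n_boot_rng, config.n_boot, col))

    morph_rows = []
    sholl_rows = []
    for genotype, n, extent_mean, rng in (
            ("WT", config.n_wt_trees, config.wt_apical_um, rng_tree_wt),
            ("KO", config.n_ko_trees, config.ko_apical_um, rng_tree_ko)):
        for i in range(n):
            extent = max(20.0, rng.normal(extent_mean, config.apical_sd_um))
            params = synthgen.TreeParams(apical_extent=extent)
            m, spines = synthgen.gen_morphology(params, rng)
            profile = morphology.sholl(m)
            for r, c in zip(profile.radii_um, profile.intersections):
                sholl_rows.append({"genotype": genotype, "tree": i,
                                   "radius_um": float(r), "intersections": int(c)})
            morph_rows.append({
                "genotype": genotype, "tree": i,
                "apical_length_um": morphology.apical_length(m),
                "spine_density_per_um": morphology.spine_density(spines),
            })
    morph_df = pd.DataFrame(morph_rows)
    morph_df.to_csv(out / "morphometry.csv", index=False)
    pd.DataFrame(sholl_rows).to_csv(out / "sholl_profiles.csv", index=False)
    for col in ["apical_length_um", "spine_density_per_um"]:
        a = morph_df.loc[morph_df.genotype == "WT", col].to_numpy()
        b = morph_df.loc[morph_df.genotype == "KO", col].to_numpy()
        comparisons.append(_comparison(a, b, n_boot_rng, config.n_boot, col))
    return {"group_comparisons": comparisons}


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured arm(s) and write the report bundle to out_dir.

    Writes per-stage CSVs, ``summary.json`` (all group comparisons and SEP
    components) and ``provenance.json`` (seed, parameters, versions).
    Returns the summary dict.
    """
    if config.arm not in ("in_vivo", "ex_vivo", "all"):
        raise ValueError(f"unknown pipeline arm {config.arm!r}")
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = synthgen.split_rng(config.seed, 9)
    boot_rng = rngs[8]
    summary: dict = {"seed": config.seed}
    if config.arm in ("in_vivo", "all"):
        summary["in_vivo"] = _in_vivo(config, rngs[0:4], out, boot_rng)
    if config.arm in ("ex_vivo", "all"):
        summary["ex_vivo"] = _ex_vivo(config, rngs[4:8], out, boot_rng)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    provenance = {
        "seed": config.seed,
        "config": asdict(config),
        "versions": {"python": platform.python_version(),
                     "numpy": np.__version__, "pandas": pd.__version__},
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2,
                                                    sort_keys=True))
    return summary
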