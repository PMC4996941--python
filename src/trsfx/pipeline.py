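"""End-to-end orchestration: simulate → disambiguate → scale/merge → stats →
difference map → occupancy → kinetics, as one reproducible, seeded run.

A single top-level seed is stretched into independent per-stage streams by
stable hashing of the stage name, so enabling or disabling one stage never
changes the random numbers another stage sees.  All artifacts are plain
text (CSV/JSON/YAML) except optional CCP4 maps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import find_peak_time, fit_multiexponential, intermediate_peak_time
from .maps import (
    difference_coefficients,
    find_peaks,
    peaks_to_frame,
    synthesize_map,
    wilson_scale,
)
from .merging import (
    merge_monte_carlo,
    resolve_indexing_ambiguity,
    scale_crystals,
    shell_statistics,
    split_halves,
)
from .occupancy import dark_subtraction_sweep, occupancy_refine
from .reflections import ReflectionSet
from .simulate import (
    ObservationList,
    PhotocycleConfig,
    SerialSimConfig,
    simulate_photocycle_traces,
    simulate_serial_observations,
)
from .symmetry import UnitCell, space_group
from .toy import build_two_state_toy, calc_structure_factors, mix_states

__all__ = ["RunConfig", "RunReport", "derive_seed", "run_end_to_end", "make_fixtures"]

ALL_STAGES = ("simulate", "ambiguity", "merge", "diffmap", "occupancy", "kinetics")


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed (< 2^31) from the top-level seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    seed: int = 42
    out_dir: str = "trsfx_run"
    stages: tuple = ALL_STAGES
    # toy structures
    n_atoms: int = 30
    displacement_A: float = 1.5
    displaced_fraction: float = 0.2
    cell: tuple = (20.0, 20.0, 24.0, 90.0, 90.0, 120.0)
    spacegroup: str = "P63"
    d_min: float = 2.3
    alpha: float = 0.13           # ground-truth activated fraction
    # serial simulation (per data set)
    n_crystals: int = 40
    fraction_observed: float = 0.7
    log_scale_spread: float = 0.3
    rel_b_spread: float = 8.0
    noise: float = 0.03
    flip_probability: float = 0.5
    saturation_threshold: float = float("inf")
    # merging
    n_cycles: int = 3
    b_reject: float = 100.0
    res_extend_nm_inv: float = 0.3
    n_shells: int = 10
    # difference map / sweep
    sigma_threshold: float = 3.0
    m_min: float = 0.0
    m_max: float = 0.95
    m_step: float = 0.01
    write_maps: bool = False
    # kinetics
    n_exp: int = 3
    trace_noise_sd: float = 0.002

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["stages"] = list(self.stages)
        data["cell"] = list(self.cell)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class RunReport:
    seed: int
    stages: dict = field(default_factory=dict)   # stage -> key numbers
    files: list = field(default_factory=list)
    version: str = "0.1.0"

    def to_json(self, path=None) -> str:
        payload = {
            "seed": self.seed, "version": self.version,
            "stages": self.stages, "files": sorted(self.files),
        }
        text = json.dumps(payload, indent=2, sort_keys=True, default=_json_safe)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_text(self) -> str:
        lines = [f"trsfx run (seed {self.seed})"]
        for stage, vals in self.stages.items():
            lines.append(f"[{stage}]")
            for k, v in vals.items():
                lines.append(f"  {k}: {v}")
        return "\n".join(lines)


def _json_safe(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _round_floats(d: dict, ndigits: int = 10) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, float):
            out[k] = round(v, ndigits)
        else:
            out[k] = v
    return out


def run_end_to_end(config: RunConfig) -> RunReport:
    """Execute the enabled stages in order; returns the populated report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    cell = UnitCell(*config.cell)
    sg = space_group(config.spacegroup)
    enabled = set(config.stages)

    def record(path: Path) -> None:
        report.files.append(str(path.relative_to(out)))

    state: dict = {}

    if "simulate" in enabled:
        dark, m_state = build_two_state_toy(
            seed=derive_seed(config.seed, "toy"), n_atoms=config.n_atoms,
            displacement_A=config.displacement_A,
            displaced_fraction=config.displaced_fraction,
            cell=cell, spacegroup=config.spacegroup,
        )
        f_dark = calc_structure_factors(dark, config.d_min)
        f_m = calc_structure_factors(m_state, config.d_min)
        f_mix = mix_states(f_dark, f_m, config.alpha)
        state.update(dark=dark, m_state=m_state, f_dark=f_dark, f_m=f_m, f_mix=f_mix)

        obs = {}
        for tag, f_true in (("dark", f_dark), ("mix", f_mix)):
            cfg = SerialSimConfig(
                n_crystals=config.n_crystals,
                fraction_observed=config.fraction_observed,
                log_scale_spread=config.log_scale_spread,
                rel_b_spread=config.rel_b_spread, noise=config.noise,
                saturation_threshold=config.saturation_threshold,
                flip_probability=config.flip_probability,
                seed=derive_seed(config.seed, f"serial-{tag}"),
            )
            o, gt = simulate_serial_observations(f_true, cfg)
            obs[tag] = (o, gt)
            p = out / f"observations_{tag}.csv"
            o.to_csv(p)
            record(p)
        state["obs"] = obs
        p = out / "f_dark_calc.csv"
        f_dark.to_csv(p)
        record(p)
        report.stages["simulate"] = {
            "n_reflections": len(f_dark), "alpha_true": config.alpha,
            "n_crystals": config.n_crystals,
        }

    if "ambiguity" in enabled and "obs" in state:
        amb_report = {}
        # model intensities pin the global orientation of each data set, so
        # dark and mixed merges end up in one common indexing setting
        model_ref = {
            tuple(h): float(np.abs(f) ** 2)
            for h, f in zip(state["f_dark"].hkl, state["f_dark"].f)
        } if "f_dark" in state else None
        for tag in ("dark", "mix"):
            o, gt = state["obs"][tag]
            relabeled, flips, info = resolve_indexing_ambiguity(
                o, seed=derive_seed(config.seed, f"ambiguity-{tag}"),
                reference=model_ref,
            )
            state["obs"][tag] = (relabeled, gt)
            truth = np.zeros(len(flips), dtype=bool)
            truth[: len(gt.flipped)] = gt.flipped
            agree = float(np.mean(flips == truth))
            consistency = max(agree, 1.0 - agree)  # defined modulo global flip
            amb_report[tag] = {
                "n_iter": info["n_iter"],
                "consistency": consistency,
                "n_unassigned": len(info["unassigned"]),
            }
        report.stages["ambiguity"] = amb_report

    if "merge" in enabled and "obs" in state:
        merged = {}
        stats_report = {}
        for tag in ("dark", "mix"):
            o, _ = state["obs"][tag]
            scaled, crystal_scales = scale_crystals(
                o, n_cycles=config.n_cycles, b_reject=config.b_reject,
                res_extend_nm_inv=config.res_extend_nm_inv,
            )
            ms = merge_monte_carlo(scaled, d_min=config.d_min)
            halves = split_halves(scaled, d_min=config.d_min)
            stats = shell_statistics(halves, n_shells=config.n_shells, merged=ms)
            merged[tag] = ms
            p = out / f"merged_{tag}.csv"
            ms.to_csv(p)
            record(p)
            p = out / f"stats_{tag}.csv"
            stats.table().to_csv(p)
            record(p)
            ov = stats.overall
            stats_report[tag] = _round_floats({
                "rsplit": ov["rsplit"], "cc_half": ov["cc_half"],
                "cc_star": ov["cc_star"], "completeness": ov["completeness"],
                "multiplicity": ov["multiplicity"],
                "i_over_sigma": ov["i_over_sigma"],
                "n_rejected": sum(1 for c in crystal_scales if c.rejected),
            }, 6)
        state["merged"] = merged
        report.stages["merge"] = stats_report

    if "diffmap" in enabled and "merged" in state:
        amp_dark = state["merged"]["dark"].to_amplitude_set("dark")
        amp_mix = state["merged"]["mix"].to_amplitude_set("mix")
        scale_model, amp_mix_scaled = wilson_scale(amp_dark, amp_mix)
        phases = state["f_dark"].to_phase_set()
        coeffs = difference_coefficients(amp_mix_scaled, amp_dark, phases)
        dmap = synthesize_map(coeffs, d_min=config.d_min)
        peaks = find_peaks(dmap, config.sigma_threshold, model=state["m_state"])
        p = out / "difference_peaks.csv"
        peaks_to_frame(peaks).to_csv(p, index=False)
        record(p)
        if config.write_maps:
            p = out / "difference_map.ccp4"
            dmap.write_ccp4(p)
            record(p)
        state.update(amp_dark=amp_dark, amp_mix_scaled=amp_mix_scaled, phases=phases)
        report.stages["diffmap"] = _round_floats({
            "wilson_k": scale_model.k, "wilson_b": scale_model.b,
            "map_sigma": dmap.sigma, "n_peaks": len(peaks),
            "top_peak_sigma": peaks[0].height_sigma if peaks else 0.0,
            "top_peak_atom": peaks[0].nearest_atom if peaks else "",
        }, 6)

    if "occupancy" in enabled and "amp_mix_scaled" in state:
        m_grid = np.arange(config.m_min, config.m_max + config.m_step / 2, config.m_step)
        sweep = dark_subtraction_sweep(
            state["amp_mix_scaled"], state["amp_dark"], phases=state["phases"],
            m_grid=m_grid, reference_m=state["m_state"],
            reference_dark=state["dark"], d_min=config.d_min, mode="amplitude",
        )
        # put the observed mixed amplitudes on the calculated model's scale
        # (overall k and B), as a refinement program's scaling step would
        _, amp_mix_on_calc = wilson_scale(
            state["f_dark"].to_amplitude_set("dark_calc"), state["amp_mix_scaled"]
        )
        refine = occupancy_refine(amp_mix_on_calc, state["f_dark"], state["f_m"])
        p = out / "sweep_curve.csv"
        sweep.curve.to_csv(p, index=False)
        record(p)
        p = out / "occupancy_curve.csv"
        refine.curve.to_csv(p, index=False)
        record(p)
        report.stages["occupancy"] = _round_floats({
            "alpha_true": config.alpha,
            "alpha_sweep": sweep.alpha, "m_star": sweep.m_star,
            "raw_crossing": sweep.raw_crossing,
            "alpha_refine": refine.alpha, "scale_refine": refine.scale,
        }, 6)

    if "kinetics" in enabled:
        kcfg = PhotocycleConfig(
            noise_sd=config.trace_noise_sd,
            seed=derive_seed(config.seed, "kinetics"),
        )
        trace = simulate_photocycle_traces(kcfg)
        p = out / "traces.csv"
        trace.to_csv(p)
        record(p)
        fit = fit_multiexponential(trace, n_exp=config.n_exp,
                                   seed=derive_seed(config.seed, "expfit"),
                                   wavelength=412.0)
        peak = find_peak_time(trace.times, trace.delta_a[412.0])
        m_index = list(kcfg.states).index("M") if "M" in kcfg.states else None
        true_peak = (intermediate_peak_time(kcfg.rates, m_index)
                     if m_index is not None else float("nan"))
        report.stages["kinetics"] = _round_floats({
            "taus_s": [float(t) for t in fit.taus],
            "residual_rms": fit.residual_rms,
            "peak_time_s": peak.time, "peak_boundary": peak.boundary,
            "true_m_peak_s": true_peak,
        }, 9)

    report.to_json(out / "report.json")
    (out / "report.txt").write_text(report.to_text() + "\n")
    report.files.extend(["report.json", "report.txt"])
    return report


def make_fixtures(seed: int, scale: str = "tiny", out_dir: str = "fixtures") -> RunConfig:
    """Write a self-contained synthetic fixture directory.

    ``tiny`` is sized for test suites (seconds); ``demo`` mirrors the default
    study conditions (activated fraction 0.13, P6_3, more crystals).
    """
    if scale == "tiny":
        cfg = RunConfig(
            seed=seed, out_dir=out_dir, n_atoms=12, n_crystals=8,
            d_min=3.0, cell=(16.0, 16.0, 18.0, 90.0, 90.0, 120.0),
            fraction_observed=0.9, flip_probability=0.0,
            stages=("simulate", "merge", "kinetics"),
        )
    elif scale == "demo":
        cfg = RunConfig(seed=seed, out_dir=out_dir)
    else:
        raise ValueError("scale must be 'tiny' or 'demo'")
    run_end_to_end(cfg)
    cfg.to_yaml(Path(out_dir) / "config.yaml")
    return cfg
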