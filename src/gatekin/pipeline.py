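"""End-to-end orchestration: simulate -> analyze -> report.

A YAML config selects stages and parameters; every run writes its outputs
plus a manifest (parameter echo, seeds, per-stage status, output
checksums) into one run directory.  Identical configs and seeds produce
byte-identical numeric outputs.

All method thresholds (4.5 A contact cutoff, 0.1/0.9 dynamic-contact
bounds, +-0.1 dpc classification, 0.9 consensus threshold, 7/14 A state
thresholds, 300 K) are configuration defaults, never hard-coded in the
stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conformational as conf
from . import contacts as cn
from . import kinetics as kin
from . import mechanism as mech
from . import synthetic as syn
from .trajectory import read_trajectory

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "DEFAULT_THRESHOLDS"]

logger = logging.getLogger("gatekin")

DEFAULT_THRESHOLDS = {
    "contact_cutoff": 4.5,     # A
    "min_sep": 3,              # residues
    "pc_low": 0.1,
    "pc_high": 0.9,
    "consensus_threshold": 0.9,
    "dpc_threshold": 0.1,
    "closed_max": 7.0,         # A
    "open_min": 14.0,          # A
    "bin_width": 0.25,         # A
    "temperature": 300.0,      # K
}

_STAGES = ("simulate", "conformational", "dcna", "kinetics", "derive_rates")


class ConfigError(ValueError):
    """The pipeline configuration is invalid."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    output_dir: Path
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    n_frames: int = 1000
    trajectory_paths: dict = field(default_factory=dict)  # condition -> path
    gate_selection: str | None = None   # for loaded trajectories
    probe_selection: str | None = None
    measured: dict = field(default_factory=dict)          # label -> param dict
    kinetics_noise_sd: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(raw, base_dir=path.parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "PipelineConfig":
        base = Path(base_dir) if base_dir else Path.cwd()
        if "output_dir" not in raw:
            raise ConfigError("config must set output_dir")
        stages = {s: True for s in _STAGES}
        for s, on in (raw.get("stages") or {}).items():
            if s not in _STAGES:
                raise ConfigError(f"unknown stage {s!r}; expected one of {_STAGES}")
            stages[s] = bool(on)
        thresholds = dict(DEFAULT_THRESHOLDS)
        for k, v in (raw.get("thresholds") or {}).items():
            if k not in DEFAULT_THRESHOLDS:
                raise ConfigError(f"unknown threshold {k!r}")
            thresholds[k] = type(DEFAULT_THRESHOLDS[k])(v)
        cfg = cls(
            output_dir=(base / raw["output_dir"]).resolve(),
            seed=int(raw.get("seed", 0)),
            stages=stages,
            thresholds=thresholds,
            n_frames=int(raw.get("n_frames", 1000)),
            trajectory_paths={
                k: (base / v) for k, v in (raw.get("trajectories") or {}).items()
            },
            gate_selection=raw.get("gate_selection"),
            probe_selection=raw.get("probe_selection"),
            measured=raw.get("measured") or {},
            kinetics_noise_sd=float(raw.get("kinetics_noise_sd", 0.05)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        t = self.thresholds
        if not 0 < t["pc_low"] < t["pc_high"] <= 1:
            raise ConfigError("need 0 < pc_low < pc_high <= 1")
        if t["closed_max"] >= t["open_min"]:
            raise ConfigError("closed_max must be below open_min")
        if t["contact_cutoff"] <= 0 or t["bin_width"] <= 0 or t["temperature"] <= 0:
            raise ConfigError("contact_cutoff, bin_width, temperature must be positive")
        for label, p in self.trajectory_paths.items():
            if not Path(p).exists():
                raise ConfigError(f"trajectory file for {label!r} not found: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, Path):
        return str(x)
    raise TypeError(f"cannot serialize {type(x)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order; returns the
    manifest (also written to ``<output_dir>/manifest.json``)."""
    config.validate()
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    t = config.thresholds
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    manifest = {
        "seed": config.seed,
        "thresholds": t,
        "stages": {},
        "outputs": {},
    }

    trajectories: dict = {}
    labels: dict = {}
    gate_probe: dict = {}  # condition -> (gate expr, probe expr)

    def record(stage: str, status: str, error: str | None = None) -> None:
        manifest["stages"][stage] = {"status": status}
        if error:
            manifest["stages"][stage]["error"] = error

    def add_output(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }

    try:
        # --- inputs: simulate or load -------------------------------------
        if config.stages["simulate"]:
            base_seed = int(seeds[0].generate_state(1)[0] % (2**31))
            specs = {
                "wild-type-like": syn.wild_type_like_spec(
                    seed=base_seed, n_frames=config.n_frames
                ),
                "variant-like": syn.variant_like_spec(
                    seed=base_seed + 1, n_frames=config.n_frames
                ),
            }
            for label, spec in specs.items():
                traj, lab = syn.generate_two_state_trajectory(spec)
                trajectories[label] = traj
                labels[label] = lab
                gate_probe[label] = (
                    f"residue {spec.gate_residue} and name CA",
                    f"residue {spec.probe_residue} and name CA",
                )
                csv = out / f"states_{label}.csv"
                pd.DataFrame({"frame": np.arange(len(lab)), "state": lab.labels}).to_csv(
                    csv, index=False
                )
                add_output(f"state_labels/{label}", csv)
            record("simulate", "ok")
        for label, path in config.trajectory_paths.items():
            trajectories[label] = read_trajectory(path, condition_label=label)

        # --- conformational statistics ------------------------------------
        if config.stages["conformational"]:
            if not trajectories:
                raise ConfigError(
                    "conformational stage needs simulated or loaded trajectories"
                )
            summary = {}

            def _pair(label):
                if label in gate_probe:
                    return gate_probe[label]
                if config.gate_selection and config.probe_selection:
                    return config.gate_selection, config.probe_selection
                raise ConfigError(
                    "gate_selection/probe_selection must be set for loaded "
                    f"trajectory {label!r}"
                )

            for label, traj in trajectories.items():
                gate, probe = _pair(label)
                rmsf = conf.compute_rmsf(traj)
                pd.DataFrame(
                    {"residue": np.arange(traj.n_residues) + 1, "rmsf_A": rmsf.rmsf}
                ).to_csv(out / f"rmsf_{label}.csv", index=False)
                add_output(f"rmsf/{label}", out / f"rmsf_{label}.csv")
                series = conf.distance_series(traj, gate, probe)
                pd.DataFrame(
                    {"frame": np.arange(len(series)), "distance_A": series.values}
                ).to_csv(out / f"distance_{label}.csv", index=False)
                add_output(f"distance/{label}", out / f"distance_{label}.csv")
                occ = conf.classify_states(
                    series, closed_max=t["closed_max"], open_min=t["open_min"]
                )
                fes = conf.free_energy_profile(
                    series, bin_width=t["bin_width"], temperature=t["temperature"]
                )
                pd.DataFrame(
                    {
                        "bin_center_A": fes.bin_centers,
                        "density": fes.density,
                        "free_energy_kcal_mol": fes.free_energy,
                    }
                ).to_csv(out / f"fes_{label}.csv", index=False)
                add_output(f"fes/{label}", out / f"fes_{label}.csv")
                summary[label] = {
                    "fraction_closed": occ.fraction_closed,
                    "fraction_intermediate": occ.fraction_intermediate,
                    "fraction_open": occ.fraction_open,
                }
            if len(trajectories) >= 1:
                trajs = list(trajectories.values())
                gate_series = [
                    conf.distance_series(tr, *_pair(lab)).values
                    for lab, tr in trajectories.items()
                ]
                result = conf.pca(
                    trajs, selection="name CA", k=2,
                    orient_by=np.concatenate(gate_series),
                )
                for label, proj in zip(trajectories, result.projections):
                    pd.DataFrame(proj, columns=["PC1", "PC2"]).to_csv(
                        out / f"pca_{label}.csv", index=False
                    )
                    add_output(f"pca/{label}", out / f"pca_{label}.csv")
                summary["pca_variance_fractions"] = result.variance_fractions[:2]
            _write_json(out / "conformational_summary.json", summary)
            add_output("conformational_summary", out / "conformational_summary.json")
            record("conformational", "ok")

        # --- difference contact network -----------------------------------
        if config.stages["dcna"]:
            if len(trajectories) < 2:
                raise ConfigError("dcna stage needs two conditions")
            (la, ta), (lb, tb) = list(trajectories.items())[:2]
            map_a = cn.compute_contact_probabilities(
                ta, cutoff=t["contact_cutoff"], min_sep=t["min_sep"]
            )
            map_b = cn.compute_contact_probabilities(
                tb, cutoff=t["contact_cutoff"], min_sep=t["min_sep"]
            )
            mask = cn.dynamic_contact_mask(
                map_a, map_b, low=t["pc_low"], high=t["pc_high"]
            )
            diff = cn.contact_difference(
                map_a, map_b, mask, threshold=t["dpc_threshold"]
            )
            diff.to_dataframe().to_csv(out / "dpc.csv", index=False)
            add_output("dpc", out / "dpc.csv")
            net = cn.build_consensus_network(
                map_a, map_b, threshold=t["consensus_threshold"]
            )
            partition = cn.detect_communities(net)
            pd.DataFrame(
                sorted(partition.membership.items()),
                columns=["residue", "community"],
            ).to_csv(out / "communities.csv", index=False)
            add_output("communities", out / "communities.csv")
            cdg = cn.community_difference(partition, diff)
            import networkx as nx

            nx.write_graphml(cdg.to_graph(), out / "community_diff.graphml")
            add_output("community_diff", out / "community_diff.graphml")
            _write_json(
                out / "dcna_summary.json",
                {
                    "conditions": [la, lb],
                    "modularity": partition.modularity,
                    "n_communities": partition.n_communities,
                    "net_dpc": {f"{a}-{b}": v for (a, b), v in sorted(cdg.net.items())},
                },
            )
            add_output("dcna_summary", out / "dcna_summary.json")
            record("dcna", "ok")

        # --- kinetics fits on synthetic data ------------------------------
        if config.stages["kinetics"]:
            kin_seed = int(seeds[1].generate_state(1)[0] % (2**31))
            kspec = syn.SyntheticKineticsSpec(
                noise_sd=config.kinetics_noise_sd, seed=kin_seed
            )
            report = {}
            trace = syn.generate_kinetic_dataset(kspec, "trace")
            trace.to_csv(out / "trace.csv", index=False)
            add_output("trace", out / "trace.csv")
            tf = kin.fit_transient(trace)
            report["transient"] = {"kobs": tf.kobs, "B": tf.amplitude, "C": tf.offset}
            sat = syn.generate_kinetic_dataset(kspec, "saturation")
            sat.to_csv(out / "saturation.csv", index=False)
            add_output("saturation", out / "saturation.csv")
            sf = kin.fit_saturation(sat)
            report["saturation"] = {
                "kred": sf.kred, "Kd": sf.Kd, "krev": sf.krev,
                "krev_retained": sf.krev_retained,
            }
            rates = syn.generate_kinetic_dataset(kspec, "initial_rates")
            rates.to_csv(out / "initial_rates.csv", index=False)
            add_output("initial_rates", out / "initial_rates.csv")
            mm = kin.fit_michaelis_menten(rates)
            report["michaelis_menten"] = {
                "kcat": mm.kcat, "Km": mm.Km, "kcat_over_Km": mm.kcat_over_Km,
            }
            ph = syn.generate_kinetic_dataset(kspec, "ph_profile")
            ph.to_csv(out / "ph_profile.csv", index=False)
            add_output("ph_profile", out / "ph_profile.csv")
            pf = kin.fit_ph_profile(ph, model="one_pka")
            report["ph_profile"] = {"pKa": pf.pKa, "limit": pf.limit}
            _write_json(out / "kinetics_fits.json", report)
            add_output("kinetics_fits", out / "kinetics_fits.json")
            record("kinetics", "ok")

        # --- mechanism inference ------------------------------------------
        if config.stages["derive_rates"]:
            measured = {
                label: mech.MeasuredParameters.from_dict(d, label=label)
                for label, d in config.measured.items()
            } or {
                "wild-type": mech.WILD_TYPE_MEASURED,
                "variant": mech.I335H_MEASURED,
            }
            mc_seed = int(seeds[2].generate_state(1)[0] % (2**31))
            derived = {}
            report = {}
            for label, m in measured.items():
                det = mech.derive_rate_constants(m)
                mc = mech.propagate_uncertainty(m, n_draws=20_000, seed=mc_seed)
                derived[label] = det
                report[label] = {
                    "deterministic": det.as_dict(),
                    "monte_carlo": mc.as_dict(),
                    "rounded_2sf": det.as_dict(sig=2),
                    "consistency": mech.consistency_check(det),
                }
            if len(derived) == 2:
                labs = list(derived)
                cmp_ = mech.compare_mechanisms(derived[labs[0]], derived[labs[1]])
                report["comparison"] = {
                    "reference": labs[0],
                    "variant": labs[1],
                    "fold_changes_2sf": cmp_.folds_2sf,
                    "direction": cmp_.direction,
                }
            _write_json(out / "rate_constants.json", report)
            add_output("rate_constants", out / "rate_constants.json")
            _write_markdown_report(out / "rate_constants.md", report)
            add_output("rate_constants_md", out / "rate_constants.md")
            record("derive_rates", "ok")
    except Exception as exc:
        failed_stage = next(
            (s for s in _STAGES if config.stages.get(s) and s not in manifest["stages"]),
            "unknown",
        )
        record(failed_stage, "failed", error=str(exc))
        _write_json(out / "manifest.json", manifest)
        raise

    _write_json(out / "manifest.json", manifest)
    return manifest


def _write_markdown_report(path: Path, report: dict) -> None:
    lines = ["# Microscopic rate constants", ""]
    for label, block in report.items():
        if label == "comparison":
            continue
        lines.append(f"## {label}")
        lines.append("")
        lines.append("| constant | value | 1-sigma | provenance |")
        lines.append("|---|---|---|---|")
        for k, d in block["rounded_2sf"].items():
            lines.append(
                f"| {k} | {d['value']:g} | {d['err']:.2g} | {d['provenance']} |"
            )
        lines.append("")
    if "comparison" in report:
        c = report["comparison"]
        lines.append(
            f"## Fold changes ({c['reference']} / {c['variant']})"
        )
        lines.append("")
        for k, v in c["fold_changes_2sf"].items():
            lines.append(f"- {k}: {v:g}-fold {c['direction'][k]}")
        lines.append("")
    path.write_text("\n".join(lines))
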