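"""Configuration-driven orchestration: simulate -> compensate -> gate ->
score -> compare, with a machine-readable report.

A run is described by a declarative config (YAML/JSON): the panel file, a
sample manifest (file, role, condition, replicate), the gating quantile,
whether to compensate, and the statistics design. Reports record the package
version, a config hash, the thresholds and the spillover matrix actually
used, and every count/MFI entering every score, so each number is traceable.
Reports carry no timestamps: rerunning the same config yields a
byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .flow import estimate_spillover, compensate, fit_gates, gate_cell_cycle
from .io import default_panel, load_panel, read_events, write_events
from .model import EventTable, PanelSpec
from .scoring import normalize_to_control, reporter_expression
from .simulate import (
    CellCycleTruth,
    SimulationTruth,
    simulate_cell_cycle_sample,
    simulate_sample,
    simulate_single_color_controls,
)
from .stats import anova_dunnett, ttest_family

__all__ = ["ManifestEntry", "RunConfig", "load_run_config", "run_fm_dsbr", "make_fixtures"]

log = logging.getLogger("fmdsbr")

ROLES = ("damaged", "undamaged", "single_color", "negative")


class ConfigError(ValueError):
    """The run configuration violates a structural requirement."""


@dataclass(frozen=True)
class ManifestEntry:
    file: str
    role: str  # damaged | undamaged | single_color | negative
    condition: str = ""
    replicate: str = ""
    fluorophore: str = ""  # for single_color entries

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigError(f"unknown sample role {self.role!r} for {self.file!r}")
        if self.role == "single_color" and not self.fluorophore:
            raise ConfigError(f"single_color entry {self.file!r} needs a fluorophore")


@dataclass(frozen=True)
class RunConfig:
    panel: str
    manifest: tuple[ManifestEntry, ...]
    output_dir: str = "."
    gating_quantile: float = 0.999
    compensation: bool = True
    stats_method: str = "t_holm_sidak"  # or "anova_dunnett"
    control_condition: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        conditions: dict[str, set[str]] = {}
        for e in self.manifest:
            if e.role in ("damaged", "undamaged"):
                conditions.setdefault(e.condition, set()).add(e.role)
        for cond, roles in conditions.items():
            if roles != {"damaged", "undamaged"}:
                raise ConfigError(
                    f"condition {cond!r} lacks matched damaged/undamaged samples "
                    f"(has {sorted(roles)})"
                )
        if self.compensation:
            if not any(e.role == "single_color" for e in self.manifest):
                raise ConfigError("compensation requires single_color control samples")
        if not any(e.role == "negative" for e in self.manifest):
            raise ConfigError("gating requires a negative control sample")
        if self.stats_method not in ("t_holm_sidak", "anova_dunnett", "none"):
            raise ConfigError(f"unknown stats method {self.stats_method!r}")


def load_run_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    entries = tuple(ManifestEntry(**e) for e in doc.pop("manifest"))
    return RunConfig(manifest=entries, **doc)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {
            "panel": config.panel,
            "manifest": [vars(e) for e in config.manifest],
            "gating_quantile": config.gating_quantile,
            "compensation": config.compensation,
            "stats_method": config.stats_method,
            "control_condition": config.control_condition,
            "seed": config.seed,
        },
        sort_keys=True,
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_fm_dsbr(config: RunConfig, base_dir: str | Path = ".") -> dict:
    """Execute a full scoring run and return the report dictionary.

    Stage failures are recorded per condition under ``"failures"`` with the
    sample id and stage name; scoring continues for the other conditions.
    """
    base = Path(base_dir)
    panel = load_panel(base / config.panel)
    report: dict = {
        "package": "fmdsbr",
        "version": __version__,
        "config_hash": _config_hash(config),
        "conditions": {},
        "failures": [],
        "log": [],
    }

    def note(msg: str) -> None:
        log.info(msg)
        report["log"].append(msg)

    samples: dict[tuple, EventTable] = {}
    singles: dict[str, EventTable] = {}
    negative: EventTable | None = None
    for e in config.manifest:
        table = read_events(base / e.file)
        if e.role == "single_color":
            singles[e.fluorophore] = table
        elif e.role == "negative":
            negative = table
        else:
            samples[(e.condition, e.replicate, e.role)] = table
        note(f"read {e.file}: {table.n_events} events ({e.role})")
    assert negative is not None  # enforced by RunConfig

    spill_record = None
    if config.compensation:
        spillover = estimate_spillover(singles, negative, panel)
        spill_record = {
            "fluorophores": list(spillover.fluorophores),
            "channels": list(spillover.channels),
            "matrix": spillover.matrix.tolist(),
        }
        negative = compensate(negative, spillover)
        samples = {k: compensate(t, spillover) for k, t in samples.items()}
        note("compensated all scored samples against estimated spillover")

    scored_channels = sorted(set(panel.fluorophore_channels.values()))
    gates = fit_gates(negative, scored_channels, config.gating_quantile)
    report["thresholds"] = {ch: gates[ch] for ch in scored_channels}
    report["spillover"] = spill_record

    conditions = sorted({c for (c, _, _) in samples})
    replicate_percents: dict[str, dict[str, list[float]]] = {}
    for cond in conditions:
        reps = sorted({r for (c, r, _) in samples if c == cond})
        cond_out: dict = {"replicates": {}}
        percents: dict[str, list[float]] = {}
        for rep in reps:
            try:
                dam = samples[(cond, rep, "damaged")]
                und = samples[(cond, rep, "undamaged")]
            except KeyError as exc:
                report["failures"].append(
                    {"condition": cond, "replicate": rep, "stage": "pairing",
                     "error": f"missing sample {exc}"}
                )
                continue
            try:
                scores = reporter_expression(dam, und, panel, gates)
            except Exception as exc:  # surfaced with sample id and stage
                report["failures"].append(
                    {"condition": cond, "replicate": rep, "stage": "scoring",
                     "sample": dam.sample_id, "error": str(exc)}
                )
                continue
            cond_out["replicates"][rep] = {
                s.pathway: {
                    "percent_expression": s.percent_expression,
                    "x": s.x_value,
                    "y": s.y_value,
                    "counts_and_mfi": {
                        k: [int(c), None if np.isnan(m) else float(m)]
                        for k, (c, m) in s.counts_and_mfi.items()
                    },
                }
                for s in scores
            }
            for s in scores:
                percents.setdefault(s.pathway, []).append(s.percent_expression)
        cond_out["mean_percent"] = {
            pw: float(np.mean(v)) for pw, v in percents.items() if v
        }
        report["conditions"][cond] = cond_out
        replicate_percents[cond] = percents

    ctrl = config.control_condition or (conditions[0] if conditions else "")
    if ctrl in replicate_percents:
        for cond in conditions:
            if cond == ctrl:
                continue
            folds = {}
            for pw, vals in replicate_percents[cond].items():
                ctrl_vals = replicate_percents[ctrl].get(pw, [])
                if vals and ctrl_vals:
                    ns = normalize_to_control(vals, ctrl_vals, cond, ctrl)
                    folds[pw] = ns.fold_change
            report["conditions"][cond]["fold_change_vs_" + ctrl] = folds

        report["comparisons"] = _run_stats(config, replicate_percents, ctrl)
    return report


def _run_stats(config: RunConfig, percents: dict[str, dict[str, list[float]]],
               ctrl: str) -> list[dict]:
    out: list[dict] = []
    conditions = [c for c in sorted(percents) if c != ctrl]
    pathways = sorted({pw for d in percents.values() for pw in d})
    if config.stats_method == "none" or not conditions:
        return out
    if config.stats_method == "t_holm_sidak":
        # one family per treated condition: its per-pathway comparisons to control
        for cond in conditions:
            pairs, labels = [], []
            for pw in pathways:
                a, b = percents[cond].get(pw, []), percents[ctrl].get(pw, [])
                if len(a) >= 2 and len(b) >= 2:
                    pairs.append((a, b))
                    labels.append(f"{cond} vs {ctrl}: {pw}")
            for r in ttest_family(pairs, labels):
                out.append(vars(r))
    else:
        # one Dunnett family per pathway across all conditions vs control
        for pw in pathways:
            groups = [percents[ctrl].get(pw, [])]
            labels = [ctrl]
            for cond in conditions:
                vals = percents[cond].get(pw, [])
                if len(vals) >= 2:
                    groups.append(vals)
                    labels.append(f"{cond} vs {ctrl}: {pw}")
            if len(groups) >= 2 and len(groups[0]) >= 2:
                for r in anova_dunnett(groups, control_index=0, labels=labels):
                    out.append(vars(r))
    return out


# --------------------------------------------------------------------------
# fixture bundle
# --------------------------------------------------------------------------

_PANEL_YAML = """\
control_fluorophore: AmCyan
channels:
  - {name: VL1, excitation_nm: 405, filter: "450/40"}
  - {name: VL2, excitation_nm: 405, filter: "525/50"}
  - {name: BL1, excitation_nm: 488, filter: "530/30"}
  - {name: YL1, excitation_nm: 561, filter: "620/15"}
damaged_cocktail:
  - {reporter: BFP_NHEJ, pathway: NHEJ, mass_ng: 100, fluorophore: BFP, channel: VL1, damaged: true}
  - {reporter: GFP_MMEJ6, pathway: MMEJ, mass_ng: 250, fluorophore: GFP, channel: BL1, damaged: true}
  - {reporter: mCherry_HR, pathway: HR, mass_ng: 100, fluorophore: mCherry, channel: YL1, damaged: true}
  - {reporter: pMax_AmCyan, pathway: TRANSFECTION_CONTROL, mass_ng: 100, fluorophore: AmCyan, channel: VL2}
  - {reporter: deltaCMV_carrier, pathway: CARRIER, mass_ng: 1000}
undamaged_cocktail:
  - {reporter: pMax_BFP, pathway: NHEJ, mass_ng: 100, fluorophore: BFP, channel: VL1}
  - {reporter: pMax_GFP, pathway: MMEJ, mass_ng: 100, fluorophore: GFP, channel: BL1}
  - {reporter: pMax_mCherry, pathway: HR, mass_ng: 100, fluorophore: mCherry, channel: YL1}
  - {reporter: pMax_AmCyan, pathway: TRANSFECTION_CONTROL, mass_ng: 100, fluorophore: AmCyan, channel: VL2}
  - {reporter: deltaCMV_carrier, pathway: CARRIER, mass_ng: 1000}
"""

FIXTURE_CONDITIONS = {
    "DMSO": {"NHEJ": 0.12, "HR": 0.015, "MMEJ": 0.01},
    "ATMi": {"NHEJ": 0.12, "HR": 0.004, "MMEJ": 0.003},
}


def make_fixtures(out_dir: str | Path, seed: int = 0, n_events: int = 2000,
                  n_replicates: int = 3) -> dict:
    """Write a complete small synthetic experiment with truth sidecars.

    Produces single-color/negative controls, damaged/undamaged samples for
    two conditions x replicates, a cell-cycle sample, the panel YAML, a run
    config, and a JSON truth sidecar; everything an end-to-end run needs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel_path = out / "panel.yaml"
    panel_path.write_text(_PANEL_YAML, encoding="utf-8")
    panel = load_panel(panel_path)

    manifest: list[dict] = []
    truth_sidecar: dict = {"seed": seed, "conditions": {}}
    base = SimulationTruth(n_events=n_events, seed=seed)
    controls = simulate_single_color_controls(base, panel, seed=seed)
    for fluor, table in controls.items():
        name = f"control_{fluor}.csv"
        write_events(table, out / name)
        if fluor == "negative":
            manifest.append({"file": name, "role": "negative"})
        else:
            manifest.append({"file": name, "role": "single_color", "fluorophore": fluor})

    for ci, (cond, repair) in enumerate(sorted(FIXTURE_CONDITIONS.items())):
        truth_sidecar["conditions"][cond] = {"repair_efficiency": repair}
        for rep in range(n_replicates):
            truth = SimulationTruth(
                repair_efficiency=repair, n_events=n_events,
                seed=seed + 1000 * (ci + 1) + rep,
            )
            for role in ("damaged", "undamaged"):
                table, _ = simulate_sample(truth, panel, role)
                name = f"{cond}_{role}_rep{rep}.csv"
                write_events(table, out / name)
                manifest.append(
                    {"file": name, "role": role, "condition": cond, "replicate": str(rep)}
                )

    cc_truth = CellCycleTruth(n_events=max(n_events, 6000), seed=seed)
    cc_table, cc_labels = simulate_cell_cycle_sample(cc_truth)
    write_events(cc_table, out / "cellcycle.csv")
    cc_labels.to_csv(out / "cellcycle_truth_labels.csv", index=False)
    truth_sidecar["cell_cycle"] = {
        "phase_fractions": list(cc_truth.phase_fractions),
        "cv": cc_truth.cv,
        "g1_position": cc_truth.g1_position,
    }

    config_doc = {
        "panel": "panel.yaml",
        "manifest": manifest,
        "gating_quantile": 0.999,
        "compensation": True,
        "stats_method": "t_holm_sidak",
        "control_condition": "DMSO",
        "seed": seed,
    }
    (out / "run_config.yaml").write_text(yaml.safe_dump(config_doc), encoding="utf-8")
    (out / "truth.json").write_text(json.dumps(truth_sidecar, indent=2), encoding="utf-8")
    return {"dir": out, "config": out / "run_config.yaml", "truth": out / "truth.json"}
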