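"""Synthetic flow-cytometry data with known ground truth.

The generative model mirrors the structure of a transient co-transfection
reporter experiment:

* a cell takes up the whole cocktail with probability
  ``transfection_efficiency`` (lipofection is all-or-none per cell);
* transfected cells share one lognormal uptake factor across all plasmids,
  which is what makes a co-delivered control plasmid informative;
* each fluorophore-bearing plasmid adds lognormal expression noise and scales
  linearly with its mass in the cocktail;
* a damaged reporter is reactivated all-or-none with the pathway's repair
  efficiency — the reporters are restored-ORF constructs, so a repaired
  plasmid expresses like its wild-type counterpart;
* detector signals mix fluorophores through the spillover matrix, then add
  per-channel lognormal autofluorescence and Gaussian instrument noise, and
  are floored at zero as written by the instrument.

Under matched cocktail masses and thresholds that capture all expressing
cells, the expected %Reporter Expression equals 100 x repair efficiency:
reactivated damaged reporters match the undamaged reporter in law, so both
the positive count ratio and the MFI ratio cancel against the control.

All distributional defaults are implementation fixtures chosen to look like
routine transient-transfection data; no instrument calibration stands behind
them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .flow import SpilloverMatrix
from .model import EventTable, PanelSpec, PATHWAYS

__all__ = [
    "SimulationTruth",
    "CellCycleTruth",
    "SimulatedSample",
    "default_spillover",
    "simulate_sample",
    "simulate_single_color_controls",
    "simulate_sce_reporter",
    "simulate_cell_cycle_sample",
]


def default_spillover() -> SpilloverMatrix:
    """Plausible four-color mixing fixture (not an instrument measurement)."""
    fluors = ("BFP", "AmCyan", "GFP", "mCherry")
    channels = ("VL1", "VL2", "BL1", "YL1")
    m = np.array(
        [
            [1.00, 0.15, 0.03, 0.00],
            [0.05, 1.00, 0.20, 0.01],
            [0.00, 0.10, 1.00, 0.02],
            [0.00, 0.00, 0.01, 1.00],
        ]
    )
    return SpilloverMatrix(m, fluors, channels)


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameters of one simulated transfection experiment.

    ``expression_mu`` is the log of median expression per ng of plasmid, so a
    100 ng plasmid in a cell with unit uptake has median intensity
    ``100 * exp(expression_mu)`` (arbitrary fluorescence units).
    """

    transfection_efficiency: float = 0.4
    uptake_sigma: float = 0.8
    expression_mu: float = math.log(40.0)
    expression_sigma: float = 0.4
    repair_efficiency: dict[str, float] = field(
        default_factory=lambda: {"NHEJ": 0.12, "HR": 0.015, "MMEJ": 0.003}
    )
    spillover: SpilloverMatrix = field(default_factory=default_spillover)
    autofluorescence_mu: float = math.log(20.0)
    autofluorescence_sigma: float = 0.5
    noise_sd: float = 5.0
    n_events: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        _check_prob("transfection_efficiency", self.transfection_efficiency)
        for pw, p in self.repair_efficiency.items():
            if pw not in PATHWAYS:
                raise ValueError(f"unknown pathway {pw!r} in repair_efficiency")
            _check_prob(f"repair_efficiency[{pw}]", p)
        for name in ("uptake_sigma", "expression_sigma", "autofluorescence_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")


class SimulatedSample(NamedTuple):
    """An event table plus the per-event truth that generated it."""

    events: EventTable
    truth_labels: pd.DataFrame


def _finish_channels(
    expression: np.ndarray,  # events x fluorophores (spillover row order)
    spillover: SpilloverMatrix,
    panel_channels: list[str],
    truth: SimulationTruth,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Mix fluorophores into detectors, add background/noise, floor at 0."""
    n = expression.shape[0]
    mixed = pd.DataFrame(0.0, index=range(n), columns=panel_channels)
    signal = expression @ spillover.matrix
    for j, ch in enumerate(spillover.channels):
        if ch in mixed.columns:
            mixed[ch] += signal[:, j]
    for ch in panel_channels:
        auto = rng.lognormal(truth.autofluorescence_mu, truth.autofluorescence_sigma, n)
        noise = rng.normal(0.0, truth.noise_sd, n) if truth.noise_sd > 0 else 0.0
        mixed[ch] = np.maximum(mixed[ch].to_numpy() + auto + noise, 0.0)
    return mixed


def simulate_sample(
    truth: SimulationTruth,
    panel: PanelSpec,
    cocktail: str,
    seed: int | None = None,
) -> SimulatedSample:
    """Simulate one transfected sample (damaged or undamaged cocktail).

    Returns the event table and per-event truth labels: the transfection
    indicator, the shared uptake factor, and per-fluorophore reactivation
    flags and noiseless abundances.
    """
    if cocktail not in ("damaged", "undamaged"):
        raise ValueError(f"cocktail must be 'damaged' or 'undamaged', got {cocktail!r}")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n = truth.n_events
    recs = panel.damaged_cocktail if cocktail == "damaged" else panel.undamaged_cocktail

    transfected = rng.random(n) < truth.transfection_efficiency
    uptake = rng.lognormal(0.0, truth.uptake_sigma, n)

    fluors = truth.spillover.fluorophores
    expr = np.zeros((n, len(fluors)))
    labels = pd.DataFrame({"transfected": transfected, "uptake": uptake})
    for rec in recs:
        if rec.fluorophore is None:
            continue
        if rec.fluorophore not in fluors:
            raise ValueError(
                f"fluorophore {rec.fluorophore!r} absent from the truth spillover"
            )
        per_plasmid = rng.lognormal(truth.expression_mu, truth.expression_sigma, n)
        e = transfected * uptake * rec.mass_ng * per_plasmid
        if rec.damaged:
            p_repair = truth.repair_efficiency.get(rec.pathway, 0.0)
            reactivated = rng.random(n) < p_repair
            e = e * reactivated
            labels[f"reactivated_{rec.fluorophore}"] = reactivated & transfected
        expr[:, fluors.index(rec.fluorophore)] += e
        labels[f"abundance_{rec.fluorophore}"] = expr[:, fluors.index(rec.fluorophore)]

    data = _finish_channels(expr, truth.spillover, panel.channel_names, truth, rng)
    table = EventTable(data, sample_id=f"sim_{cocktail}_seed{truth.seed}", cocktail=cocktail)
    return SimulatedSample(table, labels)


def simulate_single_color_controls(
    truth: SimulationTruth,
    panel: PanelSpec,
    seed: int | None = None,
) -> dict[str, EventTable]:
    """One single-color control per panel fluorophore plus a negative control.

    Each control expresses exactly one fluorophore (at the undamaged-cocktail
    mass) on top of autofluorescence and noise; the negative control
    expresses none. Keys are fluorophore names plus ``"negative"``.
    """
    base_seed = truth.seed if seed is None else seed
    fl2ch = panel.fluorophore_channels
    masses = {
        r.fluorophore: r.mass_ng for r in panel.undamaged_cocktail if r.fluorophore
    }
    out: dict[str, EventTable] = {}
    fluors = truth.spillover.fluorophores
    for k, fluor in enumerate(sorted(fl2ch)):
        rng = np.random.default_rng((base_seed, 1, k))
        n = truth.n_events
        transfected = rng.random(n) < truth.transfection_efficiency
        uptake = rng.lognormal(0.0, truth.uptake_sigma, n)
        per_plasmid = rng.lognormal(truth.expression_mu, truth.expression_sigma, n)
        expr = np.zeros((n, len(fluors)))
        expr[:, fluors.index(fluor)] = (
            transfected * uptake * masses.get(fluor, 100.0) * per_plasmid
        )
        data = _finish_channels(expr, truth.spillover, panel.channel_names, truth, rng)
        out[fluor] = EventTable(
            data, sample_id=f"single_{fluor}", cocktail=f"single_color:{fluor}"
        )
    rng = np.random.default_rng((base_seed, 2))
    data = _finish_channels(
        np.zeros((truth.n_events, len(fluors))), truth.spillover,
        panel.channel_names, truth, rng,
    )
    out["negative"] = EventTable(data, sample_id="negative", cocktail="negative")
    return out


def simulate_sce_reporter(
    p_cut_repair: float,
    p_cotransfect: float,
    background_rate: float = 0.0,
    n_events: int = 100_000,
    seed: int = 0,
    sce_present: bool = True,
) -> SimulatedSample:
    """Simulate an integrated SceI reporter line (DR-GFP / EJ2-GFP style).

    Cells taking up the transfection mix (probability ``p_cotransfect``)
    express the BFP control; among those, the genomic cassette converts to
    GFP+ with probability ``p_cut_repair`` when the nuclease is present.
    ``background_rate`` is nuclease-independent conversion affecting all
    cells. Channels: BL1 (GFP), VL1 (BFP).
    """
    for name, p in (
        ("p_cut_repair", p_cut_repair),
        ("p_cotransfect", p_cotransfect),
        ("background_rate", background_rate),
    ):
        _check_prob(name, p)
    rng = np.random.default_rng(seed)
    transfected = rng.random(n_events) < p_cotransfect
    cut = transfected & (rng.random(n_events) < (p_cut_repair if sce_present else 0.0))
    spont = rng.random(n_events) < background_rate
    gfp_pos = cut | spont

    def intensity(positive: np.ndarray, mu_pos: float) -> np.ndarray:
        bright = rng.lognormal(mu_pos, 0.6, n_events)
        auto = rng.lognormal(math.log(20.0), 0.5, n_events)
        return np.maximum(np.where(positive, bright + auto, auto), 0.0)

    data = pd.DataFrame(
        {
            "BL1": intensity(gfp_pos, math.log(3000.0)),
            "VL1": intensity(transfected, math.log(3000.0)),
        }
    )
    labels = pd.DataFrame({"transfected": transfected, "gfp_positive": gfp_pos})
    table = EventTable(data, sample_id=f"sce_seed{seed}", cocktail="none")
    return SimulatedSample(table, labels)


@dataclass(frozen=True)
class CellCycleTruth:
    """Ground truth of a DNA-content + marker staining experiment.

    DNA content: G1 events are Normal(g1_position, cv * g1_position), G2/M
    events Normal(2 * g1_position, cv * 2 * g1_position), S events uniform
    between the modes. Marker intensity is a two-component lognormal, with
    the positive component drawn per event with a phase-dependent
    probability.
    """

    g1_position: float = 50_000.0
    cv: float = 0.04
    phase_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    marker_positive_prob: dict[str, float] = field(
        default_factory=lambda: {"G1": 0.02, "S": 0.02, "G2M": 0.02}
    )
    marker_mu_pos: float = math.log(5000.0)
    marker_mu_neg: float = math.log(100.0)
    marker_sigma: float = 0.5
    n_events: int = 50_000
    seed: int = 0
    dna_channel: str = "YL1"
    marker_channel: str = "RL1"

    def __post_init__(self) -> None:
        if self.g1_position <= 0 or self.cv <= 0 or self.marker_sigma <= 0:
            raise ValueError("g1_position, cv and marker_sigma must be > 0")
        if abs(sum(self.phase_fractions) - 1.0) > 1e-9:
            raise ValueError(f"phase fractions must sum to 1: {self.phase_fractions}")
        if any(f < 0 for f in self.phase_fractions):
            raise ValueError("phase fractions must be non-negative")
        for ph, p in self.marker_positive_prob.items():
            if ph not in ("G1", "S", "G2M"):
                raise ValueError(f"unknown phase {ph!r}")
            _check_prob(f"marker_positive_prob[{ph}]", p)


def simulate_cell_cycle_sample(truth: CellCycleTruth) -> SimulatedSample:
    """Simulate a PI/DAPI DNA-content histogram with a co-stained marker."""
    rng = np.random.default_rng(truth.seed)
    n = truth.n_events
    phases = rng.choice(
        np.array(["G1", "S", "G2M"], dtype=object), size=n, p=list(truth.phase_fractions)
    )
    m1, m2 = truth.g1_position, 2.0 * truth.g1_position
    dna = np.empty(n)
    is_g1, is_s, is_g2 = (phases == p for p in ("G1", "S", "G2M"))
    dna[is_g1] = rng.normal(m1, truth.cv * m1, int(is_g1.sum()))
    dna[is_s] = rng.uniform(m1, m2, int(is_s.sum()))
    dna[is_g2] = rng.normal(m2, truth.cv * m2, int(is_g2.sum()))
    dna = np.maximum(dna, 0.0)

    p_pos = np.array([truth.marker_positive_prob.get(p, 0.0) for p in phases])
    positive = rng.random(n) < p_pos
    mu = np.where(positive, truth.marker_mu_pos, truth.marker_mu_neg)
    marker = rng.lognormal(mu, truth.marker_sigma)

    data = pd.DataFrame({truth.dna_channel: dna, truth.marker_channel: marker})
    labels = pd.DataFrame({"phase": phases, "marker_positive": positive})
    table = EventTable(data, sample_id=f"cellcycle_seed{truth.seed}", cocktail="none")
    return SimulatedSample(table, labels)
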