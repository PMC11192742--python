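"""Reporter-expression scoring statistics.

The central statistic compares total reporter fluorescence between the
damaged and undamaged cocktails, each normalized to the co-transfected
control plasmid:

    %Reporter Expression = 100 * X / Y
    X = (count_R * MFI_R) / (count_C * MFI_C)   in the damaged sample
    Y = (count_R * MFI_R) / (count_C * MFI_C)   in the undamaged sample

where counts and MFIs are taken over events gated positive on each
fluorophore's primary channel. Because count * MFI is the summed intensity of
the gated population, any common rescaling of a channel cancels between X
and Y, and a sample scored against itself returns exactly 100%.
"""

from __future__ import annotations

import math

import numpy as np

from .flow import PhaseLabels, gate_positive
from .model import (
    EventTable,
    GateSet,
    MarkerFractions,
    NormalizedScore,
    PanelSpec,
    ReporterScore,
)

__all__ = [
    "reporter_expression",
    "normalize_to_control",
    "sce_reporter_percent",
    "marker_fraction_by_phase",
    "ScoringError",
]


class ScoringError(ValueError):
    """A score cannot be formed (typically a zero-count control population)."""


def _count_mfi_product(count: int, mfi: float) -> float:
    return 0.0 if count == 0 else count * mfi


def reporter_expression(
    damaged: EventTable,
    undamaged: EventTable,
    panel: PanelSpec,
    gates: GateSet,
) -> list[ReporterScore]:
    """Score every pathway of the panel from a damaged/undamaged sample pair.

    Both tables must be gated against the same :class:`GateSet` (thresholds
    per detector channel). A zero-positive control population is an error; a
    zero Y yields an undefined (NaN) score flagged on the result.
    """
    ctrl_ch = panel.control_channel()
    ctrl = {}
    for label, table in (("damaged", damaged), ("undamaged", undamaged)):
        count, mfi = gate_positive(table, ctrl_ch, gates[ctrl_ch])
        if count == 0:
            raise ScoringError(
                f"no {panel.control_fluorophore}-positive events in "
                f"{label} sample {table.sample_id!r}"
            )
        ctrl[label] = (count, mfi)

    scores: list[ReporterScore] = []
    fl2ch = panel.fluorophore_channels
    for pathway in panel.scored_pathways:
        fluor = panel.pathway_fluorophore(pathway)
        ch = fl2ch[fluor]
        dam = gate_positive(damaged, ch, gates[ch])
        und = gate_positive(undamaged, ch, gates[ch])
        x = _count_mfi_product(*dam) / _count_mfi_product(*ctrl["damaged"])
        y = _count_mfi_product(*und) / _count_mfi_product(*ctrl["undamaged"])
        percent = 100.0 * (x / y) if y > 0 else float("nan")
        scores.append(
            ReporterScore(
                pathway=pathway,
                percent_expression=percent,
                x_value=x,
                y_value=y,
                counts_and_mfi={
                    "reporter_damaged": dam,
                    "reporter_undamaged": und,
                    "control_damaged": ctrl["damaged"],
                    "control_undamaged": ctrl["undamaged"],
                },
                sample_id=f"{damaged.sample_id}|{undamaged.sample_id}",
            )
        )
    return scores


def normalize_to_control(
    scores: list[ReporterScore] | list[float],
    control_scores: list[ReporterScore] | list[float],
    treated_label: str = "treated",
    control_label: str = "control",
) -> NormalizedScore:
    """Fold change of mean %Reporter Expression over replicate sets.

    Accepts replicate :class:`ReporterScore` objects (which must share one
    pathway) or bare replicate percentages.
    """

    def unpack(vals) -> tuple[str, np.ndarray]:
        if vals and isinstance(vals[0], ReporterScore):
            pathways = {s.pathway for s in vals}
            if len(pathways) != 1:
                raise ScoringError(f"replicates mix pathways: {sorted(pathways)}")
            return pathways.pop(), np.array([s.percent_expression for s in vals], float)
        return "", np.asarray(vals, dtype=float)

    pw_t, treated = unpack(list(scores))
    pw_c, control = unpack(list(control_scores))
    if pw_t and pw_c and pw_t != pw_c:
        raise ScoringError(f"pathway mismatch: {pw_t} vs {pw_c}")
    if treated.size == 0 or control.size == 0:
        raise ScoringError("empty replicate set")
    if not (np.isfinite(treated).all() and np.isfinite(control).all()):
        raise ScoringError("undefined score among replicates")
    control_mean = float(control.mean())
    if control_mean <= 0:
        raise ScoringError(f"control mean must be > 0, got {control_mean}")
    return NormalizedScore(
        pathway=pw_t or pw_c,
        fold_change=float(treated.mean()) / control_mean,
        treated_label=treated_label,
        control_label=control_label,
    )


def sce_reporter_percent(
    sample: EventTable,
    gfp_threshold: float,
    bfp_threshold: float,
    background: EventTable | None = None,
    gfp_channel: str = "BL1",
    bfp_channel: str = "VL1",
) -> float:
    """Normalized %GFP of an integrated SceI reporter sample.

    100 x (GFP-positive count) / (BFP-positive count); BFP positivity tracks
    transfection efficiency. If a nuclease-free ``background`` sample is
    given, its normalized value is subtracted and the result floored at 0.
    """

    def pct(table: EventTable) -> float:
        gfp_n, _ = gate_positive(table, gfp_channel, gfp_threshold)
        bfp_n, _ = gate_positive(table, bfp_channel, bfp_threshold)
        if bfp_n == 0:
            raise ScoringError(f"no BFP-positive events in sample {table.sample_id!r}")
        return 100.0 * gfp_n / bfp_n

    value = pct(sample)
    if background is not None:
        value = max(value - pct(background), 0.0)
    return value


def marker_fraction_by_phase(
    table: EventTable,
    marker_channel: str,
    marker_threshold: float,
    phases: PhaseLabels,
) -> MarkerFractions:
    """Marker-positive fractions overall and per cell-cycle phase.

    Excluded events (debris/aggregate DNA content) are left out of both the
    overall and the per-phase fractions. A phase with zero gated events gets
    a NaN (missing) proportion rather than 0.
    """
    if len(phases.labels) != table.n_events:
        raise ValueError("phase labels do not cover the event table")
    marker = table.channel_values(marker_channel)
    positive = marker > marker_threshold
    kept = phases.labels != "excluded"
    total_kept = int(kept.sum())
    overall = float(positive[kept].sum() / total_kept) if total_kept else float("nan")

    per_phase: dict[str, float] = {}
    counts: dict[str, tuple[int, int]] = {}
    for phase in ("G1", "S", "G2M"):
        sel = phases.labels == phase
        n = int(sel.sum())
        pos = int(positive[sel].sum())
        counts[phase] = (pos, n)
        per_phase[phase] = pos / n if n else float("nan")
    return MarkerFractions(overall_fraction=overall, per_phase=per_phase, counts=counts)
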