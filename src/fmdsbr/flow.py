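"""Spillover estimation, compensation, threshold gating, cell-cycle gating.

Spillover is modeled as linear mixing: the signal on channel *c* is
``sum_f M[f, c] * E_f`` plus background, where ``E_f`` is the abundance of
fluorophore *f* and ``M`` has unit diagonal when rows/columns are aligned so
column *i* is fluorophore *i*'s primary detector. Single-color controls
identify each row of ``M`` up to the background, which is removed by median
subtraction before an origin-constrained least-squares slope fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import EventTable, GateSet, PanelSpec

__all__ = [
    "SpilloverMatrix",
    "PhaseLabels",
    "estimate_spillover",
    "compensate",
    "fit_threshold",
    "fit_gates",
    "gate_positive",
    "gate_cell_cycle",
    "InsufficientControlError",
]

PHASES = ("G1", "S", "G2M")


class InsufficientControlError(ValueError):
    """A control sample has too few events to support the requested fit."""


@dataclass(frozen=True)
class SpilloverMatrix:
    """Fluorophore (rows) x detector channel (columns) mixing coefficients.

    Column ``i`` is the primary channel of fluorophore ``i``, so the diagonal
    is 1 and off-diagonals are spillover fractions in [0, 1).
    """

    matrix: np.ndarray
    fluorophores: tuple[str, ...]
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (len(self.fluorophores), len(self.channels)):
            raise ValueError("spillover matrix shape does not match labels")
        if m.shape[0] != m.shape[1]:
            raise ValueError("spillover matrix must be square over primary channels")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("spillover diagonal must be 1 (primary-channel convention)")
        off = m[~np.eye(m.shape[0], dtype=bool)]
        if np.any(off < 0) or np.any(off >= 1):
            raise ValueError("off-diagonal spillover must lie in [0, 1)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.fluorophores),
                            columns=list(self.channels))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SpilloverMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(frame.to_numpy(), tuple(frame.index), tuple(frame.columns))


@dataclass(frozen=True)
class PhaseLabels:
    """Per-event cell-cycle phase calls and the DNA-content boundaries used."""

    labels: np.ndarray  # array of {"G1","S","G2M","excluded"}
    boundaries: tuple[float, float, float, float]  # window low, G1/S, S/G2M, window high
    g2m_peak_found: bool = True

    def __post_init__(self) -> None:
        b = self.boundaries
        if not all(b[i] < b[i + 1] for i in range(3)):
            raise ValueError(f"phase boundaries must be strictly increasing: {b}")

    def fractions(self) -> dict[str, float]:
        """Phase fractions among non-excluded events."""
        kept = self.labels != "excluded"
        n = int(kept.sum())
        if n == 0:
            return {p: float("nan") for p in PHASES}
        return {p: float(np.sum(self.labels == p)) / n for p in PHASES}


def estimate_spillover(
    controls: dict[str, EventTable],
    negative: EventTable,
    panel: PanelSpec,
    min_positive: int = 100,
    positive_quantile: float = 0.999,
    robust: bool = False,
) -> SpilloverMatrix:
    """Estimate the mixing matrix from single-color controls.

    For each fluorophore's control, events above the negative control's
    ``positive_quantile`` on the primary channel are selected; each
    off-channel coefficient is the slope (through the origin) of the
    median-background-subtracted off-channel signal on the subtracted primary
    signal. ``robust=True`` uses a Theil-Sen slope instead of least squares.
    """
    fl2ch = panel.fluorophore_channels
    fluors = tuple(fl2ch)
    channels = tuple(fl2ch[f] for f in fluors)
    missing = [f for f in fluors if f not in controls]
    if missing:
        raise ValueError(f"missing single-color control(s) for: {missing}")

    bg = {ch: float(np.median(negative.channel_values(ch))) for ch in channels}
    m = np.eye(len(fluors))
    for i, fluor in enumerate(fluors):
        ctrl = controls[fluor]
        primary = ctrl.channel_values(channels[i])
        cutoff = float(np.quantile(negative.channel_values(channels[i]), positive_quantile))
        pos = primary > cutoff
        if int(pos.sum()) < min_positive:
            raise InsufficientControlError(
                f"{fluor}: {int(pos.sum())} positive events (< {min_positive})"
            )
        x = primary[pos] - bg[channels[i]]
        for j, ch in enumerate(channels):
            if j == i:
                continue
            y = ctrl.channel_values(ch)[pos] - bg[ch]
            if robust:
                slope = float(sps.theilslopes(y, x).slope)
            else:
                denom = float(np.dot(x, x))
                slope = float(np.dot(x, y) / denom) if denom > 0 else 0.0
            m[i, j] = max(slope, 0.0)
    return SpilloverMatrix(m, fluors, channels)


def compensate(table: EventTable, spillover: SpilloverMatrix) -> EventTable:
    """Unmix observed channel signals into per-fluorophore abundance estimates.

    Solves ``observed = abundance @ M`` per event over the spillover's channel
    set; untouched channels pass through. Compensated values may be negative.
    """
    cols = list(spillover.channels)
    missing = [c for c in cols if c not in table.channels]
    if missing:
        raise ValueError(f"table lacks channels required for compensation: {missing}")
    m = spillover.matrix
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"spillover matrix is singular or ill-conditioned (cond={cond:.3g})"
        )
    observed = table.data[cols].to_numpy(dtype=float)
    unmixed = np.linalg.solve(m.T, observed.T).T
    out = table.data.copy()
    out[cols] = unmixed
    return EventTable(out, sample_id=table.sample_id, cocktail=table.cocktail)


def fit_threshold(
    negative: EventTable,
    channel: str,
    quantile: float = 0.999,
    min_events: int = 1000,
) -> float:
    """Positive/negative cutoff: a high quantile of the negative control."""
    if negative.n_events < min_events:
        raise InsufficientControlError(
            f"negative control has {negative.n_events} events (< {min_events})"
        )
    if not 0 < quantile <= 1:
        raise ValueError(f"quantile must be in (0, 1], got {quantile}")
    return float(np.quantile(negative.channel_values(channel), quantile))


def fit_gates(
    negative: EventTable,
    channels: list[str],
    quantile: float = 0.999,
    min_events: int = 1000,
) -> GateSet:
    """Fit one positive threshold per channel from the negative control."""
    thresholds = {ch: fit_threshold(negative, ch, quantile, min_events) for ch in channels}
    prov = {ch: f"q{quantile} of negative control {negative.sample_id!r}" for ch in channels}
    return GateSet(thresholds, prov)


def gate_positive(table: EventTable, channel: str, threshold: float) -> tuple[int, float]:
    """Count events strictly above ``threshold`` and their mean intensity.

    Returns ``(0, nan)`` when nothing gates positive; the missing MFI must be
    handled downstream (scores divide by it loudly, never silently).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    values = table.channel_values(channel)
    pos = values > threshold
    count = int(pos.sum())
    mfi = float(values[pos].mean()) if count else float("nan")
    return count, mfi


# --------------------------------------------------------------------------
# DNA-content cell-cycle gating
# --------------------------------------------------------------------------

def _kde_peak(
    kde: sps.gaussian_kde, lo: float, hi: float, n_grid: int = 512
) -> tuple[float, float]:
    """Location and height of the dominant density peak in [lo, hi]."""
    grid = np.linspace(lo, hi, n_grid)
    dens = kde(grid)
    k = int(np.argmax(dens))
    return float(grid[k]), float(dens[k])


def _refine_peak(
    kde: sps.gaussian_kde,
    mode0: float,
    plateau: float,
    bandwidth: float,
    s_side: str,
) -> tuple[float, float, float]:
    """Refine a DNA-content peak that borders the S-phase plateau.

    The S plateau ends at the peak mode, so near the peak the smoothed
    density is (Gaussian) + plateau * Phi(+-(x - mode)/bandwidth). That step
    is subtracted before re-locating the mode and measuring the half-width at
    half maximum on the plateau-free side; the kernel width is then
    deconvolved (smoothed peak variance = sigma^2 + bandwidth^2).
    Returns (mode, sigma, peak height above the plateau step).
    """
    sign = 1.0 if s_side == "right" else -1.0
    mode = mode0
    for _ in range(2):  # subtracting the step moves the mode; iterate once
        grid = np.linspace(mode - 4 * bandwidth, mode + 4 * bandwidth, 161)
        g = kde(grid) - plateau * sps.norm.cdf(sign * (grid - mode) / bandwidth)
        k = int(np.argmax(g))
        mode, height = float(grid[k]), float(g[k])
    if height <= 0:
        return mode, 1e-12 * max(abs(mode), 1.0), 0.0
    # half-max crossing scanned outward on the clean side
    direction = -sign
    steps = mode + direction * np.linspace(0.0, max(12 * bandwidth, 0.3 * abs(mode)), 256)
    dsteps = kde(steps) - plateau * sps.norm.cdf(sign * (steps - mode) / bandwidth)
    below = np.nonzero(dsteps < height / 2)[0]
    if below.size:
        j = max(int(below[0]), 1)
        x0, x1 = steps[j - 1], steps[j]
        d0, d1 = dsteps[j - 1], dsteps[j]
        frac = (height / 2 - d0) / (d1 - d0) if d1 != d0 else 0.5
        hwhm = abs(x0 + frac * (x1 - x0) - mode)
    else:
        hwhm = float(steps[-1] - mode) * direction
    sigma = abs(hwhm) / math.sqrt(2.0 * math.log(2.0))
    sigma = math.sqrt(max(sigma**2 - bandwidth**2, (0.25 * sigma) ** 2))
    return mode, max(sigma, 1e-12 * max(abs(mode), 1.0)), height


def _balanced_offset(f_peak: float, f_s: float, sigma: float, span: float) -> float:
    """Gate offset c (in peak sigmas) balancing misclassification.

    The boundary between a Gaussian phase peak (weight ``f_peak``, width
    ``sigma``) and the flat S plateau (weight ``f_s`` spread over ``span``) is
    placed at mode + c*sigma where the expected S leakage into the gate,
    f_s * c * sigma / span, equals the expected Gaussian tail loss,
    f_peak * (1 - Phi(c)). Falls back to wide gates when S is empty.
    """
    lo_c, hi_c = 0.5, 4.0
    if f_s <= 0 or sigma <= 0 or span <= 0 or f_peak <= 0:
        return hi_c

    def imbalance(c: float) -> float:
        return f_s * c * sigma / span - f_peak * sps.norm.sf(c)

    if imbalance(hi_c) <= 0:
        return hi_c
    if imbalance(lo_c) >= 0:
        return lo_c
    from scipy.optimize import brentq

    return float(brentq(imbalance, lo_c, hi_c, xtol=1e-4))


def gate_cell_cycle(
    table: EventTable,
    dna_channel: str,
    min_events: int = 5000,
) -> PhaseLabels:
    """Call G1/S/G2M phases from a DNA-content histogram.

    The G1 mode is the dominant smoothed-density peak in the lower half of
    the distribution; the G2/M mode is searched in [1.8, 2.2] x G1. Events
    outside [0.75, 2.5] x G1 mode are excluded as debris/aggregates. The
    G1/S and S/G2M boundaries are placed where the expected misclassification
    of the Gaussian peak tail balances the leakage of the flat S-phase
    plateau under the gate. If no G2/M peak exists, the S/G2M boundary falls
    back to 1.5 x G1 mode and the result is flagged.
    """
    if table.n_events < min_events:
        raise InsufficientControlError(
            f"cell-cycle gating needs >= {min_events} events, got {table.n_events}"
        )
    x = table.channel_values(dna_channel)
    x = x[np.isfinite(x) & (x > 0)]
    kde = sps.gaussian_kde(x, bw_method="silverman")
    bandwidth = float(kde.factor * np.std(x, ddof=1))

    q_lo, q_hi = np.quantile(x, [0.001, 0.999])
    g1_rough, g1_height = _kde_peak(kde, float(q_lo), float(q_lo + 0.6 * (q_hi - q_lo)))

    lo_win, hi_win = 0.75 * g1_rough, 2.5 * g1_rough
    g2_lo, g2_hi = 1.8 * g1_rough, 2.2 * g1_rough
    g2_rough, g2_height = _kde_peak(kde, g2_lo, g2_hi)
    # a real G2/M peak is an interior maximum clearly above the S plateau
    mid = 0.5 * (g1_rough + g2_rough)
    plateau = float(kde(np.array([mid]))[0])
    interior = g2_lo + 0.02 * g1_rough < g2_rough < g2_hi - 0.02 * g1_rough
    g2m_found = bool(
        interior and g2_height > 1.5 * plateau and g2_height > 0.02 * g1_height
    )

    g1_mode, g1_sigma, _ = _refine_peak(
        kde, g1_rough, plateau if g2m_found else 0.0, bandwidth, s_side="right"
    )
    if g2m_found:
        g2_mode, g2_sigma, _ = _refine_peak(kde, g2_rough, plateau, bandwidth, s_side="left")
        mid = 0.5 * (g1_mode + g2_mode)
        span = g2_mode - g1_mode
        # phase weights for the balance equations, from coarse windows
        n_win = max(int(np.sum((x >= lo_win) & (x <= hi_win))), 1)
        f_s = plateau * span  # plateau height x width, density-normalized
        f_g1 = float(np.sum((x >= lo_win) & (x < mid))) / n_win - f_s / 2
        f_g2 = float(np.sum((x >= mid) & (x <= hi_win))) / n_win - f_s / 2
        c1 = _balanced_offset(max(f_g1, 0.0), f_s, g1_sigma, span)
        c2 = _balanced_offset(max(f_g2, 0.0), f_s, g2_sigma, span)
        b_g1s = min(g1_mode + c1 * g1_sigma, mid)
        b_sg2 = max(g2_mode - c2 * g2_sigma, mid + 1e-9 * g1_mode)
    else:
        b_g1s = g1_mode + 2.0 * g1_sigma
        b_sg2 = 1.5 * g1_mode

    values = table.channel_values(dna_channel)
    labels = np.full(table.n_events, "excluded", dtype=object)
    inside = (values >= lo_win) & (values <= hi_win) & np.isfinite(values)
    labels[inside & (values <= b_g1s)] = "G1"
    labels[inside & (values > b_g1s) & (values < b_sg2)] = "S"
    labels[inside & (values >= b_sg2)] = "G2M"
    return PhaseLabels(labels, (lo_win, float(b_g1s), float(b_sg2), hi_win), g2m_found)
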