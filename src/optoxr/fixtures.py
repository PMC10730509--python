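"""Deterministic synthetic fixtures for every pipeline input.

Toy GPCRs with known topology, simulated plate-reader traces with known 4PL
truth, behavior count tables with known expected indices, and fluorescence
traces with known peak ΔF/F.  Every generator is a pure function of its
parameters plus a seed (a fresh ``numpy`` Generator per call, never global
state), so reruns are byte-identical.

Transmembrane segments are drawn from a hydrophobic-biased residue pool and
loops from a polar pool, so toy receptor pairs align the way real topologies
do: helices anchor the alignment and length variation concentrates in loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .align import global_align
from .assay import PlateTraceSet, WellTrace, four_param_logistic
from .behavior import BehaviorCounts, FluorescenceTrace, TrackTable
from .topology import (
    CANONICAL_SEGMENT_ORDER,
    ProteinSequence,
    Segment,
    TopologyAnnotation,
)

#: Residue pools: hydrophobic-biased for TM helices, polar for loops/termini.
TM_POOL = "AVILMFWGC"
LOOP_POOL = "DEKRNQSTHPGY"

#: Default toy receptor segment lengths (residues).  Compact but large enough
#: that every canonical segment exists and flanking offsets stay inside TMs.
DEFAULT_SEGMENT_LENGTHS: dict[str, int] = {
    "NTERM": 8,
    "TM1": 12, "ICL1": 6, "TM2": 12, "ECL1": 6,
    "TM3": 12, "ICL2": 8, "TM4": 12, "ECL2": 8,
    "TM5": 12, "ICL3": 12, "TM6": 12, "ECL3": 6,
    "TM7": 12, "H8": 6, "CTERM": 10,
}


class FixtureError(ValueError):
    """Raised for invalid generator specifications."""


@dataclass(frozen=True)
class ToyReceptorSpec:
    """Specification of a synthetic receptor with known topology."""

    segment_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_LENGTHS)
    )
    seed: int = 0
    sequence_id: str = "toy"

    def __post_init__(self) -> None:
        for name, length in self.segment_lengths.items():
            if name not in CANONICAL_SEGMENT_ORDER:
                raise FixtureError(f"unknown segment {name!r}")
            if length < 1:
                raise FixtureError(f"segment {name} has zero length")
        total = sum(self.segment_lengths.values())
        if total < 15:
            raise FixtureError(f"total receptor length {total} < 15")


def _segment_pool(name: str) -> str:
    return TM_POOL if name.startswith("TM") or name == "H8" else LOOP_POOL


def make_toy_gpcr(spec: ToyReceptorSpec) -> tuple[ProteinSequence, TopologyAnnotation]:
    """Generate a toy receptor sequence and its exact topology annotation."""
    rng = np.random.default_rng(spec.seed)
    residues: list[str] = []
    segments: list[Segment] = []
    pos = 1
    for name in CANONICAL_SEGMENT_ORDER:
        if name not in spec.segment_lengths:
            continue
        length = spec.segment_lengths[name]
        pool = _segment_pool(name)
        residues.extend(pool[i] for i in rng.integers(0, len(pool), size=length))
        segments.append(Segment(name, pos, pos + length - 1))
        pos += length
    seq = ProteinSequence(id=spec.sequence_id, residues="".join(residues))
    topo = TopologyAnnotation(sequence_id=spec.sequence_id, segments=tuple(segments))
    return seq, topo


def make_toy_pair(
    seed: int,
    segment_lengths: Optional[Mapping[str, int]] = None,
    sub_rate_tm: float = 0.1,
    sub_rate_loop: float = 0.3,
    max_loop_indel: int = 2,
):
    """Generate a homologous backbone/target pair plus their alignment.

    The target derives from the backbone segment by segment: point
    substitutions everywhere (more in loops than helices, as in real
    receptor families) and small length changes confined to loops and
    termini.  Returns ``(backbone, backbone_topology, target,
    target_true_topology, column_map)`` where the column map comes from the
    package's own global aligner.
    """
    rng = np.random.default_rng(seed)
    backbone, topo = make_toy_gpcr(
        ToyReceptorSpec(
            segment_lengths=dict(segment_lengths or DEFAULT_SEGMENT_LENGTHS),
            seed=int(rng.integers(0, 2**31 - 1)),
            sequence_id=f"backbone{seed}",
        )
    )
    target_residues: list[str] = []
    target_segments: list[Segment] = []
    pos = 1
    for seg in topo.segments:
        chunk = list(backbone.residues[seg.start - 1 : seg.end])
        pool = _segment_pool(seg.name)
        rate = sub_rate_tm if pool is TM_POOL else sub_rate_loop
        for i in range(len(chunk)):
            if rng.random() < rate:
                chunk[i] = pool[rng.integers(0, len(pool))]
        if pool is LOOP_POOL and max_loop_indel > 0:
            delta = int(rng.integers(-max_loop_indel, max_loop_indel + 1))
            if delta > 0:
                insert_at = int(rng.integers(0, len(chunk) + 1))
                extra = [pool[i] for i in rng.integers(0, len(pool), size=delta)]
                chunk[insert_at:insert_at] = extra
            elif delta < 0 and len(chunk) + delta >= 2:
                cut_at = int(rng.integers(0, len(chunk) + delta))
                del chunk[cut_at : cut_at - delta]
        target_residues.extend(chunk)
        target_segments.append(Segment(seg.name, pos, pos + len(chunk) - 1))
        pos += len(chunk)
    target = ProteinSequence(id=f"target{seed}", residues="".join(target_residues))
    target_topo = TopologyAnnotation(sequence_id=target.id,
                                     segments=tuple(target_segments))
    colmap = global_align(backbone, target)
    return backbone, topo, target, target_topo, colmap


# ---------------------------------------------------------------------------
# Plate-reader simulations


@dataclass(frozen=True)
class PlateSimSpec:
    """Ground truth for a simulated dose-response (or intensity-response) plate.

    ``bottom`` is the normalized baseline fold-change (1 = no response) and
    ``top`` the saturating fold-change, mirroring the structure of
    cAMP-reporter responses; ``noise_sd`` is the relative (multiplicative)
    Gaussian noise level on each read.
    """

    doses: tuple[float, ...]
    bottom: float = 1.0
    top: float = 10.0
    ec50: float = 50.0
    hill: float = 1.0
    noise_sd: float = 0.0
    baseline_level: float = 1000.0
    baseline_reads: int = 3
    post_reads: int = 12
    replicates: int = 3
    seed: int = 0
    dose_field: str = "ligand_nM"  # or "intensity_uW_cm2"

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.doses)
        object.__setattr__(self, "doses", doses)
        if not doses or any(d <= 0 for d in doses):
            raise FixtureError("doses must be positive")
        if not (min(doses) <= self.ec50 <= max(doses)):
            raise FixtureError("ec50 must lie within the dose range")
        if self.noise_sd < 0:
            raise FixtureError("noise_sd must be non-negative")
        if self.baseline_level <= 0:
            raise FixtureError("baseline_level must be positive")
        if self.dose_field not in ("ligand_nM", "intensity_uW_cm2"):
            raise FixtureError(f"unknown dose_field {self.dose_field!r}")


def _noisy(rng: np.random.Generator, level: float, sd: float, size: int) -> np.ndarray:
    reads = level * (1.0 + sd * rng.standard_normal(size))
    return np.clip(reads, 1e-9, None)  # luminescence stays positive


def simulate_plate(spec: PlateSimSpec) -> PlateTraceSet:
    """Simulate one well per dose and replicate.

    Baseline reads sit at ``baseline_level``; post-stimulus reads are scaled
    by the 4PL fold-change at the well's dose.  With ``noise_sd = 0`` the
    normalized RLU maximum equals the 4PL fold-change exactly.
    """
    rng = np.random.default_rng(spec.seed)
    wells: list[WellTrace] = []
    n_reads = spec.baseline_reads + spec.post_reads
    times = np.arange(n_reads, dtype=float)
    for rep in range(spec.replicates):
        for d in spec.doses:
            fold = float(
                four_param_logistic(d, spec.bottom, spec.top, spec.ec50, spec.hill)
            )
            baseline = _noisy(rng, spec.baseline_level, spec.noise_sd,
                              spec.baseline_reads)
            post = _noisy(rng, spec.baseline_level * fold, spec.noise_sd,
                          spec.post_reads)
            meta = {spec.dose_field: d}
            wells.append(
                WellTrace(
                    well=f"d{d:g}_r{rep}",
                    times_s=times,
                    luminescence=np.concatenate([baseline, post]),
                    receptor="toy_optoxr",
                    g_alpha="s",
                    baseline_reads=spec.baseline_reads,
                    **meta,
                )
            )
    return PlateTraceSet(wells=wells)


def simulate_spectrum(
    wavelengths: Sequence[float] = (385.0, 425.0, 470.0, 525.0, 595.0),
    peak_nm: float = 470.0,
    width_nm: float = 60.0,
    max_fold: float = 8.0,
    baseline_level: float = 1000.0,
    baseline_reads: int = 3,
    post_reads: int = 12,
    replicates: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PlateTraceSet:
    """Simulate an action-spectrum plate with a Gaussian sensitivity profile."""
    rng = np.random.default_rng(seed)
    wells: list[WellTrace] = []
    n_reads = baseline_reads + post_reads
    times = np.arange(n_reads, dtype=float)
    for rep in range(replicates):
        for w in wavelengths:
            fold = 1.0 + (max_fold - 1.0) * float(
                np.exp(-((w - peak_nm) ** 2) / (2.0 * width_nm**2))
            )
            baseline = _noisy(rng, baseline_level, noise_sd, baseline_reads)
            post = _noisy(rng, baseline_level * fold, noise_sd, post_reads)
            wells.append(
                WellTrace(
                    well=f"w{w:g}_r{rep}",
                    times_s=times,
                    luminescence=np.concatenate([baseline, post]),
                    receptor="toy_optoxr",
                    g_alpha="s",
                    wavelength_nm=float(w),
                    baseline_reads=baseline_reads,
                )
            )
    return PlateTraceSet(wells=wells)


# ---------------------------------------------------------------------------
# Behavior simulations


def simulate_behavior_counts(
    p_odor: float, p_blank: float, n: int, seed: int = 0
) -> BehaviorCounts:
    """Multinomial draw of (odor side, blank side, middle zone) occupancy."""
    if not (0 <= p_odor <= 1 and 0 <= p_blank <= 1 and p_odor + p_blank <= 1):
        raise FixtureError("invalid side probabilities")
    rng = np.random.default_rng(seed)
    n_odor, n_blank, _ = rng.multinomial(n, [p_odor, p_blank, 1 - p_odor - p_blank])
    return BehaviorCounts(n_total=n, n_odor=int(n_odor), n_blank=int(n_blank))


def simulate_tracks(
    n_animals: int = 5,
    duration_s: float = 30.0,
    frame_rate_hz: float = 10.0,
    speed_mm_s: float = 1.0,
    turn_sd_deg: float = 10.0,
    seed: int = 0,
) -> TrackTable:
    """Correlated random walks emulating tracked larval centroids."""
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * frame_rate_hz))
    rows = []
    for animal in range(n_animals):
        heading = rng.uniform(0, 2 * np.pi)
        x, y = rng.uniform(0, 50, size=2)
        for frame in range(n_frames):
            turn = rng.normal(0.0, np.deg2rad(turn_sd_deg))
            heading += turn
            step = speed_mm_s / frame_rate_hz
            x += step * np.cos(heading)
            y += step * np.sin(heading)
            rows.append(
                {
                    "animal_id": animal,
                    "frame": frame,
                    "time_s": frame / frame_rate_hz,
                    "x_mm": x,
                    "y_mm": y,
                    "bending_deg": np.rad2deg(abs(turn)),
                }
            )
    return TrackTable(frames=pd.DataFrame(rows), frame_rate_hz=frame_rate_hz)


def simulate_fluorescence(
    f0: float = 100.0,
    peak_dff: float = 0.5,
    decay_tau_s: float = 20.0,
    baseline_frames: int = 95,
    frame_rate_hz: float = 7.5,
    n_frames: int = 600,
    rise_frames: int = 8,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FluorescenceTrace:
    """Baseline, linear rise to ``peak_dff``, then exponential decay.

    The peak is attained exactly at the end of the rise, so on a noiseless
    trace ``dff_trace`` recovers ``peak_dff`` to machine precision.
    """
    if f0 <= 0 or decay_tau_s <= 0 or frame_rate_hz <= 0:
        raise FixtureError("f0, decay_tau_s and frame_rate_hz must be positive")
    if baseline_frames >= n_frames:
        raise FixtureError("baseline_frames must be shorter than the trace")
    rng = np.random.default_rng(seed)
    dff = np.zeros(n_frames)
    stim = baseline_frames
    rise_end = min(stim + max(rise_frames, 1), n_frames)
    ramp = np.linspace(0.0, 1.0, rise_end - stim + 1)[1:]
    dff[stim:rise_end] = peak_dff * ramp
    if rise_end < n_frames:
        k = np.arange(n_frames - rise_end)
        dff[rise_end:] = peak_dff * np.exp(-(k + 1) / (decay_tau_s * frame_rate_hz))
    frames = f0 * (1.0 + dff)
    if noise_sd > 0:
        frames = frames * (1.0 + noise_sd * rng.standard_normal(n_frames))
    return FluorescenceTrace(frames=frames, baseline_frames=baseline_frames,
                             stimulus_start=stim)
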