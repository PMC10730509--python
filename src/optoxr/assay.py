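"""Quantification of photoreceptor cell assays.

Covers the standard in vitro readouts used to characterize optoXR signaling:

* cAMP-reporter luminescence traces from the chimeric-Gα ("Gsx") assay, in
  which coupling of any Gα family is redirected to a common cAMP readout.
  Each well is normalized to its own pre-stimulus baseline and summarized by
  the maximum post-stimulus fold-change ("relative light units", RLU).
* Dose-response / light-intensity-response curves fitted with the
  four-parameter logistic (4PL) model
  ``response(d) = bottom + (top - bottom) / (1 + (ec50 / d) ** hill)``.
* Action spectra: per-wavelength summaries of RLU maxima with the peak
  wavelength.
* BRET2 ratios (GFP2 acceptor / RLuc8 donor) and baseline-subtracted
  delta-BRET for G-protein dissociation biosensors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import lmfit
import numpy as np
import pandas as pd

DEFAULT_BASELINE_READS = 3

G_ALPHA_FAMILIES = ("s", "i", "t", "o", "z", "q", "12", "13", "15", "none")


class AssayError(ValueError):
    """Raised for invalid plate data or failed preconditions."""


@dataclass
class WellTrace:
    """One well's luminescence time series plus experimental metadata."""

    well: str
    times_s: np.ndarray
    luminescence: np.ndarray
    receptor: str = ""
    g_alpha: str = "none"
    wavelength_nm: Optional[float] = None
    intensity_uW_cm2: Optional[float] = None
    ligand_nM: Optional[float] = None
    baseline_reads: int = DEFAULT_BASELINE_READS
    stimulus_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.luminescence = np.asarray(self.luminescence, dtype=float)
        if self.stimulus_index is None:
            self.stimulus_index = self.baseline_reads
        if self.g_alpha not in G_ALPHA_FAMILIES:
            raise AssayError(f"well {self.well}: unknown g_alpha {self.g_alpha!r}")
        if self.baseline_reads < 1:
            raise AssayError(f"well {self.well}: baseline_reads must be positive")
        if len(self.times_s) != len(self.luminescence):
            raise AssayError(f"well {self.well}: times and luminescence differ in length")
        if len(self.luminescence) < self.baseline_reads + 1:
            raise AssayError(
                f"well {self.well}: trace shorter than baseline_reads + 1"
            )
        if self.stimulus_index < self.baseline_reads:
            raise AssayError(f"well {self.well}: stimulus before end of baseline")
        if np.any(np.diff(self.times_s) <= 0):
            raise AssayError(f"well {self.well}: times not strictly increasing")
        if np.any(self.luminescence < 0):
            raise AssayError(f"well {self.well}: negative luminescence")


@dataclass
class PlateTraceSet:
    """A collection of well traces from one plate-reader run."""

    wells: list[WellTrace]

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        baseline_reads: int = DEFAULT_BASELINE_READS,
        stimulus_index: Optional[int] = None,
    ) -> "PlateTraceSet":
        """Read a long-format CSV with columns ``well,time_s,lum`` plus
        optional metadata columns (receptor, g_alpha, wavelength_nm,
        intensity_uW_cm2, ligand_nM)."""
        df = pd.read_csv(path)
        required = {"well", "time_s", "lum"}
        if not required.issubset(df.columns):
            raise AssayError(f"plate CSV must contain columns {sorted(required)}")
        wells = []
        for well, group in df.groupby("well", sort=True):
            group = group.sort_values("time_s")
            meta = group.iloc[0]

            def _opt(col):
                if col not in group.columns or pd.isna(meta[col]):
                    return None
                return float(meta[col])

            wells.append(
                WellTrace(
                    well=str(well),
                    times_s=group["time_s"].to_numpy(),
                    luminescence=group["lum"].to_numpy(),
                    receptor=str(meta.get("receptor", "")),
                    g_alpha=str(meta["g_alpha"]) if "g_alpha" in group.columns else "none",
                    wavelength_nm=_opt("wavelength_nm"),
                    intensity_uW_cm2=_opt("intensity_uW_cm2"),
                    ligand_nM=_opt("ligand_nM"),
                    baseline_reads=baseline_reads,
                    stimulus_index=stimulus_index,
                )
            )
        return cls(wells=wells)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for w in self.wells:
            for t, lum in zip(w.times_s, w.luminescence):
                rows.append(
                    {
                        "well": w.well,
                        "time_s": t,
                        "lum": lum,
                        "receptor": w.receptor,
                        "g_alpha": w.g_alpha,
                        "wavelength_nm": w.wavelength_nm,
                        "intensity_uW_cm2": w.intensity_uW_cm2,
                        "ligand_nM": w.ligand_nM,
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class NormalizedTrace:
    """A baseline-normalized well trace and its RLU maximum."""

    well: str
    values: np.ndarray
    rlu_max: float
    baseline_reads: int
    stimulus_index: int
    wavelength_nm: Optional[float] = None
    intensity_uW_cm2: Optional[float] = None
    ligand_nM: Optional[float] = None
    g_alpha: str = "none"
    receptor: str = ""


def normalize_wells(plate: PlateTraceSet) -> list[NormalizedTrace]:
    """Normalize each well to its pre-stimulus baseline mean.

    ``values[i] = lum[i] / mean(lum[:baseline_reads])``; ``rlu_max`` is the
    maximum normalized value at or after the stimulus read.  A non-positive
    baseline mean is an error naming the offending well.
    """
    out = []
    for w in plate.wells:
        baseline = float(np.mean(w.luminescence[: w.baseline_reads]))
        if baseline <= 0:
            raise AssayError(f"well {w.well}: baseline mean is not positive")
        values = w.luminescence / baseline
        rlu_max = float(np.max(values[w.stimulus_index :]))
        out.append(
            NormalizedTrace(
                well=w.well,
                values=values,
                rlu_max=rlu_max,
                baseline_reads=w.baseline_reads,
                stimulus_index=w.stimulus_index,
                wavelength_nm=w.wavelength_nm,
                intensity_uW_cm2=w.intensity_uW_cm2,
                ligand_nM=w.ligand_nM,
                g_alpha=w.g_alpha,
                receptor=w.receptor,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Dose-response fitting


def four_param_logistic(dose, bottom, top, ec50, hill):
    """The 4PL model; at ``dose == ec50`` the response is ``(top+bottom)/2``."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / dose) ** hill)


@dataclass(frozen=True)
class DoseResponseFit:
    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float
    converged: bool

    def predict(self, dose):
        return four_param_logistic(dose, self.bottom, self.top, self.ec50, self.hill)


def fit_dose_response(
    doses: Sequence[float], responses: Sequence[float]
) -> DoseResponseFit:
    """Least-squares 4PL fit of responses against doses (or light intensities).

    Initialization is deterministic: ``bottom = min(response)``,
    ``top = max(response)``, ``ec50`` the dose whose response lies nearest
    the half-maximum, ``hill = 1``; ``ec50`` is bounded to
    ``[min(dose)/10, max(dose)*10]``.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise AssayError("doses and responses differ in length")
    if not (np.all(np.isfinite(doses)) and np.all(np.isfinite(responses))):
        raise AssayError("non-finite values in dose-response data")
    if np.any(doses <= 0):
        raise AssayError("doses must be positive")
    if len(np.unique(doses)) < 4:
        raise AssayError("at least 4 distinct dose levels are required")

    bottom0 = float(np.min(responses))
    top0 = float(np.max(responses))
    half = 0.5 * (bottom0 + top0)
    ec50_0 = float(doses[np.argmin(np.abs(responses - half))])

    model = lmfit.Model(four_param_logistic, independent_vars=["dose"])
    params = model.make_params(
        bottom=bottom0,
        top=top0,
        ec50=dict(value=ec50_0, min=float(doses.min()) / 10.0,
                  max=float(doses.max()) * 10.0),
        hill=1.0,
    )
    result = model.fit(responses, params, dose=doses)
    fitted = result.best_values
    rss = float(np.sum(np.square(result.residual)))
    return DoseResponseFit(
        bottom=float(fitted["bottom"]),
        top=float(fitted["top"]),
        ec50=float(fitted["ec50"]),
        hill=float(fitted["hill"]),
        rss=rss,
        converged=bool(result.success),
    )


# ---------------------------------------------------------------------------
# Action spectra


@dataclass(frozen=True)
class ActionSpectrum:
    """Per-wavelength RLU summaries plus the peak wavelength.

    ``peak_nm`` is the smallest wavelength achieving the maximum mean RLU
    (a fixed tie rule so the result is deterministic).
    """

    summary: pd.DataFrame  # index: wavelength_nm; columns: mean_rlu_max, sd, n
    peak_nm: float


def action_spectrum(plate: PlateTraceSet) -> ActionSpectrum:
    """Summarize RLU maxima by stimulation wavelength."""
    traces = normalize_wells(plate)
    rows = [
        {"wavelength_nm": t.wavelength_nm, "rlu_max": t.rlu_max}
        for t in traces
        if t.wavelength_nm is not None
    ]
    if not rows:
        raise AssayError("no wavelength metadata on this plate")
    df = pd.DataFrame(rows)
    if df["wavelength_nm"].nunique() < 2:
        raise AssayError("action spectrum requires at least 2 wavelengths")
    summary = (
        df.groupby("wavelength_nm")["rlu_max"]
        .agg(mean_rlu_max="mean", sd="std", n="count")
        .sort_index()
    )
    best = summary["mean_rlu_max"].max()
    peak = float(summary.index[summary["mean_rlu_max"] >= best][0])
    return ActionSpectrum(summary=summary, peak_nm=peak)


# ---------------------------------------------------------------------------
# BRET2 ratios


@dataclass
class BretTrace:
    """Donor (RLuc8) and acceptor (GFP2) emission time series for one well."""

    times_s: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    baseline_reads: int = DEFAULT_BASELINE_READS
    well: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (len(self.times_s) == len(self.donor) == len(self.acceptor)):
            raise AssayError("BRET trace arrays differ in length")
        if self.baseline_reads < 1 or self.baseline_reads > len(self.donor):
            raise AssayError("invalid baseline_reads for BRET trace")


@dataclass(frozen=True)
class BretResult:
    ratio: np.ndarray
    delta_bret: np.ndarray


def bret_ratio(trace: BretTrace) -> BretResult:
    """Acceptor/donor ratio and its change over the pre-stimulus baseline."""
    if np.any(trace.donor <= 0):
        bad = int(np.argmax(trace.donor <= 0))
        raise AssayError(
            f"donor emission non-positive at read {bad}"
            + (f" (well {trace.well})" if trace.well else "")
        )
    ratio = trace.acceptor / trace.donor
    baseline = float(np.mean(ratio[: trace.baseline_reads]))
    return BretResult(ratio=ratio, delta_bret=ratio - baseline)


def read_bret_csv(
    path: str | Path, baseline_reads: int = DEFAULT_BASELINE_READS
) -> list[BretTrace]:
    """Read a long-format BRET CSV with columns ``well,time_s,donor,acceptor``."""
    df = pd.read_csv(path)
    required = {"well", "time_s", "donor", "acceptor"}
    if not required.issubset(df.columns):
        raise AssayError(f"BRET CSV must contain columns {sorted(required)}")
    traces = []
    for well, group in df.groupby("well", sort=True):
        group = group.sort_values("time_s")
        traces.append(
            BretTrace(
                times_s=group["time_s"].to_numpy(),
                donor=group["donor"].to_numpy(),
                acceptor=group["acceptor"].to_numpy(),
                baseline_reads=baseline_reads,
                well=str(well),
            )
        )
    return traces
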