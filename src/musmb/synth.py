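"""Complete in-silico experiments: tracer runs, stand-alone desalting and
coupled SMB–MS runs with detector noise.

The generator chains the SMB simulator over feed sections (column states
carry over; MS acquisition continues across feed exchanges), renders a
conductivity detector on the extract/raffinate streams with the
instrument's linear calibrations, renders the ESI-MS detector on the
raffinate, and keeps a ground-truth table so analysis results can be
checked against what was actually simulated.

Scan rendering is streaming: each scan is synthesised, folded into the
extracted-ion chromatograms, the baseline trace and the per-switch mean
spectra, and discarded, so multi-hour runs do not hold every scan in
memory. A dense :class:`~musmb.ms.ScanSeries` is only stored on request.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .column import Chromatogram, ColumnState
from .exceptions import InsufficientDataError
from .ms import (
    HEME_MZ,
    TRIS_MZ,
    BASELINE_RANGE,
    MSSpeciesModel,
    ReconSpectrum,
    ScanSeries,
    Spectrum,
    SuppressionModel,
    charge_mz,
    default_species_models,
    mz_grid,
    peak_group_integral,
    reconstruct_protein,
    synthesize_spectrum,
)
from .smb import PAPER_RUN, SMBConfig, SMBResult, heterogeneous_columns, simulate_smb
from .transport import ColumnParams, SpeciesParams

__all__ = [
    "CalCurve",
    "EXTRACT_CAL",
    "RAFFINATE_CAL",
    "Section",
    "ExperimentPlan",
    "run1_plan",
    "run2_plan",
    "standalone_plan",
    "conductivity_to_conc",
    "conc_to_conductivity",
    "generate_conductivity_trace",
    "generate_run",
    "RunBundle",
    "MSProducts",
    "default_feed_species",
]


@dataclass(frozen=True)
class CalCurve:
    """Linear conductivity-to-concentration calibration.

    c[mM] = slope · κ[mS/cm] + intercept
    """

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


#: Calibrations of the two conductivity sensors (determined with 0–100 mM
#: Tris standards on the physical instrument).
EXTRACT_CAL = CalCurve(slope=15.359, intercept=0.3656)
RAFFINATE_CAL = CalCurve(slope=15.382, intercept=0.2993)


def conductivity_to_conc(kappa: float | np.ndarray, cal: CalCurve) -> float | np.ndarray:
    """Tris concentration (mM) from conductivity (mS/cm)."""
    k = np.asarray(kappa, dtype=float)
    if np.any(k < 0):
        raise ValueError("conductivity must be nonnegative")
    out = cal.slope * k + cal.intercept
    return float(out) if np.isscalar(kappa) else out


def conc_to_conductivity(conc: float | np.ndarray, cal: CalCurve) -> float | np.ndarray:
    """Inverse calibration; negative results are floored at zero."""
    c = np.asarray(conc, dtype=float)
    out = np.clip((c - cal.intercept) / cal.slope, 0.0, None)
    return float(out) if np.isscalar(conc) else out


def generate_conductivity_trace(
    smb: SMBResult | Chromatogram,
    cal: CalCurve,
    stream: str = "raffinate",
    species: str = "tris",
    noise_sd: float = 0.01,
    rng: Optional[np.random.Generator] = None,
) -> Chromatogram:
    """Synthetic conductivity sensor trace (mS/cm) of one outlet stream.

    κ(t) = (c(t) − intercept)/slope + Gaussian sensor noise, floored at 0.
    """
    chrom = getattr(smb, stream) if isinstance(smb, SMBResult) else smb
    kappa = conc_to_conductivity(chrom.trace(species), cal)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        kappa = kappa + rng.normal(0.0, noise_sd, size=kappa.shape)
    return Chromatogram(chrom.time, np.clip(kappa, 0.0, None), ["conductivity_mS_cm"])


# ---------------------------------------------------------------------------
# experiment plans


@dataclass(frozen=True)
class Section:
    """One feed composition held for ``n_cycles`` full SMB cycles."""

    tris_feed_mM: float
    mb_feed_gL: float
    n_cycles: int

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("each section needs at least one cycle")
        if self.tris_feed_mM < 0 or self.mb_feed_gL < 0:
            raise ValueError("feed concentrations must be nonnegative")


@dataclass(frozen=True)
class ExperimentPlan:
    """Feed schedule, seed and noise levels of one synthetic experiment."""

    sections: tuple[Section, ...]
    seed: int = 0
    conductivity_noise_sd: float = 0.01  # mS/cm
    ms_noise_scale: float = 1.0  # Poisson counts per cps; 0 disables
    apo_fraction: float = 0.08  # apoMb share of the fed myoglobin
    flow_stop_events: tuple[tuple[float, float], ...] = ()  # (t_start, duration) s

    def __post_init__(self) -> None:
        if not self.sections:
            raise ValueError("plan has no sections")
        if not 0.0 <= self.apo_fraction <= 1.0:
            raise ValueError("apo_fraction must lie in [0, 1]")

    @property
    def n_cycles(self) -> int:
        return sum(s.n_cycles for s in self.sections)


def run1_plan(seed: int = 0, cycles_first: int = 11, cycles_rest: int = 3) -> ExperimentPlan:
    """Step-wise Tris escalation: 0/1/5/10/50/100 mM at 0.2 g/L Mb.

    The Tris-free section runs long (default eleven cycles) to verify
    stability; every later concentration runs ``cycles_rest`` cycles.
    """
    concs = [0.0, 1.0, 5.0, 10.0, 50.0, 100.0]
    sections = tuple(
        Section(c, 0.2, cycles_first if i == 0 else cycles_rest) for i, c in enumerate(concs)
    )
    return ExperimentPlan(sections, seed=seed)


def run2_plan(seed: int = 0, n_cycles: int = 6) -> ExperimentPlan:
    """Constant 10 mM Tris / 0.2 g/L Mb feed, six cycles."""
    return ExperimentPlan((Section(10.0, 0.2, n_cycles),), seed=seed)


def standalone_plan(seed: int = 0, n_cycles: int = 8) -> ExperimentPlan:
    """Stand-alone desalting run: 100 mM Tris feed, conductivity only."""
    return ExperimentPlan((Section(100.0, 0.0, n_cycles),), seed=seed)


def default_feed_species(tris_mM: float = 100.0, mb_gL: float = 0.2) -> list[SpeciesParams]:
    """Tris (pore-permeating) and myoglobin (excluded) on the desalting resin."""
    return [
        SpeciesParams("tris", 121.14, pore_access=1.0, feed_conc=tris_mM),
        SpeciesParams("mb", 17566.0, pore_access=0.0, feed_conc=mb_gL),
    ]


# ---------------------------------------------------------------------------
# run generation


@dataclass
class MSProducts:
    """Streaming MS detector output of one run."""

    xics: dict[str, Chromatogram]
    baseline: Chromatogram
    switch_spectra: list[Spectrum]  # per-switch mean spectra
    switch_times: np.ndarray  # boundaries, len = n_switches + 1
    scan_interval: float
    series: Optional[ScanSeries] = None

    def switch_reconstructions(self) -> list[ReconSpectrum]:
        return [reconstruct_protein(s) for s in self.switch_spectra]


@dataclass
class RunBundle:
    """Everything one synthetic experiment produced."""

    plan: ExperimentPlan
    config: SMBConfig
    smb: SMBResult  # concatenated over sections
    section_results: list[SMBResult]
    section_boundaries: np.ndarray
    conductivity: dict[str, Chromatogram]
    ms: Optional[MSProducts]
    ground_truth: pd.DataFrame


def _concat_results(parts: list[SMBResult], cfg: SMBConfig) -> SMBResult:
    def cat(stream: str) -> Chromatogram:
        times, concs = [], []
        for i, p in enumerate(parts):
            ch = getattr(p, stream)
            sel = slice(None) if i == len(parts) - 1 else slice(None, -1)
            times.append(ch.time[sel])
            concs.append(ch.conc[sel])
        return Chromatogram(np.concatenate(times), np.concatenate(concs), parts[0].extract.species)

    return SMBResult(
        extract=cat("extract"),
        raffinate=cat("raffinate"),
        waste=cat("waste"),
        switch_boundaries=np.unique(np.concatenate([p.switch_boundaries for p in parts])),
        cycle_boundaries=np.unique(np.concatenate([p.cycle_boundaries for p in parts])),
        config=cfg,
        final_states=parts[-1].final_states,
        column_order=sum((p.column_order or [] for p in parts), []),
    )


def generate_run(
    plan: ExperimentPlan,
    cfg: SMBConfig = PAPER_RUN,
    col: ColumnParams | Sequence[ColumnParams] | None = None,
    models: Optional[dict[str, MSSpeciesModel]] = None,
    suppression: Optional[SuppressionModel] = None,
    with_ms: bool = True,
    scan_interval: float = 0.25,
    mz_step: float = 0.01,
    sample_dt: float = 1.0,
    store_scans: bool = False,
) -> RunBundle:
    """Generate one complete experiment from a plan.

    Column states carry over between sections (the process keeps running
    while the feed bottle is exchanged) and MS acquisition is continuous
    over the whole run. ``scan_interval`` / ``mz_step`` default to the
    instrument values (0.25 s, 0.01 m/z); coarser values trade detector
    resolution for speed on long runs.
    """
    ss = np.random.SeedSequence(plan.seed)
    rng_cond, rng_ms, rng_col = [np.random.default_rng(s) for s in ss.spawn(3)]
    if col is None:
        # four real columns are never packed identically; the ±1% porosity
        # spread reproduces the every-fourth-peak-comparable pattern
        col = heterogeneous_columns(ColumnParams(), spread=0.01, seed=rng_col)

    # --- chained SMB sections -------------------------------------------
    parts: list[SMBResult] = []
    states: Optional[list[ColumnState]] = None
    t0, s0 = 0.0, 0
    truth_rows = []
    bounds = [0.0]
    for i, sec in enumerate(plan.sections):
        species = default_feed_species(sec.tris_feed_mM, sec.mb_feed_gL)
        res = simulate_smb(
            cfg,
            col,
            species,
            n_cycles=sec.n_cycles,
            initial_states=states,
            sample_dt=sample_dt,
            start_time=t0,
            start_switch=s0,
        )
        parts.append(res)
        states = res.final_states
        t0 = res.raffinate.time[-1]
        s0 += sec.n_cycles * cfg.n_columns
        bounds.append(t0)
        truth_rows.append(
            pd.DataFrame(
                {
                    "time_s": res.raffinate.time,
                    "section": i,
                    "tris_feed_mM": sec.tris_feed_mM,
                    "mb_feed_gL": sec.mb_feed_gL,
                    "tris_raffinate_mM": res.raffinate.trace("tris"),
                    "mb_raffinate_gL": res.raffinate.trace("mb"),
                    "tris_extract_mM": res.extract.trace("tris"),
                }
            )
        )
    smb = _concat_results(parts, cfg)
    truth = pd.concat(truth_rows, ignore_index=True).drop_duplicates("time_s")

    conductivity = {
        "extract": generate_conductivity_trace(
            smb, EXTRACT_CAL, "extract", noise_sd=plan.conductivity_noise_sd, rng=rng_cond
        ),
        "raffinate": generate_conductivity_trace(
            smb, RAFFINATE_CAL, "raffinate", noise_sd=plan.conductivity_noise_sd, rng=rng_cond
        ),
    }

    ms_products = None
    if with_ms:
        ms_products = _render_ms(
            smb,
            plan,
            models or default_species_models(),
            suppression or SuppressionModel(),
            rng_ms,
            scan_interval,
            mz_step,
            store_scans,
        )

    return RunBundle(
        plan=plan,
        config=cfg,
        smb=smb,
        section_results=parts,
        section_boundaries=np.asarray(bounds),
        conductivity=conductivity,
        ms=ms_products,
        ground_truth=truth,
    )


def _render_ms(
    smb: SMBResult,
    plan: ExperimentPlan,
    models: dict[str, MSSpeciesModel],
    suppression: SuppressionModel,
    rng: np.random.Generator,
    scan_interval: float,
    mz_step: float,
    store_scans: bool,
) -> MSProducts:
    """Stream scans over the raffinate trace and fold them into products."""
    raff = smb.raffinate
    interp = raff.interpolator()
    t_end = raff.time[-1]
    scan_times = np.arange(0.0, t_end + 1e-9, scan_interval)
    mz = mz_grid(mz_step)

    xic_centers = {
        "tris": TRIS_MZ,
        "heme": HEME_MZ,
        "holo_main": charge_mz(models["holo"].neutral_mass, 8),
        "apo_main": charge_mz(models["apo"].neutral_mass, 8),
    }
    windows = {
        name: np.searchsorted(mz, [c - 0.02, c + 0.02 + 1e-12]) for name, c in xic_centers.items()
    }
    b0, b1 = np.searchsorted(mz, [BASELINE_RANGE[0], BASELINE_RANGE[1] + 1e-12])

    switch_times = smb.switch_boundaries
    n_switches = len(switch_times) - 1
    mean_acc = np.zeros((n_switches, mz.size))
    mean_cnt = np.zeros(n_switches, dtype=int)
    xic_vals = {name: np.empty(scan_times.size) for name in xic_centers}
    base_vals = np.empty(scan_times.size)
    dense = np.empty((scan_times.size, mz.size), dtype=np.float32) if store_scans else None

    comps = interp(scan_times)
    i_species = {name: raff.species.index(name) for name in raff.species}
    apo_f = plan.apo_fraction
    noise = plan.ms_noise_scale
    events = plan.flow_stop_events

    for i, t in enumerate(scan_times):
        mb = comps[i, i_species["mb"]]
        comp = {
            "tris": comps[i, i_species["tris"]],
            "holo": (1.0 - apo_f) * mb,
            "apo": apo_f * mb,
            "heme": apo_f * mb,
        }
        stopped = any(t0 <= t < t0 + d for t0, d in events)
        if stopped:
            comp = {k: 0.0 for k in comp}
        spec = synthesize_spectrum(
            comp,
            models,
            suppression,
            rng=rng if noise > 0 else None,
            noise_scale=noise,
            mz=mz,
        )
        intens = spec.intensity
        for name, (i0, i1) in windows.items():
            xic_vals[name][i] = intens[i0:i1].sum()
        base_vals[i] = intens[b0:b1].sum()
        k = min(np.searchsorted(switch_times, t, side="right") - 1, n_switches - 1)
        if k >= 0:
            mean_acc[k] += intens
            mean_cnt[k] += 1
        if dense is not None:
            dense[i] = intens

    mean_cnt = np.maximum(mean_cnt, 1)
    switch_spectra = [Spectrum(mz, mean_acc[k] / mean_cnt[k]) for k in range(n_switches)]
    xics = {
        name: Chromatogram(scan_times, xic_vals[name], [f"xic_{name}"]) for name in xic_centers
    }
    series = ScanSeries(scan_times, mz, dense) if dense is not None else None
    return MSProducts(
        xics=xics,
        baseline=Chromatogram(scan_times, base_vals, ["baseline"]),
        switch_spectra=switch_spectra,
        switch_times=switch_times,
        scan_interval=scan_interval,
        series=series,
    )
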