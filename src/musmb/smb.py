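"""Four-zone open-loop SMB: triangle-theory design, simulation, CSS metrics.

Topology (open loop, one column per zone): fresh diluent enters zone 1;
the extract is drawn between zones 1 and 2; the feed is mixed in between
zones 2 and 3; the raffinate is drawn between zones 3 and 4; the zone-4
outlet goes to waste — nothing is recycled. Every ``switching_time``
seconds the columns advance one zone upstream (equivalently the ports
move one column downstream), producing the time-discrete countercurrent
contact between solid and mobile phase.

For a linear SEC system the per-zone flow-rate ratio

    m_j = (Q_j · t_switch - V·ε_int) / (V·(1-ε_int))

compares fluid movement per switch with the solid-equivalent movement;
the feasible separation region in the (m2, m3) plane is the triangle
bounded by the two "Henry" coefficients H_i = ε_p·K_d,i.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .column import Chromatogram, ColumnState, simulate_column
from .exceptions import (
    InconsistentConfigError,
    InfeasibleFlowError,
    InsufficientDataError,
    NoSeparationRegionError,
)
from .transport import ColumnParams, SpeciesParams

__all__ = [
    "SMBConfig",
    "OperatingPoint",
    "SMBResult",
    "ProcessMetrics",
    "PAPER_RUN",
    "solve_raffinate_flow",
    "zone_flows",
    "flow_ratio",
    "henry_coefficient",
    "triangle_design",
    "simulate_smb",
    "detect_css",
    "detect_css_trace",
    "desalting_level",
    "process_metrics",
    "heterogeneous_columns",
]

N_ZONES = 4


def solve_raffinate_flow(
    diluent: float, extract: float, feed: float, waste: float
) -> float:
    """Raffinate flow from the overall liquid mass balance, µL/min.

    In the hyphenated setup the raffinate outlet feeds the ESI source and
    cannot be pressure-controlled directly; its flow follows from
    diluent + feed - extract - waste.
    """
    for name, v in (("diluent", diluent), ("extract", extract), ("feed", feed), ("waste", waste)):
        if v < 0:
            raise ValueError(f"{name} flow must be nonnegative")
    raff = diluent + feed - extract - waste
    if raff < 0:
        raise InfeasibleFlowError(
            f"overall balance gives negative raffinate flow ({raff:.3f} µL/min)"
        )
    return raff


@dataclass(frozen=True)
class SMBConfig:
    """Stream flow rates (µL/min) and switching time of the open-loop SMB."""

    diluent_flow: float
    extract_flow: float
    feed_flow: float
    raffinate_flow: float
    waste_flow: float
    switching_time: float
    n_zones: int = N_ZONES
    columns_per_zone: int = 1
    open_loop: bool = True

    def __post_init__(self) -> None:
        if self.switching_time <= 0:
            raise ValueError("switching_time must be positive")
        if self.n_zones != N_ZONES or self.columns_per_zone != 1:
            raise ValueError("only the four-zone, one-column-per-zone layout is supported")
        if not self.open_loop:
            raise ValueError("only the open-loop topology is supported")
        balance = self.diluent_flow + self.feed_flow - (
            self.extract_flow + self.raffinate_flow + self.waste_flow
        )
        if abs(balance) > 1e-9:
            raise InconsistentConfigError(
                f"overall flow balance violated by {balance:.3g} µL/min"
            )

    @property
    def n_columns(self) -> int:
        return self.n_zones * self.columns_per_zone

    @property
    def cycle_time(self) -> float:
        return self.n_columns * self.switching_time


#: Operating point of the desalting study: printed stream flows and
#: switching time of the experimental runs.
PAPER_RUN = SMBConfig(
    diluent_flow=122.0,
    extract_flow=44.0,
    feed_flow=15.0,
    raffinate_flow=30.0,
    waste_flow=63.0,
    switching_time=120.0,
)


def zone_flows(cfg: SMBConfig) -> tuple[float, float, float, float]:
    """Zone flow rates Q1..Q4 (µL/min) from node balances.

    Q1 = diluent; Q2 = Q1 - extract; Q3 = Q2 + feed; Q4 = Q3 - raffinate;
    the open-loop topology requires Q4 = waste.
    """
    q1 = cfg.diluent_flow
    q2 = q1 - cfg.extract_flow
    q3 = q2 + cfg.feed_flow
    q4 = q3 - cfg.raffinate_flow
    if abs(q4 - cfg.waste_flow) > 1e-9:
        raise InconsistentConfigError(
            f"zone-4 flow {q4:.4f} µL/min does not match waste flow {cfg.waste_flow:.4f}"
        )
    for j, q in enumerate((q1, q2, q3, q4), start=1):
        if q <= 0:
            raise InfeasibleFlowError(f"zone {j} flow is nonpositive ({q:.3f} µL/min)")
    return q1, q2, q3, q4


def flow_ratio(flow_ul_min: float, t_switch_s: float, col: ColumnParams) -> float:
    """Flow-rate ratio m_j of triangle theory (dimensionless)."""
    v = col.volume_ul
    eps = col.interstitial_porosity
    return (flow_ul_min / 60.0 * t_switch_s - v * eps) / (v * (1.0 - eps))


def _flow_from_ratio(m: float, t_switch_s: float, col: ColumnParams) -> float:
    v = col.volume_ul
    eps = col.interstitial_porosity
    return (m * v * (1.0 - eps) + v * eps) / t_switch_s * 60.0


def henry_coefficient(col: ColumnParams, species: SpeciesParams) -> float:
    """Linear SEC retention coefficient H = ε_p·K_d in the m-convention."""
    return col.particle_porosity * species.pore_access


@dataclass(frozen=True)
class OperatingPoint:
    """Flow-rate ratios and the zone / stream flows they imply."""

    m1: float
    m2: float
    m3: float
    m4: float
    q1: float
    q2: float
    q3: float
    q4: float
    switching_time: float

    @property
    def config(self) -> SMBConfig:
        return SMBConfig(
            diluent_flow=self.q1,
            extract_flow=self.q1 - self.q2,
            feed_flow=self.q3 - self.q2,
            raffinate_flow=self.q3 - self.q4,
            waste_flow=self.q4,
            switching_time=self.switching_time,
        )


def triangle_design(
    col: ColumnParams,
    weak: SpeciesParams,
    strong: SpeciesParams,
    t_switch_s: float,
    raffinate_target: float = 30.0,
    safety: float = 0.1,
) -> OperatingPoint:
    """Place an operating point inside the linear-isotherm triangle.

    ``weak`` is the less retained species (collected in the raffinate,
    here the protein), ``strong`` the more retained one (the buffer salt,
    to the extract). With H_i = ε_p·K_d,i the complete-separation
    constraints are m1 > H_strong, H_weak < m2 < m3 < H_strong,
    m4 < H_weak. The point is placed at the triangle vertex shrunk by
    ``safety``: m2 and m3 symmetric inside (H_weak, H_strong); m1 above
    H_strong, m4 below H_weak by the same relative margin. Zone 4 is
    then adjusted so the raffinate flow hits ``raffinate_target``
    (fixed because it feeds the ESI source at constant rate).
    """
    if not 0.0 <= safety < 0.5:
        raise ValueError("safety must lie in [0, 0.5)")
    h_weak = henry_coefficient(col, weak)
    h_strong = henry_coefficient(col, strong)
    if h_weak >= h_strong:
        raise NoSeparationRegionError(
            f"no separation region: H({weak.name})={h_weak:.3f} >= H({strong.name})={h_strong:.3f}"
        )
    span = h_strong - h_weak
    m1 = h_strong * (1.0 + safety) if h_strong > 0 else safety * span
    m2 = h_weak + safety * span
    m3 = h_strong - safety * span
    q1 = _flow_from_ratio(m1, t_switch_s, col)
    q2 = _flow_from_ratio(m2, t_switch_s, col)
    q3 = _flow_from_ratio(m3, t_switch_s, col)
    q4 = q3 - raffinate_target
    if q4 <= 0:
        raise InfeasibleFlowError(
            f"raffinate target {raffinate_target} µL/min exceeds zone-3 flow {q3:.2f}"
        )
    m4 = flow_ratio(q4, t_switch_s, col)
    m4_max = h_weak * (1.0 - safety) if h_weak > 0 else -safety * span
    if m4 > m4_max:
        raise InfeasibleFlowError(
            f"zone-4 ratio m4={m4:.3f} exceeds the regeneration bound {m4_max:.3f}; "
            "increase the raffinate target or the switching time"
        )
    point = OperatingPoint(m1, m2, m3, m4, q1, q2, q3, q4, t_switch_s)
    point.config  # validates positivity of every stream flow
    return point


@dataclass
class SMBResult:
    """Outlet traces of a multi-cycle SMB run on a common time grid."""

    extract: Chromatogram
    raffinate: Chromatogram
    waste: Chromatogram
    switch_boundaries: np.ndarray
    cycle_boundaries: np.ndarray
    config: SMBConfig
    css_cycle: Optional[int] = None
    final_states: Optional[list[ColumnState]] = None
    column_order: Optional[list[list[int]]] = None

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_boundaries) - 1

    def cycle_slice(self, k: int, stream: str = "raffinate") -> Chromatogram:
        """Traces of cycle ``k`` (0-based), time re-referenced to the cycle start."""
        chrom: Chromatogram = getattr(self, stream)
        t0, t1 = self.cycle_boundaries[k], self.cycle_boundaries[k + 1]
        mask = (chrom.time >= t0 - 1e-9) & (chrom.time < t1 - 1e-9)
        return Chromatogram(chrom.time[mask] - t0, chrom.conc[mask], list(chrom.species))


def heterogeneous_columns(
    col: ColumnParams,
    n_columns: int = N_ZONES,
    spread: float = 0.01,
    seed: Optional[int] = None,
) -> list[ColumnParams]:
    """Per-column multiplicative porosity perturbations (packing variation).

    Each physical column gets ε_int and ε_p scaled by independent factors
    drawn uniformly from [1-spread, 1+spread]; this reproduces the
    experimental pattern that only every ``n_columns``-th raffinate peak
    is directly comparable.
    """
    rng = np.random.default_rng(seed)
    cols = []
    for _ in range(n_columns):
        f_int, f_p = rng.uniform(1.0 - spread, 1.0 + spread, size=2)
        cols.append(col.perturbed(f_int, f_p))
    return cols


def simulate_smb(
    cfg: SMBConfig,
    col: ColumnParams | Sequence[ColumnParams],
    species: Sequence[SpeciesParams],
    feed_conc: Optional[Sequence[float]] = None,
    n_cycles: int = 5,
    initial_states: Optional[list[ColumnState]] = None,
    sample_dt: float = 1.0,
    start_time: float = 0.0,
    start_switch: int = 0,
    css_tol: float = 1e-2,
) -> SMBResult:
    """Simulate ``n_cycles`` full cycles of the open-loop SMB.

    Within one switching interval the four columns are solved in series —
    the open loop has no feedback, so sequential integration with the
    upstream outlet interpolated as downstream inlet is exact up to the
    sampling grid. At the feed node concentrations mix as
    ``c = (Q2·c_z2 + Q_F·c_F)/Q3``; draw nodes split flow at equal
    concentration. After each interval the columns advance one zone
    upstream. Column states persist, so runs can be chained by passing
    ``initial_states`` / ``start_time`` / ``start_switch`` from a
    previous result.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    species = list(species)
    names = [sp.name for sp in species]
    if feed_conc is None:
        feed_conc = np.array([sp.feed_conc for sp in species], dtype=float)
    feed_conc = np.asarray(feed_conc, dtype=float)

    cols = list(col) if isinstance(col, (list, tuple)) else [col] * N_ZONES
    if len(cols) != N_ZONES:
        raise ValueError("need one ColumnParams per column (4)")
    q = zone_flows(cfg)

    if initial_states is None:
        states = [ColumnState.empty(c.n_cells, names) for c in cols]
    else:
        states = [s.copy() for s in initial_states]

    t_sw = cfg.switching_time
    n_switches = n_cycles * cfg.n_columns
    # per-switch local grid; boundaries shared between switches
    n_pts = max(2, int(round(t_sw / sample_dt)))
    local_t = np.linspace(0.0, t_sw, n_pts + 1)

    times, ext, raf, was = [], [], [], []
    column_order: list[list[int]] = []
    for s in range(start_switch, start_switch + n_switches):
        # physical column sitting in zone j (position j-1) at switch s
        order = [(j + s) % N_ZONES for j in range(N_ZONES)]
        column_order.append(order)
        t0 = start_time + (s - start_switch) * t_sw

        zone_out: list[Chromatogram] = []
        inlet: object = None  # zone 1 sees clean diluent
        for j in range(N_ZONES):
            c_idx = order[j]
            if j == 2:
                # feed node mixes zone-2 outlet with fresh feed
                up = zone_out[1]
                mixed = (q[1] * up.conc + cfg.feed_flow * feed_conc[None, :]) / q[2]
                inlet = Chromatogram(up.time, mixed, names)
            elif j > 0:
                inlet = zone_out[j - 1]
            chrom, states[c_idx] = simulate_column(
                cols[c_idx],
                species,
                inlet,
                q[j],
                t_sw,
                initial=states[c_idx],
                sample_dt=local_t[1] - local_t[0],
            )
            zone_out.append(chrom)

        sel = slice(None) if s == start_switch + n_switches - 1 else slice(None, -1)
        times.append(t0 + local_t[sel])
        ext.append(zone_out[0].conc[sel])
        raf.append(zone_out[2].conc[sel])
        was.append(zone_out[3].conc[sel])

    time = np.concatenate(times)
    result = SMBResult(
        extract=Chromatogram(time, np.concatenate(ext), names),
        raffinate=Chromatogram(time, np.concatenate(raf), names),
        waste=Chromatogram(time, np.concatenate(was), names),
        switch_boundaries=start_time + t_sw * np.arange(n_switches + 1),
        cycle_boundaries=start_time + cfg.cycle_time * np.arange(n_cycles + 1),
        config=cfg,
        final_states=states,
        column_order=column_order,
    )
    if n_cycles >= 2:
        try:
            result.css_cycle = detect_css(result, tol=css_tol)
        except InsufficientDataError:
            result.css_cycle = None
    return result


def detect_css_trace(
    time: np.ndarray, values: np.ndarray, cycle_time: float, tol: float = 1e-2
) -> Optional[int]:
    """CSS detection on a bare outlet trace.

    Splits the trace into cycles of ``cycle_time`` and returns the
    smallest 1-based cycle index k >= 2 with
    ``||p_k - p_{k-1}||_2 / ||p_k||_2 < tol``, or None.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    t0 = time[0]
    # a cycle is complete when sampled up to its last grid point
    dt = float(time[1] - time[0]) if time.size > 1 else 0.0
    n_cycles = int(np.floor((time[-1] - t0 + dt) / cycle_time + 1e-9))
    if n_cycles < 2:
        raise InsufficientDataError("need at least 2 completed cycles to detect CSS")
    profiles = []
    for k in range(n_cycles):
        mask = (time >= t0 + k * cycle_time - 1e-9) & (time < t0 + (k + 1) * cycle_time - 1e-9)
        profiles.append(values[mask].ravel())
    n = min(p.size for p in profiles)
    for k in range(1, n_cycles):
        cur, prev = profiles[k][:n], profiles[k - 1][:n]
        denom = np.linalg.norm(cur)
        if denom == 0.0:
            if np.linalg.norm(prev) == 0.0:
                return k + 1
            continue
        if np.linalg.norm(cur - prev) / denom < tol:
            return k + 1
    return None


def detect_css(
    result: SMBResult,
    tol: float = 1e-2,
    stream: str = "raffinate",
    species: Optional[str] = None,
) -> Optional[int]:
    """First cycle whose profile repeats the previous one within ``tol``.

    Returns the smallest 1-based cycle index k >= 2 with
    ``||p_k - p_{k-1}||_2 / ||p_k||_2 < tol`` on the chosen stream
    profile, or None if cyclic steady state is not reached.
    """
    if result.n_cycles < 2:
        raise InsufficientDataError("need at least 2 completed cycles to detect CSS")
    chrom: Chromatogram = getattr(result, stream)
    values = chrom.trace(species)[:, None] if species else chrom.conc
    return detect_css_trace(chrom.time, values, result.config.cycle_time, tol)


def desalting_level(mean_raffinate_conc: float, feed_conc: float) -> float:
    """Desalting level 1 - c_raffinate/c_feed (fraction in [0, 1])."""
    if feed_conc <= 0:
        raise ValueError("feed concentration must be positive")
    if mean_raffinate_conc < 0:
        raise ValueError("raffinate concentration must be nonnegative")
    if mean_raffinate_conc > feed_conc:
        import warnings

        warnings.warn(
            "raffinate concentration exceeds feed concentration; clamping "
            "desalting level to 0",
            stacklevel=2,
        )
        return 0.0
    return 1.0 - mean_raffinate_conc / feed_conc


@dataclass(frozen=True)
class ProcessMetrics:
    """CSS performance summary of one SMB run."""

    css_cycle: Optional[int]
    desalting_level: float
    protein_recovery_raffinate: float
    mean_raffinate_conc: dict[str, float]


def process_metrics(
    result: SMBResult,
    species: Sequence[SpeciesParams],
    salt: str = "tris",
    protein: str = "mb",
    feed_conc: Optional[Sequence[float]] = None,
) -> ProcessMetrics:
    """Compute CSS-averaged desalting level and protein recovery.

    Means are taken over completed cycles at / after the detected CSS
    ('the' desalting level of a continuous process is a property of the
    repeating state, not of the startup transient). Recovery is the mass
    flow of protein leaving in the raffinate over the mass flow fed.
    """
    species = list(species)
    names = [sp.name for sp in species]
    if feed_conc is None:
        feed_conc = np.array([sp.feed_conc for sp in species], dtype=float)
    feed_conc = np.asarray(feed_conc, dtype=float)
    css = result.css_cycle if result.css_cycle is not None else detect_css(result)
    if css is None:
        raise InsufficientDataError("cyclic steady state not reached; metrics undefined")
    raff = result.raffinate
    t0 = result.cycle_boundaries[css - 1]
    mask = raff.time >= t0 - 1e-9
    t = raff.time[mask]
    means = {
        name: float(np.trapezoid(raff.conc[mask, j], t) / (t[-1] - t[0]))
        for j, name in enumerate(names)
    }
    level = desalting_level(means[salt], float(feed_conc[names.index(salt)]))
    fed = result.config.feed_flow * float(feed_conc[names.index(protein)])
    out = result.config.raffinate_flow * means[protein]
    recovery = out / fed if fed > 0 else float("nan")
    return ProcessMetrics(
        css_cycle=css,
        desalting_level=level,
        protein_recovery_raffinate=min(recovery, 1.0) if np.isfinite(recovery) else recovery,
        mean_raffinate_conc=means,
    )
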