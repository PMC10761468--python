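"""Single-column SEC simulation with the lumped rate model with pores (LRMP).

The model resolves, per species ``i``, a bulk (interstitial) phase with
convection, axial dispersion and film mass transfer into a well-mixed pore
phase, without adsorption — the separation is purely entropic size
exclusion carried by the distribution coefficient ``K_d``:

    bulk:  dc/dt  = -u_int dc/dz + D_ax d2c/dz2
                    - (1-e_int)/e_int * (3/r_p) * k_film * (c - c_p)
    pore:  e_p K_d dc_p/dt = (3/r_p) * k_film * (c - c_p)

A fully excluded species (``K_d = 0``) has no pore phase at all; the
exchange term is dropped rather than made singular.

Discretisation is finite volume with first-order upwind convection and
central dispersion, Danckwerts (flux) inlet and zero-gradient outlet
boundary conditions, integrated in time with LSODA on a banded Jacobian.
Species do not interact, so each is integrated separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import EstimationError, IntegrationError, UndefinedMomentError
from .transport import (
    ColumnParams,
    FluidProps,
    SpeciesParams,
    WATER_20C,
    axial_dispersion,
    film_transfer,
    interstitial_velocity,
)

__all__ = [
    "Chromatogram",
    "ColumnState",
    "simulate_column",
    "pulse_experiment",
    "first_moment",
    "estimate_porosities",
]

# Species with K_d * e_p below this hold no measurable pore volume and are
# treated as fully excluded (pore phase dropped).
_KD_EXCLUDED = 1e-9


@dataclass
class Chromatogram:
    """Concentration traces on a uniform time grid.

    ``conc`` has shape ``(n_times, n_species)``; column order follows
    ``species``. Units are whatever the feed was declared in (the model
    is linear, so units pass through).
    """

    time: np.ndarray
    conc: np.ndarray
    species: list[str]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.conc.ndim == 1:
            self.conc = self.conc[:, None]
        if self.conc.shape[0] != self.time.size:
            raise ValueError("time and conc length mismatch")
        if self.conc.shape[1] != len(self.species):
            raise ValueError("species list does not match conc columns")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.conc))):
            raise ValueError("chromatogram contains non-finite values")

    def trace(self, species: str) -> np.ndarray:
        return self.conc[:, self.species.index(species)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.time})
        for j, name in enumerate(self.species):
            df[name] = self.conc[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Chromatogram":
        names = [c for c in df.columns if c != "time_s"]
        return cls(df["time_s"].to_numpy(), df[names].to_numpy(), names)

    def interpolator(self) -> Callable[[np.ndarray], np.ndarray]:
        """Linear interpolant t -> (n_species,) clamped to 0 outside the grid."""
        t, c = self.time, self.conc

        def f(tq):
            tq = np.atleast_1d(np.asarray(tq, dtype=float))
            out = np.empty((tq.size, c.shape[1]))
            for j in range(c.shape[1]):
                out[:, j] = np.interp(tq, t, c[:, j], left=0.0, right=0.0)
            return out

        return f


@dataclass
class ColumnState:
    """Axial concentration profiles of one column, per species.

    ``bulk`` and ``pore`` have shape ``(n_species, n_cells)``; the pore
    rows of fully excluded species stay zero.
    """

    bulk: np.ndarray
    pore: np.ndarray
    species: list[str]

    @classmethod
    def empty(cls, n_cells: int, species: Sequence[str]) -> "ColumnState":
        n = len(list(species))
        return cls(np.zeros((n, n_cells)), np.zeros((n, n_cells)), list(species))

    def copy(self) -> "ColumnState":
        return ColumnState(self.bulk.copy(), self.pore.copy(), list(self.species))

    def holdup(self, col: ColumnParams, species: Sequence[SpeciesParams]) -> np.ndarray:
        """Mass held in the column per species, in (conc unit)·µL."""
        eps = col.interstitial_porosity
        v_ul = col.volume_ul
        out = np.empty(len(self.species))
        for i, sp in enumerate(species):
            cap = (1.0 - eps) * col.particle_porosity * sp.pore_access
            out[i] = v_ul * (eps * self.bulk[i].mean() + cap * self.pore[i].mean())
        return out


InletLike = Union[None, float, np.ndarray, Callable[[float], np.ndarray], Chromatogram]


def _inlet_functions(inlet: InletLike, n_species: int) -> list[Callable[[float], float]]:
    """Normalise the many accepted inlet forms to one scalar function per species."""
    if inlet is None:
        return [lambda t: 0.0] * n_species
    if isinstance(inlet, Chromatogram):
        t, c = inlet.time, inlet.conc
        return [
            (lambda j: lambda x: float(np.interp(x, t, c[:, j], left=c[0, j], right=c[-1, j])))(j)
            for j in range(n_species)
        ]
    if np.isscalar(inlet):
        v = float(inlet)
        return [lambda t, v=v: v] * n_species
    if isinstance(inlet, np.ndarray) or isinstance(inlet, (list, tuple)):
        vals = np.asarray(inlet, dtype=float)
        return [(lambda v: lambda t: float(v))(vals[j]) for j in range(n_species)]
    if callable(inlet):
        return [(lambda j: lambda t: float(np.asarray(inlet(t)).ravel()[j]))(j) for j in range(n_species)]
    raise TypeError(f"unsupported inlet type: {type(inlet)!r}")


def _integrate_species(
    c0: np.ndarray,
    cp0: np.ndarray,
    has_pore: bool,
    cin: Callable[[float], float],
    u: float,
    d_ax: float,
    kappa: float,
    phi: float,
    cap: float,
    dz: float,
    t_eval: np.ndarray,
    rtol: float,
    atol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate one species; returns (bulk profiles, pore profiles, outlet trace)."""
    n = c0.size

    if has_pore:
        # interleaved [c0, cp0, c1, cp1, ...] keeps the Jacobian banded
        y0 = np.empty(2 * n)
        y0[0::2] = c0
        y0[1::2] = cp0
        band = 2
    else:
        y0 = c0.copy()
        band = 1

    inv_dz = 1.0 / dz
    d_over_dz = d_ax * inv_dz

    def rhs(t, y):
        if has_pore:
            c = y[0::2]
            cp = y[1::2]
        else:
            c = y
        flux = np.empty(n + 1)
        flux[0] = u * cin(t)  # Danckwerts: total inlet flux prescribed
        flux[1:-1] = u * c[:-1] - d_over_dz * (c[1:] - c[:-1])
        flux[-1] = u * c[-1]  # zero outlet gradient
        dc = (flux[:-1] - flux[1:]) * inv_dz
        if has_pore:
            ex = kappa * (c - cp)
            dc -= phi * ex
            dy = np.empty_like(y)
            dy[0::2] = dc
            dy[1::2] = ex / cap
            return dy
        return dc

    sol = solve_ivp(
        rhs,
        (t_eval[0], t_eval[-1]),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        lband=band,
        uband=band,
    )
    if not sol.success:
        raise IntegrationError(
            f"column integration failed at t={sol.t[-1] if sol.t.size else t_eval[0]:.3f} s: "
            f"{sol.message}"
        )
    if has_pore:
        bulk = sol.y[0::2, :]
        pore = sol.y[1::2, :]
    else:
        bulk = sol.y
        pore = np.zeros_like(bulk)
    outlet = bulk[-1, :]
    return bulk[:, -1], pore[:, -1], outlet


def simulate_column(
    col: ColumnParams,
    species: Sequence[SpeciesParams],
    inlet: InletLike,
    flow_rate_ul_min: float,
    duration_s: float,
    initial: Optional[ColumnState] = None,
    fluid: FluidProps = WATER_20C,
    sample_dt: float = 0.5,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> tuple[Chromatogram, ColumnState]:
    """Simulate one column over ``duration_s`` and return (outlet, final state).

    ``inlet`` may be None (clean buffer), a constant per-species vector, a
    callable ``t -> (n_species,)`` or a :class:`Chromatogram` from an
    upstream column. The outlet trace is sampled every ``sample_dt``
    seconds; ``col.dead_time_s`` is applied as a pure transport delay on
    the outlet.
    """
    if flow_rate_ul_min <= 0:
        raise ValueError("flow_rate must be positive")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    species = list(species)
    names = [sp.name for sp in species]
    n = col.n_cells
    if initial is None:
        initial = ColumnState.empty(n, names)
    if initial.bulk.shape != (len(species), n):
        raise ValueError("initial state shape does not match species/n_cells")

    u = interstitial_velocity(flow_rate_ul_min, col)
    d_ax = axial_dispersion(u, col, fluid)
    dz = col.length / n
    eps = col.interstitial_porosity
    phi = (1.0 - eps) / eps

    n_steps = max(2, int(round(duration_s / sample_dt)))
    t_eval = np.linspace(0.0, duration_s, n_steps + 1)

    cin_fns = _inlet_functions(inlet, len(species))
    # negative inlet concentrations are unphysical
    for fn in cin_fns:
        probe = min(fn(0.0), fn(0.5 * duration_s), fn(duration_s))
        if probe < -1e-12:
            raise ValueError("inlet concentrations must be nonnegative")

    bulk_f = np.empty_like(initial.bulk)
    pore_f = np.empty_like(initial.pore)
    outlet = np.empty((t_eval.size, len(species)))
    for i, sp in enumerate(species):
        cap = col.particle_porosity * sp.pore_access
        has_pore = cap > _KD_EXCLUDED
        kappa = 3.0 * film_transfer(sp, u, col) / col.particle_radius if has_pore else 0.0
        bulk_f[i], pore_f[i], out = _integrate_species(
            initial.bulk[i],
            initial.pore[i],
            has_pore,
            cin_fns[i],
            u,
            d_ax,
            kappa,
            phi,
            cap,
            dz,
            t_eval,
            rtol,
            atol,
        )
        outlet[:, i] = out

    if col.dead_time_s > 0:
        shifted = np.empty_like(outlet)
        for i in range(outlet.shape[1]):
            shifted[:, i] = np.interp(
                t_eval - col.dead_time_s, t_eval, outlet[:, i], left=0.0, right=outlet[-1, i]
            )
        outlet = shifted

    # report nonnegative concentrations; the integrator state keeps its
    # small signed oscillations so chained solves stay consistent
    chrom = Chromatogram(t_eval, np.clip(outlet, 0.0, None), names)
    return chrom, ColumnState(bulk_f, pore_f, names)


def pulse_experiment(
    col: ColumnParams,
    species: Sequence[SpeciesParams],
    inject_volume_ul: float = 2.5,
    inject_conc: Union[float, Sequence[float]] = 1.0,
    flow_rate_ul_min: float = 100.0,
    duration_s: Optional[float] = None,
    **kwargs,
) -> Chromatogram:
    """Rectangular tracer injection fed to :func:`simulate_column`.

    The plug width is ``inject_volume / flow_rate``; duration defaults to
    several retention times of the slowest species so the full peak
    (including tailing) is captured.
    """
    species = list(species)
    if inject_volume_ul <= 0:
        raise ValueError("inject_volume must be positive")
    if inject_volume_ul >= col.volume_ul:
        raise ValueError("inject_volume must be smaller than the column volume")
    conc = np.broadcast_to(np.asarray(inject_conc, dtype=float), (len(species),)).copy()
    t_inj = inject_volume_ul / (flow_rate_ul_min / 60.0)  # s

    if duration_s is None:
        acc = max(col.accessible_porosity(sp.pore_access) for sp in species)
        t_ret = col.volume_ul * acc / (flow_rate_ul_min / 60.0)
        duration_s = col.dead_time_s + t_inj + 4.0 * t_ret

    def inlet(t):
        return conc if t < t_inj else np.zeros_like(conc)

    chrom, _ = simulate_column(col, species, inlet, flow_rate_ul_min, duration_s, **kwargs)
    return chrom


def first_moment(
    chrom: Chromatogram,
    species: Optional[str] = None,
    injection_width_s: float = 0.0,
) -> float:
    """Retention time as the first temporal moment, s.

    ``∫ t·c dt / ∫ c dt`` by trapezoidal quadrature. For a rectangular
    injection of width ``w`` the plug contributes ``w/2`` to the moment;
    pass ``injection_width_s`` to remove that offset.
    """
    if species is None:
        if len(chrom.species) != 1:
            raise ValueError("specify species for a multi-species chromatogram")
        c = chrom.conc[:, 0]
    else:
        c = chrom.trace(species)
    area = np.trapezoid(c, chrom.time)
    if area <= 0:
        raise UndefinedMomentError("trace has zero integral; moment undefined")
    mu = np.trapezoid(chrom.time * c, chrom.time) / area
    return float(mu - 0.5 * injection_width_s)


def estimate_porosities(
    t_acetone_s: float,
    t_dextran_s: float,
    t_system_s: float,
    volume_ul: float,
    flow_rate_ul_min: float,
) -> tuple[float, float, float]:
    """Invert tracer retention times to (ε_int, ε_total, ε_p).

    A fully excluded tracer (blue dextran) probes the interstitial volume,
    a fully permeating one (acetone) the total porosity; both corrected by
    the system contribution measured with a zero-dead-volume connector:

        ε_int   = (t_dextran - t_system)·Q / V
        ε_total = (t_acetone - t_system)·Q / V
        ε_p     = (ε_total - ε_int) / (1 - ε_int)
    """
    if not (t_acetone_s > t_dextran_s > t_system_s):
        raise EstimationError(
            f"tracer times must satisfy t_acetone > t_dextran > t_system, got "
            f"{t_acetone_s}, {t_dextran_s}, {t_system_s}"
        )
    q = flow_rate_ul_min / 60.0  # µL/s
    eps_int = (t_dextran_s - t_system_s) * q / volume_ul
    eps_total = (t_acetone_s - t_system_s) * q / volume_ul
    for label, val in (("interstitial porosity", eps_int), ("total porosity", eps_total)):
        if not 0.0 < val < 1.0:
            raise EstimationError(f"{label} = {val:.4f} outside (0, 1)")
    eps_p = (eps_total - eps_int) / (1.0 - eps_int)
    if not 0.0 < eps_p < 1.0:
        raise EstimationError(f"particle porosity = {eps_p:.4f} outside (0, 1)")
    return eps_int, eps_total, eps_p
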